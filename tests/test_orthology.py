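"""RBH orthology, paralogous families, ortholog clusters and synteny."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gvlineage.align import SimilarityHit, all_vs_all, mirror_hits
from gvlineage.orthology import (
    OrthologPair,
    ParalogFamily,
    Thresholds,
    gene_order,
    ortholog_clusters,
    paralog_families,
    reciprocal_best_hits,
    shared_cluster_proportion,
    synteny_index,
)
from gvlineage.simulate import mutate_protein, random_protein


def _hit(q, s, bits, ident=90.0, ev=1e-30, cov=90.0):
    return SimilarityHit(
        query_id=q, subject_id=s, raw_score=int(bits), bitscore=bits, evalue=ev,
        identity_pct=ident, aln_len=100, mismatch=0, gapopen=0,
        qstart=1, qend=90, sstart=1, send=90, q_cov=cov, s_cov=cov,
    )


class TestRBH:
    def test_identical_proteomes_full_rbh(self, tiny_family):
        _, genomes, _ = tiny_family
        prots = {f.cds_id: f.protein for f in genomes[0].features}
        a = {f"A_{k}": v for k, v in prots.items()}
        b = {f"B_{k}": v for k, v in prots.items()}
        hits = all_vs_all(a, b)
        back = mirror_hits(hits, sum(len(s) for s in a.values()))
        pairs = reciprocal_best_hits(hits, back, "gA", "gB")
        # duplicated paralog copies can swap partners, but the pair count
        # matches the proteome size and all identities are 100
        assert len(pairs) == len(a)
        assert all(p.identity_pct == 100.0 for p in pairs)

    def test_toy_tables_match_exhaustive_enumeration(self):
        # hand-built 5x5 hit tables; the oracle enumerates all candidate
        # pairs and checks mutual-best-ness directly
        hits_ab = [
            _hit("a1", "b1", 500), _hit("a1", "b2", 300),
            _hit("a2", "b2", 400), _hit("a2", "b1", 390),
            _hit("a3", "b3", 200, ident=25.0),  # fails identity threshold
            _hit("a4", "b4", 100, ev=1e-3),  # fails e-value
            _hit("a5", "b5", 90, cov=40.0),  # fails coverage
        ]
        hits_ba = [
            _hit("b1", "a1", 500), _hit("b2", "a2", 400),
            _hit("b2", "a1", 300), _hit("b1", "a2", 390),
            _hit("b3", "a3", 200, ident=25.0),
            _hit("b4", "a4", 100, ev=1e-3),
            _hit("b5", "a5", 90, cov=40.0),
        ]
        thr = Thresholds()
        got = {
            (p.protein_a, p.protein_b)
            for p in reciprocal_best_hits(hits_ab, hits_ba, "A", "B", thr)
        }
        # oracle: brute force over all (a, b) combinations
        tab_ab = {(h.query_id, h.subject_id): h for h in hits_ab if thr.passes(h)}
        tab_ba = {(h.query_id, h.subject_id): h for h in hits_ba if thr.passes(h)}
        expect = set()
        for (a, b), h in tab_ab.items():
            best_a = max(
                (x for (q, _), x in tab_ab.items() if q == a),
                key=lambda x: x.bitscore,
            )
            best_b = max(
                (x for (q, _), x in tab_ba.items() if q == b),
                key=lambda x: x.bitscore,
            )
            if best_a.subject_id == b and best_b.subject_id == a:
                expect.add((a, b))
        assert got == expect == {("a1", "b1"), ("a2", "b2")}

    def test_symmetry_and_cardinality(self, family_run):
        _, genomes, truth, res = family_run
        for (ga, gb), pairs in res.rbh.items():
            na = len(res.proteomes[ga])
            nb = len(res.proteomes[gb])
            assert len(pairs) <= min(na, nb)
            assert len({p.protein_a for p in pairs}) == len(pairs)
            assert len({p.protein_b for p in pairs}) == len(pairs)

    def test_rbh_recovers_true_orthologs(self, family_run):
        # >=95% of truth ortholog pairs recovered at family-level divergence
        _, genomes, truth, res = family_run
        true_pairs = {
            (ga, pa, gb, pb) for ga, pa, gb, pb in truth.ortholog_pairs
        }
        found = set()
        for (ga, gb), pairs in res.rbh.items():
            for p in pairs:
                found.add((ga, p.protein_a, gb, p.protein_b))
                found.add((gb, p.protein_b, ga, p.protein_a))
        hit = sum(1 for t in true_pairs if t in found)
        assert hit / len(true_pairs) >= 0.95

    def test_mismatched_tables_rejected(self):
        # passing the same direction twice mixes the proteome id sets
        with pytest.raises(ValueError):
            reciprocal_best_hits([_hit("x1", "y1", 10)], [_hit("x1", "y1", 10)], "A", "B")


class TestParalogFamilies:
    def test_two_triangles_give_two_families(self):
        hits = []
        for grp in (("p1", "p2", "p3"), ("q1", "q2", "q3")):
            for a, b in itertools.permutations(grp, 2):
                hits.append(_hit(a, b, 200))
        fams = paralog_families(hits, "G")
        assert sorted(sorted(f.members) for f in fams) == [
            ["p1", "p2", "p3"],
            ["q1", "q2", "q3"],
        ]

    def test_no_hits_no_families(self):
        assert paralog_families([], "G") == []

    def test_singletons_are_not_families(self):
        # a hit failing thresholds leaves both proteins unclustered
        fams = paralog_families([_hit("p1", "p2", 10, ident=20.0)], "G")
        assert fams == []

    def test_large_expansion_detected(self):
        # 14 near-identical copies -> one family of 14
        rng = np.random.default_rng(4)
        base = random_protein(200, rng)
        prots = {f"m{i:02d}": mutate_protein(base, 90.0, rng) for i in range(14)}
        hits = all_vs_all(prots, prots, exclude_self=True)
        fams = paralog_families(hits, "G")
        assert len(fams) == 1
        assert len(fams[0].members) == 14

    def test_members_share_qualifying_hits(self, family_run):
        _, _, _, res = family_run
        thr = Thresholds()
        for gid, fams in res.paralogs.items():
            seen = set()
            for f in fams:
                assert len(f.members) >= 2
                assert not (f.members & seen)  # disjoint
                seen |= f.members


class TestOrthologClusters:
    def test_universal_gene_spans_all_lineages(self):
        pairs = [
            OrthologPair("g1", "p1", "g2", "p2", 95.0, 100.0),
            OrthologPair("g2", "p2", "g3", "p3", 95.0, 100.0),
        ]
        cs = ortholog_clusters(pairs, [], {"g1": "A", "g2": "B", "g3": "C"})
        assert len(cs.clusters) == 1
        assert cs.lineage_presence[0] == {"A", "B", "C"}

    def test_zero_rbh_gives_singletons(self):
        cs = ortholog_clusters(
            [], [], {"g1": "A", "g2": "B"},
            all_proteins={"g1": ["p1", "p2"], "g2": ["q1"]},
        )
        assert all(len(c) == 1 for c in cs.clusters)
        assert len(cs.clusters) == 3

    def test_missing_lineage_mapping_raises(self):
        with pytest.raises(KeyError):
            ortholog_clusters(
                [OrthologPair("g1", "p", "gX", "q", 90.0, 50.0)], [], {"g1": "A"}
            )

    def test_within_lineage_sharing_exceeds_between(self, family_run):
        _, _, truth, res = family_run
        cs = res.cluster_set
        part = res.partition
        lineages = part.labels
        multi = [l for l in lineages if len(part.members(l)) >= 2]
        between = [
            shared_cluster_proportion(cs, la, lb)
            for la, lb in itertools.combinations(lineages, 2)
        ]
        for lin in multi:
            ms = set(part.members(lin))
            both = sum(
                1 for c in cs.clusters
                if len({m.split("|")[0] for m in c} & ms) >= 2
            )
            any_ = sum(
                1 for c in cs.clusters if {m.split("|")[0] for m in c} & ms
            )
            assert both / any_ > max(between)


class TestSynteny:
    def _orders(self, n, strands=None):
        strands = strands or ["+"] * n
        return [(f"p{i}", strands[i]) for i in range(n)]

    def _rbh(self, n):
        return [
            OrthologPair("a", f"p{i}", "b", f"p{i}", 99.0, 100.0) for i in range(n)
        ]

    def test_identical_order_scores_one(self):
        oa = self._orders(6)
        assert synteny_index(oa, oa, self._rbh(6)) == 1.0

    def test_full_reversal_scores_one(self):
        oa = self._orders(6)
        ob = [(p, "-" if s == "+" else "+") for p, s in reversed(oa)]
        assert synteny_index(oa, ob, self._rbh(6)) == 1.0

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            synteny_index(self._orders(2), self._orders(2), self._rbh(1))

    def test_inversions_degrade_index_on_average(self):
        rng = np.random.default_rng(0)
        n = 40
        base = self._orders(n)
        means = []
        for n_inv in (1, 4, 10):
            vals = []
            for _ in range(15):
                order = list(base)
                for _ in range(n_inv):
                    i = int(rng.integers(n - 1))
                    j = int(rng.integers(i + 1, n))
                    seg = [
                        (p, "-" if s == "+" else "+") for p, s in reversed(order[i:j+1])
                    ]
                    order[i : j + 1] = seg
                vals.append(synteny_index(base, order, self._rbh(n)))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_within_lineage_more_syntenic(self, family_run):
        _, _, truth, res = family_run
        within = [
            v for (a, b), v in res.synteny.items()
            if truth.genome_lineage[a] == truth.genome_lineage[b]
        ]
        between = [
            v for (a, b), v in res.synteny.items()
            if truth.genome_lineage[a] != truth.genome_lineage[b]
        ]
        assert np.mean(within) > np.mean(between)

    def test_gene_order_sorted_by_start(self, tiny_family):
        _, genomes, _ = tiny_family
        order = gene_order(genomes[0].features)
        starts = {f.cds_id: f.start for f in genomes[0].features}
        assert [starts[p] for p, _ in order] == sorted(starts.values())
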