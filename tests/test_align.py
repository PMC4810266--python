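"""Smith-Waterman engine, e-values and the k-mer prefilter."""

from __future__ import annotations

import math

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from gvlineage.align import (
    ScoringScheme,
    all_vs_all,
    default_scheme,
    evalue,
    kmer_prefilter,
    mirror_hits,
    smith_waterman,
)
from gvlineage.orthology import Thresholds
from gvlineage.simulate import mutate_protein, random_protein

from _oracles import naive_sw_score

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _bl62():
    m = substitution_matrices.load("BLOSUM62")
    return lambda x, y: int(m[x][y])


def _random_proteins(rng, n, lo=20, hi=60):
    return ["".join(rng.choice(list(AAS), rng.integers(lo, hi))) for _ in range(n)]


class TestSmithWaterman:
    def test_self_alignment_is_perfect(self):
        rng = np.random.default_rng(1)
        for seq in _random_proteins(rng, 5, 30, 80):
            h = smith_waterman(seq, seq)
            assert h.identity_pct == 100.0
            assert h.q_cov == h.s_cov == 100.0

    def test_textbook_pair_matches_naive_dp(self):
        scheme = default_scheme()
        h = smith_waterman("HEAGAWGHEE", "PAWHEAE", scheme)
        expect = naive_sw_score(
            "HEAGAWGHEE", "PAWHEAE", _bl62(), scheme.gap_open, scheme.gap_extend
        )
        assert h.raw_score == expect

    def test_random_pairs_match_naive_dp(self):
        # includes reversed-sequence pairs, which stress the local traceback
        rng = np.random.default_rng(42)
        scheme = default_scheme()
        score = _bl62()
        seqs = _random_proteins(rng, 12)
        pairs = [(a, b) for a in seqs[:6] for b in seqs[6:]]
        pairs += [(a, a[::-1]) for a in seqs[:4]]
        for a, b in pairs:
            h = smith_waterman(a, b, scheme)
            expect = naive_sw_score(a, b, score, scheme.gap_open, scheme.gap_extend)
            got = 0 if h is None else h.raw_score
            assert got == expect, (a, b)

    def test_matches_biopython_aligner(self):
        # second, fully independent engine
        scheme = default_scheme()
        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.mode = "local"
        aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
        aligner.extend_gap_score = -scheme.gap_extend
        rng = np.random.default_rng(7)
        base = random_protein(120, rng)
        for ident in (95.0, 70.0, 45.0):
            other = mutate_protein(base, ident, rng)
            h = smith_waterman(base, other, scheme)
            assert h.raw_score == int(aligner.score(base, other))

    def test_score_symmetry(self):
        # the optimal score is symmetric; identities may differ between
        # co-optimal tracebacks, so only the score is asserted
        rng = np.random.default_rng(5)
        for a, b in zip(_random_proteins(rng, 6), _random_proteins(rng, 6)):
            ha, hb = smith_waterman(a, b), smith_waterman(b, a)
            if ha is None:
                assert hb is None
            else:
                assert ha.raw_score == hb.raw_score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACDE")


class TestEvalue:
    def test_closed_forms(self):
        assert evalue(0.0, 17, 23) == 17 * 23
        assert evalue(50.0, 300, 10**6) == pytest.approx(300 * 10**6 * 2.0**-50)

    def test_linear_in_search_space(self):
        assert evalue(12.5, 100, 2000) == pytest.approx(2 * evalue(12.5, 100, 1000))

    def test_monotone_decreasing_in_bitscore(self):
        es = [evalue(b, 200, 10**5) for b in np.linspace(0, 100, 21)]
        assert all(x > y for x, y in zip(es, es[1:]))

    def test_bitscore_conversion(self):
        s = ScoringScheme()
        raw = 100
        bits = s.bitscore(raw)
        assert bits == pytest.approx(
            (s.karlin_lambda * raw - math.log(s.karlin_K)) / math.log(2)
        )


class TestPrefilter:
    def test_identical_proteins_retained(self):
        rng = np.random.default_rng(2)
        p = random_protein(300, rng)
        assert ("q", "s") in kmer_prefilter({"q": p}, {"s": p}, k=4, min_shared=1)

    def test_disjoint_kmer_sets_dropped(self):
        a = "ACDEFGHIKL" * 4
        b = "MNPQRSTVWY" * 4
        assert kmer_prefilter({"q": a}, {"s": b}, k=4, min_shared=1) == set()

    def test_k_range_enforced(self):
        with pytest.raises(ValueError):
            kmer_prefilter({"q": "ACDEFG"}, {"s": "ACDEFG"}, k=2)

    def test_prefilter_keeps_all_hits_at_family_divergence(self):
        # a single-copy proteome pair at ~60% identity: the prefiltered hit
        # set equals the exhaustive one above the orthology thresholds
        rng = np.random.default_rng(19)
        a = {f"a{i}": random_protein(int(rng.integers(80, 250)), rng) for i in range(40)}
        b = {f"b{i}": mutate_protein(s, 60.0, rng) for i, s in enumerate(a.values())}
        thr = Thresholds()
        keep = lambda hits: {
            (h.query_id, h.subject_id) for h in hits if thr.passes(h)
        }
        assert keep(all_vs_all(a, b, prefilter=True)) == keep(
            all_vs_all(a, b, prefilter=False)
        )

    def test_prefilter_preserves_rbh_and_aai(self, tiny_family):
        # on a simulated family pair (paralogs included) the prefilter may
        # skip weak cross-copy hits but must leave reciprocal best hits and
        # the resulting AAI untouched
        from gvlineage.aai import two_way_aai
        from gvlineage.orthology import reciprocal_best_hits

        _, genomes, _ = tiny_family
        a = {f.cds_id: f.protein for f in genomes[0].features}
        d = {f.cds_id: f.protein for f in genomes[-1].features}
        la = sum(len(s) for s in a.values())
        out = {}
        for pf in (True, False):
            hits = all_vs_all(a, d, prefilter=pf)
            rbh = reciprocal_best_hits(
                hits, mirror_hits(hits, la), "a", "d", Thresholds()
            )
            out[pf] = rbh
        assert {(p.protein_a, p.protein_b) for p in out[True]} == {
            (p.protein_a, p.protein_b) for p in out[False]
        }
        assert two_way_aai(out[True]).mean_identity == pytest.approx(
            two_way_aai(out[False]).mean_identity
        )


class TestAllVsAll:
    def test_self_comparison_top_hit_is_self(self, tiny_family):
        _, genomes, _ = tiny_family
        prots = {f.cds_id: f.protein for f in genomes[0].features}
        sub = dict(list(prots.items())[:30])
        hits = all_vs_all(sub, sub)
        best: dict[str, tuple] = {}
        for h in hits:
            if h.query_id not in best or h.bitscore > best[h.query_id][0]:
                best[h.query_id] = (h.bitscore, h.subject_id, h.identity_pct)
        for q, (_, s, ident) in best.items():
            assert s == q and ident == 100.0

    def test_unrelated_proteomes_mostly_silent(self):
        rng = np.random.default_rng(11)
        qs = {f"q{i}": random_protein(150, rng) for i in range(20)}
        ss = {f"s{i}": random_protein(150, rng) for i in range(20)}
        hits = all_vs_all(qs, ss, prefilter=False, report_evalue=float("inf"))
        strong = [h for h in hits if h.evalue <= 1e-5]
        assert len(strong) <= 0.05 * len(qs) * len(ss)

    def test_mirror_roundtrip(self, tiny_family):
        _, genomes, _ = tiny_family
        a = {f.cds_id: f.protein for f in genomes[0].features}
        b = {f.cds_id: f.protein for f in genomes[1].features}
        hits = all_vs_all(a, b)
        la = sum(len(s) for s in a.values())
        lb = sum(len(s) for s in b.values())
        back = mirror_hits(mirror_hits(hits, la), lb)
        assert {(h.query_id, h.subject_id, h.raw_score) for h in hits} == {
            (h.query_id, h.subject_id, h.raw_score) for h in back
        }
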