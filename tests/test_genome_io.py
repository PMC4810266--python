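"""Genome I/O and descriptive statistics."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq

from gvlineage.genome_io import (
    AnnotatedGenome,
    CdsFeature,
    GenomeIOError,
    compute_stats,
    read_genbank,
    usage_profile,
    write_genbank,
)


def _simple_genome() -> AnnotatedGenome:
    seq = "ATG" + "GCT" * 32 + "TAA"  # 1 CDS of 33 codons
    pad = "ATATATCGCG" * 10
    return AnnotatedGenome(
        genome_id="toy1",
        sequence=seq + pad,
        topology="circular",
        features=[
            CdsFeature("cds1", 1, len(seq), "+", protein="M" + "A" * 32),
        ],
    )


class TestReadWrite:
    def test_roundtrip_preserves_everything(self, tmp_path, tiny_family):
        _, genomes, _ = tiny_family
        g = genomes[0]
        path = tmp_path / "g.gb"
        write_genbank(g, path)
        back = read_genbank(path)
        assert back.sequence == g.sequence
        assert back.topology == "circular"
        assert len(back.features) == len(g.features)
        for f0, f1 in zip(g.features, back.features):
            assert (f0.start, f0.end, f0.strand) == (f1.start, f1.end, f1.strand)
            assert f0.protein == f1.protein

    def test_single_gene_linear_record(self, tmp_path):
        # 300 bp gene: 99 aa protein, stop removed on translation
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        prot = "M" + "".join(rng.choice(list(aas), 98))
        codon = {  # one codon per residue, standard code
            "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
            "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
            "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
            "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
        }
        nt = "".join(codon[c] for c in prot) + "TAA"
        g = AnnotatedGenome(
            "lin1", nt, "linear", [CdsFeature("c1", 1, 300, "+", prot)]
        )
        path = tmp_path / "lin.gb"
        write_genbank(g, path)
        back = read_genbank(path)
        assert len(back.features) == 1
        assert back.features[0].protein == prot
        assert len(back.features[0].protein) == 99

    def test_origin_spanning_cds(self, tmp_path):
        # a CDS running join(334..L, 1..33) on a circular genome; expected
        # protein derived independently by translating the unwrapped span
        prot = "M" + "AVLDKRT" * 5 + "GHWY"  # 40 aa
        codon = {
            "A": "GCT", "D": "GAT", "G": "GGT", "H": "CAT", "K": "AAA",
            "L": "CTT", "M": "ATG", "R": "CGT", "T": "ACT", "V": "GTT",
            "W": "TGG", "Y": "TAT",
        }
        orf = "".join(codon[c] for c in prot) + "TAA"  # 123 nt
        body = "".join(np.random.default_rng(3).choice(list("ACGT"), 300))
        seq = orf[90:] + body + orf[:90]  # wraps: last 90 nt at genome end
        g = AnnotatedGenome(
            "circ1",
            seq,
            "circular",
            [
                CdsFeature(
                    "wrap1",
                    start=len(seq) - 90 + 1,
                    end=33,
                    strand="+",
                    protein=prot,
                    wraps_origin=True,
                )
            ],
        )
        path = tmp_path / "wrap.gb"
        write_genbank(g, path)
        back = read_genbank(path)
        f = back.features[0]
        assert f.wraps_origin
        assert (f.start, f.end) == (len(seq) - 89, 33)
        unwrapped = seq[f.start - 1 :] + seq[:33]
        assert unwrapped == orf
        assert f.protein == str(Seq(unwrapped).translate()).rstrip("*") == prot

    def test_missing_sequence_rejected(self, tmp_path):
        p = tmp_path / "bad.gb"
        p.write_text("LOCUS       bad   0 bp  DNA  linear  01-JAN-2016\n//\n")
        with pytest.raises(GenomeIOError):
            read_genbank(p)


class TestStats:
    def test_full_coverage_single_cds(self):
        g = AnnotatedGenome(
            "g", "ATGC" * 25, "linear", [CdsFeature("c", 1, 100, "+", "M" * 33)]
        )
        s = compute_stats(g)
        assert s.coding_density == 100.0
        assert s.gc_overall == 50.0
        assert s.gene_density == pytest.approx(10.0)

    def test_overlapping_cds_counted_once(self):
        seq = "A" * 100
        g = AnnotatedGenome(
            "g",
            seq,
            "linear",
            [
                CdsFeature("c1", 1, 60, "+", "M" * 20),
                CdsFeature("c2", 31, 90, "-", "M" * 20),
            ],
        )
        s = compute_stats(g)
        assert s.coding_density == pytest.approx(90.0)
        assert s.n_plus == 1 and s.n_minus == 1

    def test_gc_mixture_identity(self, tiny_family):
        # overall G+C is the coverage-weighted mix of coding and non-coding
        _, genomes, _ = tiny_family
        for g in genomes[:3]:
            s = compute_stats(g)
            w = s.coding_density / 100.0
            mixed = w * s.gc_coding + (1 - w) * s.gc_noncoding
            assert mixed == pytest.approx(s.gc_overall, abs=1e-6)

    def test_reverse_complement_invariance(self, tiny_family):
        _, genomes, _ = tiny_family
        g = genomes[0]
        L = len(g.sequence)
        flipped = AnnotatedGenome(
            g.genome_id,
            str(Seq(g.sequence).reverse_complement()),
            g.topology,
            [
                CdsFeature(
                    f.cds_id,
                    L - f.end + 1,
                    L - f.start + 1,
                    "-" if f.strand == "+" else "+",
                    f.protein,
                )
                for f in g.features
                if not f.wraps_origin
            ],
        )
        s0, s1 = compute_stats(g), compute_stats(flipped)
        assert s0.n_cds == s1.n_cds
        assert {f.protein for f in g.features} == {f.protein for f in flipped.features}
        u0, u1 = usage_profile(g), usage_profile(flipped)
        for aa, fr in u0.aa_freq.items():
            assert u1.aa_freq[aa] == pytest.approx(fr)


class TestUsage:
    def test_codon_counts_small_cds(self):
        g = AnnotatedGenome(
            "g", "ATGTTTTTC" + "A" * 21, "linear",
            [CdsFeature("c", 1, 9, "+", "MFF")],
        )
        u = usage_profile(g)
        assert u.codon_counts == {"ATG": 1, "TTT": 1, "TTC": 1}
        assert u.codon_freq["F"] == {"TTT": 0.5, "TTC": 0.5}
        assert sum(u.aa_freq.values()) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic(self, tiny_family):
        _, genomes, _ = tiny_family
        a = usage_profile(genomes[0])
        b = usage_profile(genomes[0])
        assert a.codon_counts == b.codon_counts and a.aa_freq == b.aa_freq

    def test_matches_independent_recount(self, tiny_family):
        # brute-force recount of codons over all CDS with collections.Counter
        _, genomes, _ = tiny_family
        g = genomes[1]
        expected = Counter()
        for f in g.features:
            nt = g.cds_nucleotides(f)
            for i in range(0, len(nt) - len(nt) % 3, 3):
                c = nt[i : i + 3]
                if "N" not in c:
                    expected[c] += 1
        assert usage_profile(g).codon_counts == dict(expected)

    def test_stop_codons_excluded_from_aa_freq(self, tiny_family):
        _, genomes, _ = tiny_family
        u = usage_profile(genomes[0])
        assert "*" not in u.aa_freq
        assert set(u.aa_freq) <= set("ACDEFGHIKLMNPQRSTVWY")
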