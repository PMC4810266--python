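"""Greedy protein clustering into COGs and pan-/core-genome accumulation.

Clustering is centroid-greedy in the BLASTclust/CD-HIT style: proteins are
sorted longest-first and each either joins the first existing cluster whose
representative it matches at the identity/coverage thresholds (defaults
30% / 50%, coverage of both sequences) or founds a new cluster.  The
pan-genome at step k of an inclusion order is the number of clusters touched
by the first k genomes; the core genome is the number touched by every one
of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .align import ScoringScheme, default_scheme, kmer_set, smith_waterman
from .orthology import Thresholds


@dataclass
class GeneCluster:
    cluster_id: str
    members: list[str]  # genome-qualified 'genome|protein' ids
    representative: str  # longest member (the founder)

    @property
    def genomes(self) -> set[str]:
        return {m.split("|", 1)[0] for m in self.members}

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)


@dataclass
class PanCoreCurve:
    inclusion_order: list[str]
    pan_sizes: list[int]
    core_sizes: list[int]

    @property
    def pan_increments(self) -> list[int]:
        return [self.pan_sizes[0]] + [
            b - a for a, b in zip(self.pan_sizes, self.pan_sizes[1:])
        ]

    @property
    def core_decrements(self) -> list[int]:
        return [0] + [a - b for a, b in zip(self.core_sizes, self.core_sizes[1:])]


CLUSTER_THRESHOLDS = Thresholds(evalue=float("inf"), identity=30.0, coverage=50.0)


def greedy_cluster(
    proteins: Mapping[str, str],
    thresholds: Thresholds = CLUSTER_THRESHOLDS,
    scheme: ScoringScheme | None = None,
    prefilter: bool = True,
    k: int = 4,
    min_shared: int = 1,
) -> list[GeneCluster]:
    """Centroid-greedy clustering of genome-qualified proteins.

    Deterministic: candidates are processed by descending length with ties
    broken by id; each joins the first (oldest) cluster whose representative
    it matches at the thresholds.  A k-mer prefilter against representatives
    skips hopeless comparisons.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    scheme = scheme or default_scheme()
    order = sorted(proteins, key=lambda p: (-len(proteins[p]), p))
    clusters: list[GeneCluster] = []
    rep_kmers: list[set[str]] = []
    for pid in order:
        seq = proteins[pid]
        words = kmer_set(seq, k) if prefilter else None
        joined = False
        for ci, cl in enumerate(clusters):
            if prefilter:
                shared = len(words & rep_kmers[ci])
                if shared < min_shared:
                    continue
            h = smith_waterman(seq, proteins[cl.representative], scheme)
            if h is None:
                continue
            if (
                h.identity_pct >= thresholds.identity
                and h.q_cov >= thresholds.coverage
                and h.s_cov >= thresholds.coverage
            ):
                cl.members.append(pid)
                joined = True
                break
        if not joined:
            clusters.append(
                GeneCluster(
                    cluster_id=f"COG_{len(clusters) + 1:04d}",
                    members=[pid],
                    representative=pid,
                )
            )
            if prefilter:
                rep_kmers.append(words)
    return clusters


def accumulation(
    clusters: Sequence[GeneCluster], inclusion_order: Sequence[str]
) -> PanCoreCurve:
    """Stepwise pan-/core-genome sizes along a genome inclusion order."""
    known = set()
    for c in clusters:
        known |= c.genomes
    for g in inclusion_order:
        if g not in known:
            raise KeyError(f"genome {g} contributed no proteins to clustering")
    pan, core = [], []
    for k in range(1, len(inclusion_order) + 1):
        prefix = set(inclusion_order[:k])
        pan.append(sum(1 for c in clusters if c.genomes & prefix))
        core.append(sum(1 for c in clusters if prefix <= c.genomes))
    return PanCoreCurve(
        inclusion_order=list(inclusion_order), pan_sizes=pan, core_sizes=core
    )


def accumulation_summary(
    clusters: Sequence[GeneCluster],
    genome_ids: Sequence[str],
    max_permutations: int = 5000,
    seed: int = 0,
) -> "object":
    """Per-step pan/core statistics over inclusion orders.

    Exhaustive over all n! orders when that count is within
    ``max_permutations``, otherwise over a seeded random sample.  Returns a
    DataFrame with mean/min/max pan and core sizes per step.
    """
    import itertools
    import math

    import numpy as np
    import pandas as pd

    ids = list(genome_ids)
    n = len(ids)
    pos = {g: i for i, g in enumerate(ids)}
    masks = []
    for c in clusters:
        m = 0
        for g in c.genomes:
            if g in pos:
                m |= 1 << pos[g]
        if m:
            masks.append(m)
    if math.factorial(n) <= max_permutations:
        orders = itertools.permutations(range(n))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        orders = (tuple(rng.permutation(n)) for _ in range(max_permutations))
        exhaustive = False
    pan = [[] for _ in range(n)]
    core = [[] for _ in range(n)]
    for order in orders:
        prefix = 0
        for k, gi in enumerate(order):
            prefix |= 1 << gi
            pan[k].append(sum(1 for m in masks if m & prefix))
            core[k].append(sum(1 for m in masks if m & prefix == prefix))
    rows = []
    for k in range(n):
        rows.append(
            {
                "step": k + 1,
                "pan_mean": float(np.mean(pan[k])),
                "pan_min": int(np.min(pan[k])),
                "pan_max": int(np.max(pan[k])),
                "core_mean": float(np.mean(core[k])),
                "core_min": int(np.min(core[k])),
                "core_max": int(np.max(core[k])),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["exhaustive"] = exhaustive
    return df


def core_ratio(
    genome_ids: Sequence[str], clusters: Sequence[GeneCluster]
) -> dict[str, float]:
    """Per-genome ratio of set-wide core clusters to the genome's clusters."""
    gset = set(genome_ids)
    out = {}
    for g in genome_ids:
        mine = [c for c in clusters if g in c.genomes]
        core = [c for c in mine if gset <= c.genomes]
        out[g] = len(core) / len(mine) if mine else 0.0
    return out


# ---------------------------------------------------------------------------
# output


def write_clusters_tsv(clusters: Iterable[GeneCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative\tn_members\tn_genomes\tmembers\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.representative}\t{len(c.members)}\t"
                f"{c.n_genomes}\t{','.join(c.members)}\n"
            )


def write_clusters_blastclust(
    clusters: Iterable[GeneCluster], path: str | Path
) -> None:
    """BLASTclust-style line format: one cluster per line, ids separated
    by spaces, largest cluster first."""
    lines = sorted(
        (" ".join(c.members) for c in clusters),
        key=lambda s: (-s.count(" "), s),
    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_curve_tsv(curve: PanCoreCurve, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "step": range(1, len(curve.inclusion_order) + 1),
            "genome": curve.inclusion_order,
            "pan": curve.pan_sizes,
            "core": curve.core_sizes,
            "d_pan": curve.pan_increments,
            "d_core": curve.core_decrements,
        }
    ).to_csv(path, sep="\t", index=False)
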