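"""Average amino-acid identity (AAI) between genome pairs.

Two-way AAI summarises the percent identities of reciprocal-best-hit
alignments between two proteomes; one-way AAI uses each query's best hit
only and is generally asymmetric.  AAI is the central lineage statistic:
genomes of one lineage sit near 97% two-way AAI, genomes of different
lineages well below ~73%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import SimilarityHit
from .orthology import OrthologPair, Thresholds, _best_per_query


class NoOrthologsError(ValueError):
    """Raised when an AAI is requested for a pair with zero qualifying hits."""


@dataclass(frozen=True)
class AAIResult:
    genome_a: str
    genome_b: str
    mode: str  # one_way_ab | one_way_ba | two_way
    n_pairs: int
    mean_identity: float
    median_identity: float
    sd_identity: float


def _summarise(
    genome_a: str, genome_b: str, mode: str, identities: Sequence[float]
) -> AAIResult:
    if not identities:
        raise NoOrthologsError(
            f"no qualifying ortholog pairs between {genome_a} and {genome_b}"
        )
    arr = np.asarray(identities, dtype=float)
    return AAIResult(
        genome_a=genome_a,
        genome_b=genome_b,
        mode=mode,
        n_pairs=len(arr),
        mean_identity=float(arr.mean()),
        median_identity=float(np.median(arr)),
        sd_identity=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
    )


def two_way_aai(
    rbh: Sequence[OrthologPair], genome_a: str | None = None, genome_b: str | None = None
) -> AAIResult:
    """AAI over reciprocal best hits (unweighted mean/median/sd).

    Symmetric in the two genomes by construction.
    """
    if not rbh:
        raise NoOrthologsError("empty RBH list")
    ga = genome_a or rbh[0].genome_a
    gb = genome_b or rbh[0].genome_b
    return _summarise(ga, gb, "two_way", [p.identity_pct for p in rbh])


def one_way_aai(
    hits: Sequence[SimilarityHit],
    genome_a: str,
    genome_b: str,
    thresholds: Thresholds = Thresholds(),
) -> AAIResult:
    """AAI over per-query best hits after thresholds (direction a -> b)."""
    best = _best_per_query(hits, thresholds)
    return _summarise(
        genome_a, genome_b, "one_way_ab", [h.identity_pct for h in best.values()]
    )


def aai_matrix(
    genome_ids: Sequence[str],
    rbh_map: Mapping[tuple[str, str], Sequence[OrthologPair]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric two-way AAI matrix over a genome set.

    ``rbh_map`` holds RBH lists keyed by unordered genome pairs (either key
    order accepted).  Returns (aai, n_pairs) DataFrames; the diagonal is
    100 with n_pairs 0, and a pair with no qualifying orthologs is NaN
    (missing), never silently 0.
    """
    ids = list(genome_ids)
    aai = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    npairs = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for g in ids:
        aai.loc[g, g] = 100.0
    for i, ga in enumerate(ids):
        for gb in ids[i + 1 :]:
            pairs = rbh_map.get((ga, gb), rbh_map.get((gb, ga)))
            if not pairs:
                continue
            res = two_way_aai(list(pairs), ga, gb)
            aai.loc[ga, gb] = aai.loc[gb, ga] = res.mean_identity
            npairs.loc[ga, gb] = npairs.loc[gb, ga] = res.n_pairs
    return aai, npairs


def write_aai_long_tsv(results: Iterable[AAIResult], path: str | Path) -> None:
    rows = [
        {
            "genome_a": r.genome_a,
            "genome_b": r.genome_b,
            "mode": r.mode,
            "n_pairs": r.n_pairs,
            "mean": r.mean_identity,
            "median": r.median_identity,
            "sd": r.sd_identity,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.3f")
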