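"""Phyletic profiles and Pearson-distance hierarchical clustering.

A genome's phyletic profile is its 0/1 presence vector over gene clusters.
Genomes are compared by the Pearson-correlation distance d = 1 - r over
profiles (d in [0, 2]) and agglomerated by average linkage (UPGMA) into an
ultrametric dendrogram — gene gain/loss history as a clustering signal,
complementary to sequence identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pangenome import GeneCluster


class ZeroVarianceError(ValueError):
    """A genome's profile has zero variance; its Pearson distance is undefined."""


def build_matrix(
    clusters: Sequence[GeneCluster], genome_ids: Sequence[str]
) -> pd.DataFrame:
    """Presence/absence matrix: rows = cluster ids, columns = genomes.

    A cell is 1 iff the genome contributes at least one protein to the
    cluster.  Any cluster-membership source can be supplied (in-repo COGs
    by default; externally computed assignments can be loaded into
    GeneCluster records).
    """
    if not clusters:
        raise ValueError("empty cluster set")
    m = pd.DataFrame(
        0, index=[c.cluster_id for c in clusters], columns=list(genome_ids), dtype=int
    )
    for c in clusters:
        for g in c.genomes:
            if g in m.columns:
                m.loc[c.cluster_id, g] = 1
    return m


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def write_matrix_mtx(matrix: pd.DataFrame, path) -> None:
    """MatrixMarket sparse output (rows/cols listed in companion files)."""
    from pathlib import Path

    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    path = Path(path)
    mmwrite(str(path), csr_matrix(matrix.to_numpy()))
    path.with_suffix(".rows.txt").write_text("\n".join(matrix.index) + "\n")
    path.with_suffix(".cols.txt").write_text("\n".join(matrix.columns) + "\n")


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Genome-genome distance d(i, j) = 1 - r(profile_i, profile_j).

    Raises ZeroVarianceError when a genome is present in every cluster (or
    none), since r is then undefined.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 genomes")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    bad = [g for g, s in zip(matrix.columns, sd) if s == 0]
    if bad:
        raise ZeroVarianceError(
            f"zero-variance phyletic profile for genome(s): {', '.join(bad)}"
        )
    r = np.corrcoef(X.T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


@dataclass
class Dendrogram:
    """Rooted ultrametric tree; leaves carry labels, internals a height."""

    label: str | None = None
    height: float = 0.0
    children: tuple["Dendrogram", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk(parent_height=self.height) + ";"

    def _nwk(self, parent_height: float) -> str:
        bl = parent_height - self.height
        if self.is_leaf:
            return f"{self.label}:{bl:.6g}"
        inner = ",".join(c._nwk(self.height) for c in self.children)
        return f"({inner}):{bl:.6g}"

    def monophyletic(self, labels: set[str]) -> bool:
        """True if some clade's leaf set equals ``labels`` exactly."""
        if set(self.leaves()) == labels:
            return True
        return any(c.monophyletic(labels) for c in self.children)


def upgma(dist: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a symmetric zero-diagonal distance matrix.

    Average linkage (UPGMA) by default; 'single' and 'complete' selectable.
    Ties in the minimum inter-cluster distance are broken by the
    lexicographically smallest pair of cluster labels, so the merge order is
    deterministic.  Heights are half the merge distance (ultrametric).
    """
    labels = list(dist.index)
    D = dist.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    if len(labels) == 1:
        return Dendrogram(label=labels[0])
    # active clusters: key -> (node, size, sort_label)
    nodes: dict[int, Dendrogram] = {
        i: Dendrogram(label=lab) for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in range(len(labels))}
    names = {i: lab for i, lab in enumerate(labels)}
    d: dict[tuple[int, int], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d[(i, j)] = D[i, j]
    nxt = len(labels)
    while len(nodes) > 1:
        best = None
        for (i, j), v in d.items():
            key = (v, *sorted((names[i], names[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = d[(min(i, j), max(i, j))]
        merged = Dendrogram(
            height=dij / 2.0,
            children=tuple(
                sorted((nodes[i], nodes[j]), key=lambda n: min(n.leaves()))
            ),
        )
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            if linkage == "average":
                v = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            elif linkage == "single":
                v = min(dik, djk)
            elif linkage == "complete":
                v = max(dik, djk)
            else:
                raise ValueError(f"unknown linkage {linkage!r}")
            d[(min(nxt, k), max(nxt, k))] = v
        del d[(min(i, j), max(i, j))]
        sizes[nxt] = sizes.pop(i) + sizes.pop(j)
        names[nxt] = min(names.pop(i), names.pop(j))
        del nodes[i], nodes[j]
        nodes[nxt] = merged
        nxt += 1
    root = next(iter(nodes.values()))
    return root
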