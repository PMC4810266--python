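"""Core-gene phylogeny: marker selection, MSA, NJ trees, SPR supertree.

Five Megavirales core genes (family B DNA polymerase, D6/D11 helicase,
VV A18 helicase, D5 primase-helicase, major capsid protein) are located in
each genome by similarity to seed sequences, aligned progressively, and
summarised either as a concatenated distance tree (neighbor joining on
Kimura-corrected protein distances) or as a supertree minimising the total
subtree prune-and-regraft (SPR) distance to the per-gene trees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import (
    AA_INDEX,
    ScoringScheme,
    default_scheme,
    kmer_set,
    smith_waterman,
)
from ._kernels import nw_profile_traceback
from .orthology import Thresholds
from .trees import (
    UnrootedTree,
    key_distance_map,
    key_neighbors,
    key_spr_distance,
    mask_key,
    rf_distance,
    tree_from_key,
)

MARKER_GENES = (
    "polB",  # family B DNA polymerase
    "mcp",  # major capsid protein
    "vv_a18_helicase",
    "d5_primase_helicase",
    "d6d11_helicase",
)


@dataclass
class CoreGeneSet:
    """Per-genome protein ids for each marker gene (None if absent)."""

    assignments: dict[str, dict[str, str | None]]  # gene -> genome -> protein id

    def genomes_with(self, gene: str) -> list[str]:
        return [g for g, p in self.assignments[gene].items() if p is not None]


@dataclass
class MultipleAlignment:
    gene: str
    rows: dict[str, str]  # genome id -> aligned sequence ('-' gaps)

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.rows.values()}
        if len(lens) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def select_markers(
    proteomes: Mapping[str, Mapping[str, str]],
    marker_seeds: Mapping[str, str],
    thresholds: Thresholds = Thresholds(),
    scheme: ScoringScheme | None = None,
) -> CoreGeneSet:
    """Best qualifying hit of each marker seed in each proteome.

    Duplicate marker copies resolve to the higher bitscore, ties to the
    longer protein then lexicographic id.  A marker absent from more than
    half the genomes triggers a warning.
    """
    scheme = scheme or default_scheme()
    out: dict[str, dict[str, str | None]] = {}
    for gene, seed in marker_seeds.items():
        out[gene] = {}
        for genome, prots in proteomes.items():
            best: tuple[float, int, str] | None = None
            best_id: str | None = None
            for pid in sorted(prots):
                h = smith_waterman(
                    seed, prots[pid], scheme, search_space_n=sum(
                        len(s) for s in prots.values()
                    ),
                )
                if h is None or not thresholds.passes(h):
                    continue
                key = (h.bitscore, len(prots[pid]), pid)
                if best is None or key[:2] > best[:2] or (
                    key[:2] == best[:2] and pid < best[2]
                ):
                    best = key
                    best_id = pid
            out[gene][genome] = best_id
        n_missing = sum(1 for v in out[gene].values() if v is None)
        if n_missing > len(proteomes) / 2:
            warnings.warn(
                f"marker {gene} absent from {n_missing}/{len(proteomes)} genomes",
                stacklevel=2,
            )
    return CoreGeneSet(assignments=out)


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _profile(rows: Sequence[str], scheme: ScoringScheme) -> np.ndarray:
    """Column residue-frequency matrix (L x alphabet); gaps contribute 0."""
    L = len(rows[0])
    P = np.zeros((L, len(AA_INDEX)))
    for r in rows:
        for i, c in enumerate(r):
            if c != "-":
                P[i, AA_INDEX.get(c, AA_INDEX["X"])] += 1
    return P / len(rows)


def _merge(
    rows_a: dict[str, str],
    rows_b: dict[str, str],
    scheme: ScoringScheme,
) -> dict[str, str]:
    Pa = _profile(list(rows_a.values()), scheme)
    Pb = _profile(list(rows_b.values()), scheme)
    S = Pa @ scheme.matrix @ Pb.T
    moves = nw_profile_traceback(S, float(scheme.gap_open), float(scheme.gap_extend))
    out: dict[str, list[str]] = {k: [] for k in (*rows_a, *rows_b)}
    i = j = 0
    for mv in moves:
        if mv == 1:
            for k, r in rows_a.items():
                out[k].append(r[i])
            for k, r in rows_b.items():
                out[k].append(r[j])
            i += 1
            j += 1
        elif mv == 2:  # consume A, gap in B
            for k, r in rows_a.items():
                out[k].append(r[i])
            for k in rows_b:
                out[k].append("-")
            i += 1
        else:  # consume B
            for k in rows_a:
                out[k].append("-")
            for k, r in rows_b.items():
                out[k].append(r[j])
            j += 1
    return {k: "".join(v) for k, v in out.items()}


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka, kb = kmer_set(a, k), kmer_set(b, k)
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def progressive_align(
    seqs: Mapping[str, str],
    gene: str = "gene",
    scheme: ScoringScheme | None = None,
) -> MultipleAlignment:
    """Progressive profile-profile alignment along a k-mer UPGMA guide tree.

    Deterministic: the guide tree uses lexicographic tie-breaking and
    profile merges follow its merge order.  Ungapping any row recovers the
    input sequence exactly.
    """
    from .phyletics import Dendrogram, upgma

    if not seqs:
        raise ValueError("no sequences")
    scheme = scheme or default_scheme()
    names = sorted(seqs)
    if len(names) == 1:
        return MultipleAlignment(gene=gene, rows={names[0]: seqs[names[0]]})
    D = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            D.loc[a, b] = D.loc[b, a] = _kmer_distance(seqs[a], seqs[b])
    guide = upgma(D)

    def build(node: Dendrogram) -> dict[str, str]:
        if node.is_leaf:
            return {node.label: seqs[node.label]}
        parts = [build(c) for c in node.children]
        merged = parts[0]
        for p in parts[1:]:
            merged = _merge(merged, p, scheme)
        return merged

    return MultipleAlignment(gene=gene, rows=build(guide))


# ---------------------------------------------------------------------------
# distances


def kimura_protein_distance(p: float) -> float:
    """Kimura's correction of an observed protein p-distance."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return float("inf")
    return -math.log(arg)


def concat_and_distance(
    alignments: Sequence[MultipleAlignment], genome_ids: Sequence[str]
) -> pd.DataFrame:
    """Kimura-corrected pairwise distances on the concatenated alignment.

    Genomes missing from a gene enter as all-gap blocks; a pair with zero
    comparable (both non-gap) columns gets NaN.
    """
    blocks = []
    for aln in alignments:
        L = aln.n_cols
        blocks.append({g: aln.rows.get(g, "-" * L) for g in genome_ids})
    concat = {g: "".join(b[g] for b in blocks) for g in genome_ids}
    ids = list(genome_ids)
    D = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ra, rb = concat[a], concat[b]
            comp = diff = 0
            for x, y in zip(ra, rb):
                if x != "-" and y != "-":
                    comp += 1
                    if x != y:
                        diff += 1
            if comp == 0:
                D.loc[a, b] = D.loc[b, a] = float("nan")
            else:
                D.loc[a, b] = D.loc[b, a] = kimura_protein_distance(diff / comp)
    return D


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dist: pd.DataFrame) -> UnrootedTree:
    """Canonical neighbor joining; exact on additive matrices.

    Negative branch lengths are clamped to 0; ties in the Q criterion break
    by the lexicographically smallest label pair.
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("need >= 3 taxa")
    D = dist.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    t = UnrootedTree()
    nodes = [t.new_node(lab) for lab in labels]
    names = list(labels)
    while len(nodes) > 2:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((names[i], names[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = t.new_node()
        t.add_edge(nodes[i], new, li)
        t.add_edge(nodes[j], new, lj)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((n - 1, n - 1))
        D2[: n - 2, : n - 2] = D[np.ix_(keep, keep)]
        D2[-1, : n - 2] = D2[: n - 2, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(names[i], names[j])]
    t.add_edge(nodes[0], nodes[1], max(D[0, 1], 0.0))
    return t


# ---------------------------------------------------------------------------
# SPR distance


def spr_distance(
    t1: UnrootedTree, t2: UnrootedTree, max_exact_leaves: int = 8
) -> int | tuple[int, int]:
    """SPR distance between two unrooted binary trees on the same leaves.

    Exact (breadth-first search over SPR neighborhoods) for trees of up to
    ``max_exact_leaves`` leaves; beyond that an admissible (lower, upper)
    bound pair is returned instead.
    """
    if t1.leaf_labels() != t2.leaf_labels():
        raise ValueError("leaf sets differ")
    n = len(t1.leaf_labels())
    if n > max_exact_leaves:
        return spr_distance_bounds(t1, t2)
    labels, k1 = mask_key(t1)
    _, k2 = mask_key(t2)
    return key_spr_distance(k1, k2, n)


def spr_distance_bounds(t1: UnrootedTree, t2: UnrootedTree) -> tuple[int, int]:
    """Admissible (lower, upper) bounds on the SPR distance.

    Lower: one move changes at most n-3 splits, so d >= ceil((RF/2)/(n-3)).
    Upper: greedy RF-descent move count if it reaches the target, else the
    constructive leaf-relocation bound n-3.
    """
    n = len(t1.leaf_labels())
    rf_half = rf_distance(t1, t2) // 2
    if rf_half == 0:
        return (0, 0)
    lower = max(1, math.ceil(rf_half / max(n - 3, 1)))
    upper = n - 3
    cur = t2
    moves = 0
    cur_rf = rf_distance(t1, cur)
    while moves < n and cur_rf > 0:
        best = None
        for nb in cur.spr_neighbors():
            r = rf_distance(t1, nb)
            if best is None or r < best[0]:
                best = (r, nb)
        if best is None or best[0] >= cur_rf:
            break  # stalled
        cur_rf, cur = best
        moves += 1
    if cur_rf == 0:
        upper = min(upper, moves)
    return (lower, max(lower, upper))


# ---------------------------------------------------------------------------
# SPR supertree


@dataclass
class SupertreeResult:
    tree: UnrootedTree
    total_distance: int
    per_input: list[int]
    method: str
    seed: int | None = None
    newick: str = field(init=False)

    def __post_init__(self) -> None:
        self.newick = self.tree.to_newick(lengths=False)


def _projector(union_labels: Sequence[str], sub_labels: Sequence[str]):
    """Map a topology key over union_labels to one over sub_labels.

    Restricting a tree to a leaf subset projects every split onto the
    subset; trivial projections drop out.
    """
    pos = {lab: i for i, lab in enumerate(union_labels)}
    sub_bits = [(1 << pos[lab]) for lab in sub_labels]
    k = len(sub_labels)
    Uk = (1 << k) - 1

    def project(key: frozenset[int]) -> frozenset[int]:
        out = set()
        for m in key:
            x = 0
            for j, b in enumerate(sub_bits):
                if m & b:
                    x |= 1 << j
            if x & 1:
                x = Uk ^ x
            if 1 < x.bit_count() < k - 1:
                out.add(x)
        return frozenset(out)

    return project


def _caterpillar_key(labels: Sequence[str]) -> frozenset[int]:
    n = len(labels)
    U = (1 << n) - 1
    masks = set()
    tail = U
    for i in range(n - 2):
        tail &= ~(1 << i)
        masks.add(tail if not tail & 1 else U ^ tail)
    return frozenset(m for m in masks if 1 < m.bit_count() < n - 1)


def spr_supertree(
    gene_trees: Sequence[UnrootedTree],
    restarts: int = 10,
    seed: int = 0,
    exhaustive_max_leaves: int = 7,
) -> SupertreeResult:
    """Supertree minimising the total SPR distance to the input trees.

    The candidate leaf set is the union of input leaf sets; each input is
    compared against the candidate restricted (projected) to its own
    leaves.  Up to ``exhaustive_max_leaves`` leaves the full topology space
    is scanned, which is globally optimal; beyond that, SPR hill-climbing
    from each full-leaf-set input tree plus seeded random restarts, guided
    by per-input BFS distance maps (distances capped at 3 during the climb;
    final scores are exact).  Ties break on the sorted split masks, so the
    result is deterministic.
    """
    if len(gene_trees) < 1:
        raise ValueError("need >= 1 input tree")
    union: set[str] = set()
    for t in gene_trees:
        if not t.leaf_labels():
            raise ValueError("input tree with empty leaf set")
        union |= t.leaf_labels()
    if len(gene_trees) > 1:
        for i, t in enumerate(gene_trees):
            others = set()
            for j, o in enumerate(gene_trees):
                if j != i:
                    others |= o.leaf_labels()
            if t.leaf_labels().isdisjoint(others):
                raise ValueError("an input tree shares no leaves with the others")
    union_labels = tuple(sorted(union))
    n = len(union_labels)
    inputs = []
    for t in gene_trees:
        labels_i, key_i = mask_key(t)
        inputs.append((labels_i, key_i, len(labels_i), _projector(union_labels, labels_i)))

    def exact_score(key: frozenset[int]) -> tuple[int, list[int]]:
        per = [
            key_spr_distance(project(key), key_i, n_i)
            for (labels_i, key_i, n_i, project) in inputs
        ]
        return sum(per), per

    if n <= exhaustive_max_leaves:
        space = key_distance_map(_caterpillar_key(union_labels), n)
        maps = [
            key_distance_map(key_i, n_i) for (labels_i, key_i, n_i, _) in inputs
        ]
        best = None
        for cand in space:
            per = [
                maps[i][inp[3](cand)] for i, inp in enumerate(inputs)
            ]
            total = sum(per)
            tie = tuple(sorted(cand))
            if best is None or (total, tie) < (best[0], best[1]):
                best = (total, tie, cand, per)
        total, _, key, per = best
        tree = tree_from_key(key, union_labels)
        return SupertreeResult(tree, total, per, method="exhaustive")

    # hill-climb with capped distance maps
    cap = 2
    maps = [
        key_distance_map(key_i, n_i, max_depth=cap)
        for (labels_i, key_i, n_i, _) in inputs
    ]

    def capped_score(key: frozenset[int]) -> int:
        s = 0
        for i, (labels_i, key_i, n_i, project) in enumerate(inputs):
            s += maps[i].get(project(key), cap + 1)
        return s

    rng = np.random.default_rng(seed)
    starts: list[frozenset[int]] = []
    for t in gene_trees:
        if t.leaf_labels() == frozenset(union_labels):
            starts.append(mask_key(t)[1])
    starts.append(_caterpillar_key(union_labels))
    for _ in range(restarts):
        starts.append(_random_key(union_labels, rng))
    candidates: set[frozenset[int]] = set(starts)
    for start in starts:
        cur = start
        cur_s = capped_score(cur)
        improved = True
        while improved:
            improved = False
            for nb in sorted(key_neighbors(cur, n), key=lambda k: tuple(sorted(k))):
                s = capped_score(nb)
                if s < cur_s:
                    cur, cur_s = nb, s
                    improved = True
                    break
        candidates.add(cur)
    best = None
    for cand in candidates:
        total, per = exact_score(cand)
        tie = tuple(sorted(cand))
        if best is None or (total, tie) < (best[0], best[1]):
            best = (total, tie, cand, per)
    total, _, key, per = best
    tree = tree_from_key(key, union_labels)
    return SupertreeResult(tree, total, per, method="hill_climb", seed=seed)


def _random_key(labels: Sequence[str], rng: np.random.Generator) -> frozenset[int]:
    """Random unrooted binary topology key by random leaf insertion."""
    t = UnrootedTree()
    c = t.new_node()
    for lab in labels[:3]:
        t.add_edge(c, t.new_node(lab))
    for lab in labels[3:]:
        edges = t.edges()
        u, v = edges[int(rng.integers(len(edges)))]
        w = t.new_node()
        t.remove_edge(u, v)
        t.add_edge(u, w)
        t.add_edge(w, v)
        t.add_edge(w, t.new_node(lab))
    return mask_key(t)[1]
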