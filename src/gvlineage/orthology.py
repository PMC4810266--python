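"""Ortholog and paralog detection from pairwise similarity hits.

Bona fide orthologs are reciprocal best hits (RBH) between two proteomes
under e-value / identity / coverage thresholds (defaults 1e-5 / 30% / 50%,
with coverage required of both sequences).  Within-genome paralogous
families are connected components of the thresholded self-hit graph refined
by a Markov-style clustering step.  Cross-genome ortholog clusters are
connected components of the union graph (RBH edges + paralog edges), the
unit of lineage-sharing accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import SimilarityHit


@dataclass(frozen=True)
class Thresholds:
    """Hit-qualification thresholds (BLAST-style)."""

    evalue: float = 1e-5
    identity: float = 30.0  # percent
    coverage: float = 50.0  # percent, required of query AND subject

    def passes(self, h: SimilarityHit) -> bool:
        return (
            h.evalue <= self.evalue
            and h.identity_pct >= self.identity
            and h.q_cov >= self.coverage
            and h.s_cov >= self.coverage
        )


@dataclass(frozen=True)
class OrthologPair:
    genome_a: str
    protein_a: str
    genome_b: str
    protein_b: str
    identity_pct: float
    bitscore: float


@dataclass
class ParalogFamily:
    genome_id: str
    members: frozenset[str]  # protein ids, >= 2
    label: str | None = None


@dataclass
class OrthologClusterSet:
    clusters: list[frozenset[str]]  # 'genome|protein' ids
    lineage_presence: list[frozenset[str]]  # lineages contributing per cluster


def _best_per_query(
    hits: Iterable[SimilarityHit], thresholds: Thresholds
) -> dict[str, SimilarityHit]:
    """Best qualifying hit per query; ties by identity then subject id."""
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        if h.query_id == h.subject_id or not thresholds.passes(h):
            continue
        cur = best.get(h.query_id)
        # ties broken by higher identity, then lexicographic subject id
        if cur is None or (
            (h.bitscore, h.identity_pct) > (cur.bitscore, cur.identity_pct)
            or (
                (h.bitscore, h.identity_pct) == (cur.bitscore, cur.identity_pct)
                and h.subject_id < cur.subject_id
            )
        ):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: Sequence[SimilarityHit],
    hits_ba: Sequence[SimilarityHit],
    genome_a: str,
    genome_b: str,
    thresholds: Thresholds = Thresholds(),
) -> list[OrthologPair]:
    """Reciprocal best hits between two proteomes.

    Thresholds are applied before best-hit selection, so a pair qualifies
    only if each member is the other's best *qualifying* hit.  At most one
    pair per protein.
    """
    qa = {h.query_id for h in hits_ab} | {h.subject_id for h in hits_ba}
    qb = {h.subject_id for h in hits_ab} | {h.query_id for h in hits_ba}
    if qa & qb:
        raise ValueError("hit tables do not come from two distinct proteomes")
    best_ab = _best_per_query(hits_ab, thresholds)
    best_ba = _best_per_query(hits_ba, thresholds)
    pairs = []
    for a_id, h in sorted(best_ab.items()):
        b_id = h.subject_id
        back = best_ba.get(b_id)
        if back is not None and back.subject_id == a_id:
            pairs.append(
                OrthologPair(
                    genome_a=genome_a,
                    protein_a=a_id,
                    genome_b=genome_b,
                    protein_b=b_id,
                    identity_pct=h.identity_pct,
                    bitscore=h.bitscore,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# paralogous families


def _mcl_refine(
    nodes: list[str], weights: dict[tuple[str, str], float], inflation: float
) -> list[list[str]]:
    """Markov-style clustering of one connected component.

    Expansion (matrix square) and inflation (elementwise power) on the
    column-stochastic similarity matrix with self-loops, iterated to
    convergence; clusters read off attractor rows.
    """
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for (u, v), w in weights.items():
        M[idx[u], idx[v]] = M[idx[v], idx[u]] = w
    np.fill_diagonal(M, M.max(axis=1).clip(min=1.0))
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(100):
        M2 = M @ M
        M2 = M2**inflation
        M2 /= M2.sum(axis=0, keepdims=True)
        if np.allclose(M2, M, atol=1e-8):
            M = M2
            break
        M = M2
    M[M < 1e-6] = 0.0
    clusters: list[set[int]] = []
    for i in range(n):  # attractor rows
        members = set(np.nonzero(M[i])[0])
        if not members:
            continue
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if not merged:
            clusters.append(members)
    # overlap resolution: assign each node to first containing cluster
    seen: set[int] = set()
    out = []
    for c in clusters:
        keep = sorted(c - seen)
        seen |= c
        if keep:
            out.append([nodes[i] for i in keep])
    for i in range(n):
        if i not in seen:
            out.append([nodes[i]])
    return out


def paralog_families(
    self_hits: Sequence[SimilarityHit],
    genome_id: str,
    thresholds: Thresholds = Thresholds(),
    inflation: float = 1.5,
) -> list[ParalogFamily]:
    """Within-genome paralogous families.

    Families are connected components of the thresholded self-hit graph
    (self-hits excluded), refined by Markov-style clustering with the given
    inflation.  Singletons are not families.
    """
    import networkx as nx

    G = nx.Graph()
    weights: dict[tuple[str, str], float] = {}
    for h in self_hits:
        if h.query_id == h.subject_id or not thresholds.passes(h):
            continue
        G.add_edge(h.query_id, h.subject_id)
        key = tuple(sorted((h.query_id, h.subject_id)))
        weights[key] = max(weights.get(key, 0.0), h.bitscore)
    fams = []
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        sub = {
            k: w
            for k, w in weights.items()
            if k[0] in comp and k[1] in comp
        }
        for cluster in _mcl_refine(nodes, sub, inflation):
            if len(cluster) >= 2:
                fams.append(
                    ParalogFamily(genome_id=genome_id, members=frozenset(cluster))
                )
    fams.sort(key=lambda f: sorted(f.members)[0])
    return fams


# ---------------------------------------------------------------------------
# cross-genome ortholog clusters


def qualify(genome: str, protein: str) -> str:
    return f"{genome}|{protein}"


def ortholog_clusters(
    rbh_pairs: Iterable[OrthologPair],
    paralogs: Iterable[ParalogFamily],
    lineage_map: Mapping[str, str],
    all_proteins: Mapping[str, Iterable[str]] | None = None,
) -> OrthologClusterSet:
    """Connected components of the union graph (RBH + paralog edges).

    ``lineage_map`` maps genome id -> lineage label; every genome seen in
    the inputs must be mapped.  If ``all_proteins`` (genome -> protein ids)
    is given, unclustered proteins are emitted as singleton clusters.
    """
    import networkx as nx

    G = nx.Graph()
    for p in rbh_pairs:
        for g in (p.genome_a, p.genome_b):
            if g not in lineage_map:
                raise KeyError(f"genome {g} missing from lineage map")
        G.add_edge(qualify(p.genome_a, p.protein_a), qualify(p.genome_b, p.protein_b))
    for fam in paralogs:
        if fam.genome_id not in lineage_map:
            raise KeyError(f"genome {fam.genome_id} missing from lineage map")
        members = sorted(fam.members)
        for a, b in zip(members, members[1:]):
            G.add_edge(qualify(fam.genome_id, a), qualify(fam.genome_id, b))
    if all_proteins is not None:
        for g, prots in all_proteins.items():
            for p in prots:
                G.add_node(qualify(g, p))
    clusters = sorted(
        (frozenset(c) for c in nx.connected_components(G)),
        key=lambda c: sorted(c)[0],
    )
    presence = [
        frozenset(lineage_map[m.split("|", 1)[0]] for m in c) for c in clusters
    ]
    return OrthologClusterSet(clusters=clusters, lineage_presence=presence)


def lineage_sharing(cs: OrthologClusterSet) -> dict[frozenset[str], int]:
    """Cluster counts per lineage-presence combination (Venn-style)."""
    counts: dict[frozenset[str], int] = {}
    for pres in cs.lineage_presence:
        counts[pres] = counts.get(pres, 0) + 1
    return counts


def shared_cluster_proportion(
    cs: OrthologClusterSet, lin_a: str, lin_b: str
) -> float:
    """Proportion of clusters involving lineage a or b that involve both."""
    either = both = 0
    for pres in cs.lineage_presence:
        if lin_a in pres or lin_b in pres:
            either += 1
            if lin_a in pres and lin_b in pres:
                both += 1
    return both / either if either else float("nan")


# ---------------------------------------------------------------------------
# synteny


def synteny_index(
    order_a: Sequence[tuple[str, str]],
    order_b: Sequence[tuple[str, str]],
    rbh: Iterable[OrthologPair],
) -> float:
    """Fraction of ortholog adjacencies of genome a conserved in genome b.

    ``order_a``/``order_b`` are the circular gene orders as (protein_id,
    strand) tuples sorted by forward-strand CDS start.  An adjacency (x, y)
    in a is conserved when the orthologs of x and y are adjacent in b (in
    either order) with consistent relative orientation (both strands
    preserved or both flipped).  A lightweight proxy for whole-genome
    synteny.
    """
    amap = {p.protein_a: p.protein_b for p in rbh}
    if len(amap) < 2:
        raise ValueError("need >= 2 RBH pairs for a synteny index")
    strand_a = dict(order_a)
    strand_b = dict(order_b)
    ord_a = [p for p, _ in order_a if p in amap]
    bset = set(amap.values())
    ord_b = [p for p, _ in order_b if p in bset]
    pos_b = {p: i for i, p in enumerate(ord_b)}
    nb = len(ord_b)
    conserved = 0
    total = 0
    na = len(ord_a)
    for i in range(na):
        x, y = ord_a[i], ord_a[(i + 1) % na]
        if na == 2 and i == 1:
            break  # a 2-gene circle has a single adjacency
        total += 1
        bx, by = amap[x], amap[y]
        d = (pos_b[by] - pos_b[bx]) % nb
        if nb == 2:
            adjacent = True
        else:
            adjacent = d == 1 or d == nb - 1
        if not adjacent:
            continue
        flip_x = strand_a[x] != strand_b[bx]
        flip_y = strand_a[y] != strand_b[by]
        if flip_x == flip_y:
            conserved += 1
    return conserved / total if total else float("nan")


def gene_order(features) -> list[tuple[str, str]]:
    """Circular gene order of an AnnotatedGenome's features by CDS start."""
    return [
        (f.cds_id, f.strand)
        for f in sorted(features, key=lambda f: (f.start, f.cds_id))
    ]


# ---------------------------------------------------------------------------
# tabular output


def write_rbh_tsv(pairs: Iterable[OrthologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_a\tprotein_a\tgenome_b\tprotein_b\tidentity_pct\tbitscore\n")
        for p in pairs:
            fh.write(
                f"{p.genome_a}\t{p.protein_a}\t{p.genome_b}\t{p.protein_b}\t"
                f"{p.identity_pct:.2f}\t{p.bitscore:.1f}\n"
            )


def write_groups_txt(cs: OrthologClusterSet, path: str | Path) -> None:
    """OrthoMCL-style groups text: ``cluster_0001: gA|p12 gB|p7 ...``"""
    with open(path, "w") as fh:
        for i, c in enumerate(cs.clusters, 1):
            fh.write(f"cluster_{i:04d}: " + " ".join(sorted(c)) + "\n")
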