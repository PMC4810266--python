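"""Independent reference implementations used only to check the package.

Everything here is written naively and separately from the library code:
a textbook affine-gap Smith-Waterman, a replayed greedy clustering, and a
brute-force SPR neighborhood on plain adjacency dicts.
"""

from __future__ import annotations

import itertools


def naive_sw_score(a: str, b: str, score, gap_open: int, gap_extend: int) -> int:
    """Textbook O(mn) affine-gap local alignment, score only.

    ``score(x, y)`` is the substitution score; a gap of length k costs
    gap_open + k * gap_extend.
    """
    m, n = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0, H[i - 1][j - 1] + score(a[i - 1], b[j - 1]), E[i][j], F[i][j]
            )
            best = max(best, H[i][j])
    return best


def replay_greedy_clusters(proteins: dict[str, str], matches) -> list[list[str]]:
    """Independent replay of longest-first centroid clustering.

    ``matches(seq_a, seq_b) -> bool`` decides threshold qualification; the
    order rule (descending length, then id; join the oldest matching
    cluster's representative) is re-implemented from scratch.
    """
    order = sorted(proteins, key=lambda p: (-len(proteins[p]), p))
    clusters: list[list[str]] = []
    for pid in order:
        for cl in clusters:
            if matches(proteins[pid], proteins[cl[0]]):
                cl.append(pid)
                break
        else:
            clusters.append([pid])
    return clusters


# ---------------------------------------------------------------------------
# naive SPR on adjacency dicts


def tree_from_newick_simple(s: str):
    """Parse newick (topology only) into (adjacency dict, labels dict)."""
    s = s.strip().rstrip(";")
    adj: dict[int, set[int]] = {}
    labels: dict[int, str] = {}
    counter = itertools.count()

    def new_node(label=None):
        n = next(counter)
        adj[n] = set()
        if label:
            labels[n] = label
        return n

    pos = 0

    def parse():
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            node = new_node()
            while True:
                child = parse()
                adj[node].add(child)
                adj[child].add(node)
                if s[pos] == ",":
                    pos += 1
                else:
                    break
            assert s[pos] == ")"
            pos += 1
            _skip_label()
            return node
        start = pos
        while pos < len(s) and s[pos] not in ",():":
            pos += 1
        name = s[start:pos]
        _skip_label()
        return new_node(name)

    def _skip_label():
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            while pos < len(s) and s[pos] not in ",()":
                pos += 1

    root = parse()
    # unroot a degree-2 root
    if root not in labels and len(adj[root]) == 2:
        x, y = adj[root]
        adj[x].discard(root)
        adj[y].discard(root)
        adj[x].add(y)
        adj[y].add(x)
        del adj[root]
    return adj, labels


def naive_splits(adj, labels) -> frozenset:
    """Non-trivial splits as frozensets of label-frozensets (both sides
    reduced to the side without the min label)."""
    all_labels = frozenset(labels.values())
    ref = min(all_labels)
    n = len(all_labels)
    edges = {frozenset((u, v)) for u in adj for v in adj[u]}
    out = set()
    for e in edges:
        u, v = tuple(e)
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if x in labels:
                side.add(labels[x])
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(side)
        if ref in side:
            side = all_labels - side
        if 1 < len(side) < n - 1:
            out.add(side)
    return frozenset(out)


def naive_spr_neighbors(adj, labels):
    """All topologies (as split sets) one SPR move away, brute force."""
    import copy

    own = naive_splits(adj, labels)
    out = set()
    edges = [(u, v) for u in adj for v in adj[u]]
    for u, v in edges:  # prune component containing v
        if len(adj[u]) == 1:
            continue
        a2 = {k: set(vs) for k, vs in adj.items()}
        a2[u].discard(v)
        a2[v].discard(u)
        if u not in labels and len(a2[u]) == 2:
            x, y = a2[u]
            a2[x].discard(u)
            a2[y].discard(u)
            a2[x].add(y)
            a2[y].add(x)
            del a2[u]
            anchor = x
        else:
            anchor = u
        comp = set()
        stack = [anchor]
        while stack:
            z = stack.pop()
            if z in comp:
                continue
            comp.add(z)
            stack.extend(a2[z])
        targets = {
            frozenset((p, q)) for p in comp for q in a2[p] if q in comp
        }
        for e in targets:
            p, q = tuple(e)
            a3 = {k: set(vs) for k, vs in a2.items()}
            w = max(max(a3), max(labels)) + 1
            a3[p].discard(q)
            a3[q].discard(p)
            a3[w] = {p, q, v}
            a3[p].add(w)
            a3[q].add(w)
            a3[v].add(w)
            key = naive_splits(a3, labels)
            if key != own:
                out.add(key)
    return out
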