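"""Light unrooted leaf-labeled trees: newick I/O, splits, SPR moves.

The phylogeny code needs exact, enumerable tree surgery (subtree
prune-and-regraft neighborhoods, topology canonicalisation) on small trees;
this module provides a minimal adjacency-based structure built for that.
Topologies are compared via their non-trivial splits.
"""

from __future__ import annotations

from typing import Iterable, Iterator


class UnrootedTree:
    """Unrooted tree as an adjacency map; leaves carry string labels.

    Branch lengths are optional (None for topology-only trees).  Internal
    nodes of a binary unrooted tree have degree 3; degree-2 nodes are
    suppressed by the surgery operations.
    """

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float | None]] = {}
        self.labels: dict[int, str] = {}
        self._next = 0

    # -- construction -------------------------------------------------------

    def new_node(self, label: str | None = None) -> int:
        n = self._next
        self._next += 1
        self.adj[n] = {}
        if label is not None:
            self.labels[n] = label
        return n

    def add_edge(self, u: int, v: int, length: float | None = None) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree()
        t.adj = {u: dict(nb) for u, nb in self.adj.items()}
        t.labels = dict(self.labels)
        t._next = self._next
        return t

    # -- queries ------------------------------------------------------------

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(self.labels.values())

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in sorted(self.adj) for v in self.adj[u] if u < v]

    def is_binary(self) -> bool:
        return all(
            self.degree(u) == (1 if u in self.labels else 3) for u in self.adj
        )

    def _side(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels on v's side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            x = stack.pop()
            if x in self.labels:
                out.append(self.labels[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial splits, each canonicalised as the side that does not
        contain the lexicographically smallest leaf."""
        all_leaves = self.leaf_labels()
        ref = min(all_leaves)
        n = len(all_leaves)
        out = set()
        for u, v in self.edges():
            side = self._side(u, v)
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < n - 1:
                out.add(side)
        return frozenset(out)

    def topology_key(self) -> tuple[frozenset[str], frozenset[frozenset[str]]]:
        return (self.leaf_labels(), self.splits())

    # -- surgery ------------------------------------------------------------

    def suppress_degree_two(self) -> None:
        for u in [n for n in self.adj if self.degree(n) == 2 and n not in self.labels]:
            (x, lx), (y, ly) = list(self.adj[u].items())
            self.remove_edge(u, x)
            self.remove_edge(u, y)
            del self.adj[u]
            length = None if lx is None or ly is None else lx + ly
            self.add_edge(x, y, length)

    def prune_leaf(self, label: str) -> None:
        node = next(n for n, lab in self.labels.items() if lab == label)
        (nbr,) = list(self.adj[node])
        self.remove_edge(node, nbr)
        del self.adj[node]
        del self.labels[node]
        if nbr not in self.labels and self.degree(nbr) == 2:
            self.suppress_degree_two()

    def restrict(self, labels: Iterable[str]) -> "UnrootedTree":
        keep = set(labels)
        t = self.copy()
        for lab in sorted(t.leaf_labels() - keep):
            t.prune_leaf(lab)
        return t

    # -- SPR ----------------------------------------------------------------

    def spr_neighbors(self) -> Iterator["UnrootedTree"]:
        """All distinct topologies one SPR move away (topology-only).

        For each directed edge (u, v): detach the subtree on v's side,
        suppress the degree-2 remnant of u, and regraft v onto every
        remaining edge.  Duplicate topologies (and the original) are
        filtered out.
        """
        own = self.splits()
        seen = {own}
        for u in sorted(self.adj):
            for v in sorted(self.adj[u]):
                if self.degree(u) == 1:
                    continue  # nothing left to regraft onto
                t0 = self.copy()
                t0.remove_edge(u, v)
                nbrs = list(t0.adj[u])
                if len(nbrs) == 2:
                    x, y = nbrs
                    t0.remove_edge(u, x)
                    t0.remove_edge(u, y)
                    del t0.adj[u]
                    t0.add_edge(x, y)
                # remaining component = the one containing x (or u)
                anchor = nbrs[0]
                comp = set()
                stack = [anchor]
                while stack:
                    a = stack.pop()
                    if a in comp:
                        continue
                    comp.add(a)
                    stack.extend(t0.adj[a])
                targets = [
                    (p, q)
                    for p in sorted(comp)
                    for q in t0.adj[p]
                    if p < q and q in comp
                ]
                for p, q in targets:
                    t = t0.copy()
                    w = t.new_node()
                    t.remove_edge(p, q)
                    t.add_edge(p, w)
                    t.add_edge(w, q)
                    t.add_edge(w, v)
                    key = t.splits()
                    if key not in seen:
                        seen.add(key)
                        yield t

    # -- newick -------------------------------------------------------------

    def to_newick(self, lengths: bool = True) -> str:
        """Deterministic newick: rooted at the internal node adjacent to the
        lexicographically smallest leaf; children ordered by smallest
        descendant label."""
        if len(self.labels) == 1:
            (lab,) = self.labels.values()
            return f"{lab};"
        min_leaf = min(self.labels, key=lambda n: self.labels[n])
        if len(self.labels) == 2:
            a, b = sorted(self.labels.values())
            ln = next(iter(self.adj[min_leaf].values()))
            s = f":{ln:.6g}" if lengths and ln is not None else ""
            return f"({a}{s},{b}{s});"
        root = next(iter(self.adj[min_leaf]))

        def fmt(u: int, parent: int, blen: float | None) -> tuple[str, str]:
            if u in self.labels:
                body = self.labels[u]
                key = self.labels[u]
            else:
                parts = sorted(
                    fmt(w, u, self.adj[u][w]) for w in self.adj[u] if w != parent
                )
                body = "(" + ",".join(p[1] for p in parts) + ")"
                key = min(p[0] for p in parts)
            if lengths and blen is not None:
                body = f"{body}:{blen:.6g}"
            return key, body

        parts = sorted(fmt(w, root, self.adj[root][w]) for w in self.adj[root])
        return "(" + ",".join(p[1] for p in parts) + ");"

    @classmethod
    def from_newick(cls, s: str) -> "UnrootedTree":
        """Parse a newick string (names, optional branch lengths) and unroot
        it (a degree-2 root is suppressed)."""
        s = s.strip()
        if not s.endswith(";"):
            raise ValueError("newick string must end with ';'")
        s = s[:-1]
        t = cls()
        pos = 0

        def parse() -> tuple[int, float | None]:
            nonlocal pos
            if s[pos] == "(":
                pos += 1
                node = t.new_node()
                while True:
                    child, blen = parse()
                    t.add_edge(node, child, blen)
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
                name, blen = parse_label()
                if name:
                    t.labels[node] = name
                return node, blen
            name, blen = parse_label()
            node = t.new_node(name or None)
            return node, blen

        def parse_label() -> tuple[str, float | None]:
            nonlocal pos
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            token = s[start:pos]
            blen = None
            if ":" in token:
                name, _, num = token.partition(":")
                blen = float(num)
            elif pos < len(s) and s[pos] == ":":
                pos += 1
                start = pos
                while pos < len(s) and s[pos] not in ",():;":
                    pos += 1
                name = token
                blen = float(s[start:pos])
            else:
                name = token
            return name, blen

        root, _ = parse()
        if pos != len(s):
            raise ValueError(f"trailing characters in newick: {s[pos:]!r}")
        if root not in t.labels and t.degree(root) == 2:
            t.suppress_degree_two()
        return t


def enumerate_topologies(labels: Iterable[str]) -> Iterator[UnrootedTree]:
    """All (2n-5)!! unrooted binary topologies on a leaf set, each once,
    by recursive leaf insertion in sorted label order."""
    labs = sorted(set(labels))
    if len(labs) < 3:
        raise ValueError("need >= 3 leaves")

    base = UnrootedTree()
    c = base.new_node()
    for lab in labs[:3]:
        leaf = base.new_node(lab)
        base.add_edge(c, leaf)

    def grow(t: UnrootedTree, remaining: list[str]) -> Iterator[UnrootedTree]:
        if not remaining:
            yield t
            return
        lab = remaining[0]
        for u, v in t.edges():
            t2 = t.copy()
            w = t2.new_node()
            t2.remove_edge(u, v)
            t2.add_edge(u, w)
            t2.add_edge(w, v)
            leaf = t2.new_node(lab)
            t2.add_edge(w, leaf)
            yield from grow(t2, remaining[1:])

    yield from grow(base, labs[3:])


# ---------------------------------------------------------------------------
# bitmask topology keys
#
# For SPR searches, a topology over sorted leaf labels l_0 < l_1 < ... is
# encoded as a frozenset of integer bitmasks, one per non-trivial split,
# each mask being the split side that excludes bit 0.  All SPR-neighbor
# enumeration is pure integer arithmetic on these keys — no tree objects.


def mask_key(t: UnrootedTree) -> tuple[tuple[str, ...], frozenset[int]]:
    """(sorted labels, split-mask set) canonical topology key."""
    labels = tuple(sorted(t.leaf_labels()))
    bit = {lab: 1 << i for i, lab in enumerate(labels)}
    n = len(labels)
    U = (1 << n) - 1
    masks = set()
    for u, v in t.edges():
        side = 0
        for lab in t._side(u, v):
            side |= bit[lab]
        if side & 1:
            side = U ^ side
        if 1 < side.bit_count() < n - 1:
            masks.add(side)
    return labels, frozenset(masks)


def _edge_masks(key: frozenset[int], n: int) -> list[int]:
    """All 2n-3 edge side-masks (trivial + internal) of a binary topology."""
    U = (1 << n) - 1
    edges = set(key)
    for i in range(1, n):
        edges.add(1 << i)
    edges.add(U ^ 1)  # edge of leaf 0, canonical side
    return sorted(edges)


def key_neighbors(key: frozenset[int], n: int) -> set[frozenset[int]]:
    """All distinct topology keys one SPR move away."""
    U = (1 << n) - 1
    edges = _edge_masks(key, n)
    out: set[frozenset[int]] = set()
    for m in edges:
        for S in (m, U ^ m):
            Up = U & ~S
            if Up.bit_count() < 2:
                continue
            rp = Up & -Up  # lowest bit = local reference leaf
            eprime = set()
            for g in edges:
                x = g & Up
                if x == 0 or x == Up:
                    continue
                if x & rp:
                    x = Up ^ x
                eprime.add(x)
            # splits internal to the pruned subtree survive unchanged
            inner = []
            for g in edges:
                y = g if (g & ~S) == 0 else (U ^ g if ((U ^ g) & ~S) == 0 else 0)
                if y and y != S:
                    inner.append(y)
            elist = sorted(eprime)
            for f in elist:
                sides = [S, f, f | S] + inner
                for g in elist:
                    if g == f:
                        continue
                    sides.append(g | S if (f & ~g) == 0 else g)
                new = set()
                for x in sides:
                    if x & 1:
                        x = U ^ x
                    if 1 < x.bit_count() < n - 1:
                        new.add(x)
                nk = frozenset(new)
                if nk != key:
                    out.add(nk)
    return out


def tree_from_key(key: frozenset[int], labels: tuple[str, ...]) -> UnrootedTree:
    """Rebuild an UnrootedTree (topology only) from a split-mask key."""
    n = len(labels)
    U = (1 << n) - 1
    t = UnrootedTree()
    root = t.new_node()  # internal node adjacent to leaf 0
    t.add_edge(root, t.new_node(labels[0]))

    def build(mask: int, parent: int) -> None:
        if mask.bit_count() == 1:
            leaf = t.new_node(labels[mask.bit_length() - 1])
            t.add_edge(parent, leaf)
            return
        node = t.new_node()
        t.add_edge(parent, node)
        children = _maximal_partition(mask)
        for c in children:
            build(c, node)

    def _maximal_partition(mask: int) -> list[int]:
        subs = [m for m in key if m != mask and (m & ~mask) == 0]
        maximal = []
        for m in sorted(subs, key=lambda x: -x.bit_count()):
            if not any((m & ~q) == 0 for q in maximal):
                maximal.append(m)
        covered = 0
        for m in maximal:
            covered |= m
        for i in range(n):
            b = 1 << i
            if (mask & b) and not (covered & b):
                maximal.append(b)
        return maximal

    for c in _maximal_partition(U ^ 1):
        build(c, root)
    return t


def key_spr_distance(
    k1: frozenset[int], k2: frozenset[int], n: int, max_depth: int | None = None
) -> int:
    """Exact SPR distance between two topology keys (bidirectional BFS)."""
    if k1 == k2:
        return 0
    cap = max_depth if max_depth is not None else max(n, 4)
    side_a = {k1: 0}
    side_b = {k2: 0}
    frontier_a, frontier_b = [k1], [k2]
    da = db = 0
    while da + db < cap:
        # expand the smaller frontier
        if len(frontier_a) <= len(frontier_b):
            frontier, dist, other = frontier_a, side_a, side_b
            da += 1
            d = da
        else:
            frontier, dist, other = frontier_b, side_b, side_a
            db += 1
            d = db
        nxt = []
        for k in frontier:
            for nb in key_neighbors(k, n):
                if nb in dist:
                    continue
                if nb in other:
                    return d + other[nb]
                dist[nb] = d
                nxt.append(nb)
        if not nxt:
            break
        if frontier is frontier_a:
            frontier_a = nxt
        else:
            frontier_b = nxt
    raise RuntimeError("SPR bidirectional search exceeded depth cap")


def key_distance_map(
    key: frozenset[int], n: int, max_depth: int | None = None
) -> dict[frozenset[int], int]:
    """BFS distances from a topology key (whole space if max_depth None)."""
    dist = {key: 0}
    frontier = [key]
    d = 0
    while frontier and (max_depth is None or d < max_depth):
        d += 1
        nxt = []
        for k in frontier:
            for nb in key_neighbors(k, n):
                if nb not in dist:
                    dist[nb] = d
                    nxt.append(nb)
        frontier = nxt
    return dist


def rf_distance(t1: UnrootedTree, t2: UnrootedTree) -> int:
    """Robinson-Foulds distance (count of splits unique to either tree)."""
    if t1.leaf_labels() != t2.leaf_labels():
        raise ValueError("leaf sets differ")
    s1, s2 = t1.splits(), t2.splits()
    return len(s1 ^ s2)
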