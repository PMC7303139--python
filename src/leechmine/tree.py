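"""Unrooted gene trees and clan-based orthology testing.

A clan is a leaf set separated from all other leaves by a single edge of an
unrooted tree -- the unrooted analogue of a monophyletic group.  The bundled
tree builder is distance-based (Poisson-corrected distances + neighbor
joining with bootstrap resampling); externally computed trees, e.g. from a
maximum-likelihood program, can be imported as newick with supports stored
as internal node labels and are analysed identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .align import semiglobal_align
from .records import ProteinRecord
from .scoring import ScoringScheme

#: Bootstrap / likelihood support below which a clan is called unsupported.
DEFAULT_SUPPORT_THRESHOLD = 75.0

#: Cap on the observed difference fraction before Poisson correction.
MAX_P_DISTANCE = 0.95


@dataclass
class Edge:
    length: float = 0.0
    support: float | None = None


class UnrootedTree:
    """Leaf-labelled unrooted tree with branch lengths and edge supports."""

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, Edge]] = {}
        self.leaf_label: dict[int, str] = {}
        self._next_id = 0

    # -- construction -----------------------------------------------------

    def add_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = {}
        if label is not None:
            if label in self.leaf_label.values():
                raise ValueError(f"duplicate leaf label {label!r}")
            self.leaf_label[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float = 0.0,
                 support: float | None = None) -> None:
        e = Edge(length=max(length, 0.0), support=support)
        self.adj[u][v] = e
        self.adj[v][u] = e

    def remove_node(self, u: int) -> None:
        for v in list(self.adj[u]):
            del self.adj[v][u]
        del self.adj[u]
        self.leaf_label.pop(u, None)

    # -- queries ----------------------------------------------------------

    @property
    def leaves(self) -> set[str]:
        return set(self.leaf_label.values())

    def node_of(self, label: str) -> int:
        for nid, lab in self.leaf_label.items():
            if lab == label:
                return nid
        raise KeyError(label)

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def edges(self):
        """Iterate (u, v, Edge) with u < v."""
        for u, nbrs in self.adj.items():
            for v, e in nbrs.items():
                if u < v:
                    yield u, v, e

    def is_internal_edge(self, u: int, v: int) -> bool:
        return self.degree(u) > 1 and self.degree(v) > 1

    def side_leaves(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels on the v side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = []
        while stack:
            x = stack.pop()
            if x in self.leaf_label:
                out.append(self.leaf_label[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def bipartitions(self):
        """Iterate (leafset_on_v_side, Edge, (u, v)) over all edges."""
        for u, v, e in self.edges():
            yield self.side_leaves(u, v), e, (u, v)

    def clans(self) -> list[frozenset[str]]:
        """All clans: both sides of every edge."""
        all_leaves = frozenset(self.leaves)
        out = []
        for side, _, _ in self.bipartitions():
            out.append(side)
            out.append(all_leaves - side)
        return out

    def path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        start, goal = self.node_of(a), self.node_of(b)
        dist = {start: 0.0}
        stack = [start]
        while stack:
            x = stack.pop()
            if x == goal:
                return dist[x]
            for y, e in self.adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + e.length
                    stack.append(y)
        raise ValueError("tree is not connected")

    def distance_matrix(self) -> "DistanceMatrix":
        labels = sorted(self.leaves)
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = self.path_distance(labels[i], labels[j])
        return DistanceMatrix(labels=labels, d=d)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and non-negative")


@dataclass
class ClanResult:
    query: str
    archetype: str
    smallest_clan: frozenset[str]
    support: float | None
    is_pair_clan: bool
    call: str  # orthologue_supported | orthologue_unsupported | not_orthologue
    is_trivial: bool = False


# -- newick I/O -----------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> UnrootedTree:
    tree = UnrootedTree()
    node_map: dict = {}
    for node in dtree.preorder_node_iter():
        label = node.taxon.label if node.taxon is not None else None
        if node.is_leaf() and label is None:
            label = node.label
        nid = tree.add_node(label if node.is_leaf() else None)
        node_map[node] = nid
        if node.parent_node is not None:
            support = None
            if not node.is_leaf() and node.label is not None:
                try:
                    support = float(node.label)
                except ValueError:
                    support = None
            length = node.edge.length if node.edge.length is not None else 0.0
            tree.add_edge(node_map[node.parent_node], nid, length=length,
                          support=support)
    # dissolve a rooted (degree-2) root by merging its two edges
    root = node_map[dtree.seed_node]
    if tree.degree(root) == 2 and root not in tree.leaf_label:
        (a, ea), (b, eb) = tree.adj[root].items()
        support = ea.support if ea.support is not None else eb.support
        tree.remove_node(root)
        tree.add_edge(a, b, length=ea.length + eb.length, support=support)
    return tree


def read_newick(source: str | Path) -> UnrootedTree:
    """Read a newick tree (file path or string); any rooting is dissolved.

    Internal node labels, when numeric, are attached to the subtending edge
    as supports.
    """
    text = None
    if isinstance(source, Path) or ("(" not in str(source)):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: UnrootedTree, path: str | Path | None = None) -> str:
    """Serialise as newick, supports as internal node labels."""

    # root at an internal node when one exists, else at the first leaf
    internal = [n for n in tree.adj if n not in tree.leaf_label]
    root = internal[0] if internal else min(tree.adj)

    def emit(u: int, parent: int | None, edge: Edge | None) -> str:
        children = [(v, e) for v, e in sorted(tree.adj[u].items()) if v != parent]
        if not children:
            s = tree.leaf_label.get(u, "")
        else:
            inner = ",".join(emit(v, u, e) for v, e in children)
            label = ""
            if edge is not None and edge.support is not None:
                label = format(edge.support, "g")
            s = f"({inner}){label}"
        if edge is not None:
            s += f":{edge.length:.17g}"
        return s

    out = emit(root, None, None) + ";"
    if path is not None:
        Path(path).write_text(out + "\n")
    return out


# -- distances ------------------------------------------------------------


def poisson_distance(a: ProteinRecord, b: ProteinRecord,
                     scheme: ScoringScheme) -> float:
    """Poisson-corrected distance -ln(1-p) from a pairwise global alignment.

    p is the differing fraction of shared (gap-free) columns, capped at 0.95
    so saturated pairs stay finite.
    """
    res = semiglobal_align(a.sequence, b.sequence, scheme)
    shared = diff = 0
    for ca, cb in zip(res.row_a, res.row_b):
        if ca == "-" or cb == "-":
            continue
        shared += 1
        if ca != cb:
            diff += 1
    if shared == 0:
        raise ValueError(f"no shared columns between {a.id!r} and {b.id!r}")
    p = min(diff / shared, MAX_P_DISTANCE)
    return -math.log(1.0 - p)


def msa_distance_matrix(ids: list[str], rows: list[str],
                        columns: np.ndarray | None = None) -> DistanceMatrix:
    """Poisson distances between MSA rows over shared columns.

    ``columns`` optionally selects (with repetition) a column resample, as
    used by the bootstrap.
    """
    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)
    if columns is not None:
        arr = arr[:, columns]
    gap = arr == b"-"
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(gap[i] | gap[j])
            ns = int(shared.sum())
            if ns == 0:
                p = MAX_P_DISTANCE
            else:
                p = min(float((arr[i, shared] != arr[j, shared]).sum()) / ns,
                        MAX_P_DISTANCE)
            d[i, j] = d[j, i] = -math.log(1.0 - p)
    order = np.argsort(np.array(ids))
    labels = [ids[k] for k in order]
    return DistanceMatrix(labels=labels, d=d[np.ix_(order, order)])


# -- neighbor joining ------------------------------------------------------


def nj_tree(D: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei neighbor joining with a deterministic tie-break.

    When several pairs minimise the Q criterion, the pair whose clusters have
    the lexicographically smallest representative leaf labels is joined, so
    the topology is invariant under permutations of the input label order.
    Negative branch-length estimates are clamped to zero.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = UnrootedTree()
    nodes = [tree.add_node(lab) for lab in D.labels]
    reps = list(D.labels)  # representative (min leaf label) per active cluster
    d = D.d.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, tuple(sorted((reps[i], reps[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        new = tree.add_node()
        tree.add_edge(new, nodes[i], length=max(li, 0.0))
        tree.add_edge(new, nodes[j], length=max(lj, 0.0))
        # distances to the new cluster
        k_new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[k_new, k] = d[k, k_new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [k_new]

    i, j, k = active
    hub = tree.add_node()
    tree.add_edge(hub, nodes[i], length=max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0))
    tree.add_edge(hub, nodes[j], length=max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0))
    tree.add_edge(hub, nodes[k], length=max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0))
    return tree


def bootstrap_support(msa, n_reps: int = 1000, seed: int = 0) -> UnrootedTree:
    """NJ tree from an MSA with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each internal
    edge of the full-data tree gets the percentage of replicates whose tree
    contains the same leaf bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(msa.ids) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    rng = np.random.default_rng(seed)
    full = nj_tree(msa_distance_matrix(msa.ids, msa.rows))
    all_leaves = frozenset(full.leaves)
    targets = {}
    for side, e, _ in full.bipartitions():
        comp = all_leaves - side
        key = min(side, comp, key=sorted)
        targets[key] = e
    counts = {key: 0 for key in targets}
    ncols = len(msa.rows[0])
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep = nj_tree(msa_distance_matrix(msa.ids, msa.rows, columns=cols))
        rep_parts = set()
        for side, _, _ in rep.bipartitions():
            comp = all_leaves - side
            rep_parts.add(min(side, comp, key=sorted))
        for key in counts:
            if key in rep_parts:
                counts[key] += 1
    for key, e in targets.items():
        e.support = 100.0 * counts[key] / n_reps
    return full


# -- clan analysis ---------------------------------------------------------


def is_clan(tree: UnrootedTree, S: set[str]) -> bool:
    """True iff one edge's removal separates S exactly from the other leaves."""
    S = frozenset(S)
    all_leaves = frozenset(tree.leaves)
    if not S or S == all_leaves:
        raise ValueError("S must be a non-empty proper subset of the leaves")
    if not S <= all_leaves:
        raise ValueError("S contains labels not in the tree")
    for side, _, _ in tree.bipartitions():
        if side == S or all_leaves - side == S:
            return True
    return False


def smallest_clan(
    tree: UnrootedTree,
    must_contain: set[str],
    families: dict[str, str] | None = None,
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    query: str | None = None,
    archetype: str | None = None,
) -> ClanResult:
    """Smallest clan containing all of ``must_contain``, with an orthology call.

    The call is ``not_orthologue`` when the clan holds a leaf annotated with
    a family different from the query/archetype's; otherwise orthologue,
    supported iff the defining edge's support reaches the threshold.  Ties
    between equally small clans (possible on multifurcating imports) prefer a
    support-bearing clan, then the lexicographically smallest leaf set.
    """
    must = frozenset(must_contain)
    if len(must) < 2:
        raise ValueError("must_contain needs at least 2 leaves")
    all_leaves = frozenset(tree.leaves)
    if not must <= all_leaves:
        raise ValueError("must_contain has labels not in the tree")
    query = query if query is not None else sorted(must)[0]
    archetype = archetype if archetype is not None else sorted(must)[1]

    if must == all_leaves:
        return ClanResult(query=query, archetype=archetype,
                          smallest_clan=all_leaves, support=None,
                          is_pair_clan=False, call="orthologue_unsupported",
                          is_trivial=True)

    candidates = []
    for side, e, _ in tree.bipartitions():
        comp = all_leaves - side
        for clan in (side, comp):
            if must <= clan and clan != all_leaves:
                candidates.append((clan, e.support))
    if not candidates:
        return ClanResult(query=query, archetype=archetype,
                          smallest_clan=all_leaves, support=None,
                          is_pair_clan=False, call="orthologue_unsupported",
                          is_trivial=True)
    candidates.sort(key=lambda c: (len(c[0]), c[1] is None, sorted(c[0])))
    clan, support = candidates[0]

    fam = (families or {}).get(query) or (families or {}).get(archetype)
    foreign = False
    if families:
        for leaf in clan:
            lf = families.get(leaf)
            if lf is not None and fam is not None and lf != fam:
                foreign = True
                break
    is_pair = not foreign and all(
        leaf in (query, archetype)
        or (families or {}).get(leaf) == fam
        for leaf in clan
    )
    if foreign:
        call = "not_orthologue"
    elif support is not None and support >= support_threshold:
        call = "orthologue_supported"
    else:
        call = "orthologue_unsupported"
    return ClanResult(query=query, archetype=archetype, smallest_clan=clan,
                      support=support, is_pair_clan=is_pair, call=call)


def adjacent_group(tree: UnrootedTree, clan: set[str]) -> list[frozenset[str]]:
    """The clans adjacent (sister, in rooted terms) to the given clan.

    These are the maximal clans B disjoint from the input with B united with
    the input also a clan: the leaf sets hanging off the other edges at the
    complement-side endpoint of the clan's defining edge.
    """
    clan = frozenset(clan)
    all_leaves = frozenset(tree.leaves)
    defining = None
    for side, e, (u, v) in tree.bipartitions():
        if side == clan:
            defining = (v, u)  # clan on v side; complement endpoint u
            break
        if all_leaves - side == clan:
            defining = (u, v)
            break
    if defining is None:
        raise ValueError("input leaf set is not a clan of this tree")
    _, comp_node = defining
    return [
        tree.side_leaves(comp_node, w)
        for w in sorted(tree.adj[comp_node])
        if w != defining[0]
    ]
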