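"""Independent brute-force oracles used by the test suite.

These deliberately avoid dynamic programming: alignments are enumerated as
monotone matched-subsequence pairs, clans by explicit bipartition listing,
and tree distances by path walking, so they share no code path with the
implementation they check.
"""

from __future__ import annotations

import itertools
import random


def enumerate_alignment_best(a: str, b: str, score, gap_open: int,
                             gap_extend: int, mode: str = "local"):
    """Best gapped alignment score by exhaustive enumeration.

    Every alignment with >= 1 aligned column is generated as a pair of
    strictly increasing index tuples (the matched columns); residues between
    consecutive matches form one gap run per row, costing
    gap_open + gap_extend * run_length.  In local mode residues outside the
    first/last match cost nothing.  In semiglobal mode one leading and one
    lagging gap are free, so when both sequences have unmatched residues at
    an end the cheaper run is charged.
    """

    def gapcost(length):
        return gap_open + gap_extend * length if length > 0 else 0

    n, m = len(a), len(b)
    best = None
    for k in range(1, min(n, m) + 1):
        for ii in itertools.combinations(range(n), k):
            for jj in itertools.combinations(range(m), k):
                s = 0
                for x, y in zip(ii, jj):
                    s += score(a[x], b[y])
                for t in range(k - 1):
                    s -= gapcost(ii[t + 1] - ii[t] - 1)
                    s -= gapcost(jj[t + 1] - jj[t] - 1)
                if mode == "semiglobal":
                    lead_a, lead_b = ii[0], jj[0]
                    if lead_a and lead_b:
                        s -= min(gapcost(lead_a), gapcost(lead_b))
                    trail_a, trail_b = n - 1 - ii[-1], m - 1 - jj[-1]
                    if trail_a and trail_b:
                        s -= min(gapcost(trail_a), gapcost(trail_b))
                if best is None or s > best:
                    best = s
    if mode == "semiglobal":
        # the matchless alignment: one sequence skipped free, the other paid
        matchless = -(gap_open + gap_extend * min(n, m))
        if best is None or matchless > best:
            best = matchless
    return best


def all_bipartitions(tree):
    """All (side, complement) leaf-set pairs of an UnrootedTree, by edge."""
    leaves = frozenset(tree.leaves)
    out = []
    for u, v, _ in tree.edges():
        side = tree.side_leaves(u, v)
        out.append((side, leaves - side))
    return out


def brute_is_clan(tree, S):
    S = frozenset(S)
    return any(S in pair for pair in all_bipartitions(tree))


def brute_smallest_clan(tree, must):
    """Minimum-size clan containing must, by exhaustive listing."""
    must = frozenset(must)
    leaves = frozenset(tree.leaves)
    best = None
    for side, comp in all_bipartitions(tree):
        for clan in (side, comp):
            if must <= clan and clan != leaves:
                if best is None or (len(clan), sorted(clan)) < (len(best), sorted(best)):
                    best = clan
    return best


def random_binary_tree(labels, rng: random.Random, min_len=0.1, max_len=1.0):
    """Random unrooted binary tree by sequential leaf attachment."""
    from leechmine.tree import UnrootedTree

    tree = UnrootedTree()
    if len(labels) < 3:
        raise ValueError("need >= 3 leaves")
    hub = tree.add_node()
    for lab in labels[:3]:
        leaf = tree.add_node(lab)
        tree.add_edge(hub, leaf, length=rng.uniform(min_len, max_len))
    for lab in labels[3:]:
        edges = list(tree.edges())
        u, v, e = edges[rng.randrange(len(edges))]
        mid = tree.add_node()
        length = e.length
        split = rng.uniform(0.2, 0.8)
        del tree.adj[u][v]
        del tree.adj[v][u]
        tree.add_edge(u, mid, length=length * split)
        tree.add_edge(mid, v, length=length * (1 - split))
        leaf = tree.add_node(lab)
        tree.add_edge(mid, leaf, length=rng.uniform(min_len, max_len))
    return tree
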