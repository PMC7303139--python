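"""Progressive multiple alignment over a neighbor-joining guide tree.

Pairwise Poisson distances give the guide tree; profiles are merged in
post-order with affine-gap profile-profile alignment.  Column scores between
profiles are sums of pairwise substitution scores (gap against residue
scores zero), which keeps the dynamic programme integer-valued and the
traceback bit-exact.  This is a deliberately plain progressive aligner: no
iterative refinement, no position-specific gap penalties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import _DIAG, _LEFT, _UP, align_grid
from .records import ProteinRecord
from .scoring import ScoringScheme
from .tree import DistanceMatrix, UnrootedTree, nj_tree, poisson_distance


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{r}\n" for i, r in zip(self.ids, self.rows))


def _profile_counts(rows: list[str], scheme: ScoringScheme) -> np.ndarray:
    """Column x letter residue counts (gaps contribute nothing)."""
    k = len(scheme.alphabet)
    ncols = len(rows[0])
    counts = np.zeros((ncols, k), dtype=np.int64)
    index = {aa: i for i, aa in enumerate(scheme.alphabet)}
    for row in rows:
        for c, ch in enumerate(row):
            if ch != "-":
                counts[c, index[ch]] += 1
    return counts


def _merge_profiles(a: MultipleAlignment, b: MultipleAlignment,
                    scheme: ScoringScheme) -> MultipleAlignment:
    ca = _profile_counts(a.rows, scheme)
    cb = _profile_counts(b.rows, scheme)
    # sum-of-pairs grid is integer; scale gap costs by the pair count so the
    # relative weighting matches the average-score formulation exactly
    grid = (ca @ scheme.matrix @ cb.T).astype(np.float64)
    scale = len(a.rows) * len(b.rows)
    res = align_grid(grid, scheme.gap_open * scale, scheme.gap_extend * scale,
                     mode="semiglobal")
    rows_a = ["" for _ in a.rows]
    rows_b = ["" for _ in b.rows]
    for move, i, j in res.path:
        if move == _DIAG:
            for k, r in enumerate(a.rows):
                rows_a[k] += r[i - 1]
            for k, r in enumerate(b.rows):
                rows_b[k] += r[j - 1]
        elif move == _UP:
            for k, r in enumerate(a.rows):
                rows_a[k] += r[i - 1]
            for k in range(len(b.rows)):
                rows_b[k] += "-"
        else:
            for k in range(len(a.rows)):
                rows_a[k] += "-"
            for k, r in enumerate(b.rows):
                rows_b[k] += r[j - 1]
    return MultipleAlignment(ids=a.ids + b.ids, rows=rows_a + rows_b)


def progressive_msa(seqs: list[ProteinRecord],
                    scheme: ScoringScheme) -> MultipleAlignment:
    """Align sequences progressively along an NJ guide tree.

    With two sequences this reduces to the pairwise global alignment; a
    single sequence is returned unchanged as a one-row alignment.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return MultipleAlignment(ids=[seqs[0].id], rows=[seqs[0].sequence])
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(seqs) == 2:
        msa = _merge_profiles(
            MultipleAlignment([seqs[0].id], [seqs[0].sequence]),
            MultipleAlignment([seqs[1].id], [seqs[1].sequence]),
            scheme,
        )
        return msa

    n = len(seqs)
    d = np.zeros((n, n))
    order = sorted(range(n), key=lambda i: ids[i])
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = poisson_distance(seqs[order[a]], seqs[order[b]], scheme)
    guide: UnrootedTree = nj_tree(
        DistanceMatrix(labels=[ids[i] for i in order], d=d)
    )
    by_id = {s.id: s for s in seqs}

    # root the guide at its last-created hub and merge in post-order,
    # children visited in order of their smallest leaf label
    root = max(guide.adj)

    def subtree_min(u: int, parent: int) -> str:
        if u in guide.leaf_label:
            return guide.leaf_label[u]
        return min(subtree_min(v, u) for v in guide.adj[u] if v != parent)

    def build(u: int, parent: int | None) -> MultipleAlignment:
        if u in guide.leaf_label:
            s = by_id[guide.leaf_label[u]]
            return MultipleAlignment([s.id], [s.sequence])
        children = sorted(
            (v for v in guide.adj[u] if v != parent),
            key=lambda v: subtree_min(v, u),
        )
        acc = build(children[0], u)
        for v in children[1:]:
            acc = _merge_profiles(acc, build(v, u), scheme)
        return acc

    msa = build(root, None)
    # restore the input order
    pos = {pid: k for k, pid in enumerate(msa.ids)}
    return MultipleAlignment(ids=ids, rows=[msa.rows[pos[i]] for i in ids])
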