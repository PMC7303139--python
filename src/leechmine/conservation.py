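"""Candidate-vs-archetype conservation reports.

Each candidate is globally aligned to its archetype with free terminal gaps,
terminal gap columns are truncated, and statistics are computed over the
remaining columns: percent identity/similarity over shared (gap-free)
columns, conservation of the archetype's cysteine positions, internal indel
spans and the longest homopolymer run per sequence.

"Similarity" counts identical residues plus positive-scoring substitutions;
both identity and similarity are always reported because usage of the word
in the literature is loose.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .align import semiglobal_align
from .records import ProteinRecord
from .scoring import ScoringScheme


@dataclass
class PairwiseAlignment:
    """Two equal-length gapped rows plus bookkeeping."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str
    trimmed: bool = False
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows must have equal length")
        if any(a == "-" and b == "-" for a, b in zip(self.row_a, self.row_b)):
            raise ValueError("alignment contains a gap-only column")

    def __len__(self) -> int:
        return len(self.row_a)

    def column_map(self) -> list[tuple[int | None, int | None]]:
        """Per column: (residue index in a | None, residue index in b | None), 1-based."""
        out = []
        ia = ib = 0
        for ca, cb in zip(self.row_a, self.row_b):
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
            out.append((ia if ca != "-" else None, ib if cb != "-" else None))
        return out


@dataclass
class ConservationReport:
    pct_identity_shared: float
    pct_similarity_shared: float
    n_shared_columns: int
    cys_in_archetype: int
    cys_conserved: int
    indel_spans: list[tuple[str, int, int]]  # (row label 'a'|'b', start column, length)
    max_homopolymer: dict[str, tuple[str, int]]  # row label -> (residue, run length)


def global_align(a: ProteinRecord, b: ProteinRecord, scheme: ScoringScheme) -> PairwiseAlignment:
    """Optimal global alignment with affine internal gaps and free end gaps."""
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    res = semiglobal_align(a.sequence, b.sequence, scheme)
    return PairwiseAlignment(
        id_a=a.id, id_b=b.id, row_a=res.row_a, row_b=res.row_b, score=res.score
    )


def trim_terminal_gaps(aln: PairwiseAlignment) -> PairwiseAlignment:
    """Truncate leading and lagging gap columns; internal gaps are kept."""
    n = len(aln)
    lead = 0
    while lead < n and ("-" in (aln.row_a[lead], aln.row_b[lead])):
        lead += 1
    if lead == n:
        raise ValueError("alignment has no gap-free column; nothing to keep")
    lag = n
    while lag > lead and ("-" in (aln.row_a[lag - 1], aln.row_b[lag - 1])):
        lag -= 1
    return PairwiseAlignment(
        id_a=aln.id_a,
        id_b=aln.id_b,
        row_a=aln.row_a[lead:lag],
        row_b=aln.row_b[lead:lag],
        trimmed=True,
        score=aln.score,
    )


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal gap runs as (1-based start column, length)."""
    runs = []
    start = None
    for i, c in enumerate(row):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start + 1, i - start))
            start = None
    if start is not None:
        runs.append((start + 1, len(row) - start))
    return runs


def _max_homopolymer(seq: str) -> tuple[str, int]:
    best, best_len = "", 0
    cur, cur_len = "", 0
    for c in seq:
        if c == cur:
            cur_len += 1
        else:
            cur, cur_len = c, 1
        if cur_len > best_len:
            best, best_len = cur, cur_len
    return best, best_len


def conservation_stats(
    aln: PairwiseAlignment,
    scheme: ScoringScheme,
    archetype_row: str = "b",
) -> ConservationReport:
    """Conservation statistics over a trimmed candidate/archetype alignment.

    Shared columns are those with a residue in both rows; identity and
    similarity are percentages of shared columns.  Cysteine conservation
    counts archetype cysteines whose column holds C in both rows.
    """
    if not aln.trimmed:
        raise ValueError("statistics are defined over a trimmed alignment")
    if archetype_row not in ("a", "b"):
        raise ValueError("archetype_row must be 'a' or 'b'")
    arch = aln.row_a if archetype_row == "a" else aln.row_b
    shared = ident = simil = 0
    cys_total = cys_cons = 0
    for ca, cb in zip(aln.row_a, aln.row_b):
        arch_c = ca if archetype_row == "a" else cb
        if arch_c == "C":
            cys_total += 1
            if ca == "C" and cb == "C":
                cys_cons += 1
        if ca == "-" or cb == "-":
            continue
        shared += 1
        if ca == cb:
            ident += 1
            simil += 1
        elif scheme.score(ca, cb) > 0:
            simil += 1
    if shared == 0:
        raise ValueError("zero shared columns; no basis for statistics")
    indels = [("a", s, l) for s, l in _gap_runs(aln.row_a)] + \
             [("b", s, l) for s, l in _gap_runs(aln.row_b)]
    indels.sort(key=lambda x: x[1])
    return ConservationReport(
        pct_identity_shared=100.0 * ident / shared,
        pct_similarity_shared=100.0 * simil / shared,
        n_shared_columns=shared,
        cys_in_archetype=cys_total,
        cys_conserved=cys_cons,
        indel_spans=indels,
        max_homopolymer={
            "a": _max_homopolymer(aln.row_a.replace("-", "")),
            "b": _max_homopolymer(aln.row_b.replace("-", "")),
        },
    )


def write_aligned_fasta(aln: PairwiseAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{aln.id_a}\n{aln.row_a}\n>{aln.id_b}\n{aln.row_b}\n")


def reports_to_table(pairs: list[tuple[str, str, ConservationReport]]) -> pd.DataFrame:
    rows = []
    for cand, arch, rep in pairs:
        rows.append(
            {
                "candidate": cand,
                "archetype": arch,
                "pct_identity_shared": round(rep.pct_identity_shared, 1),
                "pct_similarity_shared": round(rep.pct_similarity_shared, 1),
                "n_shared_columns": rep.n_shared_columns,
                "cys_in_archetype": rep.cys_in_archetype,
                "cys_conserved": rep.cys_conserved,
                "n_indels": len(rep.indel_spans),
                "max_indel_len": max((l for _, _, l in rep.indel_spans), default=0),
                "max_homopolymer": "{}{}".format(*rep.max_homopolymer["a"])
                if rep.max_homopolymer["a"][1] else "",
            }
        )
    return pd.DataFrame(rows)
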