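"""Ranked local-alignment database search with E-value statistics.

This is the desk-scale replacement for a BLASTp search: every query/target
pair gets an optimal Smith-Waterman alignment, scores are converted to bits
with the scheme's Karlin-Altschul parameters, and the E-value uses the raw
query length times the summed database residue count as its search space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import local_align
from .records import ProteinRecord
from .scoring import ScoringScheme, bit_score, expect_value


@dataclass
class LocalHit:
    """One scored local alignment of a query against a database target."""

    query_id: str
    target_id: str
    raw_score: int
    bit_score: float
    evalue: float
    query_range: tuple[int, int] | None
    target_range: tuple[int, int] | None
    pct_identity: float
    pct_similarity: float
    target_coverage: float
    n_columns: int = 0
    n_mismatch: int = 0
    n_gap_opens: int = 0
    target_description: str = ""
    row_query: str = field(default="", repr=False)
    row_target: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if self.raw_score < 0:
            raise ValueError("raw score must be non-negative")
        if self.pct_identity > self.pct_similarity + 1e-9:
            raise ValueError("pct_identity cannot exceed pct_similarity")


def _alignment_stats(row_q: str, row_t: str, scheme: ScoringScheme):
    ident = simil = mismatch = gap_opens = 0
    in_gap = False
    for ca, cb in zip(row_q, row_t):
        if ca == "-" or cb == "-":
            if not in_gap:
                gap_opens += 1
            in_gap = True
            continue
        in_gap = False
        if ca == cb:
            ident += 1
            simil += 1
        else:
            mismatch += 1
            if scheme.score(ca, cb) > 0:
                simil += 1
    ncols = len(row_q)
    nres = sum(1 for ca, cb in zip(row_q, row_t) if ca != "-" and cb != "-")
    pid = 100.0 * ident / nres if nres else 0.0
    psim = 100.0 * simil / nres if nres else 0.0
    return pid, psim, ncols, mismatch, gap_opens


def smith_waterman(
    query: ProteinRecord,
    target: ProteinRecord,
    scheme: ScoringScheme,
    db_residues: int | None = None,
) -> LocalHit:
    """Optimal local alignment of query vs target as a scored hit.

    ``db_residues`` sets the n of the E-value search space; by default it is
    the target length (single-sequence search).
    """
    if not query.sequence or not target.sequence:
        raise ValueError("cannot align an empty sequence")
    aln = local_align(query.sequence, target.sequence, scheme)
    raw = max(int(aln.score), 0)
    bits = bit_score(raw, scheme)
    n = db_residues if db_residues is not None else len(target)
    ev = expect_value(bits, len(query), n)
    pid, psim, ncols, mism, gaps = _alignment_stats(aln.row_a, aln.row_b, scheme)
    if aln.b_range is not None:
        cov = (aln.b_range[1] - aln.b_range[0] + 1) / len(target)
    else:
        cov = 0.0
    return LocalHit(
        query_id=query.id,
        target_id=target.id,
        raw_score=raw,
        bit_score=bits,
        evalue=ev,
        query_range=aln.a_range,
        target_range=aln.b_range,
        pct_identity=pid,
        pct_similarity=psim,
        target_coverage=cov,
        n_columns=ncols,
        n_mismatch=mism,
        n_gap_opens=gaps,
        target_description=target.description,
        row_query=aln.row_a,
        row_target=aln.row_b,
    )


def search(
    query: ProteinRecord,
    db: list[ProteinRecord],
    scheme: ScoringScheme,
    evalue_cutoff: float = 1e-5,
) -> list[LocalHit]:
    """Search a protein database, returning hits with E <= cutoff.

    One best hit per target; the E-value search space uses the summed residue
    count of the whole database.  Hits are sorted by ascending E-value, ties
    broken by descending bit score then target id.
    """
    if not db:
        raise ValueError("database is empty")
    n_total = sum(len(t) for t in db)
    hits = []
    for target in db:
        hit = smith_waterman(query, target, scheme, db_residues=n_total)
        if hit.evalue <= evalue_cutoff:
            hits.append(hit)
    hits.sort(key=lambda h: (h.evalue, -h.bit_score, h.target_id))
    return hits


#: Canonical 12 columns of tabular search output.
HIT_TABLE_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def hits_to_table(hits) -> pd.DataFrame:
    rows = []
    for h in hits:
        qs, qe = h.query_range or (0, 0)
        ss, se = h.target_range or (0, 0)
        rows.append(
            {
                "qseqid": h.query_id,
                "sseqid": h.target_id,
                "pident": round(h.pct_identity, 3),
                "length": h.n_columns,
                "mismatch": h.n_mismatch,
                "gapopen": h.n_gap_opens,
                "qstart": qs, "qend": qe, "sstart": ss, "send": se,
                "evalue": h.evalue,
                "bitscore": round(h.bit_score, 1),
            }
        )
    return pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)


def write_hit_table(hits, path: str | Path) -> None:
    hits_to_table(hits).to_csv(path, sep="\t", index=False, header=False)
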