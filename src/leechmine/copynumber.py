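"""Gene-family copy number, cross-family deduplication and tandem arrays.

A proteome member counts as a copy of a family when the family's top hit
aligns to it with E <= 1e-5, covering at least 50% of its length, at >= 70%
sequence similarity over the aligned columns.  Because related families
share hits, every protein is then assigned to the single family whose query
scores it best.  Copies that occupy consecutive gene positions on one
scaffold form tandem arrays; exon and intron length conservation across the
copies of a family is summarised as strong / mixed / low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import GeneModel, ProteinRecord
from .scoring import ScoringScheme
from .search import LocalHit, smith_waterman


@dataclass
class CopyNumberThresholds:
    evalue: float = 1e-5
    min_target_coverage: float = 0.5
    min_pct_similarity: float = 70.0
    #: 'coverage' = aligned span over target length (standard reading);
    #: 'length_ratio' = literal query length / target length.
    coverage_mode: str = "coverage"
    #: 'similarity' counts positives; 'identity' counts identities only.
    similarity_metric: str = "similarity"


@dataclass
class CopyNumberResult:
    family: str
    query_id: str
    copies: list[str]
    scaffolds: set[str] = field(default_factory=set)
    assignments_dropped: list[tuple[str, str, str]] = field(default_factory=list)
    hits: dict[str, LocalHit] = field(default_factory=dict, repr=False)
    unknown_scaffold_ids: list[str] = field(default_factory=list)

    @property
    def n_copies(self) -> int:
        return len(self.copies)


@dataclass
class TandemArray:
    scaffold_id: str
    family: str
    member_gene_ids: list[str]
    gene_index_span: tuple[int, int]

    def __len__(self) -> int:
        return len(self.member_gene_ids)


def count_copies(
    top_hit: ProteinRecord,
    family: str,
    proteome: list[ProteinRecord],
    scheme: ScoringScheme,
    models: dict[str, GeneModel] | None = None,
    thresholds: CopyNumberThresholds | None = None,
) -> CopyNumberResult:
    """Count proteome members qualifying as copies of the family's top hit.

    The query itself always counts as a copy.  Scaffold membership comes from
    the protein_id -> GeneModel mapping; copies without a model are counted
    once with their scaffold recorded as unknown.
    """
    th = thresholds or CopyNumberThresholds()
    n_total = sum(len(p) for p in proteome)
    result = CopyNumberResult(family=family, query_id=top_hit.id, copies=[])
    for target in proteome:
        if target.id == top_hit.id:
            qualifies = True
            hit = smith_waterman(top_hit, target, scheme, db_residues=n_total)
        else:
            hit = smith_waterman(top_hit, target, scheme, db_residues=n_total)
            if th.coverage_mode == "length_ratio":
                cov = len(top_hit) / len(target)
            else:
                cov = hit.target_coverage
            sim = (hit.pct_identity if th.similarity_metric == "identity"
                   else hit.pct_similarity)
            qualifies = (
                hit.evalue <= th.evalue
                and cov >= th.min_target_coverage
                and sim >= th.min_pct_similarity
            )
        if not qualifies:
            continue
        result.copies.append(target.id)
        result.hits[target.id] = hit
        model = models.get(target.id) if models else None
        if model is not None:
            result.scaffolds.add(model.scaffold_id)
        else:
            result.unknown_scaffold_ids.append(target.id)
    return result


def dedupe(results: list[CopyNumberResult]) -> list[CopyNumberResult]:
    """Assign every protein to exactly one family.

    The winning family is the one whose query alignment has the highest bit
    score; ties go to the lower E-value, then the lexicographically first
    family name.  Losing assignments are recorded on the losing results.
    """
    by_family = {r.family: r for r in results}
    claims: dict[str, list[tuple[float, float, str]]] = {}
    for r in results:
        for pid in r.copies:
            h = r.hits.get(pid)
            bit = h.bit_score if h else 0.0
            ev = h.evalue if h else float("inf")
            claims.setdefault(pid, []).append((-bit, ev, r.family))
    winners = {pid: min(cands)[2] for pid, cands in claims.items()}
    out = []
    for r in results:
        kept, dropped = [], []
        for pid in r.copies:
            win = winners[pid]
            if win == r.family:
                kept.append(pid)
            else:
                dropped.append((pid, r.family, win))
        nr = CopyNumberResult(
            family=r.family,
            query_id=r.query_id,
            copies=kept,
            scaffolds=set(),
            assignments_dropped=dropped,
            hits={pid: r.hits[pid] for pid in kept if pid in r.hits},
            unknown_scaffold_ids=[p for p in r.unknown_scaffold_ids if p in kept],
        )
        out.append(nr)
    return out


def attach_scaffolds(results: list[CopyNumberResult],
                     models: dict[str, GeneModel]) -> None:
    """Recompute scaffold sets from gene-model linkage (after dedupe)."""
    for r in results:
        r.scaffolds = {
            models[pid].scaffold_id for pid in r.copies if pid in models
        }


def detect_tandem(
    copies: CopyNumberResult,
    models: dict[str, GeneModel],
    max_gap: int = 0,
) -> list[TandemArray]:
    """Maximal runs of same-family copies at consecutive gene positions.

    Neighbouring members may be separated by at most ``max_gap`` intervening
    genes (0 = strictly adjacent).  Runs of length >= 2 are reported.
    """
    per_scaffold: dict[str, list[GeneModel]] = {}
    for pid in copies.copies:
        m = models.get(pid)
        if m is not None and m.gene_index_on_scaffold is not None:
            per_scaffold.setdefault(m.scaffold_id, []).append(m)
    arrays = []
    for scaffold, members in per_scaffold.items():
        members.sort(key=lambda m: m.gene_index_on_scaffold)
        run = [members[0]]
        for m in members[1:]:
            if m.gene_index_on_scaffold - run[-1].gene_index_on_scaffold <= max_gap + 1:
                run.append(m)
            else:
                if len(run) >= 2:
                    arrays.append(_to_array(scaffold, copies.family, run))
                run = [m]
        if len(run) >= 2:
            arrays.append(_to_array(scaffold, copies.family, run))
    return arrays


def _to_array(scaffold: str, family: str, run: list[GeneModel]) -> TandemArray:
    return TandemArray(
        scaffold_id=scaffold,
        family=family,
        member_gene_ids=[m.gene_id for m in run],
        gene_index_span=(run[0].gene_index_on_scaffold, run[-1].gene_index_on_scaffold),
    )


#: Class thresholds for exon/intron length conservation.
STRONG_THRESHOLD = 0.9
LOW_THRESHOLD = 0.6


def _pairwise_conservation(lens_a: list[int], lens_b: list[int]) -> float:
    """Positional mean of 1 - |a-b|/max(a,b); unpaired positions score 0."""
    n = max(len(lens_a), len(lens_b))
    if n == 0:
        return 1.0
    total = 0.0
    for i in range(n):
        if i < len(lens_a) and i < len(lens_b):
            a, b = lens_a[i], lens_b[i]
            total += 1.0 - abs(a - b) / max(a, b) if max(a, b) > 0 else 1.0
    return total / n


def _classify(mean: float) -> str:
    if mean >= STRONG_THRESHOLD:
        return "strong"
    if mean < LOW_THRESHOLD:
        return "low"
    return "mixed"


def exon_intron_conservation(copies: list[GeneModel]) -> dict[str, str]:
    """Classify exon and intron length conservation across family copies.

    Lengths are paired positionally over all copy pairs; the mean of
    1 - |a-b|/max(a,b) over paired positions (unpaired positions scoring 0)
    is classed strong (>= 0.9), low (< 0.6) or mixed.  Fewer than two
    modelled copies yield an empty report.
    """
    if len(copies) < 2:
        return {}
    exon_scores, intron_scores = [], []
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            exon_scores.append(
                _pairwise_conservation(copies[i].exon_lengths(), copies[j].exon_lengths())
            )
            ia, ib = copies[i].intron_lengths(), copies[j].intron_lengths()
            if ia or ib:
                intron_scores.append(_pairwise_conservation(ia, ib))
    report = {
        "exon_mean": sum(exon_scores) / len(exon_scores),
        "exon_class": _classify(sum(exon_scores) / len(exon_scores)),
    }
    if intron_scores:
        report["intron_mean"] = sum(intron_scores) / len(intron_scores)
        report["intron_class"] = _classify(sum(intron_scores) / len(intron_scores))
    return report


def results_to_table(
    results: list[CopyNumberResult],
    arrays: dict[str, list[TandemArray]] | None = None,
) -> pd.DataFrame:
    rows = []
    for r in sorted(results, key=lambda x: x.family):
        fam_arrays = (arrays or {}).get(r.family, [])
        rows.append(
            {
                "family": r.family,
                "query_id": r.query_id,
                "n_copies": r.n_copies,
                "n_scaffolds": len(r.scaffolds),
                "scaffolds": ";".join(sorted(r.scaffolds)),
                "tandem_arrays": ";".join(
                    f"{a.scaffold_id}:{a.gene_index_span[0]}-{a.gene_index_span[1]}"
                    for a in fam_arrays
                ),
                "dropped": ";".join(
                    f"{pid}->{win}" for pid, _, win in r.assignments_dropped
                ),
            }
        )
    return pd.DataFrame(rows)


def write_copy_table(results, path: str | Path, arrays=None) -> None:
    results_to_table(results, arrays).to_csv(path, sep="\t", index=False)
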