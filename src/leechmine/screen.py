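"""Forward + reciprocal similarity screening for orthologue candidacy.

The forward screen searches the predicted proteome against an archetype
panel at an E-value cutoff (1e-5 by default).  Each family's best hit is
then searched reciprocally against one or more global protein databases;
a candidate is rejected only when some global database returns a clearly
better hit whose description matches none of the family's synonyms.
Uninformative descriptions ("hypothetical protein" and kin) can never
trigger rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import family_index
from .records import ArchetypeEntry, ProteinRecord
from .scoring import ScoringScheme
from .search import LocalHit, search

#: Description substrings that carry no identity information and therefore
#: cannot reject a candidate.
UNINFORMATIVE_DESCRIPTIONS = (
    "hypothetical protein",
    "uncharacterized protein",
    "uncharacterised protein",
    "unnamed protein product",
    "predicted protein",
)

#: A reciprocal hit must be this many times smaller in E-value than the best
#: family-consistent hit before it can reject a candidate (guards against
#: float-noise rejections).
DEFAULT_REJECTION_MARGIN = 10.0


@dataclass
class ScreenDecision:
    """Outcome of the forward+reciprocal screen for one candidate protein."""

    protein_id: str
    family: str
    forward_evalue: float
    reciprocal_best: dict[str, tuple[str, float] | None] = field(default_factory=dict)
    status: str = "no_hit"  # candidate | rejected_unrelated | no_hit
    rejection_reason: str | None = None


def forward_screen(
    proteome: list[ProteinRecord],
    panel: list[ArchetypeEntry],
    scheme: ScoringScheme,
    cutoff: float = 1e-5,
) -> dict[str, list[LocalHit]]:
    """Search every panel family against the proteome.

    Returns, per family, the proteome members hitting any family member at
    E <= cutoff, ranked by best E-value (the planted orthologue, if any,
    ranks first).  Hits are labelled with the archetype as query.
    """
    families = family_index(panel)
    if not families:
        raise ValueError("panel has no families")
    out: dict[str, list[LocalHit]] = {}
    for fam, members in families.items():
        best_per_target: dict[str, LocalHit] = {}
        for entry in members:
            qrec = entry.as_protein()
            for hit in search(qrec, proteome, scheme, evalue_cutoff=cutoff):
                prev = best_per_target.get(hit.target_id)
                if prev is None or (hit.evalue, -hit.bit_score) < (prev.evalue, -prev.bit_score):
                    best_per_target[hit.target_id] = hit
        ranked = sorted(
            best_per_target.values(),
            key=lambda h: (h.evalue, -h.bit_score, h.target_id),
        )
        out[fam] = ranked
    return out


def reciprocal_screen(
    candidate: ProteinRecord,
    global_dbs: dict[str, list[ProteinRecord]],
    scheme: ScoringScheme,
    cutoff: float = 1e-5,
) -> dict[str, LocalHit | None]:
    """Best hit of the candidate in each named global database (or None)."""
    if not global_dbs:
        raise ValueError("no global databases supplied")
    out: dict[str, LocalHit | None] = {}
    for name, db in global_dbs.items():
        if not db:
            raise ValueError(f"global database {name!r} is empty")
        hits = search(candidate, db, scheme, evalue_cutoff=cutoff)
        out[name] = hits[0] if hits else None
    return out


def _matches_family(description: str, synonyms: list[str]) -> bool:
    d = description.lower()
    return any(s in d for s in synonyms)


def _is_uninformative(description: str) -> bool:
    d = description.lower()
    return any(u in d for u in UNINFORMATIVE_DESCRIPTIONS)


def classify(
    forward_hit: LocalHit,
    family: str,
    reciprocals: dict[str, LocalHit | None],
    synonyms: dict[str, list[str]],
    rejection_margin: float = DEFAULT_REJECTION_MARGIN,
) -> ScreenDecision:
    """Decide orthologue candidacy from forward and reciprocal hits.

    A candidate is rejected when some reciprocal best hit is at least
    ``rejection_margin`` times smaller in E-value than the best
    family-consistent reciprocal hit and its description matches no family
    synonym.  Family synonyms always include the family name itself.
    """
    fam_syn = list(synonyms.get(family, []))
    if family.lower() not in fam_syn:
        fam_syn.append(family.lower())
    decision = ScreenDecision(
        protein_id=forward_hit.target_id,
        family=family,
        forward_evalue=forward_hit.evalue,
        reciprocal_best={
            name: (h.target_description or h.target_id, h.evalue) if h else None
            for name, h in reciprocals.items()
        },
        status="candidate",
    )
    consistent = [
        h.evalue
        for h in reciprocals.values()
        if h is not None and _matches_family(h.target_description or h.target_id, fam_syn)
    ]
    # with no family-consistent reciprocal hit anywhere, compare against the
    # forward E-value instead (the hit that nominated the candidate)
    best_consistent = min(consistent) if consistent else forward_hit.evalue
    for name, h in reciprocals.items():
        if h is None:
            continue
        desc = h.target_description or h.target_id
        if _matches_family(desc, fam_syn) or _is_uninformative(desc):
            continue
        if h.evalue * rejection_margin <= best_consistent:
            decision.status = "rejected_unrelated"
            decision.rejection_reason = (
                f"{name}: better hit against unrelated {desc!r} "
                f"(E={h.evalue:.2g} vs family-consistent E={best_consistent:.2g})"
            )
            break
    return decision


def screen_proteome(
    proteome: list[ProteinRecord],
    panel: list[ArchetypeEntry],
    global_dbs: dict[str, list[ProteinRecord]],
    scheme: ScoringScheme,
    cutoff: float = 1e-5,
    rejection_margin: float = DEFAULT_REJECTION_MARGIN,
) -> tuple[dict[str, list[LocalHit]], dict[str, ScreenDecision]]:
    """Run the full forward + reciprocal screen.

    Returns the forward hit lists per family and, for each family's top hit,
    the candidacy decision keyed by family.
    """
    proteins = {p.id: p for p in proteome}
    synonyms = {}
    for e in panel:
        syn = synonyms.setdefault(e.family, [])
        for s in e.synonyms + [e.name.lower()]:
            if s not in syn:
                syn.append(s)
    fwd = forward_screen(proteome, panel, scheme, cutoff=cutoff)
    decisions: dict[str, ScreenDecision] = {}
    for fam, hits in fwd.items():
        if not hits:
            decisions[fam] = ScreenDecision(protein_id="", family=fam,
                                            forward_evalue=float("inf"),
                                            status="no_hit")
            continue
        top = hits[0]
        recip = reciprocal_screen(proteins[top.target_id], global_dbs, scheme,
                                  cutoff=cutoff) if global_dbs else {}
        decisions[fam] = classify(top, fam, recip, synonyms,
                                  rejection_margin=rejection_margin)
    return fwd, decisions


def decisions_to_table(
    decisions: dict[str, ScreenDecision],
    signal_annotations=None,
    copy_numbers=None,
) -> pd.DataFrame:
    """Final report table: one row per family, mirroring a hit-summary table."""
    db_names: list[str] = []
    for d in decisions.values():
        for name in d.reciprocal_best:
            if name not in db_names:
                db_names.append(name)
    rows = []
    for fam in sorted(decisions):
        d = decisions[fam]
        row = {
            "family": fam,
            "gene_id": d.protein_id,
            "status": d.status,
            "forward_evalue": d.forward_evalue if d.protein_id else "",
        }
        if copy_numbers and fam in copy_numbers:
            cn = copy_numbers[fam]
            row["copy_number"] = f"{cn.n_copies} ({len(cn.scaffolds)})"
        else:
            row["copy_number"] = ""
        for name in db_names:
            best = d.reciprocal_best.get(name)
            row[f"best_{name}"] = (
                f"{best[0]} ({best[1]:.1e})" if best else "no hit"
            )
        if signal_annotations is not None:
            ann = signal_annotations.get(d.protein_id)
            row["signal_peptide"] = str(ann) if ann else "NA"
        row["rejection_reason"] = d.rejection_reason or ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_decisions(decisions, path: str | Path, **kw) -> None:
    decisions_to_table(decisions, **kw).to_csv(path, sep="\t", index=False)
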