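"""Readers and writers for the formats the pipeline touches.

FASTA (proteome, panel sequences), GFF3 (gene models, 1-based inclusive),
TSV (archetype panels, signal-peptide annotations, truth tables, reports)
and newick (via :mod:`leechmine.tree`).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    ArchetypeEntry,
    FormatError,
    GeneModel,
    ProteinRecord,
    SignalPeptideAnnotation,
)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records.

    Sequences are uppercased; duplicate ids and empty sequences are rejected
    with an error naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    # line-aware validation pass (SeqIO is forgiving about these defects)
    header_line: int | None = None
    seen_residues = False
    seen_any_header = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if header_line is not None and not seen_residues:
                raise FormatError(f"{path}:{header_line}: record with empty sequence")
            if stripped == ">":
                raise FormatError(f"{path}:{lineno}: malformed header (no id)")
            header_line, seen_residues, seen_any_header = lineno, False, True
        else:
            if not seen_any_header:
                raise FormatError(
                    f"{path}:{lineno}: sequence data before any FASTA header"
                )
            seen_residues = True
    if header_line is not None and not seen_residues:
        raise FormatError(f"{path}:{header_line}: record with empty sequence")
    if not seen_any_header:
        raise FormatError(f"{path}: no FASTA records found")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicated sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), description=desc))
    return records


def write_fasta(records, path: str | Path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def _attr_map(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon features) from a GFF3 file.

    Exons are grouped under their mRNA and sorted by start; each model gets a
    per-scaffold gene order index by ascending start coordinate.  An exon
    whose Parent is not a declared mRNA, or overlapping exons within one
    mRNA, raise :class:`FormatError`.
    """
    path = Path(path)
    mrna_info: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
        seqid, _, ftype, start, end, _, strand, _, attrs = cols
        attrs = _attr_map(attrs)
        if ftype == "mRNA":
            mid = attrs.get("ID")
            if not mid:
                raise FormatError(f"{path}:{lineno}: mRNA without ID")
            mrna_info[mid] = {
                "scaffold": seqid,
                "strand": strand,
                "gene_id": attrs.get("Parent", mid),
                "protein_id": attrs.get("protein_id", mid),
            }
            exons.setdefault(mid, [])
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent is None:
                raise FormatError(f"{path}:{lineno}: exon without Parent attribute")
            exons.setdefault(parent, []).append((int(start), int(end)))

    models: list[GeneModel] = []
    for mid, ex in exons.items():
        if mid not in mrna_info:
            raise FormatError(f"{path}: exon(s) reference unknown mRNA {mid!r}")
        if not ex:
            raise FormatError(f"{path}: mRNA {mid!r} has no exons")
        info = mrna_info[mid]
        try:
            models.append(
                GeneModel(
                    gene_id=info["gene_id"],
                    scaffold_id=info["scaffold"],
                    strand=info["strand"],
                    exons=ex,
                    protein_id=info["protein_id"],
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    assign_gene_indices(models)
    return models


def assign_gene_indices(models: list[GeneModel]) -> None:
    """Assign per-scaffold gene order indices by ascending start coordinate."""
    by_scaffold: dict[str, list[GeneModel]] = {}
    for m in models:
        by_scaffold.setdefault(m.scaffold_id, []).append(m)
    for group in by_scaffold.values():
        group.sort(key=lambda m: (m.start, m.gene_id))
        for idx, m in enumerate(group):
            m.gene_index_on_scaffold = idx


PANEL_COLUMNS = ["name", "family", "accession", "species", "sequence",
                 "known_cys_count", "synonyms"]


def read_panel(path: str | Path) -> list[ArchetypeEntry]:
    """Read an archetype panel TSV.

    Expected columns: name, family, accession, species, sequence,
    known_cys_count (optional per row), synonyms (semicolon-separated).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(PANEL_COLUMNS)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if unknown:
        raise FormatError(f"{path}: unknown panel column(s) {sorted(unknown)}")
    if missing:
        raise FormatError(f"{path}: missing panel column(s) {sorted(missing)}")
    entries = []
    for idx, row in df.iterrows():
        if not row["family"]:
            raise FormatError(f"{path}: row {idx + 2}: missing family")
        cys = row["known_cys_count"]
        entries.append(
            ArchetypeEntry(
                name=row["name"],
                family=row["family"],
                accession=row["accession"],
                species=row["species"],
                sequence=row["sequence"],
                known_cys_count=int(cys) if cys not in ("", "NA") else None,
                synonyms=[s.strip() for s in row["synonyms"].split(";") if s.strip()],
            )
        )
    return entries


def panel_template() -> pd.DataFrame:
    """The bundled archetype panel template, sequences left blank.

    Lists the classic leech anticoagulant archetypes with family labels,
    source accessions, species and relatedness synonyms.  Sequences cannot
    be redistributed here and must be filled in from the listed source
    records before the template passes :func:`read_panel`; the manillase
    entry is patent-derived and has no public accession, so its sequence is
    always user-supplied.
    """
    path = Path(__file__).parent / "data" / "panel_template.tsv"
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_panel(entries, path: str | Path) -> None:
    rows = [
        {
            "name": e.name,
            "family": e.family,
            "accession": e.accession,
            "species": e.species,
            "sequence": e.sequence,
            "known_cys_count": "" if e.known_cys_count is None else e.known_cys_count,
            "synonyms": ";".join(e.synonyms),
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def family_index(entries) -> dict[str, list[ArchetypeEntry]]:
    """Map family name to its panel members."""
    out: dict[str, list[ArchetypeEntry]] = {}
    for e in entries:
        out.setdefault(e.family, []).append(e)
    return out


def read_signal_annotations(path: str | Path) -> dict[str, SignalPeptideAnnotation]:
    """Read a signal-peptide TSV: protein_id, present (Yes/No), region (s-e)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for _, row in df.iterrows():
        present = row["present"].strip().lower() in ("yes", "true", "1")
        region = None
        if present and row.get("region", ""):
            s, e = row["region"].replace("–", "-").split("-")
            region = (int(s), int(e))
        out[row["protein_id"]] = SignalPeptideAnnotation(
            protein_id=row["protein_id"], present=present, region=region
        )
    return out


def write_signal_annotations(annotations, path: str | Path) -> None:
    rows = []
    for ann in annotations:
        rows.append(
            {
                "protein_id": ann.protein_id,
                "present": "Yes" if ann.present else "No",
                "region": f"{ann.region[0]}-{ann.region[1]}" if ann.region else "",
            }
        )
    pd.DataFrame(rows, columns=["protein_id", "present", "region"]).to_csv(
        path, sep="\t", index=False
    )
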