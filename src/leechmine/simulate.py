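"""Synthetic proteomes with planted anticoagulant-like gene families.

Each family gets a random archetype with a frozen cysteine scaffold; copies
evolve from it under a 20-state Jukes-Cantor substitution model plus a
Poisson indel process, and are laid out on scaffolds either as tandem
arrays (consecutive gene positions) or dispersed, among unrelated decoy
proteins.  A machine-readable truth table makes every downstream pipeline
stage testable offline.

The substitution model is uniform rather than BLOSUM-biased so that the
expected observed difference fraction has the closed form
(19/20) * (1 - exp(-20 t / 19)), which calibration tests check directly.
Insertions draw only non-cysteine letters, keeping the planted cysteine
positions the exact truth for conservation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import assign_gene_indices, write_fasta, write_panel, write_signal_annotations
from .records import (
    CANONICAL_AA,
    ArchetypeEntry,
    GeneModel,
    ProteinRecord,
    SignalPeptideAnnotation,
)

_NON_CYS = CANONICAL_AA.replace("C", "")


@dataclass
class SimConfig:
    """Parameters of the planted-family simulation."""

    seed: int = 0
    n_families: int = 3
    archetype_length: int = 300
    cys_count: int = 10
    copies_per_family: int = 4
    tandem_fraction: float = 0.5
    divergence_t: float = 0.1
    cys_retention_p: float = 1.0
    indel_rate: float = 1.0
    indel_length_p: float = 0.4
    n_decoys: int = 20
    n_scaffolds: int = 8
    intron_jitter: float = 0.1
    signal_peptide_p: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_families", "archetype_length", "cys_count",
                     "copies_per_family", "n_decoys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")
        for name in ("tandem_fraction", "cys_retention_p", "signal_peptide_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.indel_length_p <= 1.0:
            raise ValueError("indel_length_p must be in (0, 1]")
        if self.divergence_t < 0 or self.indel_rate < 0 or self.intron_jitter < 0:
            raise ValueError("rates must be non-negative")
        if self.cys_count > self.archetype_length:
            raise ValueError("cys_count cannot exceed archetype_length")


@dataclass
class EvolvedEvents:
    """Realised mutation record for one evolved copy."""

    sub_fraction: float
    indel_spans: list[tuple[str, int, int]]  # (kind 'ins'|'del', 1-based pos, length)
    cys_positions: list[int]  # 1-based, in the child sequence


@dataclass
class TruthRow:
    protein_id: str
    family: str  # family name or 'decoy'
    scaffold_id: str
    gene_index: int
    tandem_array_id: str  # '' when dispersed
    sub_fraction: float
    indel_spans: str
    cys_positions: str
    signal_peptide: bool


def expected_difference_fraction(t: float) -> float:
    """Expected observed difference per site under the 20-state model."""
    return (19.0 / 20.0) * (1.0 - np.exp(-20.0 * t / 19.0))


def simulate_archetype(length: int, cys_count: int,
                       rng: np.random.Generator,
                       seq_id: str = "archetype") -> tuple[ProteinRecord, list[int]]:
    """Random archetype: uniform non-C residues with cys_count planted C's."""
    if cys_count > length:
        raise ValueError("cys_count cannot exceed length")
    letters = rng.choice(list(_NON_CYS), size=length)
    cys_pos = sorted(rng.choice(length, size=cys_count, replace=False).tolist())
    for p in cys_pos:
        letters[p] = "C"
    return (
        ProteinRecord(id=seq_id, sequence="".join(letters)),
        [p + 1 for p in cys_pos],
    )


def evolve(
    parent: ProteinRecord,
    t: float,
    config: SimConfig,
    rng: np.random.Generator,
    cys_positions: list[int] | None = None,
    child_id: str = "child",
) -> tuple[ProteinRecord, EvolvedEvents]:
    """Evolve a copy: JC substitutions, then Poisson indels.

    Cysteine sites substitute only with probability (1 - cys_retention_p)
    of the baseline rate; when cysteines are fully retained, deletions are
    placed so they never remove a cysteine.
    """
    if t < 0:
        raise ValueError("divergence must be non-negative")
    seq = list(parent.sequence)
    n = len(seq)
    cys = set((p - 1) for p in (cys_positions or
                                [i + 1 for i, c in enumerate(seq) if c == "C"]))
    p_sub = expected_difference_fraction(t)
    n_sub = 0
    for i in range(n):
        p_here = p_sub * ((1.0 - config.cys_retention_p) if i in cys else 1.0)
        if p_here > 0 and rng.random() < p_here:
            alternatives = [a for a in CANONICAL_AA if a != seq[i]]
            seq[i] = alternatives[int(rng.integers(len(alternatives)))]
            n_sub += 1
            if i in cys and seq[i] != "C":
                cys.discard(i)

    sub_fraction = n_sub / n if n else 0.0
    # indels operate on the substituted sequence; positions recorded 1-based
    spans: list[tuple[str, int, int]] = []
    n_indels = int(rng.poisson(config.indel_rate)) if config.indel_rate > 0 else 0
    for _ in range(n_indels):
        length = int(rng.geometric(config.indel_length_p))
        kind = "del" if rng.random() < 0.5 else "ins"
        if kind == "del":
            if len(seq) <= length:
                continue
            placed = False
            for _attempt in range(20):
                pos = int(rng.integers(0, len(seq) - length + 1))
                window = set(range(pos, pos + length))
                if config.cys_retention_p >= 1.0 and window & cys:
                    continue
                placed = True
                break
            if not placed:
                continue
            del seq[pos:pos + length]
            cys = {c - length if c >= pos + length else c
                   for c in cys if c not in window}
            spans.append(("del", pos + 1, length))
        else:
            pos = int(rng.integers(0, len(seq) + 1))
            insert = [
                _NON_CYS[int(rng.integers(len(_NON_CYS)))] for _ in range(length)
            ]
            seq[pos:pos] = insert
            cys = {c + length if c >= pos else c for c in cys}
            spans.append(("ins", pos + 1, length))

    child = ProteinRecord(id=child_id, sequence="".join(seq))
    events = EvolvedEvents(
        sub_fraction=sub_fraction,
        indel_spans=spans,
        cys_positions=sorted(c + 1 for c in cys),
    )
    return child, events


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimConfig
    proteome: list[ProteinRecord]
    gene_models: list[GeneModel]
    panel: list[ArchetypeEntry]
    truth: list[TruthRow]
    signal_annotations: list[SignalPeptideAnnotation]
    global_dbs: dict[str, list[ProteinRecord]] = field(default_factory=dict)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein_id": r.protein_id,
                    "family": r.family,
                    "scaffold_id": r.scaffold_id,
                    "gene_index": r.gene_index,
                    "tandem_array_id": r.tandem_array_id,
                    "sub_fraction": round(r.sub_fraction, 6),
                    "indel_spans": r.indel_spans,
                    "cys_positions": r.cys_positions,
                    "signal_peptide": "Yes" if r.signal_peptide else "No",
                }
                for r in self.truth
            ]
        )

    def models_by_protein(self) -> dict[str, GeneModel]:
        return {m.protein_id: m for m in self.gene_models}

    def expected_copy_numbers(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.truth:
            if r.family != "decoy":
                out[r.family] = out.get(r.family, 0) + 1
        return out

    def expected_tandem_arrays(self) -> dict[str, list[list[str]]]:
        arrays: dict[str, list[str]] = {}
        for r in self.truth:
            if r.tandem_array_id:
                arrays.setdefault(r.tandem_array_id, []).append(r.protein_id)
        out: dict[str, list[list[str]]] = {}
        for aid, members in arrays.items():
            fam = aid.rsplit("_", 1)[0]
            out.setdefault(fam, []).append(sorted(members))
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": outdir / "proteome.fasta",
            "gff3": outdir / "genes.gff3",
            "panel": outdir / "panel.tsv",
            "truth": outdir / "truth.tsv",
            "signal": outdir / "signal_peptides.tsv",
        }
        write_fasta(self.proteome, paths["proteome"])
        _write_gff3(self.gene_models, paths["gff3"])
        write_panel(self.panel, paths["panel"])
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        write_signal_annotations(self.signal_annotations, paths["signal"])
        for name, db in self.global_dbs.items():
            p = outdir / f"globaldb_{name}.fasta"
            write_fasta(db, p)
            paths[f"globaldb_{name}"] = p
        return paths


def _write_gff3(models: list[GeneModel], path: Path) -> None:
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda x: (x.scaffold_id, x.start)):
        lines.append(
            "\t".join(
                [m.scaffold_id, "leechmine_sim", "gene", str(m.start), str(m.end),
                 ".", m.strand, ".", f"ID={m.gene_id}"]
            )
        )
        mid = f"{m.gene_id}.mRNA"
        lines.append(
            "\t".join(
                [m.scaffold_id, "leechmine_sim", "mRNA", str(m.start), str(m.end),
                 ".", m.strand, ".",
                 f"ID={mid};Parent={m.gene_id};protein_id={m.protein_id}"]
            )
        )
        for s, e in m.exons:
            lines.append(
                "\t".join(
                    [m.scaffold_id, "leechmine_sim", "exon", str(s), str(e),
                     ".", m.strand, ".", f"Parent={mid}"]
                )
            )
    path.write_text("\n".join(lines) + "\n")


def _exon_structure(protein_len: int, fractions: np.ndarray,
                    intron_lengths: list[int], start: int) -> list[tuple[int, int]]:
    """Exon coordinate pairs from a CDS split into fractional exon sizes."""
    cds = protein_len * 3
    sizes = np.maximum(np.round(fractions * cds).astype(int), 3)
    sizes[-1] = max(cds - int(sizes[:-1].sum()), 3)
    exons = []
    pos = start
    for k, size in enumerate(sizes):
        exons.append((pos, pos + int(size) - 1))
        pos += int(size)
        if k < len(sizes) - 1:
            pos += intron_lengths[k]
    return exons


def plant_genome(config: SimConfig) -> SyntheticBundle:
    """Generate the full synthetic bundle for one configuration.

    Per family: one archetype (written to the panel) and ``copies_per_family``
    evolved copies, ``round(tandem_fraction * copies)`` of them placed at
    consecutive gene positions on one scaffold, the rest dispersed; decoys
    are independent random sequences with no shared ancestry.  Identical
    configs yield byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    panel: list[ArchetypeEntry] = []
    proteins: list[ProteinRecord] = []
    truth_info: dict[str, dict] = {}
    # (item) placement units: either a tandem block (list of ids) or single id
    blocks: list[list[str]] = []
    singles: list[str] = []
    family_meta: dict[str, dict] = {}

    for f in range(config.n_families):
        fam = f"fam{f:02d}"
        arch, cys_pos = simulate_archetype(
            config.archetype_length, config.cys_count, rng, seq_id=f"{fam}_arch"
        )
        panel.append(
            ArchetypeEntry(
                name=f"{fam} archetype",
                family=fam,
                accession=f"ARCH{f:03d}",
                species="synthetic taxon",
                sequence=arch.sequence,
                known_cys_count=config.cys_count,
                synonyms=[fam, f"{fam} archetype"],
            )
        )
        n_exons = int(rng.integers(2, 5))
        cuts = np.sort(rng.uniform(0.1, 0.9, size=n_exons - 1))
        fractions = np.diff(np.concatenate([[0.0], cuts, [1.0]]))
        base_introns = [int(rng.integers(80, 500)) for _ in range(n_exons - 1)]
        signal = bool(rng.random() < config.signal_peptide_p)
        family_meta[fam] = {
            "fractions": fractions,
            "base_introns": base_introns,
            "signal": signal,
        }
        n_tandem = int(round(config.tandem_fraction * config.copies_per_family))
        if n_tandem == 1:
            n_tandem = 0  # an array needs at least two members
        block: list[str] = []
        for c in range(config.copies_per_family):
            pid = f"{fam}_copy{c}"
            child, events = evolve(
                arch, config.divergence_t, config, rng,
                cys_positions=cys_pos, child_id=pid,
            )
            child.description = f"planted {fam} copy"
            proteins.append(child)
            in_tandem = c < n_tandem
            truth_info[pid] = {
                "family": fam,
                "events": events,
                "tandem": f"{fam}_arr0" if in_tandem else "",
                "signal": signal,
            }
            if in_tandem:
                block.append(pid)
            else:
                singles.append(pid)
        if block:
            blocks.append(block)

    for k in range(config.n_decoys):
        pid = f"decoy{k:03d}"
        length = int(rng.integers(
            max(50, config.archetype_length // 2),
            config.archetype_length * 2,
        ))
        seq = "".join(rng.choice(list(CANONICAL_AA), size=length))
        proteins.append(ProteinRecord(id=pid, sequence=seq,
                                      description="unrelated decoy protein"))
        truth_info[pid] = {"family": "decoy", "events": None, "tandem": "",
                           "signal": False}
        singles.append(pid)

    # lay items out on scaffolds; re-draw if dispersal accidentally puts two
    # same-family genes adjacent (which would fake an unplanted tandem pair)
    for _attempt in range(200):
        layout: list[list[object]] = [[] for _ in range(config.n_scaffolds)]
        for block in blocks:
            layout[int(rng.integers(config.n_scaffolds))].append(list(block))
        for pid in singles:
            layout[int(rng.integers(config.n_scaffolds))].append(pid)
        for scaffold in layout:
            order = rng.permutation(len(scaffold))
            scaffold[:] = [scaffold[i] for i in order]
        ordered: list[list[str]] = []
        for scaffold in layout:
            flat: list[str] = []
            for item in scaffold:
                flat.extend(item if isinstance(item, list) else [item])
            ordered.append(flat)
        if _layout_ok(ordered, truth_info):
            break
    else:
        raise RuntimeError("could not place genes without spurious adjacency")

    protein_by_id = {p.id: p for p in proteins}
    gene_models: list[GeneModel] = []
    for s, flat in enumerate(ordered):
        scaffold = f"scaffold{s:03d}"
        pos = 1000
        for pid in flat:
            fam = truth_info[pid]["family"]
            if fam == "decoy":
                fractions = np.array([1.0])
                introns: list[int] = []
            else:
                meta = family_meta[fam]
                fractions = meta["fractions"]
                introns = [
                    max(30, int(round(b * (1.0 + config.intron_jitter * rng.standard_normal()))))
                    for b in meta["base_introns"]
                ]
            exons = _exon_structure(len(protein_by_id[pid]), fractions, introns, pos)
            strand = "+" if rng.random() < 0.5 else "-"
            gene_models.append(
                GeneModel(
                    gene_id=f"{pid}_gene",
                    scaffold_id=scaffold,
                    strand=strand,
                    exons=exons,
                    protein_id=pid,
                )
            )
            pos = exons[-1][1] + int(rng.integers(500, 2000))
    assign_gene_indices(gene_models)
    model_by_protein = {m.protein_id: m for m in gene_models}

    truth: list[TruthRow] = []
    signal_annotations: list[SignalPeptideAnnotation] = []
    for p in proteins:
        info = truth_info[p.id]
        m = model_by_protein[p.id]
        events: EvolvedEvents | None = info["events"]
        truth.append(
            TruthRow(
                protein_id=p.id,
                family=info["family"],
                scaffold_id=m.scaffold_id,
                gene_index=m.gene_index_on_scaffold,
                tandem_array_id=info["tandem"],
                sub_fraction=events.sub_fraction if events else 0.0,
                indel_spans=";".join(
                    f"{k}:{pos}:{ln}" for k, pos, ln in (events.indel_spans if events else [])
                ),
                cys_positions=";".join(
                    str(c) for c in (events.cys_positions if events else [])
                ),
                signal_peptide=info["signal"],
            )
        )
        signal_annotations.append(
            SignalPeptideAnnotation(
                protein_id=p.id,
                present=info["signal"],
                region=(1, 20) if info["signal"] else None,
            )
        )

    global_dbs = _make_global_dbs(panel, rng, config)
    return SyntheticBundle(
        config=config,
        proteome=proteins,
        gene_models=gene_models,
        panel=panel,
        truth=truth,
        signal_annotations=signal_annotations,
        global_dbs=global_dbs,
    )


def _layout_ok(ordered: list[list[str]], truth_info: dict[str, dict]) -> bool:
    """No two same-family genes adjacent unless in the same planted array."""
    for flat in ordered:
        for a, b in zip(flat, flat[1:]):
            fa, fb = truth_info[a]["family"], truth_info[b]["family"]
            if fa == fb and fa != "decoy":
                if truth_info[a]["tandem"] != truth_info[b]["tandem"] or \
                        not truth_info[a]["tandem"]:
                    return False
    return True


def _make_global_dbs(panel, rng: np.random.Generator,
                     config: SimConfig) -> dict[str, list[ProteinRecord]]:
    """Three small fixture databases standing in for nr / SWISS-PROT / Pfam.

    Each holds every archetype under a family-consistent description, plus
    named unrelated proteins and uninformatively annotated entries, so both
    the acceptance and the rejection branch of the reciprocal screen are
    exercisable.
    """
    unrelated_names = [
        "neurohemerythrin", "hemoglobin subunit", "actin", "tubulin beta chain",
        "heat shock protein 70",
    ]
    dbs: dict[str, list[ProteinRecord]] = {}
    for db_name in ("nr", "swissprot", "pfam"):
        entries: list[ProteinRecord] = []
        for e in panel:
            entries.append(
                ProteinRecord(
                    id=f"{db_name}_{e.accession}",
                    sequence=e.sequence,
                    description=f"{e.name} [{e.species}]",
                )
            )
        for k, name in enumerate(unrelated_names):
            length = int(rng.integers(150, 400))
            entries.append(
                ProteinRecord(
                    id=f"{db_name}_unrel{k}",
                    sequence="".join(rng.choice(list(CANONICAL_AA), size=length)),
                    description=name,
                )
            )
        for k in range(3):
            length = int(rng.integers(150, 400))
            entries.append(
                ProteinRecord(
                    id=f"{db_name}_hypo{k}",
                    sequence="".join(rng.choice(list(CANONICAL_AA), size=length)),
                    description=f"hypothetical protein H{k}",
                )
            )
        dbs[db_name] = entries
    return dbs
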