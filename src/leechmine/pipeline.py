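"""End-to-end orchestration: screen, copy number, conservation, trees.

Every stage is a pure function of (inputs, config, seed).  The combined
report mirrors a hit-summary table: one row per panel family with the top
gene id, copy number (scaffold count), per-database reciprocal hits,
signal-peptide call, conservation statistics and the clan-based orthology
call.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import conservation as cons
from . import copynumber as cn
from . import io as lio
from . import screen as scr
from . import tree as tr
from .msa import progressive_msa
from .records import ProteinRecord
from .scoring import ScoringScheme
from .simulate import SimConfig, plant_genome


@dataclass
class PipelineConfig:
    """Paths, thresholds and mode switches for a pipeline run."""

    proteome: str = ""
    gff3: str = ""
    panel: str = ""
    global_dbs: dict[str, str] = field(default_factory=dict)
    signal_tsv: str = ""
    outdir: str = "leechmine_out"

    forward_cutoff: float = 1e-5
    copy_evalue: float = 1e-5
    copy_min_coverage: float = 0.5
    copy_min_similarity: float = 70.0
    rejection_margin: float = 10.0
    support_threshold: float = 75.0
    bootstrap_reps: int = 1000
    seed: int = 0

    similarity_metric: str = "similarity"  # or 'identity'
    coverage_mode: str = "coverage"  # or 'length_ratio'
    mature_peptide_only: bool = False
    tandem_max_gap: int = 0

    sim: dict = field(default_factory=dict)  # overrides for SimConfig

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate_paths(self, need: list[str]) -> None:
        missing = []
        for name in need:
            p = getattr(self, name)
            if not p:
                missing.append(f"{name} (not set)")
            elif not Path(p).exists():
                missing.append(f"{name}: {p}")
        for name, p in self.global_dbs.items():
            if not Path(p).exists():
                missing.append(f"global_dbs[{name}]: {p}")
        if missing:
            raise FileNotFoundError(
                "missing pipeline input(s): " + "; ".join(missing)
            )

    def echo(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "effective_config.yaml").write_text(
            yaml.safe_dump(asdict(self), sort_keys=True)
        )

    def thresholds(self) -> cn.CopyNumberThresholds:
        return cn.CopyNumberThresholds(
            evalue=self.copy_evalue,
            min_target_coverage=self.copy_min_coverage,
            min_pct_similarity=self.copy_min_similarity,
            coverage_mode=self.coverage_mode,
            similarity_metric=self.similarity_metric,
        )


def _load_inputs(config: PipelineConfig):
    config.validate_paths(["proteome", "panel"])
    proteome = lio.read_fasta(config.proteome)
    panel = lio.read_panel(config.panel)
    if not panel:
        raise ValueError("panel is empty")
    models = {}
    if config.gff3:
        config.validate_paths(["gff3"])
        models = {m.protein_id: m for m in lio.read_gff3(config.gff3)}
    global_dbs = {
        name: lio.read_fasta(path) for name, path in config.global_dbs.items()
    }
    signal = (
        lio.read_signal_annotations(config.signal_tsv) if config.signal_tsv else {}
    )
    return proteome, panel, models, global_dbs, signal


def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate a synthetic bundle under the configured seed into outdir."""
    sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
    bundle = plant_genome(sim_cfg)
    outdir = Path(config.outdir)
    paths = bundle.write(outdir)
    config.proteome = str(paths["proteome"])
    config.gff3 = str(paths["gff3"])
    config.panel = str(paths["panel"])
    config.signal_tsv = str(paths["signal"])
    config.global_dbs = {
        name: str(paths[f"globaldb_{name}"]) for name in bundle.global_dbs
    }
    config.echo(outdir)
    return paths


def run_screen(config: PipelineConfig, scheme: ScoringScheme | None = None):
    """Forward + reciprocal screen; writes decisions.tsv and hit tables."""
    scheme = scheme or ScoringScheme()
    proteome, panel, _, global_dbs, signal = _load_inputs(config)
    fwd, decisions = scr.screen_proteome(
        proteome, panel, global_dbs, scheme,
        cutoff=config.forward_cutoff, rejection_margin=config.rejection_margin,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scr.write_decisions(decisions, outdir / "decisions.tsv",
                        signal_annotations=signal or None)
    from .search import write_hit_table

    (outdir / "hits").mkdir(exist_ok=True)
    for fam, hits in fwd.items():
        write_hit_table(hits, outdir / "hits" / f"{fam}.tsv")
    return fwd, decisions


def run_copies(config: PipelineConfig, scheme: ScoringScheme | None = None):
    """Copy-number calling with dedup and tandem-array detection."""
    scheme = scheme or ScoringScheme()
    proteome, panel, models, _, _ = _load_inputs(config)
    prot_by_id = {p.id: p for p in proteome}
    fwd = scr.forward_screen(proteome, panel, scheme, cutoff=config.forward_cutoff)
    results = []
    for fam, hits in fwd.items():
        if not hits:
            continue
        top = prot_by_id[hits[0].target_id]
        results.append(
            cn.count_copies(top, fam, proteome, scheme, models=models,
                            thresholds=config.thresholds())
        )
    results = cn.dedupe(results)
    cn.attach_scaffolds(results, models)
    arrays = {
        r.family: cn.detect_tandem(r, models, max_gap=config.tandem_max_gap)
        for r in results
    }
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cn.write_copy_table(results, outdir / "copy_number.tsv", arrays=arrays)
    return results, arrays


def run_conserve(config: PipelineConfig, scheme: ScoringScheme | None = None):
    """Candidate-vs-archetype conservation reports + aligned FASTA."""
    scheme = scheme or ScoringScheme()
    proteome, panel, _, _, signal = _load_inputs(config)
    prot_by_id = {p.id: p for p in proteome}
    families = lio.family_index(panel)
    fwd = scr.forward_screen(proteome, panel, scheme, cutoff=config.forward_cutoff)
    outdir = Path(config.outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    reports: dict[str, tuple[str, str, cons.ConservationReport]] = {}
    for fam, hits in sorted(fwd.items()):
        if not hits:
            continue
        cand = prot_by_id[hits[0].target_id]
        if config.mature_peptide_only:
            ann = signal.get(cand.id)
            if ann and ann.region:
                cand = ProteinRecord(
                    id=cand.id, sequence=cand.sequence[ann.region[1]:],
                    description=cand.description,
                )
        arch = families[fam][0]
        aln = cons.global_align(cand, arch.as_protein(), scheme)
        trimmed = cons.trim_terminal_gaps(aln)
        rep = cons.conservation_stats(trimmed, scheme, archetype_row="b")
        cons.write_aligned_fasta(trimmed, outdir / "alignments" / f"{fam}.afa")
        reports[fam] = (cand.id, arch.accession or arch.name, rep)
    table = cons.reports_to_table(list(reports.values()))
    table.insert(0, "family", list(reports))
    table.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    return reports


def run_tree(config: PipelineConfig, scheme: ScoringScheme | None = None):
    """Per-family gene trees (NJ + bootstrap) and clan-based orthology calls."""
    scheme = scheme or ScoringScheme()
    proteome, panel, _, _, _ = _load_inputs(config)
    prot_by_id = {p.id: p for p in proteome}
    families = lio.family_index(panel)
    fwd = scr.forward_screen(proteome, panel, scheme, cutoff=config.forward_cutoff)
    outdir = Path(config.outdir)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)
    archetype_leaves = {
        (e.accession or e.name): e.family for fam in families.values() for e in fam
    }
    clan_rows = []
    results = {}
    for k, (fam, hits) in enumerate(sorted(fwd.items())):
        if not hits:
            continue
        members = [prot_by_id[h.target_id] for h in hits]
        leaves = members + [e.as_protein() for f in families.values() for e in f]
        leaf_families = {m.id: fam for m in members} | archetype_leaves
        if len(leaves) < 4:
            continue
        msa = progressive_msa(leaves, scheme)
        tree = tr.bootstrap_support(msa, n_reps=config.bootstrap_reps,
                                    seed=config.seed + 7919 * (k + 1))
        tr.write_newick(tree, outdir / "trees" / f"{fam}.nwk")
        arch_id = families[fam][0].accession or families[fam][0].name
        res = tr.smallest_clan(
            tree, {hits[0].target_id, arch_id}, families=leaf_families,
            support_threshold=config.support_threshold,
            query=hits[0].target_id, archetype=arch_id,
        )
        results[fam] = res
        clan_rows.append(
            {
                "family": fam,
                "query": res.query,
                "archetype": res.archetype,
                "clan_size": len(res.smallest_clan),
                "support": "" if res.support is None else round(res.support, 1),
                "is_pair_clan": res.is_pair_clan,
                "call": res.call,
            }
        )
    pd.DataFrame(clan_rows).to_csv(outdir / "clans.tsv", sep="\t", index=False)
    return results


def run_all(config: PipelineConfig, scheme: ScoringScheme | None = None) -> pd.DataFrame:
    """Run every stage and write the combined report."""
    scheme = scheme or ScoringScheme()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    _, _, _, _, signal = _load_inputs(config)
    fwd, decisions = run_screen(config, scheme)
    copies, arrays = run_copies(config, scheme)
    conserve = run_conserve(config, scheme)
    clans = run_tree(config, scheme)

    copy_by_family = {r.family: r for r in copies}
    report = scr.decisions_to_table(
        decisions, signal_annotations=signal or None, copy_numbers=copy_by_family
    )
    cons_by_family = {fam: rep for fam, (_, _, rep) in conserve.items()}
    report["pct_similarity_shared"] = [
        round(cons_by_family[f].pct_similarity_shared, 1)
        if f in cons_by_family else "" for f in report["family"]
    ]
    report["cys_conserved"] = [
        f"{cons_by_family[f].cys_conserved}/{cons_by_family[f].cys_in_archetype}"
        if f in cons_by_family else "" for f in report["family"]
    ]
    report["tandem_arrays"] = [
        ";".join(
            f"{a.scaffold_id}:{a.gene_index_span[0]}-{a.gene_index_span[1]}"
            for a in arrays.get(f, [])
        )
        for f in report["family"]
    ]
    report["clan_call"] = [
        clans[f].call if f in clans else "" for f in report["family"]
    ]
    report["clan_support"] = [
        ("" if clans[f].support is None else round(clans[f].support, 1))
        if f in clans else "" for f in report["family"]
    ]
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    manifest = {
        "outputs": sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*")
                          if p.is_file()),
        "seed": config.seed,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return report
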