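"""End-to-end orchestration: Phase 1 (bidirectional screen) and Phase 2
(two-step mediation batch), driven by a YAML/JSON run configuration.

Every run writes TSV result tables, per-stage exclusion logs (no variant is
ever dropped silently: harmonization, clumping, F-filter and MR-PRESSO
removals all appear, and stage counts reconcile) and a machine-readable
manifest (config hash, seeds, package version).  Outputs contain no
timestamps, so identical config + seeds give byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .exceptions import ConfigError
from .harmonize import HarmonizeConfig
from .instruments import DistanceOnlyLD, LDLookup, MatrixLD, SelectionConfig, ZeroLD
from .io import ColumnMap, SummaryStatsTable, read_summary_stats
from .mediation import MediationConfig, batch_screen, bidirectional_screen

log = logging.getLogger("medmr")


class TableSpec(BaseModel):
    path: str
    name: str | None = None
    trait_type: str = "continuous"
    column_map: dict | None = None
    delimiter: str = "\t"

    def load(self) -> SummaryStatsTable:
        cmap = ColumnMap(**self.column_map) if self.column_map else None
        return read_summary_stats(
            self.path, cmap, trait_type=self.trait_type,
            trait_name=self.name, delimiter=self.delimiter,
        )


class LDSpec(BaseModel):
    mode: str = "file"  # file | zero | distance_only
    file: str | None = None
    default_r2: float | None = 0.0

    def build(self) -> LDLookup:
        if self.mode == "zero":
            return ZeroLD()
        if self.mode == "distance_only":
            return DistanceOnlyLD()
        if self.mode == "file":
            if self.file is None:
                raise ConfigError("ld.mode=file requires ld.file")
            return MatrixLD.from_tsv(self.file, default=self.default_r2)
        raise ConfigError(f"unknown ld.mode {self.mode!r}")


class RunConfig(BaseModel):
    """Full pipeline configuration; see the package docs for a worked example."""

    exposures: list[TableSpec]
    mediators: list[TableSpec] = Field(default_factory=list)
    outcome: TableSpec
    ld: LDSpec = LDSpec(mode="zero")
    selection_molecular: SelectionConfig = SelectionConfig(p_threshold=5e-5)
    selection_outcome: SelectionConfig = SelectionConfig(p_threshold=5e-8)
    harmonization: HarmonizeConfig = HarmonizeConfig()
    method: str = "ivw_re"
    alpha: float = 0.05
    n_boot: int = 1000
    n_presso_simulations: int = 1000
    run_presso: bool = True
    seed: int = 0
    mediated_ci_method: str = "delta"
    exclude_exposure_instruments: bool = True
    multiple_testing: str = "none"
    output_dir: str = "medmr_results"

    model_config = {"arbitrary_types_allowed": True}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def mediation_config(self) -> MediationConfig:
        return MediationConfig(
            selection_molecular=self.selection_molecular,
            selection_outcome=self.selection_outcome,
            harmonization=self.harmonization,
            method=self.method,
            alpha=self.alpha,
            n_boot=self.n_boot,
            n_presso_simulations=self.n_presso_simulations,
            run_presso=self.run_presso,
            seed=self.seed,
            mediated_ci_method=self.mediated_ci_method,
            exclude_exposure_instruments=self.exclude_exposure_instruments,
            multiple_testing=self.multiple_testing,
        )

    def validate_paths(self) -> None:
        """Fail fast before any output is produced."""
        missing = []
        for spec in [*self.exposures, *self.mediators, self.outcome]:
            if not Path(spec.path).exists():
                missing.append(spec.path)
        if self.ld.mode == "file" and self.ld.file and not Path(self.ld.file).exists():
            missing.append(self.ld.file)
        if missing:
            raise ConfigError(f"input path(s) do not exist: {missing}")

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(config: RunConfig, outdir: Path, phase: str, extra: dict | None = None) -> None:
    manifest = {
        "phase": phase,
        "medmr_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
    }
    if extra:
        manifest.update(extra)
    with open(outdir / f"manifest_{phase}.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


def _funnel_logs(res, direction: str, exposure: str, outcome: str) -> pd.DataFrame:
    """Per-variant removal log for one MR run (selection + harmonization)."""
    rows = []
    model = res.model
    if model.selection is not None:
        rep = model.selection.report
        for rec in rep.loc[~rep["kept"]].itertuples(index=False):
            rows.append((exposure, outcome, direction, rec.variant_id, f"selection:{rec.drop_reason}"))
    if model.harmonized is not None:
        for rec in model.harmonized.exclusions.itertuples(index=False):
            rows.append((exposure, outcome, direction, rec.variant_id, f"harmonization:{rec.reason}"))
    if res.presso is not None:
        for vid in res.presso.outliers:
            rows.append((exposure, outcome, direction, vid, "presso:outlier"))
    return pd.DataFrame(rows, columns=["exposure", "outcome", "direction", "variant_id", "reason"])


def run_phase1(config: RunConfig) -> pd.DataFrame:
    """Bidirectional screen of every exposure against the outcome.

    Writes phase1_results.tsv, phase1_diagnostics.tsv, phase1_exclusions.tsv
    and manifest_phase1.json to the output directory; returns the result table.
    Exit status (via the CLI) reflects validation errors only — a
    scientifically null screen still succeeds.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.mediation_config()
    outcome = config.outcome.load()
    ld = config.ld.build()

    rows, diag_rows, excl_frames = [], [], []
    for spec in config.exposures:
        exposure = spec.load()
        log.info("phase1: screening %s (%d variants) against %s", exposure.trait_name, len(exposure), outcome.trait_name)
        screen = bidirectional_screen(exposure, outcome, ld, cfg)
        row = {"exposure": exposure.trait_name, "outcome": outcome.trait_name}
        for tag, res in (("c", screen.forward), ("d", screen.reverse)):
            if res is None:
                row.update({f"{tag}_beta": float("nan"), f"{tag}_se": float("nan"),
                            f"{tag}_pval": float("nan"), f"{tag}_n_snps": 0})
            else:
                row.update({f"{tag}_beta": res.beta, f"{tag}_se": res.se,
                            f"{tag}_pval": res.pval, f"{tag}_n_snps": res.n_snps})
                d = res.diagnostics_row()
                d["direction"] = "forward" if tag == "c" else "reverse"
                diag_rows.append(d)
                excl_frames.append(_funnel_logs(res, d["direction"], row["exposure"], row["outcome"]))
                log.info("phase1: %s %s: %d instruments kept", exposure.trait_name, d["direction"], res.n_snps)
        row["passes_screen"] = screen.passes(cfg.alpha)
        row["failure_reason"] = screen.failure_reason or ""
        rows.append(row)

    results = pd.DataFrame(rows)
    results.to_csv(outdir / "phase1_results.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(diag_rows).to_csv(outdir / "phase1_diagnostics.tsv", sep="\t", index=False, float_format="%.10g")
    excl = pd.concat(excl_frames, ignore_index=True) if excl_frames else pd.DataFrame(
        columns=["exposure", "outcome", "direction", "variant_id", "reason"])
    excl.to_csv(outdir / "phase1_exclusions.tsv", sep="\t", index=False)
    _write_manifest(config, outdir, "phase1", {"n_exposures": len(config.exposures)})
    return results


def run_phase2(config: RunConfig, force: bool = False) -> pd.DataFrame:
    """Two-step mediation batch over every exposure x mediator pathway.

    Requires a prior phase-1 run in the output directory unless ``force`` is
    set (then a prominent warning is logged).  Writes phase2_pathways.tsv,
    phase2_rejections.tsv, phase2_diagnostics.tsv and manifest_phase2.json.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    phase1_path = outdir / "phase1_results.tsv"
    if not phase1_path.exists():
        if not force:
            raise ConfigError(
                f"phase 1 results not found at {phase1_path}; run phase1 first or pass --force"
            )
        log.warning("phase2 --force: running WITHOUT a phase-1 screen on record")
    outdir.mkdir(parents=True, exist_ok=True)

    cfg = config.mediation_config()
    outcome = config.outcome.load()
    ld = config.ld.build()
    exposures = [s.load() for s in config.exposures]
    mediators = [s.load() for s in config.mediators]
    log.info("phase2: %d exposures x %d mediators", len(exposures), len(mediators))

    batch = batch_screen(exposures, mediators, outcome, ld, cfg)

    diag_rows, excl_frames = [], []
    for r in batch.pathways:
        for direction, res in (("a", r.a), ("b", r.b), ("forward", r.screen.forward), ("reverse", r.screen.reverse)):
            if res is not None:
                d = res.diagnostics_row()
                d["direction"] = direction
                diag_rows.append(d)
                excl_frames.append(_funnel_logs(res, direction, r.exposure, r.outcome))

    report = batch.report
    if report.empty:
        report = pd.DataFrame(columns=list(batch.pathways[0].row().keys()) if batch.pathways else [])
    report.to_csv(outdir / "phase2_pathways.tsv", sep="\t", index=False, float_format="%.10g")
    batch.rejections.to_csv(outdir / "phase2_rejections.tsv", sep="\t", index=False)
    diag = pd.DataFrame(diag_rows).drop_duplicates()
    diag.to_csv(outdir / "phase2_diagnostics.tsv", sep="\t", index=False, float_format="%.10g")
    excl = pd.concat(excl_frames, ignore_index=True).drop_duplicates() if excl_frames else pd.DataFrame(
        columns=["exposure", "outcome", "direction", "variant_id", "reason"])
    excl.to_csv(outdir / "phase2_exclusions.tsv", sep="\t", index=False)
    _write_manifest(
        config, outdir, "phase2",
        {"n_pathways_tested": len(batch.pathways), "n_pathways_passing": len(batch.report)},
    )
    log.info("phase2: %d/%d pathways pass", len(batch.report), len(batch.pathways))
    return report
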