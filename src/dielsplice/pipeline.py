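"""End-to-end pipeline: stage functions, run configuration, and manifest.

Stages run in method order: annotate -> quantify -> normalize-time ->
fit-rhythms -> ratios -> temperature-regression.  Every stage is a pure
function of its inputs plus the configuration and seed; ``run_all`` writes
tidy CSV outputs and a JSON manifest recording the seed and a parameter hash
so identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .clock_genes import clock_gene_fixture
from .fragment_quant import quantify_peak_table, read_panel, read_peak_table
from .gene_models import consequences_table, read_gff3, events_from_yaml
from .rhythm_stats import fit_all_series
from .splice_ratio_temp import (
    RatioSeries,
    ratio_fold_range,
    ratio_table,
    read_temperature_csv,
    regression_table,
)
from .time_norm import annotate_samples, read_season_config

logger = logging.getLogger("dielsplice")


@dataclass
class RunConfig:
    outdir: str = "dielsplice_run"
    seed: int = 0
    simulate: bool = True  # generate a synthetic study when no inputs given
    # input paths (required when simulate=False)
    metadata_csv: Optional[str] = None
    peak_tables_csv: Optional[str] = None
    panel_yaml: Optional[str] = None
    seasons_yaml: Optional[str] = None
    temperature_csv: Optional[str] = None
    gff3: Optional[str] = None
    fasta: Optional[str] = None
    events_yaml: Optional[str] = None
    # analysis parameters
    span: float = 0.5
    grid_step: float = 0.1
    n_boot: int = 200
    assignment_tol: float = 2.0
    sizing_method: str = "piecewise_linear"
    pseudo_count: Optional[float] = None  # None -> half smallest nonzero abundance
    log_base: str = "10"
    alpha: float = 0.05
    expression_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of human-readable violations; empty iff usable."""
    v = []
    if not (0 < cfg.span <= 1):
        v.append(f"span must be a fraction in (0, 1], got {cfg.span}")
    if cfg.grid_step <= 0:
        v.append(f"grid_step must be > 0, got {cfg.grid_step}")
    if not (0 < cfg.alpha < 1):
        v.append(f"alpha must be in (0, 1), got {cfg.alpha}")
    if cfg.pseudo_count is not None and cfg.pseudo_count < 0:
        v.append(f"pseudo_count must be >= 0, got {cfg.pseudo_count}")
    if cfg.log_base not in {"10", "e"}:
        v.append(f"log_base must be '10' or 'e', got {cfg.log_base}")
    if cfg.assignment_tol <= 0:
        v.append(f"assignment_tol must be > 0, got {cfg.assignment_tol}")
    if cfg.n_boot < 2:
        v.append(f"n_boot must be >= 2, got {cfg.n_boot}")
    if not (0 <= cfg.expression_threshold <= 1):
        v.append(f"expression_threshold must be in [0, 1], got {cfg.expression_threshold}")
    if not cfg.simulate:
        for name in ("metadata_csv", "peak_tables_csv", "panel_yaml",
                     "seasons_yaml", "temperature_csv"):
            path = getattr(cfg, name)
            if path is None:
                v.append(f"{name} is required when simulate=false")
            elif not Path(path).exists():
                v.append(f"{name}: file not found: {path}")
    return v


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_annotate(cfg: RunConfig) -> pd.DataFrame:
    """AS-event consequence table from gene models (built-in clock fixture
    unless a GFF3/FASTA/events triple is supplied)."""
    if cfg.gff3 and cfg.fasta and cfg.events_yaml:
        genes = read_gff3(cfg.gff3, cfg.fasta)
        events = events_from_yaml(Path(cfg.events_yaml).read_text())
    else:
        genes, events = clock_gene_fixture()
    return consequences_table(genes, events)


def stage_quantify(cfg: RunConfig, peaks: pd.DataFrame, panel_path) -> pd.DataFrame:
    defs, refs, ladder = read_panel(panel_path)
    return quantify_peak_table(
        peaks, defs, refs,
        tol=cfg.assignment_tol,
        sizing_method=cfg.sizing_method,
        ladder_sizes=ladder,
    )


def stage_normtime(cfg: RunConfig, metadata: pd.DataFrame, seasons_path) -> pd.DataFrame:
    photoperiods = read_season_config(seasons_path)
    return annotate_samples(metadata, photoperiods)


def stage_rhythms(cfg: RunConfig, tidy: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    return fit_all_series(
        tidy,
        span=cfg.span,
        grid_step=cfg.grid_step,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        expression_threshold=cfg.expression_threshold,
    )


def stage_ratios(cfg: RunConfig, tidy: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    ratios = ratio_table(tidy, pseudo=cfg.pseudo_count, base=cfg.log_base)
    fold_rows = []
    for (gene_id, event_id), grp in ratios.groupby(["gene_id", "event_id"], sort=True):
        rs = RatioSeries(
            gene_id=gene_id, event_id=event_id, organ="*", season_id="*",
            zt=grp["zt"].to_numpy(), replicate=grp["replicate"].to_numpy(),
            clock_time=grp["clock_time"].to_numpy(),
            log_ratio=grp["log_ratio"].to_numpy(),
            pseudo_count=float(grp["pseudo_count"].iloc[0]),
            log_base=float(grp["log_base"].iloc[0]),
        )
        fold_rows.append({
            "gene_id": gene_id,
            "event_id": event_id,
            "fold_range": ratio_fold_range(rs, smooth=True, span=cfg.span),
            "n_points": len(grp),
        })
    return ratios, pd.DataFrame(fold_rows)


def stage_tempcor(cfg: RunConfig, ratios: pd.DataFrame, temperature_path) -> pd.DataFrame:
    temps = read_temperature_csv(temperature_path)
    return regression_table(ratios, temps, alpha=cfg.alpha)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _param_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns a manifest dict (also written to disk)."""
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid configuration:\n" + "\n".join(violations))

    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "param_hash": _param_hash(cfg),
        "stages": {},
    }

    def record(stage: str, t0: float, **info):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **info}
        logger.info("stage %s done (%.2fs) %s", stage, time.time() - t0, info)

    if cfg.simulate:
        from .synthetic_data import SimConfig, simulate_peak_tables, simulate_study, write_study

        t0 = time.time()
        study = simulate_study(SimConfig(seed=cfg.seed))
        peaks = simulate_peak_tables(study)
        paths = write_study(study, out / "inputs", peak_tables=peaks)
        cfg.metadata_csv = paths["metadata"]
        cfg.peak_tables_csv = paths["peak_tables"]
        cfg.panel_yaml = paths["panel"]
        cfg.seasons_yaml = paths["seasons"]
        cfg.temperature_csv = paths["temperature"]
        record("simulate", t0, n_samples=len(study.metadata))

    t0 = time.time()
    consequences = stage_annotate(cfg)
    consequences.to_csv(out / "consequences.csv", index=False)
    record("annotate", t0, n_events=len(consequences))

    t0 = time.time()
    peaks = read_peak_table(cfg.peak_tables_csv)
    abund = stage_quantify(cfg, peaks, cfg.panel_yaml)
    abund.to_csv(out / "abundances_normalized.csv", index=False)
    record("quantify", t0, n_records=len(abund),
           excluded=abund.attrs.get("excluded_samples", []))

    t0 = time.time()
    metadata = pd.read_csv(cfg.metadata_csv)
    metadata = stage_normtime(cfg, metadata, cfg.seasons_yaml)
    metadata.to_csv(out / "metadata_zt.csv", index=False)
    record("normtime", t0, n_samples=len(metadata))

    tidy = abund.merge(
        metadata[["sample_id", "organ", "season_id", "clock_time", "replicate", "zt"]],
        on="sample_id",
    )

    t0 = time.time()
    fits, summary = stage_rhythms(cfg, tidy)
    fits.to_csv(out / "loess_fits.csv", index=False)
    summary.to_csv(out / "rhythm_summary.csv", index=False)
    record("rhythms", t0, n_series=len(summary))

    t0 = time.time()
    ratios, folds = stage_ratios(cfg, tidy)
    ratios.to_csv(out / "ratios.csv", index=False)
    folds.to_csv(out / "ratio_fold_ranges.csv", index=False)
    record("ratios", t0, n_points=len(ratios))

    t0 = time.time()
    regressions = stage_tempcor(cfg, ratios, cfg.temperature_csv)
    regressions.to_csv(out / "temp_regression.csv", index=False)
    record("tempcor", t0, n_groups=len(regressions))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
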