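"""Synthetic field-study generator.

Produces complete synthetic diel studies with the statistical structure the
analysis assumes: two seasonal photoperiods (11.5 h and 13.25 h days), a
14-point 26-h sampling course starting 2 h before dawn, three pooled
biological replicates per point, truncated-cosine fully spliced (FS) rhythms,
alternative (AS) isoforms whose log10(AS/FS) ratio carries a rhythmic term
plus a temperature coupling, two constant reference genes, lognormal
replicate scatter, a diel temperature log with AR(1) noise (winter cooler
than summer), and capillary peak tables with ladder peaks and per-sample
gain.  Every generating parameter is recorded in a truth table so parameter
recovery can be asserted end to end.

All randomness flows through one seeded generator; the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fragment_quant import AmpliconDef, check_panel, write_panel
from .splice_ratio_temp import TemperatureSeries
from .time_norm import Photoperiod, build_schedule, write_season_config

# GeneScan-500-LIZ-like ladder fragment sizes (bp)
LADDER_SIZES = [35, 50, 75, 100, 139, 150, 160, 200, 250, 300, 340, 350, 400, 450, 490, 500]


@dataclass(frozen=True)
class GeneSim:
    gene_id: str
    fs_peak_zt: float
    amplitude: float
    baseline: float
    fs_amplicon_bp: float


@dataclass(frozen=True)
class EventSim:
    gene_id: str
    event_id: str
    ratio_peak_zt: float  # peak of the rhythmic log-ratio term
    rel_level: float      # mean linear AS/FS ratio (10**ratio_mean)
    temp_slope: float     # log10-ratio change per degree C
    ratio_amp: float      # amplitude of the rhythmic log10-ratio term
    delta_bp: float       # AS amplicon size minus FS amplicon size


@dataclass(frozen=True)
class RefGeneSim:
    gene_id: str
    level: float
    amplicon_bp: float


@dataclass(frozen=True)
class TempSim:
    mean_c: dict  # season_id -> daily mean temperature
    diel_amplitude_c: float = 5.0
    phase_clock: float = 14.0  # clock hour of the daily maximum
    ar1_phi: float = 0.7
    ar1_sd: float = 0.5
    interval_h: float = 0.5
    duration_h: float = 36.0


@dataclass
class SimConfig:
    seed: int = 0
    seasons: dict = field(default_factory=lambda: {
        "winter": Photoperiod("winter", 6.5, 18.0),    # 11.5 h day / 12.5 h night
        "summer": Photoperiod("summer", 5.75, 19.0),   # 13.25 h day / 10.75 h night
    })
    organs_by_season: dict = field(default_factory=lambda: {
        "winter": ["L1"],
        "summer": ["L1", "I1", "I5"],
    })
    start_offset: float = 2.0
    interval: float = 2.0
    duration: float = 26.0
    n_replicates: int = 3
    genes: list = field(default_factory=lambda: [
        GeneSim("ScLHY", 4.0, 1.0, 0.05, 242.0),
        GeneSim("ScPRR37", 8.0, 0.8, 0.05, 250.0),
        GeneSim("ScPRR73", 10.0, 0.6, 0.05, 260.0),
    ])
    events: list = field(default_factory=lambda: [
        EventSim("ScLHY", "I1R", 0.0, 0.10, -0.05, 0.5, +152.0),
        EventSim("ScLHY", "I5R", 0.0, 0.15, -0.05, 0.5, +176.0),
        EventSim("ScPRR37", "I6R", 4.0, 0.20, 0.0, 0.5, +131.0),
        EventSim("ScPRR73", "I2R", 5.0, 0.20, 0.0, 0.5, +190.0),
    ])
    reference_genes: list = field(default_factory=lambda: [
        RefGeneSim("ScGAPDH", 1.0, 300.0),
        RefGeneSim("ScPP2AA2", 0.8, 330.0),
    ])
    noise_sd: float = 0.15       # lognormal sigma of replicate scatter
    gain_sd: float = 0.3         # lognormal sigma of per-sample gain
    temperature: TempSim = field(default_factory=lambda: TempSim(
        mean_c={"winter": 18.0, "summer": 26.0}))
    ladder_sizes: list = field(default_factory=lambda: list(LADDER_SIZES))
    # migration model: scans = m0 + slope * bp + curvature * bp**2
    migration_m0: float = 500.0
    migration_slope: float = 3.0
    migration_curvature: float = 0.0005
    assignment_tol: float = 2.0

    def validate(self) -> None:
        if any(g.amplitude < 0 for g in self.genes):
            raise ValueError("amplitudes must be >= 0")
        if any(not (0 <= e.ratio_peak_zt < 24) for e in self.events):
            raise ValueError("ratio_peak_zt must be in [0, 24)")
        for s in self.seasons.values():
            if s.day_length + s.night_length != 24.0:
                raise ValueError("photoperiod must sum to 24 h")
        check_panel(self.panel()[0], self.assignment_tol)

    def panel(self) -> tuple[list[AmpliconDef], list[str], list[float]]:
        defs = [AmpliconDef(g.gene_id, "FS", g.fs_amplicon_bp) for g in self.genes]
        fs_bp = {g.gene_id: g.fs_amplicon_bp for g in self.genes}
        defs += [
            AmpliconDef(e.gene_id, e.event_id, fs_bp[e.gene_id] + e.delta_bp)
            for e in self.events
        ]
        defs += [AmpliconDef(r.gene_id, r.gene_id, r.amplicon_bp) for r in self.reference_genes]
        return defs, [r.gene_id for r in self.reference_genes], list(self.ladder_sizes)


def truncated_cosine(zt: np.ndarray, peak_zt: float) -> np.ndarray:
    """Sharp-peaked diel waveform: the positive part of a 24-h cosine."""
    return np.maximum(0.0, np.cos(2 * np.pi * (np.asarray(zt, float) - peak_zt) / 24.0))


# ---------------------------------------------------------------------------
# Temperature
# ---------------------------------------------------------------------------

def simulate_temperature(cfg: SimConfig, rng: Optional[np.random.Generator] = None
                         ) -> dict[str, TemperatureSeries]:
    """Diel temperature log per season: seasonal mean + cosine + AR(1) noise."""
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1])
    ts = cfg.temperature
    out = {}
    for season in sorted(cfg.seasons):
        t = np.arange(0.0, ts.duration_h + 1e-9, ts.interval_h)
        smooth = ts.mean_c[season] + ts.diel_amplitude_c * np.cos(
            2 * np.pi * (t - ts.phase_clock) / 24.0
        )
        noise = np.zeros_like(t)
        innov_sd = ts.ar1_sd * np.sqrt(max(1e-12, 1 - ts.ar1_phi**2))
        e = rng.normal(0.0, 1.0, size=len(t))
        noise[0] = e[0] * ts.ar1_sd
        for i in range(1, len(t)):
            noise[i] = ts.ar1_phi * noise[i - 1] + innov_sd * e[i]
        out[season] = TemperatureSeries(season, t, smooth + noise)
    return out


def smooth_temperature_at(cfg: SimConfig, season: str, clock_time: np.ndarray) -> np.ndarray:
    """Noise-free part of the temperature model (used for truth curves)."""
    ts = cfg.temperature
    return ts.mean_c[season] + ts.diel_amplitude_c * np.cos(
        2 * np.pi * (np.asarray(clock_time, float) - ts.phase_clock) / 24.0
    )


# ---------------------------------------------------------------------------
# Abundances
# ---------------------------------------------------------------------------

@dataclass
class SimStudy:
    config: SimConfig
    metadata: pd.DataFrame        # sample_id, organ, season_id, clock_time, replicate, T, zt, day_index
    abundances: pd.DataFrame      # tidy noisy normalized abundances (truth x lognormal noise)
    truth_abundances: pd.DataFrame
    truth_params: pd.DataFrame
    temperature: dict             # season_id -> TemperatureSeries


def _true_fs(g: GeneSim, zt: np.ndarray) -> np.ndarray:
    return g.baseline + g.amplitude * truncated_cosine(zt, g.fs_peak_zt)


def _true_log_ratio(e: EventSim, zt: np.ndarray, temp: np.ndarray, season_mean: float) -> np.ndarray:
    return (
        np.log10(e.rel_level)
        + e.ratio_amp * np.cos(2 * np.pi * (np.asarray(zt, float) - e.ratio_peak_zt) / 24.0)
        + e.temp_slope * (np.asarray(temp, float) - season_mean)
    )


def true_peak_zt(curve_fn, window: tuple[float, float] = (0.0, 22.0)) -> float:
    """Numeric argmax of a noiseless truth curve on a fine ZT grid."""
    grid = np.arange(window[0], window[1] + 1e-9, 0.01)
    return float(grid[int(np.argmax(curve_fn(grid)))])


def simulate_abundances(cfg: SimConfig, rng: Optional[np.random.Generator] = None,
                        temperature: Optional[dict] = None) -> SimStudy:
    """Generate sample metadata, truth and noisy abundances, and truth tables."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 2])
    if temperature is None:
        temperature = simulate_temperature(cfg)

    meta_rows, truth_rows, abund_rows = [], [], []
    for season in sorted(cfg.seasons):
        pp = cfg.seasons[season]
        schedule = build_schedule(pp, cfg.start_offset, cfg.interval, cfg.duration)
        temps = temperature[season]
        for organ in cfg.organs_by_season[season]:
            for _, point in schedule.iterrows():
                clock = float(point["clock_time"])
                zt = float(point["zt"])
                temp_here = float(temps.at(np.array([clock]))[0])
                iso_truth: list[tuple[str, str, float]] = []
                for g in cfg.genes:
                    fs = float(_true_fs(g, np.array([zt]))[0])
                    iso_truth.append((g.gene_id, "FS", fs))
                    for e in cfg.events:
                        if e.gene_id != g.gene_id:
                            continue
                        lr = float(_true_log_ratio(
                            e, np.array([zt]), np.array([temp_here]),
                            cfg.temperature.mean_c[season])[0])
                        iso_truth.append((g.gene_id, e.event_id, fs * 10**lr))
                for r in cfg.reference_genes:
                    iso_truth.append((r.gene_id, r.gene_id, r.level))

                for rep in range(1, cfg.n_replicates + 1):
                    sample_id = f"{season}_{organ}_t{int(point['time_index']):02d}_r{rep}"
                    meta_rows.append({
                        "sample_id": sample_id,
                        "organ": organ,
                        "season_id": season,
                        "clock_time": clock,
                        "replicate": rep,
                        "T": float(point["T"]),
                        "zt": zt,
                        "day_index": int(point["day_index"]),
                    })
                    for gene_id, isoform_id, truth in iso_truth:
                        noisy = truth * float(np.exp(rng.normal(0.0, cfg.noise_sd))) \
                            if cfg.noise_sd > 0 else truth
                        abund_rows.append({
                            "sample_id": sample_id,
                            "gene_id": gene_id,
                            "isoform_id": isoform_id,
                            "norm_abundance": noisy,
                        })
                        truth_rows.append({
                            "sample_id": sample_id,
                            "gene_id": gene_id,
                            "isoform_id": isoform_id,
                            "true_abundance": truth,
                        })

    params = _truth_params(cfg)
    return SimStudy(
        config=cfg,
        metadata=pd.DataFrame(meta_rows),
        abundances=pd.DataFrame(abund_rows),
        truth_abundances=pd.DataFrame(truth_rows),
        truth_params=params,
        temperature=temperature,
    )


def _truth_params(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for season in sorted(cfg.seasons):
        season_mean = cfg.temperature.mean_c[season]
        pp = cfg.seasons[season]
        for g in cfg.genes:
            fs_peak = true_peak_zt(lambda z: _true_fs(g, z))
            rows.append({
                "season_id": season, "gene_id": g.gene_id, "isoform_id": "FS",
                "true_peak_zt": fs_peak, "amplitude": g.amplitude,
                "baseline": g.baseline, "temp_slope": 0.0,
                "rel_level": 1.0, "ratio_amp": 0.0,
            })
            for e in cfg.events:
                if e.gene_id != g.gene_id:
                    continue

                def as_curve(z, g=g, e=e, season=season):
                    # noiseless AS abundance over one cycle: evaluate the
                    # smooth temperature at the clock time of each zt
                    from .time_norm import zt_denormalize
                    clock = np.array([
                        pp.dawn + zt_denormalize(zi, pp) for zi in np.atleast_1d(z)
                    ])
                    temp = smooth_temperature_at(cfg, season, clock)
                    fs = _true_fs(g, z)
                    return fs * 10 ** _true_log_ratio(e, z, temp, season_mean)

                rows.append({
                    "season_id": season, "gene_id": g.gene_id, "isoform_id": e.event_id,
                    "true_peak_zt": true_peak_zt(as_curve),
                    "amplitude": g.amplitude, "baseline": g.baseline,
                    "temp_slope": e.temp_slope, "rel_level": e.rel_level,
                    "ratio_amp": e.ratio_amp,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Peak tables and raw traces
# ---------------------------------------------------------------------------

def migration_of(cfg: SimConfig, bp: np.ndarray) -> np.ndarray:
    bp = np.asarray(bp, float)
    return cfg.migration_m0 + cfg.migration_slope * bp + cfg.migration_curvature * bp**2


def simulate_peak_tables(
    study: SimStudy,
    rng: Optional[np.random.Generator] = None,
    area_scale: float = 1000.0,
) -> pd.DataFrame:
    """Per-sample capillary peak table: ladder peaks at known sizes plus one
    target peak per amplicon, areas proportional to abundance x per-sample
    gain."""
    cfg = study.config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 3])
    defs, _, ladder_sizes = cfg.panel()
    if not defs:
        raise ValueError("empty amplicon panel")
    size_of = {(d.gene_id, d.isoform_id): d.expected_size for d in defs}
    rows = []
    abund = study.abundances.set_index(["sample_id", "gene_id", "isoform_id"])["norm_abundance"]
    for sample_id in study.metadata["sample_id"]:
        gain = float(np.exp(rng.normal(0.0, cfg.gain_sd))) if cfg.gain_sd > 0 else 1.0
        for bp in ladder_sizes:
            rows.append({
                "sample_id": sample_id, "dye": "ladder",
                "migration": float(migration_of(cfg, np.array([bp]))[0]),
                "height": 100.0, "area": 500.0,
            })
        for (gene_id, isoform_id), bp in sorted(size_of.items()):
            try:
                level = float(abund.loc[(sample_id, gene_id, isoform_id)])
            except KeyError:
                continue
            area = level * gain * area_scale
            if area <= 0:
                continue
            rows.append({
                "sample_id": sample_id, "dye": "target",
                "migration": float(migration_of(cfg, np.array([bp]))[0]),
                "height": area / 10.0, "area": area,
            })
    return pd.DataFrame(rows)


def simulate_trace(
    peak_migrations: np.ndarray,
    peak_areas: np.ndarray,
    n_scans: int = 4000,
    width: float = 3.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Gaussian-peak electropherogram for exercising the raw-trace peak caller."""
    x = np.arange(n_scans, dtype=float)
    y = np.zeros(n_scans)
    for m, a in zip(np.asarray(peak_migrations, float), np.asarray(peak_areas, float)):
        y += a / (width * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - m) / width) ** 2)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        y = np.maximum(0.0, y + rng.normal(0.0, noise_sd, size=n_scans))
    return y


# ---------------------------------------------------------------------------
# Whole-study driver and file output
# ---------------------------------------------------------------------------

def simulate_study(cfg: Optional[SimConfig] = None, seed: Optional[int] = None) -> SimStudy:
    """Convenience wrapper: default config (optionally reseeded) -> SimStudy."""
    if cfg is None:
        cfg = SimConfig()
    if seed is not None:
        cfg.seed = int(seed)
    return simulate_abundances(cfg)


def write_study(study: SimStudy, outdir, peak_tables: Optional[pd.DataFrame] = None) -> dict:
    """Write the study in the formats the analysis stages read."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    paths = {
        "metadata": out / "metadata.csv",
        "abundances": out / "abundances.csv",
        "truth_abundances": out / "truth_abundances.csv",
        "truth_params": out / "truth_params.csv",
        "temperature": out / "temperature.csv",
        "panel": out / "panel.yaml",
        "seasons": out / "seasons.yaml",
    }
    study.metadata.to_csv(paths["metadata"], index=False)
    study.abundances.to_csv(paths["abundances"], index=False)
    study.truth_abundances.to_csv(paths["truth_abundances"], index=False)
    study.truth_params.to_csv(paths["truth_params"], index=False)
    temp_rows = []
    for season, series in sorted(study.temperature.items()):
        for t, c in zip(series.clock_time, series.temp_c):
            temp_rows.append({"season_id": season, "clock_time": t, "temp_c": c})
    pd.DataFrame(temp_rows).to_csv(paths["temperature"], index=False)
    defs, refs, ladder = cfg.panel()
    write_panel(paths["panel"], defs, refs, ladder)
    write_season_config(paths["seasons"], cfg.seasons)
    if peak_tables is not None:
        paths["peak_tables"] = out / "peak_tables.csv"
        peak_tables.to_csv(paths["peak_tables"], index=False)
    return {k: str(v) for k, v in paths.items()}
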