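"""Splicing-ratio rhythms and their relationship to ambient temperature.

The splicing ratio of an alternative isoform is log(AS/FS) at each replicate
time point (log10 by default, with a symmetric pseudo-count against zeros).
The ratio's rhythm is summarized by its fold range — the max/min ratio on the
linear AS/FS scale — and regressed on ambient temperature interpolated to the
sampling instants (ordinary least squares; slope, R², two-sided p per pooled
group).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rhythm_stats import IsoformSeries, _lowess_grid


class AlignmentError(ValueError):
    """AS and FS series do not share (zt, replicate) keys."""


class InsufficientDataError(ValueError):
    """Too few matched points for a regression."""


@dataclass
class RatioSeries:
    gene_id: str
    event_id: str
    organ: str
    season_id: str
    zt: np.ndarray
    replicate: np.ndarray
    clock_time: np.ndarray  # hours, for temperature matching
    log_ratio: np.ndarray
    pseudo_count: float
    log_base: float  # 10 or e
    n_dropped: int = 0  # points where both isoforms were below detection


def default_pseudo_count(abundances: Sequence[float]) -> float:
    """Half the smallest nonzero abundance in the dataset (0 if none)."""
    arr = np.asarray(abundances, dtype=float)
    nz = arr[arr > 0]
    return float(nz.min() / 2.0) if nz.size else 0.0


def ratio_series(
    as_series: IsoformSeries,
    fs_series: IsoformSeries,
    pseudo: float = 0.0,
    base: str = "10",
    clock_time: Optional[np.ndarray] = None,
) -> RatioSeries:
    """log_base((AS + pseudo) / (FS + pseudo)) aligned on (zt, replicate).

    Points where both isoforms are below detection (both zero) are dropped
    and counted in ``n_dropped``.
    """
    if pseudo < 0:
        raise ValueError("pseudo-count must be >= 0")

    def keys_of(s: IsoformSeries):
        if s.point_id is not None:
            return list(s.point_id)
        # (zt, replicate) is ambiguous once a >24 h course wraps; callers with
        # wrapped points should supply point_id (e.g. the sample id)
        return list(zip(s.zt, s.replicate))

    ak, fk = keys_of(as_series), keys_of(fs_series)
    key_as = dict(zip(ak, as_series.abundance))
    key_fs = dict(zip(fk, fs_series.abundance))
    missing = set(key_as) ^ set(key_fs)
    if missing:
        raise AlignmentError(f"series misaligned at keys: {sorted(map(str, missing))[:5]} ...")

    zt_of = dict(zip(ak, as_series.zt))
    rep_of = dict(zip(ak, as_series.replicate))
    clock_map = {}
    if clock_time is not None:
        clock_map = dict(zip(ak, np.asarray(clock_time, float)))

    log_fn = np.log10 if base == "10" else np.log
    base_val = 10.0 if base == "10" else float(np.e)
    zts, reps, clocks, ratios = [], [], [], []
    dropped = 0
    for key in sorted(key_as, key=lambda k: (zt_of[k], str(rep_of[k]), str(k))):
        a, f = key_as[key], key_fs[key]
        if a <= 0 and f <= 0:
            dropped += 1
            continue
        if f + pseudo <= 0 or a + pseudo <= 0:
            dropped += 1
            continue
        zts.append(zt_of[key])
        reps.append(rep_of[key])
        clocks.append(clock_map.get(key, np.nan))
        ratios.append(log_fn((a + pseudo) / (f + pseudo)))
    return RatioSeries(
        gene_id=as_series.gene_id,
        event_id=as_series.isoform_id,
        organ=as_series.organ,
        season_id=as_series.season_id,
        zt=np.asarray(zts, float),
        replicate=np.asarray(reps),
        clock_time=np.asarray(clocks, float),
        log_ratio=np.asarray(ratios, float),
        pseudo_count=pseudo,
        log_base=base_val,
        n_dropped=dropped,
    )


def ratio_fold_range(
    ratio: RatioSeries,
    smooth: bool = False,
    span: float = 0.5,
    literal_log_ratio: bool = False,
) -> float:
    """Fold difference between the rhythm's maximum and minimum on the linear
    AS/FS scale: base ** (max - min) of the log-ratio series.

    With ``smooth`` the range is taken over a LOESS curve instead of raw
    points.  ``literal_log_ratio`` switches to the max/min quotient of the
    log values themselves (base-dependent; provided for comparison only).
    """
    if len(ratio.log_ratio) < 2:
        raise InsufficientDataError("fold range needs >=2 ratio points")
    values = ratio.log_ratio
    if smooth:
        grid = np.arange(0.0, 24.0 + 1e-9, 0.1)
        values = _lowess_grid(ratio.zt, ratio.log_ratio, grid, span)
    vmax, vmin = float(np.max(values)), float(np.min(values))
    if literal_log_ratio:
        if vmin == 0:
            raise ZeroDivisionError("literal log-ratio fold undefined: min is 0")
        return vmax / vmin
    return float(ratio.log_base ** (vmax - vmin))


@dataclass
class TemperatureSeries:
    """Weather-station log: ambient temperature over clock time, per season."""

    season_id: str
    clock_time: np.ndarray  # decimal hours from midnight of the first course day
    temp_c: np.ndarray

    def __post_init__(self) -> None:
        self.clock_time = np.asarray(self.clock_time, float)
        self.temp_c = np.asarray(self.temp_c, float)
        if not np.all(np.isfinite(self.temp_c)):
            raise ValueError("temperature values must be finite")

    def at(self, clock_times: np.ndarray) -> np.ndarray:
        """Linear interpolation to the sampling instants."""
        t = np.asarray(clock_times, float)
        if t.min() < self.clock_time.min() - 1e-9 or t.max() > self.clock_time.max() + 1e-9:
            raise ValueError("temperature log does not cover all sampling instants")
        order = np.argsort(self.clock_time)
        return np.interp(t, self.clock_time[order], self.temp_c[order])


@dataclass
class TempRegressionResult:
    gene_id: str
    event_id: str
    organ: str
    season_id: str
    slope: float  # per degree C
    intercept: float
    r_squared: float
    p_value: float
    n: int
    significant_negative: bool


def temp_regression(
    ratio: RatioSeries,
    temps: TemperatureSeries,
    alpha: float = 0.05,
) -> TempRegressionResult:
    """OLS of log-ratio on ambient temperature at the sampling instants."""
    ok = np.isfinite(ratio.clock_time)
    if ok.sum() < 3:
        raise InsufficientDataError(
            f"{ratio.gene_id}/{ratio.event_id}: {int(ok.sum())} matched points (<3)"
        )
    x = temps.at(ratio.clock_time[ok])
    y = ratio.log_ratio[ok]
    res = stats.linregress(x, y)
    return TempRegressionResult(
        gene_id=ratio.gene_id,
        event_id=ratio.event_id,
        organ=ratio.organ,
        season_id=ratio.season_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(ok.sum()),
        significant_negative=bool(res.slope < 0 and res.pvalue < alpha),
    )


# ---------------------------------------------------------------------------
# Dataset-level drivers
# ---------------------------------------------------------------------------

def ratio_table(
    tidy: pd.DataFrame,
    pseudo: Optional[float] = None,
    base: str = "10",
) -> pd.DataFrame:
    """Build log(AS/FS) ratios for every AS isoform in a tidy abundance table.

    ``tidy`` columns: gene_id, isoform_id, organ, season_id, zt, clock_time,
    replicate, norm_abundance.  The pseudo-count defaults to half the smallest
    nonzero abundance in the whole table.
    """
    if pseudo is None:
        pseudo = default_pseudo_count(tidy["norm_abundance"])
    rows = []
    keys = ["gene_id", "organ", "season_id"]
    for (gene_id, organ, season_id), grp in tidy.groupby(keys, sort=True):
        fs = grp[grp["isoform_id"] == "FS"]
        if fs.empty:
            continue
        fs_series = IsoformSeries.from_frame(fs)
        for iso, sub in grp[grp["isoform_id"] != "FS"].groupby("isoform_id", sort=True):
            rs = ratio_series(
                IsoformSeries.from_frame(sub),
                fs_series,
                pseudo=pseudo,
                base=base,
                clock_time=sub["clock_time"].to_numpy() if "clock_time" in sub else None,
            )
            for z, r, c, v in zip(rs.zt, rs.replicate, rs.clock_time, rs.log_ratio):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "event_id": iso,
                        "organ": organ,
                        "season_id": season_id,
                        "zt": z,
                        "replicate": r,
                        "clock_time": c,
                        "log_ratio": v,
                        "pseudo_count": pseudo,
                        "log_base": rs.log_base,
                    }
                )
    return pd.DataFrame(rows)


def regression_table(
    ratios: pd.DataFrame,
    temperature: dict[str, TemperatureSeries],
    alpha: float = 0.05,
    pooling: Sequence[str] = ("gene_id", "event_id", "organ", "season_id"),
) -> pd.DataFrame:
    """Run the temperature regression per pooled group (replicates pooled)."""
    rows = []
    for key, grp in ratios.groupby(list(pooling), sort=True):
        kd = dict(zip(pooling, key))
        rs = RatioSeries(
            gene_id=kd.get("gene_id", "*"),
            event_id=kd.get("event_id", "*"),
            organ=kd.get("organ", "*"),
            season_id=kd.get("season_id", "*"),
            zt=grp["zt"].to_numpy(),
            replicate=grp["replicate"].to_numpy(),
            clock_time=grp["clock_time"].to_numpy(),
            log_ratio=grp["log_ratio"].to_numpy(),
            pseudo_count=float(grp["pseudo_count"].iloc[0]),
            log_base=float(grp["log_base"].iloc[0]),
        )
        season = kd.get("season_id")
        temps = temperature[season] if season in temperature else next(iter(temperature.values()))
        res = temp_regression(rs, temps, alpha=alpha)
        rows.append(
            {
                **kd,
                "slope": res.slope,
                "intercept": res.intercept,
                "r_squared": res.r_squared,
                "p_value": res.p_value,
                "n": res.n,
                "significant_negative": res.significant_negative,
            }
        )
    return pd.DataFrame(rows)


def read_temperature_csv(path) -> dict[str, TemperatureSeries]:
    """Temperature CSV (season_id, clock_time, temp_c) -> one series per season."""
    df = pd.read_csv(path)
    out = {}
    for season, grp in df.groupby("season_id"):
        out[str(season)] = TemperatureSeries(
            season_id=str(season),
            clock_time=grp["clock_time"].to_numpy(),
            temp_c=grp["temp_c"].to_numpy(),
        )
    return out
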