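"""Diel-rhythm trend fitting and group comparisons.

Each isoform's abundance time course (normalized ZT, three biological
replicates per point) is smoothed with LOESS (local-linear, tricube weights);
the maximum of the fitted curve between ZT0 and ZT22 defines the rhythm's
peak.  Standard-error bands come from a seeded bootstrap over replicate
points.  Group comparisons use a paired Student's t-test (FS vs AS within
replicate-timepoint) and one-way ANOVA with post-hoc Tukey HSD across organs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class IsoformSeries:
    """Normalized abundance of one isoform over zeitgeber time."""

    gene_id: str
    isoform_id: str
    organ: str
    season_id: str
    zt: np.ndarray  # one entry per replicate point
    replicate: np.ndarray
    abundance: np.ndarray
    point_id: Optional[np.ndarray] = None  # unique per harvested pool; defaults
    # to (zt, replicate), which is ambiguous when a >24 h course wraps

    def __post_init__(self) -> None:
        self.zt = np.asarray(self.zt, dtype=float)
        self.replicate = np.asarray(self.replicate)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.point_id is not None:
            self.point_id = np.asarray(self.point_id)
        if len(np.unique(self.zt)) < 2:
            raise ValueError("need >=2 distinct zt values")
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IsoformSeries":
        first = df.iloc[0]
        return cls(
            gene_id=first["gene_id"],
            isoform_id=first["isoform_id"],
            organ=first["organ"],
            season_id=first["season_id"],
            zt=df["zt"].to_numpy(),
            replicate=df["replicate"].to_numpy(),
            abundance=df["norm_abundance"].to_numpy(),
            point_id=df["sample_id"].to_numpy() if "sample_id" in df else None,
        )


@dataclass
class LoessFit:
    grid: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    span: float
    peak_zt: float
    peak_value: float


def fit_loess(
    series: IsoformSeries,
    span: float = 0.5,
    grid_step: float = 0.1,
    n_boot: int = 200,
    seed: int = 0,
    peak_window: tuple[float, float] = (0.0, 22.0),
) -> LoessFit:
    """Local-linear LOESS over all replicate points (replicates are fitted as
    individual points, not pre-averaged), evaluated on a fixed ZT grid.

    The span is widened if needed so each local fit sees >=3 points.  SE at
    each grid point is the standard deviation of fits over ``n_boot`` seeded
    bootstrap resamples of the replicate points.
    """
    x, y = series.zt, series.abundance
    if len(np.unique(x)) < 4:
        raise ValueError("need >=4 distinct zt values for a local-linear fit")
    span = max(span, 3.0 / len(x))
    grid = np.arange(0.0, 24.0 + 1e-9, grid_step)

    fitted = _lowess_grid(x, y, grid, span)

    rng = np.random.default_rng(seed)
    if n_boot < 2 or np.allclose(y, y[0]):
        se = np.zeros_like(grid)
    else:
        boots = np.empty((n_boot, len(grid)))
        n = len(x)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boots[b] = _lowess_grid(x[idx], y[idx], grid, span)
        se = np.nanstd(boots, axis=0, ddof=1)

    peak_zt, peak_value = find_peak_on_grid(grid, fitted, peak_window)
    return LoessFit(grid=grid, fitted=fitted, se=se, span=span,
                    peak_zt=peak_zt, peak_value=peak_value)


def _lowess_grid(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    span: float,
    circular: bool = True,
    period: float = 24.0,
) -> np.ndarray:
    """statsmodels lowess evaluated at grid points (no robustifying
    iterations, as required with explicit xvals).

    With ``circular`` (the default) the points are padded one period to each
    side before fitting, so the diel curve has no artificial boundary at ZT0/
    ZT24 — a peak just after midnight is supported by the late-night points.
    The smoothing fraction is rescaled so the local bandwidth in hours is
    unchanged.
    """
    if np.allclose(y, y[0]):
        return np.full_like(grid, float(y[0]))
    if circular:
        xx = np.concatenate([x - period, x, x + period])
        yy = np.concatenate([y, y, y])
        frac = min(1.0, span * len(x) / len(xx))
    else:
        xx, yy, frac = x, y, span
    fit = lowess(yy, xx, frac=frac, it=0, xvals=grid, return_sorted=False)
    fit = np.asarray(fit, dtype=float)
    # lowess leaves NaN outside the data range; hold the boundary value
    if np.any(np.isnan(fit)):
        valid = ~np.isnan(fit)
        if valid.any():
            fit = np.interp(grid, grid[valid], fit[valid])
    return fit


def find_peak(fit: LoessFit, window: tuple[float, float] = (0.0, 22.0)) -> tuple[float, float]:
    """Argmax of the fitted curve over grid points inside ``window``; ties go
    to the earliest ZT."""
    return find_peak_on_grid(fit.grid, fit.fitted, window)


def find_peak_on_grid(
    grid: np.ndarray, fitted: np.ndarray, window: tuple[float, float]
) -> tuple[float, float]:
    lo, hi = window
    mask = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"empty peak window {window}")
    g, f = grid[mask], fitted[mask]
    i = int(np.argmax(f))  # np.argmax returns the first maximum: earliest ZT
    return float(g[i]), float(f[i])


def expression_call(
    fit: LoessFit,
    paired_fs_fit: Optional[LoessFit] = None,
    threshold: float = 0.05,
    floor: float = 0.0,
) -> str:
    """Call an isoform 'expressed' iff its LOESS peak reaches ``floor`` and,
    when a paired fully spliced fit is supplied, at least ``threshold`` times
    the FS peak.  The relative-threshold rule is this package's definition
    (no published criterion exists); see the methods note.
    """
    if threshold > 0 and paired_fs_fit is None:
        raise ValueError("threshold rule requires the paired FS fit")
    if fit.peak_value < floor or fit.peak_value <= 0:
        return "not_expressed"
    if paired_fs_fit is not None and fit.peak_value < threshold * paired_fs_fit.peak_value:
        return "not_expressed"
    return "expressed"


@dataclass
class ComparisonResult:
    design: str
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False
    tukey: Optional[pd.DataFrame] = None


def compare_groups(
    groups: Sequence[np.ndarray],
    design: str = "paired_t",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Paired Student's t-test (two groups) or one-way ANOVA (>=2 groups),
    optionally with post-hoc Tukey HSD ('anova_tukey').  Two-sided p; zero
    variance everywhere is flagged degenerate with p = 1."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if design == "paired_t":
        if len(arrays) != 2 or len(arrays[0]) != len(arrays[1]):
            raise ValueError("paired_t needs two equal-length groups")
        if len(arrays[0]) < 2:
            raise ValueError("paired_t needs n >= 2")
        d = arrays[0] - arrays[1]
        if np.allclose(d, d[0]):
            return ComparisonResult("paired_t", 0.0, 1.0, False, degenerate=True)
        t, p = stats.ttest_rel(arrays[0], arrays[1])
        return ComparisonResult("paired_t", float(t), float(p), bool(p < alpha))

    if design in ("anova", "anova_tukey"):
        if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
            raise ValueError(f"{design} needs >=2 groups with >=2 values each")
        if all(np.allclose(a, arrays[0][0]) for a in arrays):
            return ComparisonResult(design, 0.0, 1.0, False, degenerate=True)
        f, p = stats.f_oneway(*arrays)
        if design == "anova":
            return ComparisonResult("anova", float(f), float(p), bool(p < alpha))
        res = stats.tukey_hsd(*arrays)
        rows = []
        k = len(arrays)
        for i in range(k):
            for j in range(i + 1, k):
                pij = float(res.pvalue[i, j])
                rows.append(
                    {
                        "group_a": i,
                        "group_b": j,
                        "statistic": float(res.statistic[i, j]),
                        "p_value": pij,
                        "significant": bool(pij < alpha),
                    }
                )
        return ComparisonResult(
            "anova_tukey", float(f), float(p), bool(p < alpha), tukey=pd.DataFrame(rows)
        )

    raise ValueError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# Dataset-level driver
# ---------------------------------------------------------------------------

def fit_all_series(
    tidy: pd.DataFrame,
    span: float = 0.5,
    grid_step: float = 0.1,
    n_boot: int = 200,
    seed: int = 0,
    expression_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every (gene, isoform, organ, season) series in a tidy table.

    ``tidy`` columns: gene_id, isoform_id, organ, season_id, zt, replicate,
    norm_abundance.  Returns (per-grid-point fits, per-series summary with
    peak phase/value and expression call).
    """
    keys = ["gene_id", "isoform_id", "organ", "season_id"]
    fits: dict[tuple, LoessFit] = {}
    for key, grp in tidy.groupby(keys, sort=True):
        series = IsoformSeries.from_frame(grp)
        fits[key] = fit_loess(series, span=span, grid_step=grid_step,
                              n_boot=n_boot, seed=seed)

    fit_rows, summary_rows = [], []
    for key, fit in fits.items():
        gene_id, isoform_id, organ, season_id = key
        fs_fit = fits.get((gene_id, "FS", organ, season_id))
        if isoform_id == "FS":
            call = "expressed" if fit.peak_value > 0 else "not_expressed"
        elif fs_fit is not None:
            call = expression_call(fit, fs_fit, threshold=expression_threshold)
        else:
            call = expression_call(fit, None, threshold=0.0)
        summary_rows.append(
            {
                "gene_id": gene_id,
                "isoform_id": isoform_id,
                "organ": organ,
                "season_id": season_id,
                "peak_zt": fit.peak_zt,
                "peak_value": fit.peak_value,
                "expression_call": call,
            }
        )
        for g, f, s in zip(fit.grid, fit.fitted, fit.se):
            fit_rows.append(
                {
                    "gene_id": gene_id,
                    "isoform_id": isoform_id,
                    "organ": organ,
                    "season_id": season_id,
                    "zt": g,
                    "fitted": f,
                    "se": s,
                }
            )
    return pd.DataFrame(fit_rows), pd.DataFrame(summary_rows)
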