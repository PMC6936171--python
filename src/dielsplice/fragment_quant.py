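"""Capillary-electrophoresis fragment quantification.

Re-implements the fragment-analysis step of a high-resolution RT-PCR assay:
ladder-based sizing of peak migrations (piecewise-linear or Local Southern),
assignment of sized peaks to the expected amplicons of each isoform, and
per-sample normalization against reference genes (geometric mean of the
reference amplicon areas, the standard multi-reference rule).

Inputs are peak tables (GeneMapper-export-like CSV: sample, dye, migration,
height, area); raw traces are supported for the synthetic path via a simple
local-maximum peak caller.  Binary .fsa/ABIF parsing is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal
from scipy.stats import gmean


class CalibrationError(ValueError):
    """Ladder peaks are unusable (non-monotone or too few)."""


class PanelError(ValueError):
    """Amplicon panel is ambiguous or malformed."""


@dataclass(frozen=True)
class AmpliconDef:
    """Expected fragment size of one isoform's amplicon."""

    gene_id: str
    isoform_id: str  # "FS" or an event id
    expected_size: float  # bp


@dataclass
class AbundanceRecord:
    sample_id: str
    gene_id: str
    isoform_id: str
    raw_area: float
    norm_abundance: Optional[float] = None
    below_detection: bool = False
    extrapolated: bool = False


# ---------------------------------------------------------------------------
# Sizing
# ---------------------------------------------------------------------------

def size_peaks(
    ladder_peaks: Sequence[tuple[float, float]],
    target_migrations: Sequence[float],
    method: str = "piecewise_linear",
) -> tuple[np.ndarray, np.ndarray]:
    """Convert migration times to fragment sizes using the ladder.

    ``ladder_peaks`` are (migration, known bp) pairs.  Returns (sizes_bp,
    extrapolated_mask); targets outside the ladder span are sized by linear
    extrapolation of the end segments and flagged.

    ``piecewise_linear`` interpolates between flanking ladder points.
    ``local_southern`` fits the classic reciprocal model
    L = c + k / (m - m0) through two overlapping triplets of ladder points
    bracketing the target and averages the two estimates.
    """
    lad = sorted(ladder_peaks)
    if len(lad) < 2:
        raise CalibrationError("need at least 2 ladder peaks")
    mig = np.asarray([m for m, _ in lad], dtype=float)
    bp = np.asarray([b for _, b in lad], dtype=float)
    if np.any(np.diff(mig) <= 0) or np.any(np.diff(bp) <= 0):
        raise CalibrationError("ladder must be strictly increasing in migration and size")

    x = np.asarray(target_migrations, dtype=float)
    extrapolated = (x < mig[0]) | (x > mig[-1])

    if method == "piecewise_linear":
        sizes = np.interp(x, mig, bp)
        # linear extrapolation with the terminal segment slopes
        lo = x < mig[0]
        hi = x > mig[-1]
        if lo.any():
            s = (bp[1] - bp[0]) / (mig[1] - mig[0])
            sizes[lo] = bp[0] + s * (x[lo] - mig[0])
        if hi.any():
            s = (bp[-1] - bp[-2]) / (mig[-1] - mig[-2])
            sizes[hi] = bp[-1] + s * (x[hi] - mig[-1])
        return sizes, extrapolated

    if method == "local_southern":
        if len(lad) < 4:
            raise CalibrationError("local_southern needs at least 4 ladder peaks")
        sizes = np.empty_like(x)
        for i, xi in enumerate(x):
            j = int(np.clip(np.searchsorted(mig, xi), 2, len(mig) - 2))
            est = []
            for trip in (slice(j - 2, j + 1), slice(j - 1, j + 2)):
                est.append(_reciprocal_fit_eval(mig[trip], bp[trip], xi))
            sizes[i] = float(np.mean(est))
        return sizes, extrapolated

    raise ValueError(f"unknown sizing method {method!r}")


def _reciprocal_fit_eval(m: np.ndarray, L: np.ndarray, x: float) -> float:
    """Fit L = c + k/(m - m0) exactly through three points; evaluate at x."""
    m1, m2, m3 = m
    L1, L2, L3 = L
    # L_i - L_j = k (m_j - m_i) / ((m_i - m0)(m_j - m0)); dividing the (1,2)
    # and (2,3) differences gives A (m1 - m0) = B (m3 - m0) with
    A = (L1 - L2) / (m2 - m1)
    B = (L2 - L3) / (m3 - m2)
    m0 = (A * m1 - B * m3) / (A - B) if A != B else np.inf
    offsets = np.array([m1, m2, m3, x]) - m0
    if not np.isfinite(m0) or np.any(offsets == 0) or len(set(np.sign(offsets))) != 1:
        # degenerate (e.g. perfectly linear ladder, or the asymptote falls
        # inside the migration range): fall back to linear interpolation
        return float(np.interp(x, m, L))
    k = A * (m1 - m0) * (m2 - m0)
    c = L1 - k / (m1 - m0)
    return float(c + k / (x - m0))


# ---------------------------------------------------------------------------
# Peak calling on raw traces (synthetic-path plumbing)
# ---------------------------------------------------------------------------

def call_peaks(
    trace: np.ndarray,
    min_rel_height: float = 0.05,
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Find local maxima above ``min_rel_height`` x trace maximum after
    moving-average smoothing; peak area by trapezoid between flanking minima.

    Returns a DataFrame with migration (scan index), height and area.
    """
    y = np.asarray(trace, dtype=float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(y, kernel, mode="same")
    if y.max() <= 0:
        return pd.DataFrame(columns=["migration", "height", "area"])
    peaks, _ = signal.find_peaks(y, height=min_rel_height * y.max())
    rows = []
    for p in peaks:
        lo = p
        while lo > 0 and y[lo - 1] < y[lo]:
            lo -= 1
        hi = p
        while hi < len(y) - 1 and y[hi + 1] < y[hi]:
            hi += 1
        area = float(np.trapezoid(y[lo : hi + 1]))
        rows.append({"migration": float(p), "height": float(y[p]), "area": area})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Assignment and normalization
# ---------------------------------------------------------------------------

def check_panel(defs: Sequence[AmpliconDef], tol: float) -> None:
    """Reject panels with two amplicons closer than 2*tol (ambiguous)."""
    seen = set()
    for d in defs:
        key = (d.gene_id, d.isoform_id)
        if key in seen:
            raise PanelError(f"duplicate amplicon {key}")
        seen.add(key)
    sizes = sorted((d.expected_size, d) for d in defs)
    for (s1, d1), (s2, d2) in zip(sizes, sizes[1:]):
        if s2 - s1 < 2 * tol:
            raise PanelError(
                f"amplicons {d1.gene_id}/{d1.isoform_id} ({s1} bp) and "
                f"{d2.gene_id}/{d2.isoform_id} ({s2} bp) are within 2*tol={2 * tol} bp"
            )


def assign_isoforms(
    sample_id: str,
    sized_peaks: pd.DataFrame,  # columns: size_bp, area[, extrapolated]
    defs: Sequence[AmpliconDef],
    tol: float = 2.0,
) -> tuple[list[AbundanceRecord], pd.DataFrame]:
    """Assign each sized peak to the nearest expected amplicon within ``tol`` bp.

    Returns one record per defined isoform (missing peaks get area 0 with a
    below-detection flag) plus a residue table of unassigned peaks.
    """
    check_panel(defs, tol)
    areas: dict[tuple[str, str], float] = {(d.gene_id, d.isoform_id): 0.0 for d in defs}
    extrap: dict[tuple[str, str], bool] = {k: False for k in areas}
    unassigned = []
    exp = np.array([d.expected_size for d in defs])
    for _, peak in sized_peaks.iterrows():
        dist = np.abs(exp - peak["size_bp"])
        j = int(np.argmin(dist))
        if dist[j] <= tol:
            key = (defs[j].gene_id, defs[j].isoform_id)
            areas[key] += float(peak["area"])
            extrap[key] = extrap[key] or bool(peak.get("extrapolated", False))
        else:
            unassigned.append(dict(peak))
    records = [
        AbundanceRecord(
            sample_id=sample_id,
            gene_id=g,
            isoform_id=i,
            raw_area=areas[(g, i)],
            below_detection=areas[(g, i)] <= 0,
            extrapolated=extrap[(g, i)],
        )
        for g, i in areas
    ]
    return records, pd.DataFrame(unassigned)


def normalize(
    records: list[AbundanceRecord],
    reference_gene_ids: Sequence[str],
) -> tuple[list[AbundanceRecord], list[str]]:
    """Divide each target raw area by the geometric mean of the sample's
    reference-gene areas; reference records are dropped from the output.

    Returns (normalized records, ids of samples excluded because every
    reference amplicon was below detection).
    """
    ref_ids = set(reference_gene_ids)
    by_sample: dict[str, list[AbundanceRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)

    out: list[AbundanceRecord] = []
    excluded: list[str] = []
    for sample_id, recs in by_sample.items():
        ref_areas = [r.raw_area for r in recs if r.gene_id in ref_ids and r.raw_area > 0]
        if not ref_areas:
            excluded.append(sample_id)
            continue
        ref = float(gmean(ref_areas))
        for r in recs:
            if r.gene_id in ref_ids:
                continue
            out.append(
                AbundanceRecord(
                    sample_id=r.sample_id,
                    gene_id=r.gene_id,
                    isoform_id=r.isoform_id,
                    raw_area=r.raw_area,
                    norm_abundance=r.raw_area / ref,
                    below_detection=r.below_detection,
                    extrapolated=r.extrapolated,
                )
            )
    return out, excluded


# ---------------------------------------------------------------------------
# Whole-sample driver + I/O
# ---------------------------------------------------------------------------

def quantify_peak_table(
    peaks: pd.DataFrame,
    defs: Sequence[AmpliconDef],
    reference_gene_ids: Sequence[str],
    tol: float = 2.0,
    sizing_method: str = "piecewise_linear",
    ladder_sizes: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Size, assign and normalize a multi-sample peak table.

    ``peaks`` columns: sample_id, dye ('ladder' or 'target'), migration, area.
    Ladder rows are matched in migration order to ``ladder_sizes`` (known bp of
    the size standard, ascending).  Returns tidy normalized abundances.
    """
    if ladder_sizes is None:
        raise CalibrationError("ladder_sizes (known bp of the size standard) required")
    all_records: list[AbundanceRecord] = []
    for sample_id, grp in peaks.groupby("sample_id", sort=True):
        lad = grp[grp["dye"] == "ladder"].sort_values("migration")
        tgt = grp[grp["dye"] != "ladder"]
        if len(lad) != len(ladder_sizes):
            raise CalibrationError(
                f"{sample_id}: {len(lad)} ladder peaks but {len(ladder_sizes)} known sizes"
            )
        ladder = list(zip(lad["migration"].to_numpy(), ladder_sizes))
        sizes, extrap = size_peaks(ladder, tgt["migration"].to_numpy(), sizing_method)
        sized = tgt.assign(size_bp=sizes, extrapolated=extrap)
        recs, _ = assign_isoforms(str(sample_id), sized, defs, tol=tol)
        all_records.extend(recs)
    normalized, excluded = normalize(all_records, reference_gene_ids)
    df = records_to_frame(normalized)
    df.attrs["excluded_samples"] = excluded
    return df


def records_to_frame(records: list[AbundanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "gene_id": r.gene_id,
                "isoform_id": r.isoform_id,
                "raw_area": r.raw_area,
                "norm_abundance": r.norm_abundance,
                "below_detection": r.below_detection,
                "extrapolated": r.extrapolated,
            }
            for r in records
        ]
    )


def read_peak_table(path, column_map: Optional[dict[str, str]] = None) -> pd.DataFrame:
    """Read a peak-table CSV; ``column_map`` renames export dialects onto the
    canonical sample_id/dye/migration/height/area columns."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"sample_id", "dye", "migration", "area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df


def read_panel(path) -> tuple[list[AmpliconDef], list[str], list[float]]:
    """Amplicon panel YAML -> (amplicon defs, reference gene ids, ladder sizes)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    defs = [
        AmpliconDef(a["gene_id"], a["isoform_id"], float(a["expected_size"]))
        for a in doc["amplicons"]
    ]
    return defs, list(doc.get("reference_genes", [])), [float(x) for x in doc.get("ladder_sizes", [])]


def write_panel(path, defs: Sequence[AmpliconDef], reference_genes: Sequence[str],
                ladder_sizes: Sequence[float]) -> None:
    doc = {
        "amplicons": [
            {"gene_id": d.gene_id, "isoform_id": d.isoform_id, "expected_size": d.expected_size}
            for d in defs
        ],
        "reference_genes": list(reference_genes),
        "ladder_sizes": [float(x) for x in ladder_sizes],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
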