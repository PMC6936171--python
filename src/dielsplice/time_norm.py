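"""Zeitgeber-time normalization of field sampling times.

Field harvests run under seasonal photoperiods; to compare rhythms across
seasons, clock times are mapped onto a reference 12 h day / 12 h night scale:
ZT0 = dawn and ZT12 = dusk in every season.  With T the time since dawn,
P_d the day length and P_n the night length (hours),

    day   (0 <= T < P_d):   ZT = 12 * T / P_d
    night (P_d <= T < 24):  ZT = 12 + 12 * (T - P_d) / P_n

Both branches agree at dusk (ZT12) and wrap at 24 h.  Sampling courses longer
than 24 h wrap into [0, 24) with the cycle recorded in ``day_index``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import yaml

ORGANS = ("L1", "I1", "I5")  # leaf +1, internodes 1-2, internode 5


def parse_hours(value) -> float:
    """Parse 'HH:MM' or decimal hours into decimal hours."""
    if isinstance(value, str) and ":" in value:
        hh, mm = value.split(":")
        return int(hh) + int(mm) / 60.0
    return float(value)


@dataclass(frozen=True)
class Photoperiod:
    """Dawn/dusk times (decimal hours since midnight) for one season."""

    season_id: str
    dawn: float
    dusk: float

    def __post_init__(self) -> None:
        if not (0 <= self.dawn < self.dusk < 24):
            raise ValueError(
                f"{self.season_id}: need 0 <= dawn < dusk < 24, "
                f"got dawn={self.dawn}, dusk={self.dusk}"
            )

    @property
    def day_length(self) -> float:
        return self.dusk - self.dawn

    @property
    def night_length(self) -> float:
        return 24.0 - self.day_length


def photoperiod_from_times(season_id: str, dawn, dusk) -> Photoperiod:
    """Build a photoperiod from 'HH:MM' strings or decimal hours."""
    return Photoperiod(season_id, parse_hours(dawn), parse_hours(dusk))


def zt_normalize(T: float, pp: Photoperiod) -> tuple[float, int]:
    """Map hours-since-dawn ``T`` to (zt in [0, 24), day_index).

    ``T`` may exceed 24 (long courses) or be negative (pre-dawn points of the
    first cycle map to the night branch of the previous cycle, day_index -1).
    """
    day_index = int(T // 24)
    t = T - 24.0 * day_index
    if t < pp.day_length:
        zt = 12.0 * t / pp.day_length
    else:
        zt = 12.0 + 12.0 * (t - pp.day_length) / pp.night_length
    return zt, day_index


def zt_denormalize(zt: float, pp: Photoperiod, day_index: int = 0) -> float:
    """Inverse of :func:`zt_normalize` (returns hours since dawn)."""
    if zt < 12.0:
        t = zt * pp.day_length / 12.0
    else:
        t = pp.day_length + (zt - 12.0) * pp.night_length / 12.0
    return t + 24.0 * day_index


def round_zt(zt: float) -> int:
    """Integer ZT label, round-half-up, wrapped into [0, 24)."""
    import math

    return int(math.floor(zt + 0.5)) % 24


def build_schedule(
    pp: Photoperiod,
    start_offset: float = 2.0,
    interval: float = 2.0,
    duration: float = 26.0,
) -> pd.DataFrame:
    """Sampling-time skeleton: points every ``interval`` h for ``duration`` h,
    starting ``start_offset`` h before dawn (endpoint included).

    Returns a DataFrame with clock_time (may exceed 24), T (hours since dawn),
    zt and day_index columns.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if duration < interval:
        raise ValueError("duration must cover at least one interval")
    n = int(duration / interval) + 1
    rows = []
    for i in range(n):
        T = -start_offset + i * interval
        clock = pp.dawn + T
        zt, day_index = zt_normalize(T, pp)
        rows.append(
            {
                "time_index": i,
                "clock_time": clock,
                "T": T,
                "zt": zt,
                "day_index": day_index,
            }
        )
    return pd.DataFrame(rows)


def annotate_samples(
    metadata: pd.DataFrame, photoperiods: dict[str, Photoperiod]
) -> pd.DataFrame:
    """Add T, zt and day_index columns to a sample-metadata table.

    ``metadata`` needs season_id and clock_time columns; clock_time is decimal
    hours since midnight of the first sampling day and may exceed 24.
    """
    out = metadata.copy()
    T, zt, day = [], [], []
    for _, row in out.iterrows():
        pp = photoperiods[row["season_id"]]
        t = float(row["clock_time"]) - pp.dawn
        z, d = zt_normalize(t, pp)
        T.append(t)
        zt.append(z)
        day.append(d)
    out["T"] = T
    out["zt"] = zt
    out["day_index"] = day
    return out


def read_season_config(path) -> dict[str, Photoperiod]:
    """Season YAML: list of {season_id, dawn, dusk} mappings."""
    with open(path) as fh:
        docs = yaml.safe_load(fh)
    return {
        d["season_id"]: photoperiod_from_times(d["season_id"], d["dawn"], d["dusk"])
        for d in docs
    }


def write_season_config(path, photoperiods: dict[str, Photoperiod]) -> None:
    docs = [
        {"season_id": pp.season_id, "dawn": pp.dawn, "dusk": pp.dusk}
        for pp in photoperiods.values()
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(docs, fh, sort_keys=False)
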