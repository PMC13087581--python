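"""Reading and writing plate-reader tables.

The pipeline consumes two long-format CSV files:

* a time-series table with columns ``well,time_h,value`` — one row per
  measurement of one well, times in hours, values in the instrument's
  signal units (RNU for nephelometry, OD600 for spectrophotometry);
* a plate-layout table with columns
  ``well,construct,medium,bio_replicate,tech_replicate,role`` mapping each
  well to its experimental role.

Well addresses are normalised to the unpadded convention ("A1", not
"A01"); both forms are accepted on input.  Times are rebased so that the
earliest measurement in a file is at 0 h: every downstream computation
depends only on elapsed time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LayoutEntry",
    "PlateLayout",
    "WellTimeseries",
    "normalize_well_id",
    "read_timeseries",
    "read_layout",
    "write_results",
]

SIGNAL_KINDS = ("RNU", "OD600")
ROLES = ("sample", "blank")

_WELL_RE = re.compile(r"^([A-Za-z])0*([1-9][0-9]*)$")


def normalize_well_id(well: str) -> str:
    """Return the canonical unpadded form of a well address ("A01" -> "A1")."""
    m = _WELL_RE.match(str(well).strip())
    if m is None:
        raise ValueError(f"not a well address: {well!r}")
    return m.group(1).upper() + m.group(2)


@dataclass(frozen=True)
class LayoutEntry:
    """One well's experimental annotation."""

    well_id: str
    construct: Optional[str]
    medium: str
    bio_replicate: Optional[int]
    tech_replicate: Optional[int]
    role: str = "sample"

    def __post_init__(self) -> None:
        object.__setattr__(self, "well_id", normalize_well_id(self.well_id))
        if self.role not in ROLES:
            raise ValueError(
                f"unknown role {self.role!r} for well {self.well_id}; "
                f"expected one of {ROLES}"
            )
        if not self.medium:
            raise ValueError(f"well {self.well_id}: medium label is required")
        if self.role == "sample":
            if not self.construct:
                raise ValueError(f"sample well {self.well_id}: construct label is required")
            if self.bio_replicate is None or self.bio_replicate < 1:
                raise ValueError(f"sample well {self.well_id}: bio_replicate must be >= 1")
            if self.tech_replicate is None or self.tech_replicate < 1:
                raise ValueError(f"sample well {self.well_id}: tech_replicate must be >= 1")


@dataclass
class PlateLayout:
    """Mapping from wells to construct / medium / replicate / role."""

    entries: list[LayoutEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.well_id in seen:
                raise ValueError(f"duplicate well {e.well_id} in layout")
            seen.add(e.well_id)

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, well_id: str) -> LayoutEntry:
        wid = normalize_well_id(well_id)
        for e in self.entries:
            if e.well_id == wid:
                return e
        raise KeyError(f"well {wid} not in layout")

    @property
    def sample_entries(self) -> list[LayoutEntry]:
        return [e for e in self.entries if e.role == "sample"]

    def blank_wells(self, medium: str) -> list[str]:
        return [e.well_id for e in self.entries if e.role == "blank" and e.medium == medium]

    def wells_of(self, construct: str, medium: Optional[str] = None) -> list[str]:
        return [
            e.well_id
            for e in self.sample_entries
            if e.construct == construct and (medium is None or e.medium == medium)
        ]

    def groups(self) -> list[tuple[str, str, int]]:
        """Distinct sample (construct, medium, bio_replicate) groups, in layout order."""
        out: list[tuple[str, str, int]] = []
        for e in self.sample_entries:
            key = (e.construct, e.medium, e.bio_replicate)
            if key not in out:
                out.append(key)
        return out


@dataclass
class WellTimeseries:
    """Raw signal trace of a single well.

    ``times`` are elapsed hours from the run's first measurement and must be
    strictly increasing; a trace must hold at least 5 points (the smallest
    window the smoothing stage accepts).
    """

    well_id: str
    times: np.ndarray
    values: np.ndarray
    signal_kind: str = "RNU"

    def __post_init__(self) -> None:
        self.well_id = normalize_well_id(self.well_id)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}, got {self.signal_kind!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError(f"well {self.well_id}: times and values must be 1-d and equal length")
        if len(self.times) < 5:
            raise ValueError(f"well {self.well_id}: needs >= 5 points, got {len(self.times)}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"well {self.well_id}: times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def read_timeseries(path: str | Path, signal_kind: str = "RNU") -> list[WellTimeseries]:
    """Read a long-format plate time-series CSV into per-well traces.

    Rows are grouped by well and sorted by time; times are rebased so the
    earliest measurement in the file is 0 h.  Duplicate (well, time) rows,
    negative times and wells with fewer than 5 points are errors.
    """
    df = pd.read_csv(path)
    required = {"well", "time_h", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.copy()
    df["well"] = df["well"].map(normalize_well_id)
    df["time_h"] = pd.to_numeric(df["time_h"])
    df["value"] = pd.to_numeric(df["value"])
    if (df["time_h"] < 0).any():
        bad = df.loc[df["time_h"] < 0].iloc[0]
        raise ValueError(f"{path}: negative time {bad['time_h']} in well {bad['well']}")
    dup = df.duplicated(subset=["well", "time_h"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate measurement for well {bad['well']} at t={bad['time_h']} h"
        )
    t0 = df["time_h"].min()
    traces = []
    for well, sub in df.groupby("well", sort=True):
        sub = sub.sort_values("time_h")
        if len(sub) < 5:
            raise ValueError(f"{path}: well {well} has only {len(sub)} points (minimum 5)")
        traces.append(
            WellTimeseries(
                well_id=well,
                times=sub["time_h"].to_numpy() - t0,
                values=sub["value"].to_numpy(),
                signal_kind=signal_kind,
            )
        )
    return traces


def _opt_str(x) -> Optional[str]:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    s = str(x).strip()
    return s or None


def _opt_int(x) -> Optional[int]:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    s = str(x).strip()
    if not s:
        return None
    return int(float(s))


def read_layout(path: str | Path) -> PlateLayout:
    """Read a plate-layout CSV; role defaults to "sample" when empty."""
    df = pd.read_csv(path, dtype=str)
    required = {"well", "construct", "medium", "bio_replicate", "tech_replicate", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        role = _opt_str(row["role"]) or "sample"
        entries.append(
            LayoutEntry(
                well_id=row["well"],
                construct=_opt_str(row["construct"]),
                medium=_opt_str(row["medium"]) or "",
                bio_replicate=_opt_int(row["bio_replicate"]),
                tech_replicate=_opt_int(row["tech_replicate"]),
                role=role,
            )
        )
    return PlateLayout(entries=entries)


METRICS_COLUMNS = [
    "curve_id",
    "construct",
    "medium",
    "bio_replicate",
    "K",
    "N0",
    "r",
    "max_slope_time_h",
    "lag_time_h",
    "max_growth_rate",
    "sse",
    "converged",
    "stages",
]

COMPARISONS_COLUMNS = [
    "metric",
    "group_a",
    "group_b",
    "n_a",
    "n_b",
    "U",
    "p_value",
    "method",
]


def write_results(metrics: Sequence, comparisons: Iterable, path: str | Path) -> dict[str, Path]:
    """Write per-curve metrics and group comparisons as CSV files.

    Produces ``metrics.csv`` and ``comparisons.csv`` under ``path`` with a
    stable column order (see METRICS_COLUMNS / COMPARISONS_COLUMNS); numeric
    fields are written with 12 significant digits so a reread reproduces them.
    """
    metrics = list(metrics)
    if not metrics:
        raise ValueError("write_results: metrics list is empty")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)

    mrows = []
    for m in metrics:
        fit = m.fit
        cid = m.curve_id
        mrows.append(
            {
                "curve_id": str(cid),
                "construct": cid.construct,
                "medium": cid.medium,
                "bio_replicate": cid.bio_replicate,
                "K": fit.K,
                "N0": fit.N0,
                "r": fit.r,
                "max_slope_time_h": m.max_slope_time,
                "lag_time_h": m.lag_time,
                "max_growth_rate": m.max_growth_rate,
                "sse": fit.sse,
                "converged": fit.converged,
                "stages": "|".join(m.stages) if m.stages else "",
            }
        )
    metrics_path = outdir / "metrics.csv"
    pd.DataFrame(mrows, columns=METRICS_COLUMNS).to_csv(
        metrics_path, index=False, float_format="%.12g"
    )

    crows = []
    for c in comparisons:
        crows.append(
            {
                "metric": c.metric,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "U": c.U,
                "p_value": c.p_value,
                "method": c.method,
            }
        )
    comparisons_path = outdir / "comparisons.csv"
    pd.DataFrame(crows, columns=COMPARISONS_COLUMNS).to_csv(
        comparisons_path, index=False, float_format="%.12g"
    )
    return {"metrics": metrics_path, "comparisons": comparisons_path}
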