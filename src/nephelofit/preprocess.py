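"""Correction and preprocessing chain for plate-reader growth curves.

The chain applied to each technical-replicate trace, in order:

1. blank correction — subtract the per-time mean of the non-inoculated
   blank wells of the same growth medium;
2. negative-control normalisation — for curves grown on the test medium
   only, subtract the per-time mean background growth of the empty-vector
   negative-control strain;
3. pre-minimum clamping — find the curve's global minimum and set every
   earlier value to it;
4. initial-value rebasing — shift additively so the value at time zero is
   exactly 1 unit;
5. Savitzky–Golay smoothing — order 2, window covering 10% of the samples
   (smallest odd integer >= max(5, round(0.1 n)));

after which the technical replicates of each biological replicate are
averaged pointwise into one analysis-ready :class:`GrowthCurve`.

Negative values arising from the subtractions are retained: the clamp and
rebase steps subsume their handling, and clipping would bias the baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .plate_io import PlateLayout, WellTimeseries

__all__ = [
    "CurveId",
    "GrowthCurve",
    "STAGES",
    "blank_correct",
    "control_normalize",
    "clamp_pre_minimum",
    "rebase_initial",
    "savgol_window",
    "savgol_smooth",
    "average_replicates",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)

STAGES = (
    "blank_corrected",
    "control_normalized",
    "clamped",
    "rebased",
    "smoothed",
    "averaged",
)

#: fractional tolerance on time-step jitter before grids are declared unequal
GRID_RTOL = 0.10


@dataclass(frozen=True)
class CurveId:
    """Identity of one analysis-ready curve: (construct, medium, bio replicate).

    ``tech_replicate`` is set only when technical replicates are kept as
    separate curves instead of being averaged.
    """

    construct: str
    medium: str
    bio_replicate: int
    tech_replicate: Optional[int] = None

    def __str__(self) -> str:
        s = f"{self.construct}:{self.medium}:b{self.bio_replicate}"
        if self.tech_replicate is not None:
            s += f":t{self.tech_replicate}"
        return s


@dataclass
class GrowthCurve:
    """A preprocessed trace for one biological replicate."""

    curve_id: CurveId
    times: np.ndarray
    values: np.ndarray
    stages: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError(f"stage applied twice: {self.stages}")

    def __len__(self) -> int:
        return len(self.times)


def _check_same_grid(times_a: np.ndarray, times_b: np.ndarray, what: str) -> None:
    """Grids must agree pointwise to within half a sampling interval."""
    if len(times_a) != len(times_b):
        raise ValueError(f"{what}: time grids differ in length ({len(times_a)} vs {len(times_b)})")
    dt = float(np.median(np.diff(times_a)))
    if np.any(np.abs(times_a - times_b) > 0.5 * dt):
        raise ValueError(f"{what}: time grids differ by more than half a sampling interval")


def blank_correct(trace: WellTimeseries, blanks: Sequence[WellTimeseries]) -> WellTimeseries:
    """Subtract the per-time mean of the blank wells from a trace.

    Blanks must share the trace's medium (the caller's responsibility) and
    its time grid to within half a sampling interval.  Negative results are
    retained.
    """
    if not blanks:
        raise ValueError(f"well {trace.well_id}: no blank wells for its medium")
    for b in blanks:
        _check_same_grid(trace.times, b.times, f"blank {b.well_id} vs well {trace.well_id}")
    blank_mean = np.mean([b.values for b in blanks], axis=0)
    return WellTimeseries(
        well_id=trace.well_id,
        times=trace.times,
        values=trace.values - blank_mean,
        signal_kind=trace.signal_kind,
    )


def control_normalize(
    trace: WellTimeseries,
    controls: Sequence[WellTimeseries],
    *,
    medium: Optional[str] = None,
    test_medium: str = "citrulline",
) -> WellTimeseries:
    """Subtract the mean background growth of the negative-control strain.

    Applies only to curves grown on the test medium; called on any other
    medium the operation is a warning no-op (background growth on control
    media is informative, not a nuisance signal).
    """
    if medium is not None and medium != test_medium:
        warnings.warn(
            f"control_normalize: well {trace.well_id} is on medium {medium!r}, "
            f"not the test medium {test_medium!r}; trace left unchanged",
            stacklevel=2,
        )
        return trace
    if not controls:
        raise ValueError(f"well {trace.well_id}: empty negative-control set")
    for c in controls:
        _check_same_grid(trace.times, c.times, f"control {c.well_id} vs well {trace.well_id}")
    ctrl_mean = np.mean([c.values for c in controls], axis=0)
    return WellTimeseries(
        well_id=trace.well_id,
        times=trace.times,
        values=trace.values - ctrl_mean,
        signal_kind=trace.signal_kind,
    )


def clamp_pre_minimum(values: Sequence[float]) -> np.ndarray:
    """Set every value before the first occurrence of the global minimum to it."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sequence")
    i_min = int(np.argmin(v))  # argmin returns the first occurrence
    out = v.copy()
    out[:i_min] = v[i_min]
    return out


def rebase_initial(values: Sequence[float]) -> np.ndarray:
    """Shift additively so the initial value is exactly 1 unit.

    An additive shift preserves all pairwise differences (and hence the
    empirical maximum-slope time); a multiplicative rescale would distort
    blank-corrected values near zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sequence")
    return v - v[0] + 1.0


def savgol_window(n: int) -> int:
    """Smoothing window: smallest odd integer >= max(5, round(0.1 n))."""
    w = max(5, int(np.floor(0.1 * n + 0.5)))  # round half up
    if w % 2 == 0:
        w += 1
    return w


def savgol_smooth(values: Sequence[float], times: Sequence[float]) -> np.ndarray:
    """Savitzky–Golay smoothing, order 2, window covering 10% of the samples.

    Requires a near-uniform time grid (steps within 10% of the median step)
    and at least 5 points.  Terminal points are handled by evaluating the
    local polynomial fitted within the one-sided end windows, so no data is
    fabricated beyond the measured range.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    n = v.size
    if n < 5:
        raise ValueError(f"savgol_smooth needs >= 5 points, got {n}")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if np.any(steps <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(np.abs(steps - dt) > GRID_RTOL * dt):
        raise ValueError("time grid deviates more than 10% from its median step")
    return savgol_filter(v, window_length=savgol_window(n), polyorder=2, mode="interp")


def average_replicates(curves: Sequence[GrowthCurve]) -> GrowthCurve:
    """Pointwise mean of technical replicates sharing one biological identity."""
    if not curves:
        raise ValueError("no curves to average")
    first = curves[0]
    key = (first.curve_id.construct, first.curve_id.medium, first.curve_id.bio_replicate)
    for c in curves[1:]:
        if (c.curve_id.construct, c.curve_id.medium, c.curve_id.bio_replicate) != key:
            raise ValueError(
                f"cannot average across biological identities: {c.curve_id} vs {first.curve_id}"
            )
        _check_same_grid(first.times, c.times, f"replicate {c.curve_id}")
    mean = np.mean([c.values for c in curves], axis=0)
    stages = first.stages
    if "averaged" not in stages:
        stages = stages + ("averaged",)
    return GrowthCurve(
        curve_id=CurveId(*key),
        times=first.times.copy(),
        values=mean,
        stages=stages,
    )


def preprocess_pipeline(
    traces: Sequence[WellTimeseries],
    layout: PlateLayout,
    *,
    test_medium: str = "citrulline",
    control_construct: Optional[str] = "ccdB",
    average: bool = True,
) -> list[GrowthCurve]:
    """Run the full correction chain on every sample well of a plate.

    Per technical replicate: blank correction, then (test-medium curves
    only, when a negative-control construct is named) control
    normalisation, then clamp, rebase and smoothing; finally the technical
    replicates of each (construct, medium, bio_replicate) group are
    averaged.  With ``average=False`` each technical replicate is returned
    as its own curve (used when technical replicates are the statistical
    unit).

    Returns one :class:`GrowthCurve` per sample group, in layout order.
    """
    by_well = {tr.well_id: tr for tr in traces}
    missing = [e.well_id for e in layout.sample_entries if e.well_id not in by_well]
    if missing:
        raise ValueError(f"layout sample wells missing from time series: {missing}")

    media = {e.medium for e in layout.sample_entries}
    blanks_by_medium = {
        m: [by_well[w] for w in layout.blank_wells(m) if w in by_well] for m in media
    }

    def _corrected(entry) -> WellTimeseries:
        tr = by_well[entry.well_id]
        blanks = blanks_by_medium.get(entry.medium, [])
        if not blanks:
            raise ValueError(f"well {entry.well_id}: no blank wells for medium {entry.medium!r}")
        return blank_correct(tr, blanks)

    # negative-control background on the test medium, blank-corrected
    control_traces: list[WellTimeseries] = []
    if control_construct is not None:
        control_traces = [
            _corrected(e)
            for e in layout.sample_entries
            if e.construct == control_construct and e.medium == test_medium
        ]

    per_group: dict[tuple[str, str, int], list[GrowthCurve]] = {}
    for entry in layout.sample_entries:
        try:
            tr = _corrected(entry)
            stages = ["blank_corrected"]
            if (
                control_construct is not None
                and entry.medium == test_medium
                and entry.construct != control_construct
            ):
                if not control_traces:
                    raise ValueError(
                        f"no {control_construct!r} negative-control wells on medium "
                        f"{test_medium!r} for normalization"
                    )
                tr = control_normalize(
                    tr, control_traces, medium=entry.medium, test_medium=test_medium
                )
                stages.append("control_normalized")
            v = clamp_pre_minimum(tr.values)
            stages.append("clamped")
            v = rebase_initial(v)
            stages.append("rebased")
            v = savgol_smooth(v, tr.times)
            stages.append("smoothed")
        except ValueError as err:
            raise ValueError(f"well {entry.well_id}: {err}") from err
        curve = GrowthCurve(
            curve_id=CurveId(
                entry.construct, entry.medium, entry.bio_replicate, entry.tech_replicate
            ),
            times=tr.times,
            values=v,
            stages=tuple(stages),
        )
        key = (entry.construct, entry.medium, entry.bio_replicate)
        per_group.setdefault(key, []).append(curve)
        logger.debug("preprocessed well %s (%s): %s", entry.well_id, curve.curve_id, stages)

    out: list[GrowthCurve] = []
    for key, curves in per_group.items():
        if average:
            out.append(average_replicates(curves))
        else:
            out.extend(curves)
    return out
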