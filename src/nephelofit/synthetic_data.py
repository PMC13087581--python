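"""Synthetic plate-reader datasets with exported ground truth.

The simulator emulates the structure of a liquid yeast complementation
assay read by nephelometry or spectrophotometry:

* each construct group grows logistically with carrying capacity K,
  rate r, and an initial population N0 chosen from the closed form
  N0 = K / (1 + exp(r * mu)) so that the group's true maximum-slope time
  equals the requested mu;
* biological replicates vary through a lognormal random effect on r
  (coefficient of variation ``r_bio_cv``); technical replicates of one
  biological replicate share the same realised rate and differ only in
  measurement noise;
* blank wells carry the medium baseline plus noise; a weakly growing
  empty-vector control group provides the background that the analysis
  subtracts from test-medium curves.  That basal growth is a property of
  the host strain, so it is also added to every transporter-group well
  (at the control group's nominal kinetics): the normalisation step then
  removes exactly the component the assay design says it removes;
* in nephelometric mode an optional multiplicative peak artifact mimics
  the signal amplification by multiple scattering in dense cultures: the
  signal is scaled by 1 + a * (N/K) * exp(-decay * max(0, t - t_onset)),
  where t_onset is the first time the density reaches ``onset_fraction``
  of K.  The factor grows with density during the exponential phase and
  relaxes exponentially after onset, producing the characteristic
  peak -> decline -> plateau shape;
* measurement noise is zero-mean Gaussian with standard deviation
  ``noise_sd * K`` of the well's group (blanks use the largest group K as
  the shared instrument scale).

Nephelometric mode samples every 10 minutes over 180 h (RNU); the
spectrophotometric mode emulates manual twice-daily OD600 readings
(12 h cadence, noisier, no peak artifact).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .plate_io import LayoutEntry, PlateLayout, WellTimeseries

__all__ = [
    "GroupSpec",
    "PeakArtifact",
    "SimulationConfig",
    "GroundTruth",
    "true_n0",
    "simulate_well",
    "simulate_plate",
    "write_simulation",
]

PLATE_WELLS = tuple(f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13))

#: sentinel meaning "build the default empty-vector background group";
#: pass ``None`` explicitly to simulate a plate without control wells
DEFAULT_CONTROL = "default"


@dataclass(frozen=True)
class GroupSpec:
    """Ground-truth kinetics of one construct group."""

    construct: str
    K: float
    r: float
    max_slope_time: float
    n_bio: int = 3
    n_tech: int = 3

    def __post_init__(self) -> None:
        if self.K <= 0 or self.r <= 0 or self.max_slope_time <= 0:
            raise ValueError(f"group {self.construct}: K, r and max_slope_time must be positive")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError(f"group {self.construct}: replicate counts must be >= 1")


@dataclass(frozen=True)
class PeakArtifact:
    """Multiplicative nephelometric amplification with exponential relaxation."""

    enabled: bool = True
    amplitude: float = 0.3
    onset_fraction: float = 0.8
    decay_per_h: float = 0.05

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.decay_per_h < 0 or not (0 < self.onset_fraction <= 1):
            raise ValueError("invalid peak-artifact parameters")


@dataclass
class SimulationConfig:
    """Full description of one simulated plate run.

    Mode-dependent defaults: nephelometric runs sample every 10 minutes
    (1/6 h) with noise_sd 0.02 and the peak artifact enabled;
    spectrophotometric runs sample every 12 h with noise_sd 0.04 and no
    artifact.
    """

    groups: list[GroupSpec]
    mode: str = "nephelometric"
    duration_h: float = 180.0
    sampling_interval_h: Optional[float] = None
    control_background: Optional[GroupSpec | str] = DEFAULT_CONTROL
    medium: str = "citrulline"
    blank_level: float = 5.0
    noise_sd: Optional[float] = None
    peak_artifact: Optional[PeakArtifact] = None
    blank_drift_per_h: float = 0.0
    r_bio_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("nephelometric", "spectrophotometric"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        nephelometric = self.mode == "nephelometric"
        if self.sampling_interval_h is None:
            self.sampling_interval_h = 1.0 / 6.0 if nephelometric else 12.0
        if self.sampling_interval_h <= 0:
            raise ValueError("sampling_interval_h must be positive")
        if self.noise_sd is None:
            self.noise_sd = 0.02 if nephelometric else 0.04
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.peak_artifact is None:
            self.peak_artifact = PeakArtifact(enabled=nephelometric)
        if isinstance(self.control_background, str):
            if self.control_background != DEFAULT_CONTROL:
                raise ValueError(f"invalid control_background {self.control_background!r}")
            # weak empty-vector background growth, ~3% of a typical sample K
            ref_k = max(g.K for g in self.groups) if self.groups else 1000.0
            self.control_background = GroupSpec(
                "ccdB", K=0.03 * ref_k, r=0.05, max_slope_time=60.0
            )
        if self.r_bio_cv < 0:
            raise ValueError("r_bio_cv must be >= 0")

    @property
    def signal_kind(self) -> str:
        return "RNU" if self.mode == "nephelometric" else "OD600"

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h + 1e-9, self.sampling_interval_h)

    @property
    def all_groups(self) -> list[GroupSpec]:
        gs = list(self.groups)
        if self.control_background is not None:
            gs.append(self.control_background)
        return gs

    @property
    def reference_k(self) -> float:
        return max(g.K for g in self.all_groups)


@dataclass
class GroundTruth:
    """Per-well true parameters of a simulated plate."""

    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "well", "construct", "medium", "bio_replicate", "tech_replicate",
            "K", "N0", "r", "max_slope_time",
        ]
        return pd.DataFrame(self.records, columns=cols)

    def group_max_slope_time(self, construct: str, bio_replicate: Optional[int] = None) -> float:
        """Mean true maximum-slope time over a construct's (bio) replicates."""
        vals = [
            rec["max_slope_time"]
            for rec in self.records
            if rec["construct"] == construct
            and (bio_replicate is None or rec["bio_replicate"] == bio_replicate)
        ]
        if not vals:
            raise KeyError(f"no ground truth for construct {construct!r}")
        return float(np.mean(vals))


def true_n0(K: float, r: float, max_slope_time: float) -> float:
    """Initial population giving a logistic inflection at ``max_slope_time``.

    Inverts mu = ln((K - N0)/N0) / r, giving N0 = K / (1 + exp(r mu)).
    """
    return K / (1.0 + np.exp(r * max_slope_time))


def _logistic(K: float, N0: float, r: float, t: np.ndarray) -> np.ndarray:
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def simulate_well(
    config: SimulationConfig,
    group: GroupSpec,
    bio: int,
    tech: int,
    rng: np.random.Generator,
    *,
    well_id: str = "A1",
    r_realized: Optional[float] = None,
) -> WellTimeseries:
    """Simulate one sample well of a group.

    ``r_realized`` carries the biological replicate's rate (drawn once per
    (group, bio) in :func:`simulate_plate` so technical replicates share
    it); when omitted, a fresh lognormal perturbation of the group rate is
    drawn from ``rng``.
    """
    if group not in config.all_groups:
        raise ValueError(f"group {group.construct!r} not part of the configuration")
    t = config.times
    if r_realized is None:
        r_realized = group.r * float(np.exp(rng.normal(0.0, config.r_bio_cv)))
    n0 = true_n0(group.K, group.r, group.max_slope_time)
    n = _logistic(group.K, n0, r_realized, t)

    signal = n
    art = config.peak_artifact
    if art.enabled and art.amplitude > 0:
        above = np.nonzero(n >= art.onset_fraction * group.K)[0]
        t_onset = t[above[0]] if above.size else np.inf
        relax = np.exp(-art.decay_per_h * np.maximum(0.0, t - t_onset))
        signal = n * (1.0 + art.amplitude * (n / group.K) * relax)

    # host-strain basal growth, present in every inoculated well; the
    # negative-control wells ARE this component, so they do not get it twice
    ctrl = config.control_background
    if ctrl is not None and group.construct != ctrl.construct:
        n0_c = true_n0(ctrl.K, ctrl.r, ctrl.max_slope_time)
        signal = signal + _logistic(ctrl.K, n0_c, ctrl.r, t)

    baseline = config.blank_level + config.blank_drift_per_h * t
    values = baseline + signal
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd * group.K, size=t.shape)
    return WellTimeseries(well_id=well_id, times=t, values=values, signal_kind=config.signal_kind)


def simulate_plate(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[list[WellTimeseries], PlateLayout, GroundTruth]:
    """Simulate a full plate: sample wells, control wells and triplicate blanks.

    Well positions are shuffled deterministically from the seed, mirroring
    runs in which sample positions vary between plates.  Identical config
    and seed give a bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    groups = config.all_groups
    n_blanks = 3
    n_samples = sum(g.n_bio * g.n_tech for g in groups)
    if n_samples + n_blanks > len(PLATE_WELLS):
        raise ValueError(
            f"{n_samples} sample wells + {n_blanks} blanks exceed the 96-well plate"
        )
    wells = list(rng.permutation(PLATE_WELLS)[: n_samples + n_blanks])

    # per-(group, bio) rate effects drawn first so tech replicates share them
    r_eff: dict[tuple[str, int], float] = {}
    for g in groups:
        for bio in range(1, g.n_bio + 1):
            r_eff[(g.construct, bio)] = g.r * float(np.exp(rng.normal(0.0, config.r_bio_cv)))

    traces: list[WellTimeseries] = []
    entries: list[LayoutEntry] = []
    truth = GroundTruth()
    i_well = 0
    for g in groups:
        n0 = true_n0(g.K, g.r, g.max_slope_time)
        for bio in range(1, g.n_bio + 1):
            r_b = r_eff[(g.construct, bio)]
            for tech in range(1, g.n_tech + 1):
                wid = wells[i_well]
                i_well += 1
                traces.append(
                    simulate_well(config, g, bio, tech, rng, well_id=wid, r_realized=r_b)
                )
                entries.append(
                    LayoutEntry(
                        well_id=wid, construct=g.construct, medium=config.medium,
                        bio_replicate=bio, tech_replicate=tech, role="sample",
                    )
                )
                truth.records.append(
                    {
                        "well": wid, "construct": g.construct, "medium": config.medium,
                        "bio_replicate": bio, "tech_replicate": tech,
                        "K": g.K, "N0": n0, "r": r_b,
                        "max_slope_time": float(np.log((g.K - n0) / n0) / r_b),
                    }
                )

    t = config.times
    baseline = config.blank_level + config.blank_drift_per_h * t
    blank_sd = config.noise_sd * config.reference_k
    for _ in range(n_blanks):
        wid = wells[i_well]
        i_well += 1
        values = baseline + (
            rng.normal(0.0, blank_sd, size=t.shape) if blank_sd > 0 else 0.0
        )
        traces.append(
            WellTimeseries(well_id=wid, times=t, values=values, signal_kind=config.signal_kind)
        )
        entries.append(
            LayoutEntry(
                well_id=wid, construct=None, medium=config.medium,
                bio_replicate=None, tech_replicate=None, role="blank",
            )
        )

    return traces, PlateLayout(entries=entries), truth


def write_simulation(
    traces: Sequence[WellTimeseries],
    layout: PlateLayout,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a simulated dataset in the pipeline's CSV dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for tr in traces:
        for t, v in zip(tr.times, tr.values):
            rows.append({"well": tr.well_id, "time_h": t, "value": v})
    ts_path = outdir / "timeseries.csv"
    pd.DataFrame(rows, columns=["well", "time_h", "value"]).to_csv(
        ts_path, index=False, float_format="%.12g"
    )

    lay_rows = [
        {
            "well": e.well_id,
            "construct": e.construct or "",
            "medium": e.medium,
            "bio_replicate": e.bio_replicate if e.bio_replicate is not None else "",
            "tech_replicate": e.tech_replicate if e.tech_replicate is not None else "",
            "role": e.role,
        }
        for e in layout.entries
    ]
    lay_path = outdir / "layout.csv"
    pd.DataFrame(
        lay_rows, columns=["well", "construct", "medium", "bio_replicate", "tech_replicate", "role"]
    ).to_csv(lay_path, index=False)

    gt_path = outdir / "ground_truth.csv"
    truth.to_frame().to_csv(gt_path, index=False, float_format="%.12g")
    return {"timeseries": ts_path, "layout": lay_path, "ground_truth": gt_path}
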