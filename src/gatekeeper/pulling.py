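"""Steered translocation: staged restraints, constant-velocity pulls and
force-adjusted contact statistics.

The ligand coordinate is dragged through the pathway by a harmonic
restraint whose center follows either a staged schedule (used to place the
molecule in the binding pocket) or a constant-velocity ramp (the pull-out
proper). Contact with a pathway residue is membership of ``z`` in that
residue's zone interval — a one-dimensional stand-in for 3-D atom-pair
contacts that preserves the structure of the downstream statistics.

Contact frequencies come in two flavours: the raw per-zone fraction of
frames in contact, and an adjusted frequency in which each frame's contact
indicator is weighted by the *correction factor* of the restraint forces
in a +/-10 ps window around the frame,

    (sum of positive forces - |sum of negative forces|)
    / (sum of positive forces + |sum of negative forces|),

so contacts made while the spring pulls forward count positively and
contacts made while the ligand runs ahead of the spring count negatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import LangevinParams, Trajectory, WallSpec, _propagate
from .landscapes import Landscape

__all__ = [
    "RestraintSchedule",
    "PullConfig",
    "ResidueZone",
    "PullTrajectory",
    "ContactFrequencyTable",
    "restraint_state",
    "run_constant_velocity_pull",
    "run_staged_restraint",
    "correction_factor",
    "correction_factors",
    "adjusted_contact_frequencies",
    "mean_table",
]

#: production staged schedule: hold at the initial distance, sweep the
#: center to 0.2 nm by step 4.5e6, then release the spring by step 5e6
DEFAULT_STAGES = ((0, None, 1000.0), (4_500_000, 0.2, 1000.0), (5_000_000, 0.2, 0.0))


@dataclass(frozen=True)
class RestraintSchedule:
    """Ordered stages (step, center, kappa) with linear interpolation.

    A stage may give ``kappa=None`` to inherit the previous stage's value;
    the first stage's center may be ``None`` meaning "the initial
    distance", resolved via :meth:`resolve`.
    """

    stages: Tuple[Tuple[int, float | None, float | None], ...] = DEFAULT_STAGES

    def __post_init__(self):
        if not self.stages:
            raise ValueError("schedule must have at least one stage")
        steps = [s[0] for s in self.stages]
        if steps[0] != 0:
            raise ValueError("first stage must start at step 0")
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("stage steps must be strictly increasing")

    def resolve(self, z_init: float | None = None) -> "RestraintSchedule":
        """Fill inherited kappas and the initial-distance placeholder."""
        out = []
        prev_kappa = None
        for step, at, kappa in self.stages:
            if at is None:
                if z_init is None:
                    raise ValueError("schedule needs z_init to resolve the initial distance")
                at = float(z_init)
            if kappa is None:
                if prev_kappa is None:
                    raise ValueError("first stage must define kappa")
                kappa = prev_kappa
            if kappa < 0:
                raise ValueError("kappa must be >= 0")
            prev_kappa = kappa
            out.append((int(step), float(at), float(kappa)))
        return RestraintSchedule(stages=tuple(out))

    def arrays(self):
        steps = np.array([s[0] for s in self.stages], dtype=float)
        ats = np.array([s[1] for s in self.stages], dtype=float)
        kaps = np.array([s[2] for s in self.stages], dtype=float)
        return steps, ats, kaps


def restraint_state(schedule: RestraintSchedule, step: int) -> Tuple[float, float]:
    """(center, kappa) at an integer step: piecewise-linear between stages,
    held constant beyond the last."""
    if step < 0:
        raise ValueError("step must be >= 0")
    sched = schedule.resolve() if any(s[1] is None or s[2] is None for s in schedule.stages) else schedule
    steps, ats, kaps = sched.arrays()
    return float(np.interp(step, steps, ats)), float(np.interp(step, steps, kaps))


@dataclass(frozen=True)
class PullConfig:
    """Constant-velocity pull parameters.

    ``velocity`` is in nm/ns (the production default 0.0005 nm/ns is far
    too slow for desk runs; generators rescale it and record the value
    used). Direction is +z.
    """

    force_constant: float = 500.0
    velocity: float = 0.0005
    n_replicates: int = 25

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.velocity <= 0:
            raise ValueError("velocity must be > 0")


@dataclass(frozen=True)
class ResidueZone:
    """A pathway residue mapped to an interval of the coordinate."""

    residue_label: str
    center: float
    halfwidth: float = 0.1

    def __post_init__(self):
        if not -1.5 <= self.center <= 2.4:
            raise ValueError("zone center must lie within [-1.5, 2.4]")
        if self.halfwidth <= 0:
            raise ValueError("halfwidth must be > 0")


def _check_zones(zones: Sequence[ResidueZone]):
    labels = [z.residue_label for z in zones]
    if len(set(labels)) != len(labels):
        raise ValueError("zone labels must be unique")


@dataclass
class PullTrajectory:
    """Frames of a steered run: positions, restraint state and contacts."""

    time: np.ndarray
    z: np.ndarray
    restraint_center: np.ndarray
    pull_force: np.ndarray
    contacts: np.ndarray  # (n_zones, n_frames) boolean
    zones: List[ResidueZone]
    frame_spacing: float
    seed: int

    def __post_init__(self):
        n = self.time.size
        if not (self.z.size == self.restraint_center.size == self.pull_force.size == n):
            raise ValueError("pull trajectory arrays must have equal length")
        if self.contacts.shape != (len(self.zones), n):
            raise ValueError("contacts matrix shape mismatch")


@dataclass
class ContactFrequencyTable:
    """Per-residue raw and force-adjusted contact frequencies."""

    table: pd.DataFrame  # columns: residue, raw_frequency, adjusted_frequency
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = self.table
        if not {"residue", "raw_frequency", "adjusted_frequency"} <= set(t.columns):
            raise ValueError("table needs residue/raw_frequency/adjusted_frequency columns")
        if ((t.raw_frequency < 0) | (t.raw_frequency > 1)).any():
            raise ValueError("raw frequencies must lie in [0, 1]")
        if ((t.adjusted_frequency < -1) | (t.adjusted_frequency > 1)).any():
            raise ValueError("adjusted frequencies must lie in [-1, 1]")


def _contacts(z: np.ndarray, zones: Sequence[ResidueZone]) -> np.ndarray:
    c = np.empty((len(zones), z.size), dtype=bool)
    for j, zone in enumerate(zones):
        c[j] = np.abs(z - zone.center) <= zone.halfwidth
    return c


def run_constant_velocity_pull(landscape: Landscape, pull: PullConfig,
                               langevin: LangevinParams | None = None,
                               walls: WallSpec | None = None,
                               zones: Sequence[ResidueZone] = (),
                               z_start: float = 0.2, n_steps: int = 1,
                               seed: int = 0, frame_spacing: float = 1.0,
                               v0: float | None = None) -> PullTrajectory:
    """Pull along +z with center(t) = z_start + velocity * t.

    ``frame_spacing`` (ps) sets the analysis frame cadence; the restraint
    center moves every integrator step.
    """
    langevin = langevin or LangevinParams()
    _check_zones(zones)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    dt = langevin.timestep
    v_per_step = pull.velocity * 1e-3 * dt  # nm/ns -> nm per step
    sched = ((0.0, n_steps), (z_start, z_start + v_per_step * n_steps),
             (pull.force_constant, pull.force_constant))
    restraint = tuple(np.asarray(a, dtype=float) for a in sched)
    stride = max(1, int(round(frame_spacing / dt)))
    rng = np.random.default_rng(seed)
    out, _, _ = _propagate(landscape, langevin, walls, None, restraint,
                           n_steps, z_start, rng, stride, v0=v0)
    n_rec = out["z"].size
    time = np.arange(1, n_rec + 1) * stride * dt
    return PullTrajectory(time=time, z=out["z"], restraint_center=out["c"],
                          pull_force=out["pf"], contacts=_contacts(out["z"], zones),
                          zones=list(zones), frame_spacing=stride * dt, seed=seed)


def run_staged_restraint(landscape: Landscape, schedule: RestraintSchedule,
                         langevin: LangevinParams | None = None,
                         walls: WallSpec | None = None,
                         z_start: float = 0.0, n_steps: int = 1, seed: int = 0,
                         frame_spacing: float = 1.0) -> Trajectory:
    """Propagate under a staged moving restraint (pocket-placement stage)."""
    langevin = langevin or LangevinParams()
    sched = schedule.resolve(z_init=z_start)
    rng = np.random.default_rng(seed)
    dt = langevin.timestep
    stride = max(1, int(round(frame_spacing / dt)))
    out, _, _ = _propagate(landscape, langevin, walls, None, sched.arrays(),
                           n_steps, z_start, rng, stride)
    n_rec = out["z"].size
    return Trajectory(time=np.arange(1, n_rec + 1) * stride * dt, z=out["z"],
                      velocity=out["v"], bias_energy=out["be"],
                      total_force=out["f"], seed=seed,
                      restraint_center=out["c"], pull_force=out["pf"])


def correction_factor(pull_force: np.ndarray, frame_index: int,
                      window: float = 10.0, frame_spacing: float = 1.0) -> float:
    """Force-direction statistic over a +/-window around one frame.

    Sums positive and negative force samples in the window (truncated at
    the trajectory ends) and returns their normalized difference; 0 when
    all samples are zero. Always in [-1, 1].
    """
    f = np.asarray(pull_force, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite forces")
    if window <= 0:
        raise ValueError("window must be > 0")
    w = int(round(window / frame_spacing))
    lo = max(0, frame_index - w)
    hi = min(f.size, frame_index + w + 1)
    seg = f[lo:hi]
    pos = seg[seg > 0].sum()
    neg = -seg[seg < 0].sum()
    denom = pos + neg
    if denom == 0:
        return 0.0
    return float((pos - neg) / denom)


def correction_factors(pull_force: np.ndarray, window: float = 10.0,
                       frame_spacing: float = 1.0) -> np.ndarray:
    """Vectorized :func:`correction_factor` for every frame."""
    f = np.asarray(pull_force, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite forces")
    w = int(round(window / frame_spacing))
    cp = np.concatenate([[0.0], np.cumsum(np.where(f > 0, f, 0.0))])
    cn = np.concatenate([[0.0], np.cumsum(np.where(f < 0, -f, 0.0))])
    idx = np.arange(f.size)
    lo = np.maximum(0, idx - w)
    hi = np.minimum(f.size, idx + w + 1)
    pos = cp[hi] - cp[lo]
    neg = cn[hi] - cn[lo]
    denom = pos + neg
    with np.errstate(invalid="ignore", divide="ignore"):
        cf = np.where(denom == 0, 0.0, (pos - neg) / np.where(denom == 0, 1.0, denom))
    return cf


def adjusted_contact_frequencies(traj: PullTrajectory,
                                 window: float = 10.0) -> ContactFrequencyTable:
    """Raw and correction-factor-weighted contact frequencies per zone."""
    if traj.time.size == 0:
        raise ValueError("zero-length trajectory")
    cf = correction_factors(traj.pull_force, window=window,
                            frame_spacing=traj.frame_spacing)
    raw = traj.contacts.mean(axis=1)
    adj = (traj.contacts * cf).mean(axis=1)
    df = pd.DataFrame({
        "residue": [z.residue_label for z in traj.zones],
        "raw_frequency": raw,
        "adjusted_frequency": adj,
    })
    return ContactFrequencyTable(table=df, metadata={"seed": traj.seed,
                                                     "window_ps": window})


def mean_table(tables: Sequence[ContactFrequencyTable]) -> ContactFrequencyTable:
    """Average contact tables over replicates (matching residue sets)."""
    if not tables:
        raise ValueError("no tables to average")
    base = tables[0].table["residue"]
    raw = np.mean([t.table["raw_frequency"].to_numpy() for t in tables], axis=0)
    adj = np.mean([t.table["adjusted_frequency"].to_numpy() for t in tables], axis=0)
    df = pd.DataFrame({"residue": base, "raw_frequency": raw, "adjusted_frequency": adj})
    meta = dict(tables[0].metadata)
    meta["n_replicates"] = len(tables)
    return ContactFrequencyTable(table=df, metadata=meta)
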