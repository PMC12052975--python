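"""Well-tempered metadynamics with multiple walkers and hill-sum FES recovery.

Gaussian bias hills are deposited along the translocation coordinate at a
fixed cadence; each hill's height is damped by the accumulated bias at its
center (well-tempered scaling with bias factor gamma), so the bias
converges to ``-(1 - 1/gamma) * F(z)`` and the free-energy surface is
recovered as ``F(z) = -(gamma/(gamma-1)) * V(z)``, the hill-summation
reconstruction.

Walkers share a single bias. They propagate in synchronous rounds of
``pace_steps`` steps and then deposit in fixed walker order, which makes
multi-walker runs deterministic for a given seed (walker ``i`` draws its
noise from a generator seeded ``seed + i``). The shared bias is held both
as the exact ordered hill list and as a projection onto the configured
grid (full Gaussians evaluated at every node, no truncation); the
propagator interpolates the grid, while hill-height scaling and bias
queries use exact summation over the deposited hills.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .constants import KB
from .engine import (GridBias, LangevinParams, PropagationError, Trajectory,
                     WallSpec, _propagate)
from .landscapes import Landscape

__all__ = [
    "MetadynamicsConfig",
    "Hill",
    "HillLog",
    "FES",
    "scaled_hill_height",
    "bias_from_hills",
    "run_wt_metadynamics",
    "reconstruct_fes",
    "fes_rmse",
]


@dataclass(frozen=True)
class MetadynamicsConfig:
    """Bias parameters (defaults follow the production setup)."""

    pace_steps: int = 500
    height0: float = 0.6
    sigma: float = 0.05
    biasfactor: float = 10.0
    temperature: float = 303.15
    grid_min: float = -1.5
    grid_max: float = 2.4
    grid_bins: int = 390
    n_walkers: int = 4

    def __post_init__(self):
        if self.biasfactor <= 1:
            raise ValueError("biasfactor must be > 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.grid_min >= self.grid_max:
            raise ValueError("grid_min must be < grid_max")
        if self.pace_steps < 1:
            raise ValueError("pace_steps must be >= 1")
        if self.n_walkers < 1:
            raise ValueError("n_walkers must be >= 1")

    @property
    def grid(self) -> np.ndarray:
        """Grid node positions (grid_bins intervals, grid_bins+1 nodes)."""
        return np.linspace(self.grid_min, self.grid_max, self.grid_bins + 1)

    @property
    def grid_spacing(self) -> float:
        return (self.grid_max - self.grid_min) / self.grid_bins


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian (height already well-tempered-scaled)."""

    time: float
    center: float
    sigma: float
    height: float
    biasfactor: float


@dataclass
class HillLog:
    """Ordered deposited hills plus a snapshot of the configuration."""

    hills: List[Hill]
    config: MetadynamicsConfig

    def __post_init__(self):
        t = [h.time for h in self.hills]
        if any(b < a for a, b in zip(t, t[1:])):
            raise ValueError("hill times must be non-decreasing")

    def __len__(self):
        return len(self.hills)

    def arrays(self):
        """(times, centers, sigmas, heights) as float arrays."""
        if not self.hills:
            z = np.empty(0)
            return z, z.copy(), z.copy(), z.copy()
        a = np.array([(h.time, h.center, h.sigma, h.height) for h in self.hills])
        return a[:, 0], a[:, 1], a[:, 2], a[:, 3]


@dataclass
class FES:
    """Reconstructed free-energy surface on the config grid (min = 0)."""

    z_grid: np.ndarray
    free_energy: np.ndarray
    region_sampled: np.ndarray

    def __post_init__(self):
        if not (self.z_grid.size == self.free_energy.size == self.region_sampled.size):
            raise ValueError("FES arrays must have equal length")


def scaled_hill_height(v_bias_at_center: float, cfg: MetadynamicsConfig) -> float:
    """Well-tempered hill height: height0 * exp(-V / (kB (gamma-1) T))."""
    if cfg.biasfactor <= 1:
        raise ValueError("biasfactor must be > 1")
    if v_bias_at_center < 0:
        raise ValueError("accumulated bias must be >= 0")
    return cfg.height0 * np.exp(-v_bias_at_center / (KB * (cfg.biasfactor - 1) * cfg.temperature))


def bias_from_hills(hills: HillLog, z):
    """Sum of the logged Gaussians at z (scalar or array); empty log -> 0."""
    z = np.asarray(z, dtype=float)
    _, centers, sigmas, heights = hills.arrays()
    if centers.size == 0:
        out = np.zeros_like(z)
        return float(out) if z.ndim == 0 else out
    d = z[..., None] - centers
    v = np.sum(heights * np.exp(-0.5 * (d / sigmas) ** 2), axis=-1)
    return float(v) if z.ndim == 0 else v


@dataclass
class MetadynamicsRun:
    """Result bundle of :func:`run_wt_metadynamics`."""

    trajectories: List[Trajectory]
    hills: HillLog
    bias: GridBias
    #: accumulated grid bias at the probe points after each deposition,
    #: shape (n_hills, n_probes); empty unless probes were requested
    probe_bias: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


def run_wt_metadynamics(landscape: Landscape, cfg: MetadynamicsConfig,
                        langevin: LangevinParams | None = None,
                        walls: WallSpec | None = None,
                        n_steps_per_walker: int = 0, seed: int = 0,
                        z0: Sequence[float] | None = None,
                        record_stride: int | None = None,
                        probe_z: Sequence[float] | None = None) -> MetadynamicsRun:
    """Run shared-bias multi-walker well-tempered metadynamics.

    Every ``pace_steps`` steps each walker (in walker-index order) deposits
    one hill at its current position, with the well-tempered height
    evaluated on the bias accumulated so far (including hills deposited
    earlier in the same round). ``probe_z`` positions, if given, have the
    accumulated grid bias recorded after every deposition.
    """
    langevin = langevin or LangevinParams()
    walls = walls if walls is not None else WallSpec()
    if n_steps_per_walker < cfg.pace_steps:
        raise ValueError("n_steps_per_walker must be >= pace_steps")
    record_stride = record_stride or cfg.pace_steps

    nodes = cfg.grid
    gdz = cfg.grid_spacing
    bias = GridBias(grid_min=cfg.grid_min, spacing=gdz,
                    energy=np.zeros(nodes.size), gradient=np.zeros(nodes.size))

    n_rounds = n_steps_per_walker // cfg.pace_steps
    remainder = n_steps_per_walker - n_rounds * cfg.pace_steps
    nw = cfg.n_walkers
    cap = n_rounds * nw
    h_time = np.empty(cap)
    h_center = np.empty(cap)
    h_height = np.empty(cap)
    n_hills = 0

    if z0 is None:
        lo = max(landscape.domain[0], walls.lower_at)
        hi = min(landscape.domain[1], walls.upper_at)
        z0 = lo + (np.arange(nw) + 1.0) * (hi - lo) / (nw + 1.0)
    z = [float(v) for v in z0]
    if len(z) != nw:
        raise ValueError("need one starting position per walker")

    rngs = [np.random.default_rng(seed + i) for i in range(nw)]
    v = [float(r.normal(0.0, np.sqrt(langevin.kT / langevin.mass))) for r in rngs]
    records: List[List[dict]] = [[] for _ in range(nw)]

    probes = None if probe_z is None else np.asarray(probe_z, dtype=float)
    probe_rows = [] if probes is not None else None
    dt = langevin.timestep
    inv_2s2 = 0.5 / cfg.sigma**2

    def exact_bias(zq: float) -> float:
        if n_hills == 0:
            return 0.0
        d = zq - h_center[:n_hills]
        return float(np.dot(h_height[:n_hills], np.exp(-d * d * inv_2s2)))

    for r in range(n_rounds + 1):
        seg = cfg.pace_steps if r < n_rounds else remainder
        if seg:
            for w in range(nw):
                try:
                    out, z[w], v[w] = _propagate(
                        landscape, langevin, walls, bias, None, seg, z[w],
                        rngs[w], record_stride, v0=v[w],
                        step0=r * cfg.pace_steps, walker=w)
                except PropagationError as err:
                    raise PropagationError(err.step, walker=w) from err
                records[w].append(out)
        if r < n_rounds:
            t = (r + 1) * cfg.pace_steps * dt
            for w in range(nw):
                h = scaled_hill_height(exact_bias(z[w]), cfg)
                h_time[n_hills] = t
                h_center[n_hills] = z[w]
                h_height[n_hills] = h
                n_hills += 1
                d = nodes - z[w]
                g = h * np.exp(-d * d * inv_2s2)
                bias.energy += g
                bias.gradient += -g * d / cfg.sigma**2
                if probes is not None:
                    probe_rows.append(bias.energy_at(probes))

    hills = HillLog(
        hills=[Hill(time=h_time[i], center=h_center[i], sigma=cfg.sigma,
                    height=h_height[i], biasfactor=cfg.biasfactor)
               for i in range(n_hills)],
        config=cfg)

    trajs = []
    for w in range(nw):
        keys = ("z", "v", "be", "f", "pf", "c")
        cat = {k: np.concatenate([seg[k] for seg in records[w]]) for k in keys}
        n_rec = cat["z"].size
        trajs.append(Trajectory(
            time=np.arange(1, n_rec + 1) * record_stride * dt,
            z=cat["z"], velocity=cat["v"], bias_energy=cat["be"],
            total_force=cat["f"], seed=seed + w))
    probe_bias = (np.asarray(probe_rows) if probe_rows else np.empty((0, 0)))
    return MetadynamicsRun(trajectories=trajs, hills=hills, bias=bias,
                           probe_bias=probe_bias)


def reconstruct_fes(hills: HillLog, cfg: MetadynamicsConfig | None = None) -> FES:
    """Hill-summation FES: F(z) = -(gamma/(gamma-1)) V(z), shifted to min 0.

    ``region_sampled`` marks grid nodes within 3 sigma of at least one hill
    center.
    """
    cfg = cfg or hills.config
    nodes = cfg.grid
    if len(hills) == 0:
        warnings.warn("empty hill log: flat zero FES", stacklevel=2)
        return FES(z_grid=nodes, free_energy=np.zeros(nodes.size),
                   region_sampled=np.zeros(nodes.size, dtype=bool))
    gamma = cfg.biasfactor
    v = bias_from_hills(hills, nodes)
    f = -(gamma / (gamma - 1.0)) * v
    f -= f.min()
    _, centers, sigmas, _ = hills.arrays()
    dist = np.min(np.abs(nodes[:, None] - centers[None, :]) / sigmas[None, :], axis=1)
    return FES(z_grid=nodes, free_energy=f, region_sampled=dist <= 3.0)


def fes_rmse(a: FES, b: FES, region) -> float:
    """RMS difference of two surfaces on a region, after aligning each to
    mean zero on that region.

    ``region`` is either a ``(lo, hi)`` interval in nm or a boolean mask
    over the shared grid.
    """
    if a.z_grid.size != b.z_grid.size or not np.allclose(a.z_grid, b.z_grid):
        raise ValueError("FES grids differ")
    if isinstance(region, (tuple, list)) and len(region) == 2:
        mask = (a.z_grid >= region[0]) & (a.z_grid <= region[1])
    else:
        mask = np.asarray(region, dtype=bool)
        if mask.size != a.z_grid.size:
            raise ValueError("region mask length mismatch")
    if not mask.any():
        raise ValueError("empty comparison region")
    fa = a.free_energy[mask]
    fb = b.free_energy[mask]
    d = (fa - fa.mean()) - (fb - fb.mean())
    return float(np.sqrt(np.mean(d * d)))
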