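"""Underdamped Langevin dynamics along the translocation coordinate.

This is the physical substrate for the biased simulations: a single
coordinate ``z`` (nm) evolving on a :class:`~gatekeeper.landscapes.Landscape`
under a BAOAB-discretized Langevin integrator, optionally confined by
one-sided power walls and driven by an external bias (a grid-backed
metadynamics bias or an arbitrary callable) and/or a staged harmonic
restraint. Friction and mass are coarse-grained parameters that set
timescales only; the equilibrium distribution depends only on the
landscape and temperature.

Velocities are initialised from the Maxwell-Boltzmann distribution at the
run temperature using the run seed, so identical (configuration, seed)
pairs give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .constants import KB
from .landscapes import Landscape

__all__ = [
    "LangevinParams",
    "WallSpec",
    "GridBias",
    "Trajectory",
    "wall_energy",
    "run_langevin",
    "PropagationError",
]

_NOISE_CHUNK = 250_000  # steps of noise generated per kernel call


class PropagationError(RuntimeError):
    """Non-finite force encountered during propagation."""

    def __init__(self, step: int, walker: int | None = None):
        self.step = step
        self.walker = walker
        where = f" (walker {walker})" if walker is not None else ""
        super().__init__(f"non-finite force at step {step}{where}")


@dataclass(frozen=True)
class LangevinParams:
    """Integrator parameters.

    temperature in K, timestep in ps, friction in 1/ps, mass in g/mol.
    """

    temperature: float = 303.15
    timestep: float = 0.002
    friction: float = 1.0
    mass: float = 50.0

    #: Boltzmann constant, kJ/mol/K (immutable)
    kB = KB

    def __post_init__(self):
        for name in ("temperature", "timestep", "friction", "mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def kT(self) -> float:
        return KB * self.temperature


@dataclass(frozen=True)
class WallSpec:
    """One-sided power restraints confining z to [lower_at, upper_at].

    Outside a bound the energy is ``0.5 * kappa * (z - bound)**exponent``;
    inside, zero. With the default even quadratic exponent both energy and
    force are continuous at the bounds.
    """

    lower_at: float = -1.1
    upper_at: float = 2.0
    kappa: float = 1000.0
    exponent: int = 2

    def __post_init__(self):
        if not self.lower_at < self.upper_at:
            raise ValueError("lower_at must be < upper_at")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.exponent < 2 or self.exponent % 2:
            raise ValueError("exponent must be even and >= 2")


#: walls disabled (kappa 0, bounds wide open)
NO_WALLS = WallSpec(lower_at=-1e9, upper_at=1e9, kappa=0.0)


def wall_energy(walls: WallSpec, z) -> Tuple[np.ndarray, np.ndarray]:
    """Energy (kJ/mol) and force (kJ/mol/nm) of the wall restraints at z."""
    z = np.asarray(z, dtype=float)
    d = np.where(z < walls.lower_at, z - walls.lower_at,
                 np.where(z > walls.upper_at, z - walls.upper_at, 0.0))
    if walls.kappa == 0:
        e = np.zeros_like(d)
        f = np.zeros_like(d)
    else:
        e = 0.5 * walls.kappa * d**walls.exponent
        f = -0.5 * walls.kappa * walls.exponent * d ** (walls.exponent - 1)
        f = np.where(d == 0.0, 0.0, f)
    if z.ndim == 0:
        return float(e), float(f)
    return e, f


@dataclass
class GridBias:
    """External bias tabulated on a uniform grid (energy and dV/dz at nodes).

    The propagator interpolates both arrays linearly; values beyond the
    grid are clamped to the end nodes.
    """

    grid_min: float
    spacing: float
    energy: np.ndarray
    gradient: np.ndarray

    def energy_at(self, z):
        x = (np.asarray(z, dtype=float) - self.grid_min) / self.spacing
        return np.interp(x, np.arange(self.energy.size), self.energy)


@dataclass
class Trajectory:
    """Discrete record of a Langevin run (one row per recorded step)."""

    time: np.ndarray
    z: np.ndarray
    velocity: np.ndarray
    bias_energy: np.ndarray
    total_force: np.ndarray
    seed: int
    restraint_center: np.ndarray | None = None
    pull_force: np.ndarray | None = None

    def __post_init__(self):
        n = self.time.size
        for name in ("z", "velocity", "bias_energy", "total_force"):
            if getattr(self, name).size != n:
                raise ValueError("trajectory arrays must have equal length")


def _schedule_arrays(restraint) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if restraint is None:
        e = np.empty(0, dtype=float)
        return e, e, e
    steps, ats, kaps = restraint
    return (np.asarray(steps, dtype=float), np.asarray(ats, dtype=float),
            np.asarray(kaps, dtype=float))


def _propagate(landscape: Landscape, params: LangevinParams, walls: WallSpec | None,
               bias: GridBias | None, restraint, n_steps: int, z0: float,
               rng: np.random.Generator, stride: int,
               v0: float | None = None, step0: int = 0,
               walker: int | None = None):
    """Kernel-backed propagation; returns (records dict, z, v, steps done)."""
    walls = walls or NO_WALLS
    kind, p, tab_z, tab_f = landscape.packed()
    dom_lo, dom_hi = landscape.domain
    ss, sa, sk = _schedule_arrays(restraint)
    if bias is None:
        use_bias = False
        gmin, gdz = 0.0, 1.0
        be = np.zeros(1)
        bd = np.zeros(1)
    else:
        use_bias = True
        gmin, gdz = bias.grid_min, bias.spacing
        be, bd = bias.energy, bias.gradient
    if v0 is None:
        v = float(rng.normal(0.0, np.sqrt(params.kT / params.mass)))
    else:
        v = float(v0)
    z = float(z0)
    n_rec_total = (step0 + n_steps) // stride - step0 // stride
    out = {k: np.empty(n_rec_total) for k in ("z", "v", "be", "f", "pf", "c")}
    rec = 0
    done = 0
    while done < n_steps:
        m = min(_NOISE_CHUNK, n_steps - done)
        noise = rng.standard_normal(m)
        z, v, nrec, err = _kernels.baoab_chunk(
            kind, p, tab_z, tab_f, dom_lo, dom_hi,
            walls.lower_at, walls.upper_at, walls.kappa, walls.exponent,
            use_bias, gmin, gdz, be, bd,
            ss, sa, sk,
            params.timestep, params.friction, params.mass, params.kT,
            step0 + done, z, v, noise, stride,
            out["z"], out["v"], out["be"], out["f"], out["pf"], out["c"], rec)
        rec += nrec
        if err >= 0:
            raise PropagationError(err, walker)
        done += m
    return out, z, v


def run_langevin(landscape: Landscape, params: LangevinParams | None = None,
                 walls: WallSpec | None = None,
                 bias: Optional[GridBias | Callable[[float], tuple]] = None,
                 n_steps: int = 1, z0: float = 0.0, seed: int = 0,
                 stride: int = 1, v0: float | None = None,
                 restraint: Optional[Sequence] = None) -> Trajectory:
    """Run BAOAB Langevin dynamics and return the recorded trajectory.

    Parameters
    ----------
    bias:
        ``None``, a :class:`GridBias`, or a callable ``z -> (energy, force)``
        queried once per step at the current position (the callable path is
        a plain-Python loop intended for small runs).
    restraint:
        Optional staged harmonic restraint ``(steps, centers, kappas)``,
        each a sequence; center and stiffness interpolate linearly between
        stages and are held constant beyond the last.
    stride:
        Record every ``stride``-th step (time spacing ``stride * timestep``).
    """
    params = params or LangevinParams()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    z_lo, z_hi = landscape.domain
    if not z_lo <= z0 <= z_hi:
        raise ValueError("z0 outside the landscape domain")
    rng = np.random.default_rng(seed)
    if callable(bias) and not isinstance(bias, GridBias):
        out, _, _ = _propagate_python(landscape, params, walls or NO_WALLS, bias,
                                      restraint, n_steps, z0, rng, stride, v0)
    else:
        out, _, _ = _propagate(landscape, params, walls, bias, restraint,
                               n_steps, z0, rng, stride, v0)
    dt = params.timestep
    n_rec = out["z"].size
    time = (np.arange(1, n_rec + 1) * stride) * dt
    return Trajectory(time=time, z=out["z"], velocity=out["v"],
                      bias_energy=out["be"], total_force=out["f"], seed=seed,
                      restraint_center=out["c"], pull_force=out["pf"])


def _propagate_python(landscape, params, walls, bias_fn, restraint, n_steps,
                      z0, rng, stride, v0):
    """Reference-path propagation with a per-step Python bias callback."""
    from .landscapes import _eval_scalar

    ss, sa, sk = _schedule_arrays(restraint)
    dt = params.timestep
    c1 = np.exp(-params.friction * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1)) * np.sqrt(params.kT / params.mass)
    z = float(z0)
    v = float(v0) if v0 is not None else float(rng.normal(0.0, np.sqrt(params.kT / params.mass)))
    z_lo, z_hi = landscape.domain

    def total(z, step):
        _, d = _eval_scalar(landscape, min(max(z, z_lo), z_hi))
        _, fw = wall_energy(walls, z)
        eb, fb = bias_fn(z)
        c, k = _kernels._restraint_at(ss, sa, sk, float(step))
        pf = k * (c - z)
        return -d + fw + fb + pf, eb, pf, c

    f, eb, pf, c = total(z, 0)
    rows = []
    for s in range(n_steps):
        if not np.isfinite(f):
            raise PropagationError(s)
        v += 0.5 * dt * f / params.mass
        z += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal()
        z += 0.5 * dt * v
        f, eb, pf, c = total(z, s + 1)
        v += 0.5 * dt * f / params.mass
        if (s + 1) % stride == 0:
            rows.append((z, v, eb, f, pf, c))
    arr = np.array(rows, dtype=float).reshape(-1, 6)
    out = {k: arr[:, i] for i, k in enumerate(("z", "v", "be", "f", "pf", "c"))}
    return out, z, v
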