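"""One-dimensional free-energy landscapes along the translocation coordinate.

A :class:`Landscape` is an analytic or tabulated free-energy profile
``F(z)`` (kJ/mol) over a closed interval of the collective variable ``z``
(nm, the z-component of the ligand position along the transport pathway).
Each kind is piecewise smooth; the force returned everywhere is ``-dF/dz``
with a right-sided derivative convention at tabulated nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = ["Landscape", "evaluate_landscape", "LandscapeError"]

#: integer codes shared with the numba kernels
KIND_CODES = {
    "flat": 0,
    "harmonic": 1,
    "double_well": 2,
    "downhill_barriers": 3,
    "entry_barrier": 3,
    "gaussians": 3,
    "tabulated": 4,
}


class LandscapeError(ValueError):
    """Configuration or validation problem with a landscape definition."""


@dataclass(frozen=True)
class Landscape:
    """Free-energy profile F(z) with analytic gradient.

    Parameters
    ----------
    kind:
        One of ``flat``, ``harmonic``, ``double_well``,
        ``downhill_barriers``, ``entry_barrier`` (both realised as a linear
        trend plus Gaussian bumps), ``gaussians`` or ``tabulated``.
    params:
        Named real parameters, kind dependent (see module docstring of
        :mod:`gatekeeper.synth` for the archetype constructors).
    domain:
        Closed interval ``[z_lo, z_hi]`` in nm.
    grid / values:
        For ``tabulated`` only: strictly increasing node positions and the
        free energy at the nodes; linear interpolation in between.
    """

    kind: str
    params: dict = field(default_factory=dict)
    domain: Tuple[float, float] = (-1.5, 2.4)
    grid: np.ndarray | None = None
    values: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in KIND_CODES:
            raise LandscapeError(f"unknown landscape kind: {self.kind!r}")
        z_lo, z_hi = self.domain
        if not z_lo < z_hi:
            raise LandscapeError("domain must satisfy z_lo < z_hi")
        if self.kind == "tabulated":
            if self.grid is None or self.values is None:
                raise LandscapeError("tabulated landscape needs grid and values")
            g = np.asarray(self.grid, dtype=float)
            v = np.asarray(self.values, dtype=float)
            if g.ndim != 1 or g.size < 2 or g.size != v.size:
                raise LandscapeError("tabulated grid/values must be 1-D, length >= 2, equal length")
            if not np.all(np.diff(g) > 0):
                raise LandscapeError("tabulated grid must be strictly increasing")
            if not (np.all(np.isfinite(g)) and np.all(np.isfinite(v))):
                raise LandscapeError("tabulated grid/values must be finite")
            object.__setattr__(self, "grid", g)
            object.__setattr__(self, "values", v)

    # -- packed representation for the numba kernels --------------------

    def packed(self) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
        """Return (kind_code, params_vector, tab_z, tab_f) for the kernels."""
        code = KIND_CODES[self.kind]
        empty = np.empty(0, dtype=float)
        if self.kind == "flat":
            return 0, empty, empty, empty
        if self.kind == "harmonic":
            p = np.array([self.params.get("k", 1.0), self.params.get("z0", 0.0)])
            return 1, p, empty, empty
        if self.kind == "double_well":
            p = np.array([self.params["barrier"], self.params["minima"]])
            return 2, p, empty, empty
        if self.kind == "tabulated":
            return 4, empty, self.grid, self.values
        # linear trend + Gaussian bumps
        gs = self.params.get("gaussians", ())
        p = [self.params.get("slope", 0.0), self.params.get("intercept", 0.0), float(len(gs))]
        for amp, center, width in gs:
            p.extend([amp, center, width])
        return 3, np.asarray(p, dtype=float), empty, empty


def _eval_scalar(landscape: Landscape, z: float) -> Tuple[float, float]:
    """Energy and dF/dz at a single (already clamped) position."""
    kind = landscape.kind
    p = landscape.params
    if kind == "flat":
        return 0.0, 0.0
    if kind == "harmonic":
        k = p.get("k", 1.0)
        z0 = p.get("z0", 0.0)
        return 0.5 * k * (z - z0) ** 2, k * (z - z0)
    if kind == "double_well":
        h = p["barrier"]
        a = p["minima"]
        u = z * z - a * a
        return h * u * u / a**4, 4.0 * h * z * u / a**4
    if kind == "tabulated":
        g, v = landscape.grid, landscape.values
        i = int(np.searchsorted(g, z, side="right")) - 1
        i = min(max(i, 0), g.size - 2)
        s = (v[i + 1] - v[i]) / (g[i + 1] - g[i])
        return float(v[i] + s * (z - g[i])), float(s)
    # gaussians family
    e = p.get("intercept", 0.0) + p.get("slope", 0.0) * z
    d = p.get("slope", 0.0)
    for amp, center, width in p.get("gaussians", ()):
        ex = amp * np.exp(-0.5 * ((z - center) / width) ** 2)
        e += ex
        d += -ex * (z - center) / width**2
    return float(e), float(d)


def evaluate_landscape(landscape: Landscape, z):
    """Evaluate ``(F(z), -dF/dz)`` of a landscape.

    ``z`` outside the domain is clamped to the nearest endpoint with a
    warning. Accepts scalars or arrays (arrays evaluated elementwise).
    """
    z_arr = np.asarray(z, dtype=float)
    z_lo, z_hi = landscape.domain
    if np.any(z_arr < z_lo) or np.any(z_arr > z_hi):
        warnings.warn("z outside landscape domain; clamped to the nearest endpoint", stacklevel=2)
        z_arr = np.clip(z_arr, z_lo, z_hi)
    if z_arr.ndim == 0:
        e, d = _eval_scalar(landscape, float(z_arr))
        return e, -d
    energy = np.empty_like(z_arr)
    force = np.empty_like(z_arr)
    for i, zi in np.ndenumerate(z_arr):
        e, d = _eval_scalar(landscape, float(zi))
        energy[i] = e
        force[i] = -d
    return energy, force
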