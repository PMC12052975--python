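"""Numba kernels for the Langevin propagator.

All kernels share a packed landscape representation (integer kind code,
flat parameter vector, optional tabulated node arrays) produced by
:meth:`gatekeeper.landscapes.Landscape.packed`, so the inner loop stays
allocation-free. The harmonic moving restraint is expressed as a staged
piecewise-linear schedule of (step, center, kappa); a constant-velocity
pull is a two-stage schedule and "no restraint" an empty one.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _landscape_ed(kind, p, tab_z, tab_f, z):
    """Return (energy, dF/dz) at z. z must already be clamped to the domain."""
    if kind == 0:  # flat
        return 0.0, 0.0
    elif kind == 1:  # harmonic: p = [k, z0]
        d = z - p[1]
        return 0.5 * p[0] * d * d, p[0] * d
    elif kind == 2:  # symmetric quartic double well: p = [barrier, minima]
        h = p[0]
        a = p[1]
        u = z * z - a * a
        a4 = a * a * a * a
        return h * u * u / a4, 4.0 * h * z * u / a4
    elif kind == 3:  # linear trend + Gaussians: p = [slope, icpt, n, (A,c,w)*n]
        e = p[1] + p[0] * z
        d = p[0]
        n = int(p[2])
        for i in range(n):
            amp = p[3 + 3 * i]
            c = p[4 + 3 * i]
            w = p[5 + 3 * i]
            ex = amp * np.exp(-0.5 * ((z - c) / w) ** 2)
            e += ex
            d += -ex * (z - c) / (w * w)
        return e, d
    else:  # tabulated, linear interpolation, right-sided slope at nodes
        n = tab_z.shape[0]
        if z <= tab_z[0]:
            i = 0
        elif z >= tab_z[n - 1]:
            i = n - 2
        else:
            lo = 0
            hi = n - 1
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if tab_z[mid] <= z:
                    lo = mid
                else:
                    hi = mid
            i = lo
        s = (tab_f[i + 1] - tab_f[i]) / (tab_z[i + 1] - tab_z[i])
        return tab_f[i] + s * (z - tab_z[i]), s


@njit(cache=True)
def _wall_ed(w_lo, w_hi, kappa, exponent, z):
    """One-sided power walls: energy and dE/dz (zero between the bounds)."""
    if kappa <= 0.0:
        return 0.0, 0.0
    if z < w_lo:
        d = z - w_lo
    elif z > w_hi:
        d = z - w_hi
    else:
        return 0.0, 0.0
    e = 0.5 * kappa * d**exponent
    g = 0.5 * kappa * exponent * d ** (exponent - 1)
    return e, g


@njit(cache=True)
def _grid_lookup(gmin, gdz, arr, z):
    """Linear interpolation on a uniform grid, clamped at the ends."""
    x = (z - gmin) / gdz
    n = arr.shape[0]
    if x <= 0.0:
        return arr[0]
    if x >= n - 1:
        return arr[n - 1]
    i = int(x)
    f = x - i
    return arr[i] * (1.0 - f) + arr[i + 1] * f


@njit(cache=True)
def _restraint_at(stage_step, stage_at, stage_kap, step):
    """Piecewise-linear (center, kappa) of the staged restraint at a step."""
    n = stage_step.shape[0]
    if n == 0:
        return 0.0, 0.0
    if step <= stage_step[0]:
        return stage_at[0], stage_kap[0]
    if step >= stage_step[n - 1]:
        return stage_at[n - 1], stage_kap[n - 1]
    i = 0
    while stage_step[i + 1] < step:
        i += 1
    f = (step - stage_step[i]) / (stage_step[i + 1] - stage_step[i])
    return (
        stage_at[i] + f * (stage_at[i + 1] - stage_at[i]),
        stage_kap[i] + f * (stage_kap[i + 1] - stage_kap[i]),
    )


@njit(cache=True)
def _total_force(kind, p, tab_z, tab_f, dom_lo, dom_hi,
                 w_lo, w_hi, w_kap, w_exp,
                 use_bias, gmin, gdz, bias_e, bias_d,
                 stage_step, stage_at, stage_kap, step, z):
    """Sum of landscape + wall + grid-bias + restraint forces, plus bookkeeping.

    Returns (force, bias_energy, pull_force, center).
    """
    zc = z
    if zc < dom_lo:
        zc = dom_lo
    elif zc > dom_hi:
        zc = dom_hi
    e_l, d_l = _landscape_ed(kind, p, tab_z, tab_f, zc)
    e_w, d_w = _wall_ed(w_lo, w_hi, w_kap, w_exp, z)
    f = -d_l - d_w
    be = 0.0
    if use_bias:
        be = _grid_lookup(gmin, gdz, bias_e, z)
        f += -_grid_lookup(gmin, gdz, bias_d, z)
    center, kap = _restraint_at(stage_step, stage_at, stage_kap, step)
    pf = kap * (center - z)
    f += pf
    return f, be, pf, center


@njit(cache=True)
def baoab_chunk(kind, p, tab_z, tab_f, dom_lo, dom_hi,
                w_lo, w_hi, w_kap, w_exp,
                use_bias, gmin, gdz, bias_e, bias_d,
                stage_step, stage_at, stage_kap,
                dt, friction, mass, kT,
                step0, z, v, noise,
                stride, out_z, out_v, out_be, out_f, out_pf, out_c, rec0):
    """Propagate BAOAB for ``noise.size`` steps, recording every ``stride`` steps.

    Global step indices run from ``step0``; a state is recorded after step
    ``s`` (0-based within the chunk) whenever ``(step0 + s + 1) % stride == 0``,
    written sequentially starting at ``rec0``. Returns
    (z, v, n_recorded, error_step) with error_step >= 0 when a non-finite
    force was encountered (propagation aborts there).
    """
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1)) * np.sqrt(kT / mass)
    half = 0.5 * dt
    n = noise.shape[0]
    f, be, pf, center = _total_force(
        kind, p, tab_z, tab_f, dom_lo, dom_hi, w_lo, w_hi, w_kap, w_exp,
        use_bias, gmin, gdz, bias_e, bias_d,
        stage_step, stage_at, stage_kap, step0, z)
    nrec = 0
    for s in range(n):
        if not np.isfinite(f):
            return z, v, nrec, step0 + s
        v += half * f / mass
        z += half * v
        v = c1 * v + c2 * noise[s]
        z += half * v
        f, be, pf, center = _total_force(
            kind, p, tab_z, tab_f, dom_lo, dom_hi, w_lo, w_hi, w_kap, w_exp,
            use_bias, gmin, gdz, bias_e, bias_d,
            stage_step, stage_at, stage_kap, step0 + s + 1, z)
        v += half * f / mass
        if (step0 + s + 1) % stride == 0:
            i = rec0 + nrec
            out_z[i] = z
            out_v[i] = v
            out_be[i] = be
            out_f[i] = f
            out_pf[i] = pf
            out_c[i] = center
            nrec += 1
    return z, v, nrec, -1
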