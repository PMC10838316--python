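"""Analytic potentials in concentric-sphere volume conductors.

Independent oracle for the FEM solver: the potential of a +/- current pair
on the surface of an N-layer concentric sphere, expanded in Legendre
polynomials.  In layer j (outer radius r_j) each harmonic takes the form

    V_n(r) = A_j [ (r / r_j)^n + beta_j (r_j / r)^(n+1) ] P_n(cos gamma)

with beta = 0 in the innermost layer (regularity at the centre) and
(A, beta) propagated outward by continuity of V and of the radial current
density sigma dV/dr at each interface.  The outer Neumann condition for a
point source of current I on the surface fixes the overall scale through

    sigma_N dV/dr |_(r=R) = I (2n+1) / (4 pi R^2) * f_n(alpha),

where f_n(alpha) is the spherical-cap factor for a uniform current density
over a cap of half-angle alpha (f_n(0) = 1 recovers the point source).
Electrodes modelled as small discs in the FEM can therefore be compared
against a matched cap source rather than a singular point source.

The n = 0 monopole term is omitted: for a balanced +/- pair it cancels, and
a lone monopole is incompatible with an insulated sphere.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidGeometryError, OutOfDomainError

_EXP_CLIP = 700.0


def _cap_factors(nmax: int, half_angle: float) -> np.ndarray:
    """f_n for n = 1..nmax; uniform current over a cap of given half-angle."""
    if half_angle == 0.0:
        return np.ones(nmax)
    c = np.cos(half_angle)
    # P_{n-1}(c) - P_{n+1}(c) for n = 1..nmax via the three-term recurrence
    p = np.zeros(nmax + 2)
    p[0], p[1] = 1.0, c
    for n in range(1, nmax + 1):
        p[n + 1] = ((2 * n + 1) * c * p[n] - n * p[n - 1]) / (n + 1)
    n = np.arange(1, nmax + 1)
    return (p[n - 1] - p[n + 1]) / ((2 * n + 1) * (1.0 - c))


def _layer_coefficients(radii: np.ndarray, sigmas: np.ndarray, nmax: int,
                        current: float, cap_half_angle: float):
    """Per-layer (A_j, A_j*beta_j) for each harmonic n = 1..nmax.

    radii are outer-to-inner; layer j has outer radius radii[j].  Returns
    arrays of shape (n_layers, nmax).
    """
    nl = len(radii)
    n = np.arange(1, nmax + 1, dtype=float)
    a = np.zeros((nl, nmax))
    ab = np.zeros((nl, nmax))  # A_j * beta_j
    a[-1] = 1.0                # innermost layer, beta = 0
    # propagate innermost -> outermost
    for j in range(nl - 1, 0, -1):
        r_in_outer = radii[j]        # interface radius
        r_out_outer = radii[j - 1]
        s = r_in_outer / r_out_outer
        with np.errstate(over="ignore"):
            u = s**n                  # (r_if / r_outer)^n
            w = s**(-(n + 1.0))
        sig_ratio = sigmas[j] / sigmas[j - 1]
        p = a[j] + ab[j]                                   # V continuity
        q = sig_ratio * (n * a[j] - (n + 1.0) * ab[j])     # flux continuity
        a[j - 1] = ((n + 1.0) * p + q) / ((2.0 * n + 1.0) * u)
        ab[j - 1] = (n * p - q) / ((2.0 * n + 1.0) * w)
    r_out = radii[0]
    flux = sigmas[0] * (n * a[0] - (n + 1.0) * ab[0]) / r_out
    target = (current * (2.0 * n + 1.0) / (4.0 * np.pi * r_out**2)
              * _cap_factors(nmax, cap_half_angle))
    scale = target / flux
    return a * scale, ab * scale


def analytic_layered_sphere_potential(
    layer_radii,
    layer_conductivities,
    electrode_points,
    query_points,
    current: float = 1.0,
    truncation_order: int = 200,
    cap_half_angle: float = 0.0,
) -> np.ndarray:
    """Potential (V) of a +/- surface electrode pair in a layered sphere.

    Parameters
    ----------
    layer_radii : strictly decreasing outer radii (mm).
    layer_conductivities : one sigma (S/m) per layer, same order.
    electrode_points : (2, 3) array; current +I at the first point, -I at
        the second.  Both are radially snapped to the outer surface.
    query_points : (q, 3) evaluation points, must lie inside the sphere.
    current : I in mA; returned potentials are in volts (mA, mm, S/m are a
        consistent unit system for V, matching the FEM solver).
    truncation_order : number of Legendre harmonics (n = 1..order).
    cap_half_angle : electrode cap half-angle in radians (0 = point source).

    Returns zero-mean-free raw series values; compare after de-meaning when
    matching a zero-mean FEM solution.
    """
    radii = np.asarray(layer_radii, float)
    sigmas = np.asarray(layer_conductivities, float)
    if radii.ndim != 1 or len(radii) != len(sigmas):
        raise InvalidGeometryError("radii and conductivities length mismatch")
    if np.any(np.diff(radii) >= 0):
        raise InvalidGeometryError("layer radii must be strictly decreasing")
    if truncation_order < 1:
        raise InvalidGeometryError("truncation_order must be >= 1")
    electrodes = np.asarray(electrode_points, float).reshape(2, 3)
    pts = np.atleast_2d(np.asarray(query_points, float))
    r_out = radii[0]
    r = np.linalg.norm(pts, axis=1)
    if np.any(r > r_out * (1.0 + 1e-9)):
        raise OutOfDomainError("query point outside the outer sphere")
    r = np.minimum(r, r_out)

    nmax = int(truncation_order)
    a, ab = _layer_coefficients(radii, sigmas, nmax, current, cap_half_angle)

    # assign each query point to its layer (layer j: radii[j+1] < r <= radii[j])
    layer_of = np.searchsorted(-radii, -r, side="left") - 1
    layer_of = np.clip(layer_of, 0, len(radii) - 1)
    inner_ok = np.ones(len(pts), dtype=bool)

    n_arr = np.arange(1, nmax + 1, dtype=float)
    out = np.zeros(len(pts))
    for sign, epoint in zip((1.0, -1.0), electrodes):
        e_hat = epoint / np.linalg.norm(epoint)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosg = np.where(r > 0, pts @ e_hat / np.where(r > 0, r, 1.0), 0.0)
        cosg = np.clip(cosg, -1.0, 1.0)
        # radial factors per point per n, evaluated in log space to avoid
        # overflow of (r_j / r)^(n+1) deep inside thin layers
        rj = radii[layer_of]
        ratio_up = np.where(r > 0, r / rj, 0.0)       # <= 1
        log_dn = np.log(np.where(r > 0, rj / np.maximum(r, 1e-300), 1.0))
        p_prev = np.ones(len(pts))
        p_cur = cosg.copy()
        acc = np.zeros(len(pts))
        for idx, n in enumerate(n_arr):
            aj = a[layer_of, idx]
            abj = ab[layer_of, idx]
            term = aj * ratio_up**n
            expo = np.clip((n + 1.0) * log_dn, -_EXP_CLIP, _EXP_CLIP)
            term = term + abj * np.exp(expo) * inner_ok
            acc += term * p_cur
            p_prev, p_cur = p_cur, (
                ((2 * n + 1.0) * cosg * p_cur - n * p_prev) / (n + 1.0)
            )
        out += sign * acc
    return out


def homogeneous_sphere_potential(radius, sigma, electrode_points,
                                 query_points, current: float = 1.0
                                 ) -> np.ndarray:
    """Closed-form potential for point +/- sources on a homogeneous sphere.

    Sums the series sum_{n>=1} (2n+1)/n t^n P_n(cos g) in closed form:
    2 (1/g - 1) + ln(2 / (1 - t c + g)) with g = sqrt(1 - 2 t c + t^2).
    Used as an independent check that the layered series reduces correctly.
    """
    electrodes = np.asarray(electrode_points, float).reshape(2, 3)
    pts = np.atleast_2d(np.asarray(query_points, float))
    radius = float(radius)
    r = np.linalg.norm(pts, axis=1)
    if np.any(r > radius * (1 + 1e-9)):
        raise OutOfDomainError("query point outside the sphere")
    t = np.minimum(r / radius, 1.0)
    pref = current / (4.0 * np.pi * sigma * radius)
    out = np.zeros(len(pts))
    for sign, epoint in zip((1.0, -1.0), electrodes):
        e_hat = epoint / np.linalg.norm(epoint)
        c = np.clip(pts @ e_hat / np.where(r > 0, r, 1.0), -1.0, 1.0)
        c = np.where(r > 0, c, 0.0)
        g = np.sqrt(np.maximum(1.0 - 2.0 * t * c + t * t, 1e-300))
        series = 2.0 * (1.0 / g - 1.0) + np.log(2.0 / (1.0 - t * c + g))
        out += sign * pref * series
    return out
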