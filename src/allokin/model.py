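"""Forward model of the two-state concerted modulation scheme.

Observed catalytic parameters as functions of modulator concentration. With
``L`` the free modulator concentration, the activating sites contribute
binding polynomials ``(1 + K·L)^n`` per conformation and the inhibitory
sites ``(1 + K_BI·L)^m`` on conformation B only. The observed turnover
number mixes the two conformations with substrate-bound weights,

    kcat_obs = [kcat_A·(1+K_AL·L)^n + L_L·kcat_B·(1+K_BL·L)^n]
               / [(1+K_AL·L)^n + L_L·(1+K_BL·L)^n]

the observed Michaelis constant couples substrate-free weights (numerator)
to substrate-bound weights (denominator),

    km_obs = km_0 · [(1+K_AU·L)^n + L_U·(1+K_BI·L)^m·(1+K_BU·L)^n]
             / [(1+K_AL·L)^n + L_L·(1+K_BL·L)^n]

and the observed specificity constant is the population-weighted average of
the per-conformation specificity constants over substrate-free weights,

    (kcat/km)_obs = [kcat_A/km_A·(1+K_AU·L)^n
                     + L_U·kcat_B/km_B·(1+K_BI·L)^m·(1+K_BU·L)^n]
                    / [(1+K_AU·L)^n + L_U·(1+K_BI·L)^m·(1+K_BU·L)^n]

Note that the specificity-constant expression is not algebraically the
ratio kcat_obs/km_obs; both representations are exposed (see
:func:`efficiency_ratio` and :func:`efficiency_consistency`).
"""

from __future__ import annotations

import warnings

import numpy as np

from .scheme import ModulatorScheme

__all__ = [
    "binding_polynomial",
    "state_populations",
    "observed_kcat",
    "observed_km",
    "observed_efficiency",
    "efficiency_ratio",
    "efficiency_consistency",
    "velocity",
    "ic50",
]


def binding_polynomial(K: float, c, sites: int):
    """Binding polynomial ``(1 + K·c)^sites`` of independent identical sites.

    Equals the sum over occupancy states ``i = 0..sites`` of
    ``C(sites, i)·(K·c)^i``.

    Parameters
    ----------
    K : association constant, µM^-1.
    c : concentration, µM (scalar or array).
    sites : number of sites, >= 0.
    """
    if K < 0:
        raise ValueError(f"association constant must be >= 0, got {K}")
    if int(sites) != sites or sites < 0:
        raise ValueError(f"sites must be a non-negative integer, got {sites}")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = (1.0 + K * c) ** int(sites)
    return out if out.ndim else float(out)


def _weights(scheme: ModulatorScheme, L, form: str):
    """Conformational statistical weights (w_A, w_B) at modulator L."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("modulator concentration must be >= 0")
    if form == "unbound":
        w_A = binding_polynomial(scheme.K_AU, L, scheme.n)
        w_B = (
            scheme.L_U
            * binding_polynomial(scheme.K_BI, L, scheme.m)
            * binding_polynomial(scheme.K_BU, L, scheme.n)
        )
    elif form == "substrate_bound":
        w_A = binding_polynomial(scheme.K_AL, L, scheme.n)
        w_B = scheme.L_L * binding_polynomial(scheme.K_BL, L, scheme.n)
    else:
        raise ValueError(f"form must be 'unbound' or 'substrate_bound', got {form!r}")
    return np.asarray(w_A, dtype=float), np.asarray(w_B, dtype=float)


def state_populations(scheme: ModulatorScheme, L, form: str = "unbound"):
    """Fractional populations (f_A, f_B) of the two conformations.

    ``form='unbound'`` uses the substrate-free weights (K_AU, K_BU, L_U,
    with the inhibitory factor on B); ``form='substrate_bound'`` uses
    (K_AL, K_BL, L_L). The fractions sum to 1.
    """
    w_A, w_B = _weights(scheme, L, form)
    total = w_A + w_B
    f_A = w_A / total
    f_B = w_B / total
    if f_A.ndim:
        return f_A, f_B
    return float(f_A), float(f_B)


def observed_kcat(scheme: ModulatorScheme, L):
    """Observed turnover number (s^-1) at modulator concentration L (µM)."""
    w_A, w_B = _weights(scheme, L, "substrate_bound")
    out = (scheme.kcat_A * w_A + scheme.kcat_B * w_B) / (w_A + w_B)
    return out if out.ndim else float(out)


def observed_km(scheme: ModulatorScheme, L):
    """Observed Michaelis constant (µM) at modulator concentration L (µM)."""
    u_A, u_B = _weights(scheme, L, "unbound")
    b_A, b_B = _weights(scheme, L, "substrate_bound")
    out = scheme.km_0 * (u_A + u_B) / (b_A + b_B)
    return out if out.ndim else float(out)


def observed_efficiency(scheme: ModulatorScheme, L):
    """Observed specificity constant kcat/Km (s^-1 µM^-1), as the
    population-weighted average over substrate-free weights."""
    if scheme.km_A <= 0 or scheme.km_B <= 0:
        raise ValueError("km_A and km_B must be > 0 for the specificity constant")
    u_A, u_B = _weights(scheme, L, "unbound")
    eff_A = scheme.kcat_A / scheme.km_A
    eff_B = scheme.kcat_B / scheme.km_B
    out = (eff_A * u_A + eff_B * u_B) / (u_A + u_B)
    return out if out.ndim else float(out)


def efficiency_ratio(scheme: ModulatorScheme, L):
    """Specificity constant computed as kcat_obs / km_obs (the alternative
    representation; generally differs from :func:`observed_efficiency`)."""
    out = np.asarray(observed_kcat(scheme, L)) / np.asarray(observed_km(scheme, L))
    return out if out.ndim else float(out)


def efficiency_consistency(scheme: ModulatorScheme, L_grid) -> float:
    """Maximum relative discrepancy between the two specificity-constant
    representations over a grid of modulator concentrations.

    Zero only for degenerate schemes in which the substrate-free and
    substrate-bound weights coincide (and km_A = km_B = km_0); strictly
    positive in general — a diagnostic reported alongside fits.
    """
    L_grid = np.asarray(L_grid, dtype=float)
    if L_grid.size == 0:
        raise ValueError("L_grid must be non-empty")
    eff = np.asarray(observed_efficiency(scheme, L_grid))
    ratio = np.asarray(efficiency_ratio(scheme, L_grid))
    return float(np.max(np.abs(eff - ratio) / ratio))


def velocity(scheme: ModulatorScheme, E0: float, S, L, Ksi: float | None = None):
    """Initial velocity (nM/s) at enzyme E0 (nM), substrate S (µM),
    modulator L (µM).

    Michaelis–Menten within the observed parameters:
    ``v = E0·kcat_obs·S / (km_obs + S)``. With ``Ksi`` set, an uncompetitive
    substrate-inhibition term replaces the denominator S by
    ``S·(1 + S/Ksi)``, reproducing loss of double-reciprocal linearity at
    high substrate.
    """
    if E0 <= 0:
        raise ValueError("enzyme concentration E0 must be > 0")
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be >= 0")
    kcat = np.asarray(observed_kcat(scheme, L))
    km = np.asarray(observed_km(scheme, L))
    denom_S = S * (1.0 + S / Ksi) if Ksi is not None else S
    out = E0 * kcat * S / (km + denom_S)
    return out if out.ndim else float(out)


def ic50(
    scheme: ModulatorScheme,
    E0: float,
    S: float,
    L_max: float = 100.0,
    tolerance: float = 1e-6,
) -> float | None:
    """Modulator concentration halving the velocity at substrate S.

    Scans ``v(L)/v(0) - 1/2`` on a dense grid over (0, L_max] and refines
    the smallest sign change by bisection. Returns ``None`` when the
    velocity never drops to half of its modulator-free value; with several
    crossings the smallest is returned and a warning emitted.
    """
    if L_max <= 0:
        raise ValueError("L_max must be > 0")
    v0 = velocity(scheme, E0, S, 0.0)

    def g(L):
        return velocity(scheme, E0, S, L) / v0 - 0.5

    grid = np.concatenate([[0.0], np.geomspace(max(L_max * 1e-6, 1e-9), L_max, 4096)])
    vals = np.array([g(x) for x in grid])
    signs = np.sign(vals)
    crossings = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
    if crossings.size == 0:
        exact = np.nonzero(vals == 0.0)[0]
        if exact.size and grid[exact[0]] > 0:
            return float(grid[exact[0]])
        return None
    if crossings.size > 1:
        warnings.warn(
            "velocity ratio crosses 1/2 more than once; returning the "
            "smallest crossing",
            stacklevel=2,
        )
    lo, hi = grid[crossings[0]], grid[crossings[0] + 1]
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if g(lo) * g(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return float(0.5 * (lo + hi))
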