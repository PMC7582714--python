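"""Staged, constrained fitting of the two-state scheme to a catalytic
profile, with (n, m) model selection.

The procedure mirrors the staged logic of the modulation analysis:

Stage 1 (turnover): the observed-kcat curve determines kcat_A, kcat_B,
K_AL, K_BL and L_L. These are then frozen.

Stage 2 (affinity): the observed-Km and specificity-constant curves jointly
determine km_0, K_AU, K_BU, L_U and, when m >= 1, K_BI. Constraints of the
canonical two-state model are honored throughout: binding constants are
occupancy-independent, sigma_A = sigma_B = 1, K_AI = 0. km_A is tied to
km_0 (the modulator-free Michaelis constant); km_B is floated only when the
printed specificity-constant expression is the fitting target, otherwise it
is reported at its thermodynamic-cycle-implied value.

Site numbers are selected by a minimal-(n, m) rule: the lexicographically
smallest pair whose total RSS is within a relative margin of the global
best over the candidate grid.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .scheme import ModulatorScheme

__all__ = [
    "StageResult",
    "FitResult",
    "SelectionResult",
    "goodness_of_fit",
    "profile_from_arrays",
    "fit_turnover_stage",
    "fit_affinity_stage",
    "fit_scheme",
    "select_site_numbers",
    "bootstrap_confidence",
]

logger = logging.getLogger(__name__)

#: Absolute RSS floor added to the selection threshold so that the relative
#: margin stays meaningful when the best RSS is numerically zero (noiseless
#: data); set at the optimizer-tolerance scale.
RSS_FLOOR = 1e-16

# log10 bounds per parameter class
_BOUNDS = {
    "kcat": (1e-4, 1e4),
    "km": (1e-3, 1e5),
    "K": (1e-8, 1e6),
    "L": (1e-15, 1e6),
}
_PARAM_CLASS = {
    "kcat_A": "kcat",
    "kcat_B": "kcat",
    "km_0": "km",
    "km_B": "km",
    "K_AL": "K",
    "K_BL": "K",
    "K_AU": "K",
    "K_BU": "K",
    "K_BI": "K",
    "L_L": "L",
    "L_U": "L",
}
# multi-start jitter half-width, decades
_JITTER = {"kcat": 0.3, "km": 0.5, "K": 1.5, "L": 2.5}


# --------------------------------------------------------------------------
# generic pieces
# --------------------------------------------------------------------------


def goodness_of_fit(observed, predicted) -> tuple[float, float]:
    """(r_squared, RSS) of predicted against observed.

    r_squared = 1 - RSS/TSS with TSS about the observed mean; when TSS is
    zero (constant observations) r_squared is NaN and only RSS is
    meaningful.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if observed.size < 2:
        raise ValueError("need at least 2 points")
    rss = float(np.sum((observed - predicted) ** 2))
    tss = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    return r2, rss


def profile_from_arrays(L, Y) -> pd.DataFrame:
    """Minimal catalytic-profile frame from a modulator grid and a
    (len(L), 3) array of (kcat_obs, km_obs, efficiency_obs)."""
    L = np.asarray(L, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.shape != (L.size, 3):
        raise ValueError("Y must have shape (len(L), 3)")
    return pd.DataFrame(
        {
            "modulator_uM": L,
            "kcat_obs_per_s": Y[:, 0],
            "km_obs_uM": Y[:, 1],
            "eff_obs": Y[:, 2],
        }
    )


def _profile_arrays(profile: pd.DataFrame):
    required = ["modulator_uM", "kcat_obs_per_s", "km_obs_uM", "eff_obs"]
    missing = [c for c in required if c not in profile.columns]
    if missing:
        raise ValueError(f"profile missing columns: {missing}")
    frame = profile.sort_values("modulator_uM")
    L = frame["modulator_uM"].to_numpy(float)
    kcat = frame["kcat_obs_per_s"].to_numpy(float)
    km = frame["km_obs_uM"].to_numpy(float)
    eff = frame["eff_obs"].to_numpy(float)
    if np.any(kcat <= 0) or np.any(km <= 0) or np.any(eff <= 0):
        raise ValueError("profile rows must have positive kcat, km, efficiency")
    return L, kcat, km, eff


def _kcat_curve(L, p, n):
    wA = (1.0 + p["K_AL"] * L) ** n
    wB = p["L_L"] * (1.0 + p["K_BL"] * L) ** n
    return (p["kcat_A"] * wA + p["kcat_B"] * wB) / (wA + wB)


def _km_curve(L, p, n, m):
    U = (1.0 + p["K_AU"] * L) ** n + p["L_U"] * (1.0 + p["K_BI"] * L) ** m * (
        1.0 + p["K_BU"] * L
    ) ** n
    D = (1.0 + p["K_AL"] * L) ** n + p["L_L"] * (1.0 + p["K_BL"] * L) ** n
    return p["km_0"] * U / D


def _eff_curve_printed(L, p, n, m):
    # population-weighted specificity constant over substrate-free weights
    wA = (1.0 + p["K_AU"] * L) ** n
    wB = p["L_U"] * (1.0 + p["K_BI"] * L) ** m * (1.0 + p["K_BU"] * L) ** n
    eff_A = p["kcat_A"] / p["km_0"]  # km_A tied to km_0
    eff_B = p["kcat_B"] / p["km_B"]
    return (eff_A * wA + eff_B * wB) / (wA + wB)


def _multistart(residual_fn, names, centers, n_starts, random_state, max_nfev=4000):
    """Bounded least squares on log10-transformed positive parameters with a
    deterministic multi-start: the heuristic center first, then seeded
    log-uniform jitters. Returns (best params dict, best cost 2*RSS/2)."""
    lo = np.array([np.log10(_BOUNDS[_PARAM_CLASS[k]][0]) for k in names])
    hi = np.array([np.log10(_BOUNDS[_PARAM_CLASS[k]][1]) for k in names])
    x0_base = np.clip(
        np.array([np.log10(max(centers[k], 1e-300)) for k in names]), lo, hi
    )
    jit = np.array([_JITTER[_PARAM_CLASS[k]] for k in names])

    def fun(x):
        params = dict(zip(names, 10.0**x))
        return residual_fn(params)

    best_x, best_cost = None, np.inf
    for start in range(n_starts):
        if start == 0:
            x0 = x0_base
        else:
            rng = np.random.default_rng([int(random_state), start])
            x0 = np.clip(x0_base + jit * rng.uniform(-1.0, 1.0, len(names)), lo, hi)
        try:
            sol = least_squares(
                fun,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=max_nfev,
            )
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            logger.debug("start %d failed: %s", start, exc)
            continue
        if sol.cost < best_cost:
            best_cost, best_x = sol.cost, sol.x
    if best_x is None:
        raise RuntimeError("all optimizer starts failed")
    params = dict(zip(names, 10.0**best_x))
    rss = float(2.0 * best_cost)
    return params, rss


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


@dataclass
class StageResult:
    """Outcome of one fitting stage: parameter values, per-parameter status
    (fitted | fixed | tied | degenerate), RSS of the stage's relative
    residuals, r_squared per curve, and a degeneracy flag."""

    params: dict
    status: dict
    rss: float
    r_squared: dict
    degenerate: bool = False


def _flag_bound_hits(params: dict, status: dict) -> None:
    """Mark fitted parameters sitting within a decade of an optimizer bound:
    the data did not determine them (ridge or saturation), only the bound
    did. Statuses are downgraded in place and a warning emitted."""
    for name, value in params.items():
        if status.get(name) != "fitted" or value is None:
            continue
        lo, hi = _BOUNDS[_PARAM_CLASS[name]]
        if value <= lo * 10 or value >= hi / 10:
            status[name] = "bound-hit"
            warnings.warn(
                f"{name} = {value:.3g} sits at an optimizer bound; "
                "treat its value as unidentified",
                stacklevel=3,
            )


def _check_profile_for_fit(L):
    if np.unique(L).size < 5:
        raise ValueError("need >= 5 distinct modulator concentrations")
    if L.min() > 0:
        raise ValueError("profile must include the modulator-free point (L = 0)")


def _flat_constant(y):
    # constant c minimizing sum((c - y)^2 / y^2)
    return float(np.sum(1.0 / y) / np.sum(1.0 / y**2))


def fit_turnover_stage(
    profile: pd.DataFrame,
    n: int,
    n_starts: int = 8,
    random_state: int = 0,
    equal_kcat: bool = False,
) -> StageResult:
    """Fit the observed-kcat curve for (kcat_A, kcat_B, K_AL, K_BL, L_L).

    A profile with no modulator dependence of kcat (relative spread below
    0.1%), or the ``equal_kcat`` constraint, triggers the degenerate branch:
    kcat_A = kcat_B is returned and the substrate-bound binding parameters
    are marked unidentified (a flat curve carries no information on them).
    """
    L, kcat_obs, _, _ = _profile_arrays(profile)
    _check_profile_for_fit(L)

    spread = (kcat_obs.max() - kcat_obs.min()) / kcat_obs.mean()
    if equal_kcat or spread < 1e-3:
        c = _flat_constant(kcat_obs)
        resid = (c - kcat_obs) / kcat_obs
        r2, _ = goodness_of_fit(kcat_obs, np.full_like(kcat_obs, c))
        return StageResult(
            params={"kcat_A": c, "kcat_B": c, "K_AL": None, "K_BL": None, "L_L": None},
            status={
                "kcat_A": "fitted",
                "kcat_B": "tied" if equal_kcat else "fitted",
                "K_AL": "degenerate",
                "K_BL": "degenerate",
                "L_L": "degenerate",
            },
            rss=float(np.sum(resid**2)),
            r_squared={"kcat": r2},
            degenerate=True,
        )

    names = ["kcat_A", "kcat_B", "K_AL", "K_BL", "L_L"]
    # heuristic centers: end-point turnovers, transition midpoint for K_BL
    i0 = int(np.argmin(L))
    i1 = int(np.argmax(L))
    half = 0.5 * (kcat_obs[i0] + kcat_obs[i1])
    L_pos = L[L > 0]
    mid_idx = int(np.argmin(np.abs(kcat_obs - half)))
    L_mid = L[mid_idx] if L[mid_idx] > 0 else float(np.median(L_pos))
    centers = {
        "kcat_A": max(kcat_obs[i0], 1e-4),
        "kcat_B": max(kcat_obs[i1], 1e-4),
        "K_AL": 0.01 / L_mid,
        "K_BL": 10.0 / L_mid,
        "L_L": 1e-4,
    }

    def residuals(p):
        return (_kcat_curve(L, p, n) - kcat_obs) / kcat_obs

    params, rss = _multistart(residuals, names, centers, n_starts, random_state)
    r2, _ = goodness_of_fit(kcat_obs, _kcat_curve(L, params, n))
    status = {k: "fitted" for k in names}
    _flag_bound_hits(params, status)
    return StageResult(
        params=params,
        status=status,
        rss=rss,
        r_squared={"kcat": r2},
        degenerate=False,
    )


def fit_affinity_stage(
    profile: pd.DataFrame,
    fixed: StageResult,
    n: int,
    m: int,
    efficiency_model: str = "eq3",
    fixed_params: dict | None = None,
    n_starts: int = 8,
    random_state: int = 0,
) -> StageResult:
    """Joint fit of the observed-Km and specificity-constant curves for
    (km_0, K_AU, K_BU, L_U) plus K_BI when m >= 1, with the turnover-stage
    parameters frozen.

    ``efficiency_model`` selects the representation fitted to the
    efficiency column: ``"ratio"`` (kcat_obs/km_obs — consistent with how a
    catalytic profile computes it; default) or ``"eq3"`` (the printed
    population-weighted specificity constant, which additionally floats
    km_B). Equal weights on relative residuals of the two curves.

    ``fixed_params`` pins named stage-2 parameters at known values (e.g.
    carrying wild-type binding constants over to a gate-disrupted mutant).
    If the turnover stage was degenerate, its unidentified substrate-bound
    parameters (K_AL, K_BL, L_L) are re-floated here unless pinned — they
    still enter the observed-Km denominator.
    """
    if efficiency_model not in ("ratio", "eq3"):
        raise ValueError("efficiency_model must be 'ratio' or 'eq3'")
    fixed_params = dict(fixed_params or {})
    L, _, km_obs, eff_obs = _profile_arrays(profile)
    _check_profile_for_fit(L)

    frozen = {k: v for k, v in fixed.params.items() if v is not None}
    names = ["km_0", "K_AU", "K_BU", "L_U"]
    if m >= 1:
        names.append("K_BI")
    if efficiency_model == "eq3":
        names.append("km_B")
    if fixed.degenerate:
        for extra in ("K_AL", "K_BL", "L_L"):
            if extra not in fixed_params:
                names.append(extra)
    for pinned in fixed_params:
        if pinned in names:
            names.remove(pinned)

    km0_guess = float(km_obs[np.argmin(L)])
    L_pos = L[L > 0]
    half = 0.5 * (km_obs[np.argmin(L)] + km_obs[np.argmax(L)])
    mid_idx = int(np.argmin(np.abs(km_obs - half)))
    L_mid = L[mid_idx] if L[mid_idx] > 0 else float(np.median(L_pos))
    centers = {
        "km_0": km0_guess,
        "K_AU": 0.01 / L_mid,
        "K_BU": 10.0 / L_mid,
        "L_U": frozen.get("L_L") or 1e-5,
        "K_BI": 1.0 / float(L.max() if L.max() > 0 else 1.0),
        "km_B": max(float(km_obs.min()), 1e-3),
        "K_AL": 0.01 / L_mid,
        "K_BL": 10.0 / L_mid,
        "L_L": 1e-4,
    }

    def assemble(p):
        full = dict(frozen)
        full.update(fixed_params)
        full.update(p)
        full.setdefault("K_BI", 0.0)
        return full

    def residuals(p):
        full = assemble(p)
        km_model = _km_curve(L, full, n, m)
        if efficiency_model == "ratio":
            eff_model = _kcat_curve(L, full, n) / km_model
        else:
            eff_model = _eff_curve_printed(L, full, n, m)
        return np.concatenate(
            [(km_model - km_obs) / km_obs, (eff_model - eff_obs) / eff_obs]
        )

    params, rss = _multistart(residuals, names, centers, n_starts, random_state)
    full = assemble(params)
    km_pred = _km_curve(L, full, n, m)
    if efficiency_model == "ratio":
        eff_pred = _kcat_curve(L, full, n) / km_pred
    else:
        eff_pred = _eff_curve_printed(L, full, n, m)
    r2_km, _ = goodness_of_fit(km_obs, km_pred)
    r2_eff, _ = goodness_of_fit(eff_obs, eff_pred)

    status = {k: "fitted" for k in params}
    # identifiability: e.g. m >= 1 without a Km upturn leaves K_BI at a bound
    _flag_bound_hits(params, status)
    for pinned in fixed_params:
        status[pinned] = "fixed"
    if m == 0:
        status["K_BI"] = "fixed"
    out_params = dict(params)
    out_params.update(fixed_params)
    if m == 0:
        out_params.setdefault("K_BI", 0.0)
    return StageResult(
        params=out_params,
        status=status,
        rss=rss,
        r_squared={"km": r2_km, "efficiency": r2_eff},
        degenerate=False,
    )


# --------------------------------------------------------------------------
# combined fit and selection
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    """Fitted scheme with per-parameter provenance and stage diagnostics."""

    scheme: ModulatorScheme
    n: int
    m: int
    status: dict
    rss: dict  # per stage + total
    r_squared: dict  # per curve
    degenerate_turnover: bool
    efficiency_model: str
    intervals: dict | None = None

    @property
    def total_rss(self) -> float:
        return self.rss["total"]

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.to_dict(),
            "n": self.n,
            "m": self.m,
            "parameter_status": self.status,
            "rss": self.rss,
            "r_squared": self.r_squared,
            "degenerate_turnover": self.degenerate_turnover,
            "efficiency_model": self.efficiency_model,
            "confidence_intervals_95": self.intervals,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _implied_km_B(p, n) -> float:
    """Thermodynamic-cycle-implied Michaelis constant of conformation B:
    the high-modulator limit of the observed Km for m = 0."""
    return p["km_0"] * (p["L_U"] * p["K_BU"] ** n) / (p["L_L"] * p["K_BL"] ** n)


def fit_scheme(
    profile: pd.DataFrame,
    n: int,
    m: int,
    efficiency_model: str = "eq3",
    fixed_params: dict | None = None,
    n_starts: int = 8,
    random_state: int = 0,
    equal_kcat: bool = False,
    temperature_K: float = 310.15,
) -> FitResult:
    """Run both stages at fixed (n, m) and assemble a full scheme.

    Stage-1 parameters are frozen bit-identically before stage 2. km_A is
    tied to km_0; km_B is floated only under ``efficiency_model='eq3'``,
    otherwise reported at its cycle-implied value (status ``derived``).
    """
    stage1 = fit_turnover_stage(
        profile,
        n,
        n_starts=n_starts,
        random_state=random_state,
        equal_kcat=equal_kcat,
    )
    stage2 = fit_affinity_stage(
        profile,
        stage1,
        n,
        m,
        efficiency_model=efficiency_model,
        fixed_params=fixed_params,
        n_starts=n_starts,
        random_state=random_state,
    )
    p = {k: v for k, v in stage1.params.items() if v is not None}
    p.update(stage2.params)

    status = dict(stage1.status)
    for k, v in stage2.status.items():
        status[k] = f"stage2:{v}" if v == "fitted" else v
    for k, v in stage1.status.items():
        if v == "fitted":
            status[k] = "stage1:fitted"
        elif v == "degenerate" and k in stage2.params:
            status[k] = "stage2:fitted"

    status["km_A"] = "tied:km_0"
    if "km_B" in p:
        status["km_B"] = "stage2:fitted"
    else:
        p["km_B"] = _implied_km_B(p, n)
        status["km_B"] = "derived:cycle"
    status["K_AI"] = "fixed"
    status["sigma_A"] = "fixed"
    status["sigma_B"] = "fixed"

    scheme = ModulatorScheme(
        kcat_A=p["kcat_A"],
        kcat_B=p["kcat_B"],
        km_0=p["km_0"],
        km_A=p["km_0"],
        km_B=p["km_B"],
        K_AU=p["K_AU"],
        K_BU=p["K_BU"],
        K_AL=p["K_AL"],
        K_BL=p["K_BL"],
        K_BI=p.get("K_BI", 0.0),
        L_U=p["L_U"],
        L_L=p["L_L"],
        n=n,
        m=m,
        temperature_K=temperature_K,
    )
    rss = {
        "turnover": stage1.rss,
        "affinity": stage2.rss,
        "total": stage1.rss + stage2.rss,
    }
    r2 = dict(stage1.r_squared)
    r2.update(stage2.r_squared)
    return FitResult(
        scheme=scheme,
        n=n,
        m=m,
        status=status,
        rss=rss,
        r_squared=r2,
        degenerate_turnover=stage1.degenerate,
        efficiency_model=efficiency_model,
    )


@dataclass
class SelectionResult:
    """Outcome of minimal-(n, m) selection."""

    n: int
    m: int
    table: pd.DataFrame
    best_fit: FitResult
    rss_margin: float


def select_site_numbers(
    profile: pd.DataFrame,
    n_candidates=(1, 2, 3, 4),
    m_candidates=(0, 1, 2),
    rss_margin: float = 0.05,
    efficiency_model: str = "eq3",
    fixed_params: dict | None = None,
    n_starts: int = 8,
    random_state: int = 0,
    equal_kcat: bool = False,
    temperature_K: float = 310.15,
) -> SelectionResult:
    """Select site numbers by the minimal-(n, m) rule.

    Both stages are run for every candidate pair; the selected pair is the
    lexicographically smallest (n first, then m) whose total RSS is within
    ``rss_margin`` (relative) of the global best — the smallest model that
    still accounts for the data. Ties resolve toward smaller n, then m.
    """
    if not n_candidates or not m_candidates:
        raise ValueError("candidate grids must be non-empty")
    pairs = [(int(n), int(m)) for n in sorted(n_candidates) for m in sorted(m_candidates)]
    fits: dict[tuple[int, int], FitResult] = {}
    rows = []
    for n, m in pairs:
        fit = fit_scheme(
            profile,
            n,
            m,
            efficiency_model=efficiency_model,
            fixed_params=fixed_params,
            n_starts=n_starts,
            random_state=random_state,
            equal_kcat=equal_kcat,
            temperature_K=temperature_K,
        )
        fits[(n, m)] = fit
        rows.append(
            {
                "n": n,
                "m": m,
                "rss_turnover": fit.rss["turnover"],
                "rss_affinity": fit.rss["affinity"],
                "rss_total": fit.rss["total"],
            }
        )
    table = pd.DataFrame(rows)
    best_rss = table["rss_total"].min()
    threshold = best_rss * (1.0 + rss_margin) + RSS_FLOOR
    table["acceptable"] = table["rss_total"] <= threshold
    for n, m in pairs:  # lexicographic order
        row = table[(table["n"] == n) & (table["m"] == m)].iloc[0]
        if row["acceptable"]:
            selected = (n, m)
            break
    table["selected"] = [
        (r["n"], r["m"]) == selected for _, r in table.iterrows()
    ]
    logger.info("selected (n, m) = %s (best RSS %.3g, margin %.0f%%)",
                selected, best_rss, 100 * rss_margin)
    return SelectionResult(
        n=selected[0],
        m=selected[1],
        table=table,
        best_fit=fits[selected],
        rss_margin=rss_margin,
    )


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------


def bootstrap_confidence(
    profile: pd.DataFrame,
    fit: FitResult,
    n_boot: int = 200,
    seed: int = 0,
    n_starts: int = 4,
) -> dict:
    """Residual-bootstrap 95% percentile intervals for the floated
    parameters of a fit.

    Residuals of the three profile curves are resampled with replacement
    (jointly, preserving the row structure), added back to the fitted
    curves, and the staged fit is repeated at the fitted (n, m). Replicates
    whose refit fails are dropped and counted; more than 20% failures emits
    a warning. Fully reproducible for a given seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for percentile intervals")
    L, kcat_obs, km_obs, eff_obs = _profile_arrays(profile)
    p = {f: getattr(fit.scheme, f) for f in (
        "kcat_A", "kcat_B", "km_0", "km_B", "K_AU", "K_BU", "K_AL", "K_BL",
        "K_BI", "L_U", "L_L",
    )}
    pred_kcat = _kcat_curve(L, p, fit.n)
    pred_km = _km_curve(L, p, fit.n, fit.m)
    if fit.efficiency_model == "ratio":
        pred_eff = pred_kcat / pred_km
    else:
        pred_eff = _eff_curve_printed(L, p, fit.n, fit.m)
    resid = np.column_stack(
        [kcat_obs - pred_kcat, km_obs - pred_km, eff_obs - pred_eff]
    )
    floated = [k for k, v in fit.status.items() if str(v).endswith("fitted")]
    rng = np.random.default_rng(seed)
    draws: dict[str, list] = {k: [] for k in floated}
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, L.size, L.size)
        boot = profile_from_arrays(
            L,
            np.column_stack(
                [
                    np.maximum(pred_kcat + resid[idx, 0], 1e-12),
                    np.maximum(pred_km + resid[idx, 1], 1e-12),
                    np.maximum(pred_eff + resid[idx, 2], 1e-12),
                ]
            ),
        )
        try:
            refit = fit_scheme(
                boot,
                fit.n,
                fit.m,
                efficiency_model=fit.efficiency_model,
                n_starts=n_starts,
                random_state=seed,
            )
        except (RuntimeError, ValueError):
            failures += 1
            continue
        for k in floated:
            draws[k].append(getattr(refit.scheme, k))
    if failures > 0.2 * n_boot:
        warnings.warn(
            f"{failures}/{n_boot} bootstrap refits failed; intervals may be "
            "unreliable",
            stacklevel=2,
        )
    intervals = {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in draws.items()
        if v
    }
    intervals["_n_failed"] = failures
    return intervals
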