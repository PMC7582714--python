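"""scikit-learn style estimators for steady-state kinetic regression.

These wrap the package's kinetic fits in the fit/predict protocol so they
compose with sklearn pipelines and model selection. ``X`` is always the
controlled concentration variable (substrate for the Michaelis–Menten
regressors, modulator for :class:`TwoStateKineticsFitter`), ``y`` the
measured response.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "LineweaverBurkRegressor",
    "MichaelisMentenRegressor",
    "TwoStateKineticsFitter",
]


def _check_S_v(X, y):
    X = check_array(X, ensure_2d=True, dtype=float)
    if X.shape[1] != 1:
        raise ValueError("X must be a single column of substrate concentrations")
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have inconsistent lengths")
    return X[:, 0], y


class LineweaverBurkRegressor(RegressorMixin, BaseEstimator):
    """Double-reciprocal (Lineweaver–Burk) estimate of kcat and Km.

    Ordinary least squares of ``E0/v`` on ``1/S``:
    intercept = 1/kcat, slope = Km/kcat. The classical linear workflow;
    error amplification at low substrate is inherited by design, and the
    nonlinear :class:`MichaelisMentenRegressor` is the usual cross-check.

    Parameters
    ----------
    enzyme_nM : total enzyme concentration E0, nM.

    Attributes
    ----------
    kcat_ : turnover number, s^-1.
    km_ : Michaelis constant, µM.
    r_squared_ : coefficient of determination of the transformed regression.
    slope_, intercept_ : the regression line in double-reciprocal space.
    nonphysical_ : True when the intercept is <= 0 (kcat undefined or
        negative); values are still returned, flagged.
    """

    def __init__(self, enzyme_nM: float = 2.0):
        self.enzyme_nM = enzyme_nM

    def fit(self, X, y):
        S, v = _check_S_v(X, y)
        if S.shape[0] < 2:
            raise ValueError("need at least 2 points for a double-reciprocal fit")
        if np.unique(S).size < 2:
            raise ValueError("need at least 2 distinct substrate concentrations")
        if np.any(S <= 0):
            raise ValueError("substrate concentrations must be > 0")
        if np.any(v <= 0):
            raise ValueError(
                "velocities must be > 0 for double-reciprocal analysis "
                "(zero-velocity rows must be excluded upstream)"
            )
        x_t = 1.0 / S
        y_t = self.enzyme_nM / v
        res = stats.linregress(x_t, y_t)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.nonphysical_ = self.intercept_ <= 0
        with np.errstate(divide="ignore"):
            self.kcat_ = float(1.0 / self.intercept_)
            self.km_ = float(self.slope_ / self.intercept_)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "kcat_")
        S = check_array(X, ensure_2d=True, dtype=float)[:, 0]
        return self.enzyme_nM * self.kcat_ * S / (self.km_ + S)


class MichaelisMentenRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of v = E0·kcat·S/(Km + S).

    Initial values come from an internal double-reciprocal fit, so on clean
    data the two estimators agree; on noisy data this one is the primary
    estimate (untransformed residuals).

    Attributes
    ----------
    kcat_, km_ : fitted parameters (s^-1, µM).
    r_squared_ : 1 - RSS/TSS of the untransformed fit.
    init_ : (kcat, km) used to start the optimizer.
    """

    def __init__(self, enzyme_nM: float = 2.0, max_nfev: int = 10000):
        self.enzyme_nM = enzyme_nM
        self.max_nfev = max_nfev

    def fit(self, X, y):
        S, v = _check_S_v(X, y)
        if S.shape[0] < 3:
            raise ValueError("need at least 3 points for the nonlinear fit")
        lb = LineweaverBurkRegressor(enzyme_nM=self.enzyme_nM).fit(X, y)
        kcat0 = lb.kcat_ if not lb.nonphysical_ and lb.kcat_ > 0 else np.max(v) / self.enzyme_nM
        km0 = lb.km_ if lb.km_ > 0 else float(np.median(S))
        self.init_ = (float(kcat0), float(km0))

        def mm(S, kcat, km):
            return self.enzyme_nM * kcat * S / (km + S)

        try:
            popt, _ = optimize.curve_fit(
                mm,
                S,
                v,
                p0=self.init_,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=self.max_nfev,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"Michaelis-Menten fit did not converge: {exc}"
            ) from exc
        self.kcat_, self.km_ = float(popt[0]), float(popt[1])
        resid = v - mm(S, *popt)
        tss = float(np.sum((v - v.mean()) ** 2))
        rss = float(np.sum(resid**2))
        self.r_squared_ = 1.0 - rss / tss if tss > 0 else float("nan")
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "kcat_")
        S = check_array(X, ensure_2d=True, dtype=float)[:, 0]
        return self.enzyme_nM * self.kcat_ * S / (self.km_ + S)


class TwoStateKineticsFitter(RegressorMixin, BaseEstimator):
    """Staged constrained fit of the two-state modulation scheme to a
    catalytic profile, with minimal-(n, m) model selection.

    ``X`` is the modulator concentration (µM, single column); ``Y`` has
    three columns: observed kcat (s^-1), observed Km (µM) and observed
    kcat/Km (s^-1 µM^-1) at each modulator concentration.

    Stage 1 fits the turnover curve (kcat_A, kcat_B, K_AL, K_BL, L_L);
    those parameters are then frozen and stage 2 fits the Km and
    specificity-constant curves jointly (km_0, km_B, K_AU, K_BU, L_U, and
    K_BI when m >= 1). When ``n`` or ``m`` is None the pair is selected by
    the smallest-(n, m) rule over the candidate grids: the lexicographically
    first pair whose total RSS is within ``rss_margin`` of the global best.

    Parameters
    ----------
    n, m : site numbers; None triggers selection over the candidate grids.
    n_candidates, m_candidates : grids searched when selecting.
    rss_margin : relative RSS slack of the minimal-(n, m) rule.
    n_starts : multi-starts per stage (deterministic seed list).
    random_state : seed offset for the multi-start jitter.
    equal_kcat : constrain kcat_A = kcat_B (gate-disrupted mutant case).
    temperature_K : assay temperature recorded in the fitted scheme.

    Attributes
    ----------
    scheme_ : fitted :class:`~allokin.scheme.ModulatorScheme`.
    n_, m_ : selected (or imposed) site numbers.
    result_ : full :class:`~allokin.fitting.FitResult`.
    """

    def __init__(
        self,
        n: int | None = None,
        m: int | None = None,
        n_candidates: tuple[int, ...] = (1, 2, 3, 4),
        m_candidates: tuple[int, ...] = (0, 1, 2),
        rss_margin: float = 0.05,
        n_starts: int = 8,
        random_state: int = 0,
        equal_kcat: bool = False,
        temperature_K: float = 310.15,
        efficiency_model: str = "eq3",
        fixed_params: dict | None = None,
    ):
        self.n = n
        self.m = m
        self.n_candidates = n_candidates
        self.m_candidates = m_candidates
        self.rss_margin = rss_margin
        self.n_starts = n_starts
        self.random_state = random_state
        self.equal_kcat = equal_kcat
        self.temperature_K = temperature_K
        self.efficiency_model = efficiency_model
        self.fixed_params = fixed_params

    def fit(self, X, Y):
        from . import fitting

        X = check_array(X, ensure_2d=True, dtype=float)
        Y = check_array(Y, ensure_2d=True, dtype=float)
        if X.shape[1] != 1 or Y.shape[1] != 3:
            raise ValueError(
                "X must be one column (modulator µM) and Y three columns "
                "(kcat_obs, km_obs, efficiency_obs)"
            )
        profile = fitting.profile_from_arrays(X[:, 0], Y)
        if self.n is None or self.m is None:
            selection = fitting.select_site_numbers(
                profile,
                n_candidates=self.n_candidates,
                m_candidates=self.m_candidates,
                rss_margin=self.rss_margin,
                n_starts=self.n_starts,
                random_state=self.random_state,
                equal_kcat=self.equal_kcat,
                temperature_K=self.temperature_K,
                efficiency_model=self.efficiency_model,
                fixed_params=self.fixed_params,
            )
            self.n_, self.m_ = selection.n, selection.m
            self.selection_ = selection
            self.result_ = selection.best_fit
        else:
            self.n_, self.m_ = int(self.n), int(self.m)
            self.result_ = fitting.fit_scheme(
                profile,
                self.n_,
                self.m_,
                n_starts=self.n_starts,
                random_state=self.random_state,
                equal_kcat=self.equal_kcat,
                temperature_K=self.temperature_K,
                efficiency_model=self.efficiency_model,
                fixed_params=self.fixed_params,
            )
        self.scheme_ = self.result_.scheme
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Predicted (kcat_obs, km_obs, efficiency_obs) at modulator X."""
        from . import model

        check_is_fitted(self, "scheme_")
        L = check_array(X, ensure_2d=True, dtype=float)[:, 0]
        return np.column_stack(
            [
                model.observed_kcat(self.scheme_, L),
                model.observed_km(self.scheme_, L),
                model.observed_efficiency(self.scheme_, L),
            ]
        )
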