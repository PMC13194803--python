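"""Parametric survival models and extrapolation of digitized Kaplan–Meier curves.

Published KM plots give coordinates ``(t_i, s_i)`` — time in months and a
survival proportion — without at-risk counts, so likelihood-based fitting is
not available.  Each of the five standard families (exponential, Weibull,
Gompertz, log-logistic, log-normal) is instead fitted by bounded nonlinear
least squares on the survival proportions, scored by the sum of squared
residuals (SSR) together with least-squares information criteria

    AIC = n ln(SSR/n) + 2k,      BIC = n ln(SSR/n) + k ln(n),

with ``k`` the number of family parameters, and the best-scoring family is
selected for extrapolation beyond the trial follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvivalModel",
    "FitDiagnostics",
    "ParametricSurvivalFitter",
    "survival_at",
    "fit_model",
    "fit_all_families",
    "select_model",
    "ranking_table",
]

#: Declared family order: number of parameters, then the tie-break order used
#: by :func:`select_model`.
FAMILIES = ("exponential", "weibull", "gompertz", "loglogistic", "lognormal")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "gompertz": 2,
    "loglogistic": 2,
    "lognormal": 2,
}


@dataclass(frozen=True)
class ParametricSurvivalModel:
    """A named survival distribution with fixed parameters, time in months.

    Parameter order per family:

    - ``exponential``: (rate,) — S(t) = exp(-rate*t)
    - ``weibull``: (shape k, scale lam) — S(t) = exp(-(t/lam)**k)
    - ``gompertz``: (shape eta, rate b) — S(t) = exp(-(b/eta)*(exp(eta*t)-1))
    - ``loglogistic``: (shape beta, scale alpha) — S(t) = 1/(1+(t/alpha)**beta)
    - ``lognormal``: (meanlog mu, sdlog sigma) — S(t) = 1 - Phi((ln t - mu)/sigma)
    """

    family: str
    params: tuple

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        params = tuple(float(p) for p in self.params)
        if len(params) != _N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} takes {_N_PARAMS[self.family]} parameter(s), got {len(params)}"
            )
        object.__setattr__(self, "params", params)
        # positivity constraints (Gompertz shape may be any sign in general,
        # but the decreasing-hazard branch is not used here; require > 0 scale/rate)
        if self.family == "exponential" and params[0] <= 0:
            raise ValueError("exponential rate must be > 0")
        if self.family == "weibull" and (params[0] <= 0 or params[1] <= 0):
            raise ValueError("weibull shape and scale must be > 0")
        if self.family == "gompertz" and params[1] <= 0:
            raise ValueError("gompertz rate must be > 0")
        if self.family == "loglogistic" and (params[0] <= 0 or params[1] <= 0):
            raise ValueError("loglogistic shape and scale must be > 0")
        if self.family == "lognormal" and params[1] <= 0:
            raise ValueError("lognormal sdlog must be > 0")

    def survival(self, t):
        """Evaluate S(t) at times ``t`` (months, scalar or array)."""
        return survival_at(self, t)

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.family]

    def median(self) -> float:
        """Median survival time in months (may be inf)."""
        p = self.params
        if self.family == "exponential":
            return math.log(2.0) / p[0]
        if self.family == "weibull":
            return p[1] * math.log(2.0) ** (1.0 / p[0])
        if self.family == "loglogistic":
            return p[1]
        if self.family == "lognormal":
            return math.exp(p[0])
        # gompertz: S(t)=0.5 -> (b/eta)(e^{eta t}-1)=ln 2
        eta, b = p
        if abs(eta) < 1e-12:
            return math.log(2.0) / b
        arg = 1.0 + eta * math.log(2.0) / b
        if arg <= 0:
            return math.inf
        return math.log(arg) / eta


def survival_at(model: ParametricSurvivalModel, t):
    """S(t) for a parametric model; ``t`` in months, scalar or array, t >= 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("negative times are not allowed")
    s = _survival_unchecked(model.family, np.asarray(model.params), t_arr)
    if np.ndim(t) == 0:
        return float(s)
    return s


def _survival_unchecked(family: str, params: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (rate,) = params
        return np.exp(-rate * t)
    if family == "weibull":
        shape, scale = params
        return np.exp(-np.power(t / scale, shape))
    if family == "gompertz":
        eta, b = params
        if abs(eta) < 1e-10:
            return np.exp(-b * t)
        return np.exp(-(b / eta) * np.expm1(eta * t))
    if family == "loglogistic":
        shape, scale = params
        with np.errstate(divide="ignore"):
            return 1.0 / (1.0 + np.power(t / scale, shape))
    if family == "lognormal":
        mu, sigma = params
        out = np.ones_like(t)
        pos = t > 0
        out[pos] = stats.norm.sf((np.log(t[pos]) - mu) / sigma)
        return out
    raise ValueError(f"unknown family {family!r}")


@dataclass
class FitDiagnostics:
    """Goodness-of-fit summary for one family fitted to one curve."""

    family: str
    ssr: float
    aic: float
    bic: float
    n_points: int
    n_params: int
    converged: bool


def _information_criteria(ssr: float, n: int, k: int) -> tuple[float, float]:
    # Gaussian-residual least-squares form; guard log(0) for perfect fits.
    ssr_eff = max(ssr, 1e-300)
    aic = n * math.log(ssr_eff / n) + 2 * k
    bic = n * math.log(ssr_eff / n) + k * math.log(n)
    return aic, bic


def _initial_guesses(family: str, t: np.ndarray, s: np.ndarray) -> list[np.ndarray]:
    """Data-driven multi-start grid; scale anchored at the empirical median."""
    # crude empirical median: first time survival drops to <= 0.5
    below = np.nonzero(s <= 0.5)[0]
    if below.size:
        med = max(float(t[below[0]]), 1e-3)
    else:
        med = max(float(t[-1]), 1e-3)  # censored above 0.5: median beyond follow-up
    shapes = (0.5, 1.0, 2.0)
    if family == "exponential":
        lam = math.log(2.0) / med
        return [np.array([lam * m]) for m in (0.5, 1.0, 2.0)]
    if family == "weibull":
        return [np.array([k, med / math.log(2.0) ** (1.0 / k)]) for k in shapes]
    if family == "gompertz":
        lam = math.log(2.0) / med
        return [np.array([eta, lam]) for eta in (0.01, 0.1, 0.3)] + [
            np.array([0.05, lam * 0.5])
        ]
    if family == "loglogistic":
        return [np.array([k, med]) for k in shapes]
    if family == "lognormal":
        mu = math.log(med)
        return [np.array([mu, sig]) for sig in (0.5, 1.0, 2.0)]
    raise ValueError(family)


_BOUNDS = {
    "exponential": ([1e-8], [10.0]),
    "weibull": ([1e-3, 1e-3], [20.0, 1e4]),
    "gompertz": ([1e-6, 1e-8], [2.0, 10.0]),
    "loglogistic": ([1e-3, 1e-3], [20.0, 1e4]),
    "lognormal": ([-10.0, 1e-3], [10.0, 10.0]),
}


def fit_model(points: pd.DataFrame, family: str) -> tuple[ParametricSurvivalModel | None, FitDiagnostics]:
    """Fit one family to a digitized curve table by bounded least squares.

    Parameters
    ----------
    points : DataFrame with columns ``time_months`` and ``survival``.
    family : one of :data:`FAMILIES`.

    Returns the fitted model (or ``None`` on failure) and its diagnostics.
    SSR is minimised over a fixed grid of data-driven starting values, keeping
    the best final SSR.  A curve with no decline (all survival equal to 1) is
    non-informative and flagged as not converged.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    t = np.asarray(points["time_months"], dtype=float)
    s = np.asarray(points["survival"], dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 digitized points")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("survival proportions must lie in [0, 1]")
    k = _N_PARAMS[family]
    n = int(t.size)

    if np.all(s >= 1.0 - 1e-12):
        # degenerate: no events observed
        diag = FitDiagnostics(family, math.inf, math.inf, math.inf, n, k, False)
        return None, diag

    lo, hi = _BOUNDS[family]

    def residuals(params):
        return _survival_unchecked(family, params, t) - s

    best = None
    for x0 in _initial_guesses(family, t, s):
        x0 = np.clip(x0, lo, hi)
        try:
            res = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        ssr = float(np.sum(res.fun**2))
        if best is None or ssr < best[0]:
            best = (ssr, res.x)

    if best is None:
        diag = FitDiagnostics(family, math.inf, math.inf, math.inf, n, k, False)
        return None, diag

    ssr, x = best
    aic, bic = _information_criteria(ssr, n, k)
    model = ParametricSurvivalModel(family, tuple(x))
    diag = FitDiagnostics(family, ssr, aic, bic, n, k, True)
    return model, diag


def fit_all_families(points: pd.DataFrame) -> list[tuple[ParametricSurvivalModel | None, FitDiagnostics]]:
    """Fit every family in :data:`FAMILIES` to the same curve."""
    return [fit_model(points, fam) for fam in FAMILIES]


def select_model(
    fits: list[tuple[ParametricSurvivalModel | None, FitDiagnostics]],
    aic_tie_tol: float = 0.01,
) -> tuple[ParametricSurvivalModel, pd.DataFrame]:
    """Pick the extrapolation model: lowest AIC, ties broken by BIC, SSR,
    fewer parameters, then declared family order.

    Returns the chosen model and the full ranking table (one row per fit,
    ``chosen`` flag set) so the qualitative plausibility review the field
    applies on top of the information criteria remains possible.
    """
    converged = [(m, d) for m, d in fits if d.converged and m is not None]
    if not converged:
        raise ValueError("no converged fits to select from")

    order = {fam: i for i, fam in enumerate(FAMILIES)}
    # stable sort on the full tie-break key; AIC bucketed by the tie tolerance
    def key(item):
        m, d = item
        return (round(d.aic / aic_tie_tol), d.bic, d.ssr, d.n_params, order[d.family])

    ranked = sorted(converged, key=key)
    chosen = ranked[0][0]

    rows = []
    for m, d in fits:
        rows.append(
            {
                "family": d.family,
                "params": "" if m is None else ";".join(f"{p:.10g}" for p in m.params),
                "ssr": d.ssr,
                "aic": d.aic,
                "bic": d.bic,
                "n_points": d.n_points,
                "n_params": d.n_params,
                "converged": d.converged,
                "chosen": m is chosen and m is not None,
            }
        )
    report = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    return chosen, report


class ParametricSurvivalFitter:
    """Scikit-learn-style estimator: digitized KM coordinates in, selected
    parametric survival model out.

    Parameters
    ----------
    families : sequence of family names to try (default: all five).
    aic_tie_tol : AIC differences below this are treated as ties.

    Attributes (after :meth:`fit`)
    ------------------------------
    model_ : ParametricSurvivalModel — the selected model.
    ranking_ : DataFrame — family ranking by AIC with SSR/BIC columns.
    fits_ : list of (model, diagnostics) for every attempted family.
    """

    def __init__(self, families=FAMILIES, aic_tie_tol: float = 0.01):
        self.families = families
        self.aic_tie_tol = aic_tie_tol

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"families": self.families, "aic_tie_tol": self.aic_tie_tol}

    def set_params(self, **params):
        for name, value in params.items():
            if name not in ("families", "aic_tie_tol"):
                raise ValueError(f"invalid parameter {name!r}")
            setattr(self, name, value)
        return self

    # -----------------------------------------------------------------------
    def fit(self, X, y=None):
        """Fit all requested families to a curve.

        ``X`` is either a DataFrame with columns ``time_months``/``survival``
        or an (n, 2) array of the same; ``y`` may alternatively carry the
        survival proportions with ``X`` the times.
        """
        if y is not None:
            points = pd.DataFrame({"time_months": np.ravel(X), "survival": np.ravel(y)})
        elif isinstance(X, pd.DataFrame):
            points = X
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("X must be (n, 2): time_months, survival")
            points = pd.DataFrame({"time_months": arr[:, 0], "survival": arr[:, 1]})
        fits = [fit_model(points, fam) for fam in self.families]
        self.model_, self.ranking_ = select_model(fits, self.aic_tie_tol)
        self.fits_ = fits
        return self

    def predict(self, t):
        """S(t) of the selected model on times ``t`` (months)."""
        if not hasattr(self, "model_"):
            raise AttributeError("fit the estimator before calling predict")
        return self.model_.survival(np.asarray(t, dtype=float))


def ranking_table(fits) -> pd.DataFrame:
    """Ranking table without selecting (all fits, converged or not)."""
    _, report = select_model(fits)
    return report
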