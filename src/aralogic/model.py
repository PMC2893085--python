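"""Steady-state input-integration model of the arabinose regulon promoters.

A promoter bound by AraC-arabinose (activity ``A*``), CRP-cAMP (``C*``) or
both transcribes at rates alpha, beta and gamma respectively, all scaled by
the global polymerase signal sigma.  The default, additive form is

    B = sigma * (alpha*A* + beta*C* + gamma*A**C*) + T_B

with basal transcription ``T_B``.  An occupancy-weighted alternative divides
the activation term by the partition sum ``1 + A* + C* + A**C*``.  The fitted
coefficients are relative, not absolute: they absorb the ratio of factor
binding at the synthetic reporters to binding at the native promoters.

Fitting is by nonlinear least squares, with asymptotic standard errors from
the Jacobian, per-coefficient two-sided t-tests against zero, and model
reduction: terms insignificant at the chosen level are dropped, the reduced
model refit, and the two fits compared by residual standard error and AIC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "IntegrationCoefficients",
    "FitResult",
    "ModelComparison",
    "PromoterIntegrationModel",
    "forward_expression",
    "fit_integration_model",
    "coefficient_significance",
    "reduce_and_compare",
    "compute_aic",
]

_ACTIVITY_TERMS = ("alpha", "beta", "gamma")


@dataclass(frozen=True)
class IntegrationCoefficients:
    """Input-integration coefficients of one promoter.

    ``beta=None`` marks the CRP-alone term as structurally absent (dropped
    from the model), as opposed to fitted-and-zero.  ``form`` selects the
    additive (default) or occupancy-weighted activation term.
    """

    alpha: float
    gamma: float
    beta: float | None = None
    basal: float = 0.0
    form: str = "additive"

    def __post_init__(self) -> None:
        if self.form not in ("additive", "occupancy"):
            raise ValueError(f"unknown form {self.form!r}")
        for name in ("alpha", "gamma", "basal"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.beta is not None and not np.isfinite(self.beta):
            raise ValueError("beta must be finite or None")

    @property
    def beta_or_zero(self) -> float:
        return 0.0 if self.beta is None else self.beta

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "basal": self.basal,
            "form": self.form,
        }


@dataclass
class FitResult:
    """One least-squares fit: estimates, uncertainties and fit statistics."""

    coefficients: IntegrationCoefficients
    standard_errors: dict
    t_statistics: dict
    p_values: dict
    rss: float
    rse: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool

    def __post_init__(self) -> None:
        if self.n_obs <= self.n_params:
            raise ValueError("n_obs must exceed n_params")
        for p in self.p_values.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("p-values must lie in [0, 1]")

    def significance_stars(self, term: str) -> str:
        p = self.p_values.get(term)
        if p is None:
            return ""
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "NS"

    def to_record(self) -> dict:
        """Table-style record: per-term estimate, SE, p and stars."""
        coeffs = self.coefficients.as_dict()
        terms = {}
        for term in ("alpha", "beta", "gamma", "basal"):
            est = coeffs.get(term)
            if est is None:
                terms[term] = {"estimate": None, "note": "structurally absent"}
                continue
            terms[term] = {
                "estimate": est,
                "se": self.standard_errors.get(term),
                "p": self.p_values.get(term),
                "stars": self.significance_stars(term),
            }
        return {
            "form": self.coefficients.form,
            "terms": terms,
            "rss": self.rss,
            "rse": self.rse,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
        }


@dataclass
class ModelComparison:
    """Full vs reduced fit after dropping insignificant terms."""

    full: FitResult
    reduced: FitResult
    delta_aic: float
    delta_rse: float
    selected: str  # "full" | "reduced" | "no_reduction"
    dropped: tuple = ()

    def to_record(self) -> dict:
        return {
            "selected": self.selected,
            "dropped": list(self.dropped),
            "delta_aic": self.delta_aic,
            "delta_rse": self.delta_rse,
            "full": self.full.to_record(),
            "reduced": self.reduced.to_record(),
        }


def compute_aic(rss: float, n_obs: int, n_params: int) -> float:
    """Gaussian-likelihood AIC, error variance counted as one extra parameter.

        AIC = n * ln(rss / n) + 2 * (n_params + 1)

    Conventions differ by an additive constant; comparisons between fits on
    the same data are unaffected.  rss = 0 returns -inf with a warning.
    """
    if n_obs <= n_params:
        raise ValueError("n_obs must exceed n_params")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if rss == 0:
        warnings.warn("rss is exactly 0; AIC is -inf", stacklevel=2)
        return float("-inf")
    return n_obs * math.log(rss / n_obs) + 2.0 * (n_params + 1)


def _activation(a, c, coeffs: IntegrationCoefficients):
    term = coeffs.alpha * a + coeffs.beta_or_zero * c + coeffs.gamma * a * c
    if coeffs.form == "occupancy":
        term = term / (1.0 + a + c + a * c)
    return term


def forward_expression(a_star, c_star, sigma, coeffs: IntegrationCoefficients):
    """Promoter expression from measured activities and coefficients."""
    a = np.asarray(a_star, dtype=float)
    c = np.asarray(c_star, dtype=float)
    s = np.asarray(sigma, dtype=float)
    if np.any(a < 0) or np.any(c < 0):
        raise ValueError("activities must be >= 0")
    if np.any(s <= 0):
        raise ValueError("sigma must be > 0")
    out = s * _activation(a, c, coeffs) + coeffs.basal
    if np.isscalar(a_star) and np.isscalar(c_star) and np.isscalar(sigma):
        return float(out)
    return out


def _as_activity_matrix(X) -> np.ndarray:
    """Accept (n, 3) arrays, ActivityProfile frames, or column-named frames."""
    if isinstance(X, pd.DataFrame):
        cols = {c.lower(): c for c in X.columns}
        try:
            X = X[[cols["a_star"], cols["c_star"], cols["sigma"]]].to_numpy(float)
        except KeyError as exc:
            raise ValueError("DataFrame must have columns A_star, C_star, sigma") from exc
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X must be (n_obs, 3): columns A_star, C_star, sigma")
    if not np.all(np.isfinite(X)):
        raise ValueError("activities and sigma must be finite")
    if np.any(X[:, :2] < 0):
        raise ValueError("activities must be >= 0")
    if np.any(X[:, 2] <= 0):
        raise ValueError("sigma must be > 0")
    return X


class PromoterIntegrationModel(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the promoter input-integration model.

    X has three columns (A*, C*, sigma); y is promoter expression (CPS/OD).

    Parameters
    ----------
    terms : tuple of str
        Activity terms included in the model, subset of
        ``("alpha", "beta", "gamma")``.  Excluded terms are structurally zero.
    form : {"additive", "occupancy"}
        Activation term; additive is the default and is linear in the
        coefficients.
    fit_basal : bool
        Fit basal transcription T_B as a free intercept (default) or pin it.
    basal : float
        The pinned value when ``fit_basal=False`` (e.g. a measured uninduced
        mean).
    significance_level : float
        Two-sided level for per-coefficient t-tests.

    Attributes
    ----------
    alpha_, beta_, gamma_, basal_ : float or None
        Point estimates (None where structurally absent).
    coef_ : ndarray of fitted parameters in fit order.
    fit_result_ : FitResult with SEs, p-values, RSS/RSE/AIC.
    converged_ : bool

    Examples
    --------
    >>> import numpy as np
    >>> from aralogic.model import PromoterIntegrationModel, forward_expression
    >>> from aralogic.model import IntegrationCoefficients
    >>> rng = np.random.default_rng(0)
    >>> X = np.column_stack([rng.uniform(0, 3, 50), rng.uniform(0, 3, 50),
    ...                      np.ones(50)])
    >>> truth = IntegrationCoefficients(alpha=2.535, gamma=4.347)
    >>> y = forward_expression(X[:, 0], X[:, 1], X[:, 2], truth)
    >>> m = PromoterIntegrationModel(terms=("alpha", "gamma")).fit(X, y)
    >>> round(m.gamma_, 3)
    4.347
    """

    def __init__(
        self,
        terms: tuple = _ACTIVITY_TERMS,
        form: str = "additive",
        fit_basal: bool = True,
        basal: float = 0.0,
        significance_level: float = 0.05,
    ):
        self.terms = terms
        self.form = form
        self.fit_basal = fit_basal
        self.basal = basal
        self.significance_level = significance_level

    # -- internal plumbing ---------------------------------------------------

    def _param_names(self) -> list[str]:
        names = [t for t in _ACTIVITY_TERMS if t in self.terms]
        if self.fit_basal:
            names.append("basal")
        return names

    def _coeffs_from_vector(self, vec: np.ndarray) -> IntegrationCoefficients:
        names = self._param_names()
        values = dict(zip(names, vec))
        return IntegrationCoefficients(
            alpha=values.get("alpha", 0.0),
            beta=values["beta"] if "beta" in names else None,
            gamma=values.get("gamma", 0.0),
            basal=values.get("basal", self.basal),
            form=self.form,
        )

    def fit(self, X, y):
        X = _as_activity_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        bad = [t for t in self.terms if t not in _ACTIVITY_TERMS]
        if bad:
            raise ValueError(f"unknown terms {bad}; allowed: {_ACTIVITY_TERMS}")
        names = self._param_names()
        k = len(names)
        n = y.shape[0]
        if n <= k:
            raise ValueError(f"need n_obs > n_params ({n} <= {k})")

        a, c, s = X[:, 0], X[:, 1], X[:, 2]
        denom = (1.0 + a + c + a * c) if self.form == "occupancy" else 1.0
        regressor_map = {
            "alpha": s * a / denom,
            "beta": s * c / denom,
            "gamma": s * a * c / denom,
            "basal": np.ones(n),
        }
        design = np.column_stack([regressor_map[t] for t in names])
        if np.linalg.matrix_rank(design) < k:
            raise np.linalg.LinAlgError(
                "singular fit: the design is rank-deficient "
                "(constant or collinear activities)"
            )
        offset = 0.0 if self.fit_basal else self.basal

        def residuals(vec):
            return design @ vec + offset - y

        x0 = np.zeros(k)
        sol = optimize.least_squares(residuals, x0, jac=lambda v: design, method="lm")
        if not sol.success:
            warnings.warn(f"least-squares fit did not converge: {sol.message}", stacklevel=2)

        est = sol.x
        res = residuals(est)
        rss = float(res @ res)
        dof = n - k
        rse = math.sqrt(rss / dof)
        jtj = design.T @ design
        cov = rse**2 * np.linalg.inv(jtj)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, est / se, np.inf * np.sign(est))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

        coeffs = self._coeffs_from_vector(est)
        neg_sig = [
            t for t, e, p in zip(names, est, pvals)
            if t != "basal" and e < 0 and p < self.significance_level
        ]
        if neg_sig:
            warnings.warn(
                f"significant negative coefficient(s): {neg_sig}; "
                "no non-negativity constraint is imposed",
                stacklevel=2,
            )

        self.param_names_ = names
        self.coef_ = est
        self.alpha_ = coeffs.alpha if "alpha" in names else None
        self.beta_ = coeffs.beta
        self.gamma_ = coeffs.gamma if "gamma" in names else None
        self.basal_ = coeffs.basal
        self.converged_ = bool(sol.success)
        self.fit_result_ = FitResult(
            coefficients=coeffs,
            standard_errors=dict(zip(names, se)),
            t_statistics=dict(zip(names, tvals)),
            p_values=dict(zip(names, pvals)),
            rss=rss,
            rse=rse,
            aic=compute_aic(rss, n, k) if rss > 0 else float("-inf"),
            n_obs=n,
            n_params=k,
            converged=bool(sol.success),
        )
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        if not hasattr(self, "fit_result_"):
            raise AttributeError("model is not fitted yet; call fit first")
        X = _as_activity_matrix(X)
        return forward_expression(X[:, 0], X[:, 1], X[:, 2], self.fit_result_.coefficients)

    def significant_terms(self, level: float | None = None) -> dict:
        """Per-term significance flags from the fitted t-tests."""
        if not hasattr(self, "fit_result_"):
            raise AttributeError("model is not fitted yet; call fit first")
        return coefficient_significance(
            self.fit_result_, self.significance_level if level is None else level
        )


def fit_integration_model(
    dataset,
    y=None,
    terms: tuple = _ACTIVITY_TERMS,
    form: str = "additive",
    fit_basal: bool = True,
    basal: float = 0.0,
) -> FitResult:
    """Fit the integration model; thin wrapper over PromoterIntegrationModel.

    ``dataset`` is either a DataFrame with columns A_star, C_star, sigma and
    (if ``y`` is None) a ``expression`` column, or an (n, 3) array with ``y``
    given separately.
    """
    if y is None:
        if not isinstance(dataset, pd.DataFrame) or "expression" not in dataset.columns:
            raise ValueError("pass y explicitly or a DataFrame with an 'expression' column")
        y = dataset["expression"].to_numpy(float)
    model = PromoterIntegrationModel(
        terms=terms, form=form, fit_basal=fit_basal, basal=basal
    ).fit(dataset, y)
    return model.fit_result_


def coefficient_significance(fit: FitResult, level: float = 0.05) -> dict:
    """Two-sided t-test flags per fitted term (True = significant at level)."""
    if not fit.converged:
        raise ValueError("fit did not converge; significance is not meaningful")
    if fit.n_obs - fit.n_params <= 0:
        raise ValueError("zero residual degrees of freedom")
    return {term: bool(p < level) for term, p in fit.p_values.items()}


def reduce_and_compare(
    dataset,
    y=None,
    full_fit: FitResult | None = None,
    level: float = 0.05,
    form: str = "additive",
    fit_basal: bool = True,
    basal: float = 0.0,
) -> ModelComparison:
    """Drop activity terms insignificant at ``level``, refit, compare fits.

    Basal transcription is never dropped.  The reduced model is selected iff
    its AIC improves on the full model's.  If every term is significant the
    comparison reports ``selected="no_reduction"`` with the reduced fit equal
    to the full fit.  Dropping every activity term leaves an intercept-only
    model; a degenerate-model warning is raised but the comparison is still
    returned.
    """
    if isinstance(dataset, pd.DataFrame) and y is None:
        y = dataset["expression"].to_numpy(float)
    if full_fit is None:
        full_fit = fit_integration_model(
            dataset, y, terms=_ACTIVITY_TERMS, form=form, fit_basal=fit_basal, basal=basal
        )
    if not full_fit.converged:
        raise ValueError("full fit did not converge")
    flags = coefficient_significance(full_fit, level)
    full_terms = tuple(t for t in _ACTIVITY_TERMS if t in full_fit.p_values)
    keep = tuple(t for t in full_terms if flags.get(t, False))
    dropped = tuple(t for t in full_terms if t not in keep)
    if not dropped:
        return ModelComparison(
            full=full_fit, reduced=full_fit, delta_aic=0.0, delta_rse=0.0,
            selected="no_reduction", dropped=(),
        )
    if not keep:
        warnings.warn(
            "all activity terms dropped; reduced model is basal-only (degenerate)",
            stacklevel=2,
        )
    reduced_fit = fit_integration_model(
        dataset, y, terms=keep, form=form, fit_basal=fit_basal, basal=basal
    )
    delta_aic = reduced_fit.aic - full_fit.aic
    delta_rse = reduced_fit.rse - full_fit.rse
    selected = "reduced" if reduced_fit.aic < full_fit.aic else "full"
    return ModelComparison(
        full=full_fit, reduced=reduced_fit, delta_aic=delta_aic,
        delta_rse=delta_rse, selected=selected, dropped=dropped,
    )
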