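"""Binary logistic regression with margins and seeded bootstrap intervals.

``fit_logit`` is a thin, contract-enforcing surface over iteratively
reweighted least squares (statsmodels GLM/Binomial): grouped (frequency
weighted) and expanded unit-level data give identical coefficients, perfect
separation fails loudly, and the fit carries everything the postestimation
battery needs (coefficients, covariance, model and null log-likelihoods,
fitted probabilities).

``conditional_margins`` computes per-score-level predicted probabilities and
treatment contrasts with delta-method standard errors, optionally widening
the interval set with the Sidak multiple-comparison correction
alpha' = 1 - (1 - alpha)^(1/m) across the m reported intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

__all__ = [
    "LogitFit",
    "MarginSet",
    "SeparationError",
    "fit_logit",
    "predict_prob",
    "odds_ratios",
    "conditional_margins",
    "bootstrap_ci",
]

_CONV_TOL = 1e-10
_MAX_ITER = 100


class SeparationError(RuntimeError):
    """The likelihood is monotone (perfectly separated data)."""


@dataclass
class LogitFit:
    """A fitted binary logit.

    ``params`` are log-odds coefficients indexed by term name; ``cov`` is
    their estimated covariance; ``n`` is the (weighted) sample size and ``k``
    the parameter count.  ``fitted`` holds per-row event probabilities for the
    design the model was fit on.
    """

    terms: list[str]
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n: float
    k: int
    fitted: np.ndarray
    design: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    def linear_predictor(self, design: np.ndarray | None = None) -> np.ndarray:
        X = self.design if design is None else np.atleast_2d(design)
        return X @ self.params

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_p(self) -> np.ndarray:
        z = self.params / self.se()
        return 2.0 * stats.norm.sf(np.abs(z))

    def to_dict(self) -> dict:
        ors, lo, hi = odds_ratios(self)
        return {
            "terms": self.terms,
            "coefficients": self.params.tolist(),
            "se": self.se().tolist(),
            "p": self.wald_p().tolist(),
            "odds_ratios": ors.tolist(),
            "or_ci_low": lo.tolist(),
            "or_ci_high": hi.tolist(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "n": self.n,
            "k": self.k,
        }


def _as_design(design, add_intercept: bool) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        X = design.to_numpy(dtype=float)
        names = [str(c) for c in design.columns]
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        names = [f"x{j}" for j in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["const"] + names
    return X, names


def fit_logit(
    outcome: Sequence[int],
    design,
    weights: Sequence[float] | None = None,
    add_intercept: bool = True,
) -> LogitFit:
    """Maximum-likelihood binary logit via IRLS.

    ``design`` is a DataFrame (term names from columns) or array; an
    intercept column is prepended unless ``add_intercept`` is False.
    ``weights`` are frequency weights (grouped data); fitting grouped counts
    and their unit-record expansion gives identical coefficients.

    Raises :class:`SeparationError` when the MLE diverges (monotone
    likelihood) and ``RuntimeError`` on non-convergence.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    X, names = _as_design(design, add_intercept)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    def _glm_fit(Xmat: np.ndarray):
        model = sm.GLM(y, Xmat, family=sm.families.Binomial(), freq_weights=w)
        return model.fit(maxiter=_MAX_ITER, tol=_CONV_TOL)

    res = _glm_fit(X)
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge in {_MAX_ITER} iterations")
    if np.any(np.abs(res.params) > 25.0):
        raise SeparationError(
            "coefficients diverged; data are (quasi-)separated: "
            + ", ".join(f"{n}={p:.1f}" for n, p in zip(names, res.params)
                        if abs(p) > 25.0)
        )
    fitted = np.asarray(res.predict(X))

    n_tot = float(w.sum())
    # Intercept-only fit for the null log-likelihood (closed form).
    pbar = float(np.sum(w * y) / n_tot)
    ll_null = float(n_tot * (pbar * np.log(pbar) + (1 - pbar) * np.log1p(-pbar))) \
        if 0.0 < pbar < 1.0 else 0.0

    return LogitFit(
        terms=names,
        params=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        loglik_null=ll_null,
        n=n_tot,
        k=X.shape[1],
        fitted=fitted,
        design=X,
        outcome=y,
        weights=w,
    )


def predict_prob(fit: LogitFit, design_point: Sequence[float]) -> float:
    """Inverse-logit of the linear predictor at one design point.

    ``design_point`` covers the non-intercept terms when the fit includes an
    intercept (it is prepended automatically if one value short).
    """
    x = np.asarray(design_point, dtype=float)
    if x.size == fit.k - 1 and fit.terms[0] == "const":
        x = np.r_[1.0, x]
    if x.size != fit.k:
        raise ValueError(f"design point has {x.size} values, model has {fit.k} terms")
    return float(special.expit(x @ fit.params))


def odds_ratios(fit: LogitFit, alpha: float = 0.05):
    """exp(coefficients) with Wald normal CIs."""
    z = stats.norm.isf(alpha / 2.0)
    se = fit.se()
    return (np.exp(fit.params),
            np.exp(fit.params - z * se),
            np.exp(fit.params + z * se))


@dataclass
class MarginSet:
    """Predicted probabilities and treatment contrasts at score levels.

    One row per (level, arm) for probabilities and one per level for the
    arm contrast.  ``correction`` records whether the intervals were Sidak
    adjusted, and over how many intervals (``m``).  Interval bounds for
    probabilities are computed on the linear-predictor scale and
    inverse-logit transformed (hence asymmetric and inside (0, 1));
    contrast intervals are symmetric delta-method intervals.
    """

    levels: np.ndarray
    prob: pd.DataFrame          # columns: level, arm, prob, ci_low, ci_high
    contrast: pd.DataFrame      # columns: level, te, se, ci_low, ci_high, p
    correction: str
    m: int
    alpha: float
    extrapolated: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "levels": self.levels.tolist(),
            "probabilities": self.prob.to_dict(orient="records"),
            "contrasts": self.contrast.to_dict(orient="records"),
            "correction": self.correction,
            "m_intervals": self.m,
            "alpha": self.alpha,
            "extrapolated_levels": self.extrapolated,
        }


def conditional_margins(
    fit: LogitFit,
    levels: Sequence[float],
    correction: str = "none",
    alpha: float = 0.05,
    arm_term: str | int = 1,
    score_term: str | int = 2,
    m_intervals: int | None = None,
) -> MarginSet:
    """Per-level predicted probabilities by arm and the treatment contrast.

    The model must contain a binary treatment term and a score term (named or
    positional, on top of the intercept).  At each level the arm contrast
    P(level, arm=1) - P(level, arm=0) gets a delta-method SE; with
    ``correction='sidak'`` every interval in the set uses
    alpha' = 1 - (1-alpha)^(1/m), where m defaults to the number of reported
    probability intervals (``m_intervals`` overrides, e.g. to correct across
    a multi-outcome table).
    """
    if correction not in ("none", "sidak"):
        raise ValueError("correction must be 'none' or 'sidak'")
    ia = fit.terms.index(arm_term) if isinstance(arm_term, str) else arm_term
    isc = fit.terms.index(score_term) if isinstance(score_term, str) else score_term
    levels = np.asarray(levels, dtype=float)

    score_obs = fit.design[:, isc]
    extrapolated = [float(l) for l in levels
                    if l < score_obs.min() or l > score_obs.max()]

    n_prob_intervals = 2 * levels.size
    m = int(m_intervals) if m_intervals is not None else n_prob_intervals
    a_eff = 1.0 - (1.0 - alpha) ** (1.0 / m) if correction == "sidak" else alpha
    z = stats.norm.isf(a_eff / 2.0)

    prob_rows, con_rows = [], []
    for lev in levels:
        pts = {}
        for arm in (0, 1):
            x = np.zeros(fit.k)
            if fit.terms[0] == "const":
                x[0] = 1.0
            x[ia] = arm
            x[isc] = lev
            lp = float(x @ fit.params)
            se_lp = float(np.sqrt(x @ fit.cov @ x))
            p = float(special.expit(lp))
            prob_rows.append({
                "level": float(lev), "arm": arm, "prob": p,
                "ci_low": float(special.expit(lp - z * se_lp)),
                "ci_high": float(special.expit(lp + z * se_lp)),
            })
            pts[arm] = (x, p)
        x0, p0 = pts[0]
        x1, p1 = pts[1]
        # delta method: d expit(x'b)/db = p(1-p) x
        grad = p1 * (1 - p1) * x1 - p0 * (1 - p0) * x0
        se_te = float(np.sqrt(grad @ fit.cov @ grad))
        te = p1 - p0
        pval = 2.0 * stats.norm.sf(abs(te) / se_te) if se_te > 0 else 1.0
        con_rows.append({
            "level": float(lev), "te": te, "se": se_te,
            "ci_low": te - z * se_te, "ci_high": te + z * se_te, "p": pval,
        })

    return MarginSet(
        levels=levels,
        prob=pd.DataFrame(prob_rows),
        contrast=pd.DataFrame(con_rows),
        correction=correction,
        m=m,
        alpha=alpha,
        extrapolated=extrapolated,
    )


def bootstrap_ci(
    estimator: Callable[[np.ndarray], float],
    n_units: int,
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    max_redraws: int = 100,
) -> dict:
    """Normal-based bootstrap interval: estimate +/- z * bootstrap SD.

    ``estimator`` maps an index array (a resample of ``range(n_units)``) to a
    scalar; the point estimate uses the identity resample.  Resamples on
    which the estimator raises ``ValueError``/``ZeroDivisionError`` (e.g. an
    empty arm) are redrawn, with the redraw count reported.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = np.random.default_rng(seed)
    point = float(estimator(np.arange(n_units)))
    draws = np.empty(reps)
    redraws = 0
    for r in range(reps):
        for _ in range(max_redraws):
            idx = rng.integers(0, n_units, size=n_units)
            try:
                draws[r] = estimator(idx)
                break
            except (ValueError, ZeroDivisionError):
                redraws += 1
        else:
            raise RuntimeError("estimator failed on every redraw of a resample")
    z = stats.norm.isf(alpha / 2.0)
    sd = float(np.std(draws, ddof=1))
    return {
        "estimate": point,
        "se": sd,
        "ci_low": point - z * sd,
        "ci_high": point + z * sd,
        "reps": reps,
        "seed": seed,
        "redraws": redraws,
    }
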