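"""Generalized ordered logistic regression and the Brant test.

The day-90 modified Rankin Scale (mRS, 0-6) is modelled through cumulative
logits P(Y > j | x) = expit(a_j + x' b_j), j = 0..J-2.  Under the
proportional-odds (parallel lines) constraint b_j = b for all cutpoints;
the partial proportional-odds model frees a chosen subset of terms to vary
across cutpoints.  The Brant test checks the parallel-lines assumption by
comparing slopes of the J-1 separate cutpoint logits with their joint
covariance.

The relaxed model can produce negative fitted category probabilities (a
known pathology of unconstrained generalized ordered logits); these are
clipped for reporting and flagged as a model-validity warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

__all__ = [
    "OrdinalFit",
    "fit_ordered",
    "brant_test",
    "ordinal_margins",
]


@dataclass
class OrdinalFit:
    """A fitted (generalized) ordered logit over categories 0..J-1.

    ``thresholds`` are the J-1 cutpoint intercepts a_j of
    P(Y > j) = expit(a_j + x'b_j).  ``coef`` has shape (J-1, p): identical
    rows for terms under the proportional constraint, per-cutpoint rows for
    relaxed terms (``constraint_map[term]`` is ``"relaxed"`` or
    ``"proportional"``).
    """

    terms: list[str]
    categories: np.ndarray
    thresholds: np.ndarray
    coef: np.ndarray
    cov: np.ndarray
    params: np.ndarray
    loglik: float
    constraint_map: dict[str, str]
    n: int
    design: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)
    merged_categories: list[tuple[int, int]] = field(default_factory=list)
    negative_prob_warning: bool = False

    @property
    def J(self) -> int:
        return self.categories.size

    def category_probs(self, x: Sequence[float]) -> np.ndarray:
        """Fitted P(Y = j) at one covariate point (clipped to >= 0)."""
        x = np.asarray(x, dtype=float)
        gamma = special.expit(self.thresholds + self.coef @ x)  # P(Y > j)
        probs = np.empty(self.J)
        probs[0] = 1.0 - gamma[0]
        probs[1:-1] = gamma[:-1] - gamma[1:]
        probs[-1] = gamma[-1]
        if np.any(probs < -1e-10):
            object.__setattr__(self, "negative_prob_warning", True)
        probs = np.clip(probs, 0.0, None)
        return probs / probs.sum()


def _pack_index(J: int, p: int, relax_idx: list[int]):
    """Parameter layout: [a_0..a_{J-2}, shared betas, relaxed betas by cutpoint]."""
    shared_idx = [j for j in range(p) if j not in relax_idx]
    n_par = (J - 1) + len(shared_idx) + len(relax_idx) * (J - 1)
    return shared_idx, n_par


def _unpack(theta: np.ndarray, J: int, p: int,
            shared_idx: list[int], relax_idx: list[int]):
    a = theta[: J - 1]
    B = np.zeros((J - 1, p))
    off = J - 1
    for pos, j in enumerate(shared_idx):
        B[:, j] = theta[off + pos]
    off += len(shared_idx)
    for pos, j in enumerate(relax_idx):
        B[:, j] = theta[off + pos * (J - 1): off + (pos + 1) * (J - 1)]
    return a, B


def _negloglik_and_grad(theta, y, X, J, shared_idx, relax_idx):
    n, p = X.shape
    a, B = _unpack(theta, J, p, shared_idx, relax_idx)
    eta = a[None, :] + X @ B.T                     # (n, J-1)
    gamma = special.expit(eta)                     # P(Y > j)
    # P(Y = y_i) = gamma_{y-1} - gamma_y with gamma_{-1}=1, gamma_{J-1}=0
    gpad = np.column_stack([np.ones(n), gamma, np.zeros(n)])
    prob = gpad[np.arange(n), y] - gpad[np.arange(n), y + 1]
    prob = np.clip(prob, 1e-300, None)
    nll = -np.sum(np.log(prob))

    # dlogP_i/dgamma_j: +1/P at j = y_i - 1, -1/P at j = y_i (0-based cutpoints)
    dP = np.zeros((n, J - 1))
    rows = np.arange(n)
    mask_lo = y >= 1
    dP[rows[mask_lo], y[mask_lo] - 1] = 1.0 / prob[mask_lo]
    mask_hi = y <= J - 2
    dP[rows[mask_hi], y[mask_hi]] = -1.0 / prob[mask_hi]
    dgamma = dP * gamma * (1.0 - gamma)            # chain through expit

    grad = np.zeros_like(theta)
    grad[: J - 1] = -dgamma.sum(axis=0)
    off = J - 1
    for pos, j in enumerate(shared_idx):
        grad[off + pos] = -np.sum(dgamma * X[:, [j]])
    off += len(shared_idx)
    for pos, j in enumerate(relax_idx):
        grad[off + pos * (J - 1): off + (pos + 1) * (J - 1)] = \
            -(dgamma * X[:, [j]]).sum(axis=0)
    return nll, grad


def fit_ordered(
    outcome: Sequence[int],
    design,
    mode: str = "proportional",
    relax: Sequence[str] | None = None,
) -> OrdinalFit:
    """MLE of a (generalized) ordered logit over cumulative logits.

    ``mode='proportional'`` constrains all slopes across cutpoints;
    ``mode='partial'`` frees the terms named in ``relax``.  Categories with
    no observations are merged into the adjacent lower category (logged on
    the fit).  With only two observed categories the model reduces to a
    binary logit.
    """
    if mode not in ("proportional", "partial"):
        raise ValueError("mode must be 'proportional' or 'partial'")
    if isinstance(design, pd.DataFrame):
        X = design.to_numpy(dtype=float)
        names = [str(c) for c in design.columns]
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        names = [f"x{j}" for j in range(X.shape[1])]
    y_raw = np.asarray(outcome, dtype=int)

    # Collapse empty categories into the adjacent lower one.
    observed = np.unique(y_raw)
    merged: list[tuple[int, int]] = []
    full = np.arange(y_raw.min(), y_raw.max() + 1)
    for c in full:
        if c not in observed:
            merged.append((int(c), int(observed[observed < c].max())))
    remap = {c: rank for rank, c in enumerate(observed)}
    y = np.array([remap[v] for v in y_raw])
    J = observed.size
    if J < 2:
        raise ValueError("outcome has a single category")

    relax = list(relax or [])
    if mode == "proportional" and relax:
        raise ValueError("relax is only meaningful in partial mode")
    unknown = [t for t in relax if t not in names]
    if unknown:
        raise ValueError(f"relax names unknown terms: {unknown}")
    relax_idx = [names.index(t) for t in relax]
    shared_idx, n_par = _pack_index(J, X.shape[1], relax_idx)

    # Start: empirical cumulative logits, zero slopes.
    cum = np.array([(y > j).mean() for j in range(J - 1)])
    cum = np.clip(cum, 1e-4, 1 - 1e-4)
    theta0 = np.zeros(n_par)
    theta0[: J - 1] = special.logit(cum)

    res = optimize.minimize(
        _negloglik_and_grad, theta0, args=(y, X, J, shared_idx, relax_idx),
        jac=True, method="BFGS",
        options={"maxiter": 500, "gtol": 1e-8},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3 * max(1, len(y) ** 0.5):
        raise RuntimeError(f"ordered-logit MLE did not converge: {res.message}")
    theta = res.x

    H = numdiff.approx_hess(
        theta, lambda t: _negloglik_and_grad(t, y, X, J, shared_idx, relax_idx)[0]
    )
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)

    a, B = _unpack(theta, J, X.shape[1], shared_idx, relax_idx)
    cmap = {t: ("relaxed" if t in relax else "proportional") for t in names}
    fit = OrdinalFit(
        terms=names,
        categories=observed,
        thresholds=a,
        coef=B,
        cov=cov,
        params=theta,
        loglik=float(-res.fun),
        constraint_map=cmap,
        n=len(y),
        design=X,
        outcome=y,
        merged_categories=merged,
    )
    # Evaluate probabilities once over the sample to surface the warning.
    for xi in X[:: max(1, len(y) // 50)]:
        fit.category_probs(xi)
    if fit.negative_prob_warning:
        warnings.warn(
            "relaxed ordered logit produced negative category probabilities "
            "(clipped); interpret the partial model with caution"
        )
    return fit


def brant_test(fit: OrdinalFit) -> dict:
    """Brant test of the parallel (proportional) odds assumption.

    Fits the J-1 separate binary logits 1{Y > j} on the design, computes the
    joint covariance of their slopes (Brant's formula), and Wald-tests the
    equality of slopes across cutpoints; df = p * (J - 2).  Returns the
    omnibus result plus a per-term breakdown.
    """
    if any(v == "relaxed" for v in fit.constraint_map.values()):
        raise ValueError("Brant test applies to the proportional fit")
    J, p = fit.J, len(fit.terms)
    if J < 3:
        raise ValueError("need >= 3 outcome categories")
    X = np.column_stack([np.ones(fit.n), fit.design])
    y = fit.outcome

    betas = []       # per-cutpoint (p+1,) including intercept
    pis = []         # fitted P(Y > j) per unit from each separate logit
    from .logit import fit_logit
    for j in range(J - 1):
        z = (y > j).astype(float)
        if z.min() == z.max():
            raise ValueError(f"cutpoint {j} splits with an empty side")
        f = fit_logit(z, fit.design)
        betas.append(f.params)
        pis.append(f.fitted)
    betas = np.array(betas)
    pis = np.array(pis)

    # Joint covariance of slope estimates (Brant 1990).
    XtWX_inv = []
    for j in range(J - 1):
        Wjj = pis[j] * (1 - pis[j])
        XtWX_inv.append(np.linalg.inv(X.T @ (X * Wjj[:, None])))
    nslope = p
    V = np.zeros(((J - 1) * nslope, (J - 1) * nslope))
    for j in range(J - 1):
        for l in range(J - 1):
            lo, hi = min(j, l), max(j, l)
            Wjl = pis[hi] - pis[lo] * pis[hi]   # pi_hi <= pi_lo
            M = XtWX_inv[j] @ (X.T @ (X * Wjl[:, None])) @ XtWX_inv[l]
            V[j * nslope:(j + 1) * nslope, l * nslope:(l + 1) * nslope] = \
                M[1:, 1:]

    beta_vec = betas[:, 1:].ravel()              # slopes only
    # Contrast: slopes at cutpoint j vs cutpoint 0, for j = 1..J-2.
    D = np.zeros(((J - 2) * nslope, (J - 1) * nslope))
    for j in range(1, J - 1):
        for t in range(nslope):
            row = (j - 1) * nslope + t
            D[row, t] = 1.0
            D[row, j * nslope + t] = -1.0
    d = D @ beta_vec
    chi2 = float(d @ np.linalg.solve(D @ V @ D.T, d))
    df = (J - 2) * nslope
    pval = float(stats.chi2.sf(chi2, df))

    per_term = {}
    for t, name in enumerate(fit.terms):
        sel = [j * nslope + t for j in range(J - 1)]
        Dt = np.zeros((J - 2, (J - 1) * nslope))
        for j in range(1, J - 1):
            Dt[j - 1, sel[0]] = 1.0
            Dt[j - 1, sel[j]] = -1.0
        dt = Dt @ beta_vec
        c = float(dt @ np.linalg.solve(Dt @ V @ Dt.T, dt))
        per_term[name] = {
            "chi2": c, "df": J - 2, "p": float(stats.chi2.sf(c, J - 2)),
        }
    return {"chi2": chi2, "df": df, "p": pval, "per_term": per_term}


def ordinal_margins(
    fit: OrdinalFit,
    levels: Sequence[float],
    arm_term: str = "arm",
    score_term: str = "hti",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-category treatment contrasts of fitted probabilities by score level.

    At each score level, contrast = P(Y = j | arm=1, level) -
    P(Y = j | arm=0, level) with delta-method CIs (numerical gradient of the
    contrast in the packed parameter vector).  Contrasts across categories
    sum to zero at every level.
    """
    ia = fit.terms.index(arm_term)
    isc = fit.terms.index(score_term)
    J, p = fit.J, len(fit.terms)
    relax_idx = [p_i for p_i, t in enumerate(fit.terms)
                 if fit.constraint_map[t] == "relaxed"]
    shared_idx, _ = _pack_index(J, p, relax_idx)
    z = stats.norm.isf(alpha / 2.0)

    def probs_at(theta, x):
        a, B = _unpack(theta, J, p, shared_idx, relax_idx)
        gamma = special.expit(a + B @ x)
        pr = np.empty(J)
        pr[0] = 1 - gamma[0]
        pr[1:-1] = gamma[:-1] - gamma[1:]
        pr[-1] = gamma[-1]
        return pr

    rows = []
    for lev in levels:
        x1 = np.zeros(p); x1[ia] = 1.0; x1[isc] = lev
        x0 = np.zeros(p); x0[isc] = lev
        def contrast(theta, x1=x1, x0=x0):
            return probs_at(theta, x1) - probs_at(theta, x0)
        c = contrast(fit.params)
        G = numdiff.approx_fprime(fit.params, contrast)  # (J, n_par)
        se = np.sqrt(np.einsum("jp,pq,jq->j", G, fit.cov, G))
        for j, cat in enumerate(fit.categories):
            pv = 2.0 * stats.norm.sf(abs(c[j]) / se[j]) if se[j] > 0 else 1.0
            rows.append({
                "level": float(lev), "category": int(cat),
                "contrast": float(c[j]), "se": float(se[j]),
                "ci_low": float(c[j] - z * se[j]),
                "ci_high": float(c[j] + z * se[j]),
                "p": float(pv),
            })
    return pd.DataFrame(rows)
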