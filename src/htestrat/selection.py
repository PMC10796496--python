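"""Postestimation battery for logistic model selection.

The candidate models are treatment-plus-risk-score logits for symptomatic
hemorrhagic transformation.  Each model is screened on specification (link
test), linearity of continuous terms (Box-Tidwell augmentation), calibration
(Hosmer-Lemeshow), collinearity (VIF), overall fit (deviance, likelihood
ratio, pseudo R-squared, AIC/BIC), multiplicity-adjusted significance
(Romano-Wolf stepdown bootstrap) and discrimination (AUC with DeLong
variance, and DeLong paired AUC contrasts between models).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .logit import LogitFit, fit_logit

__all__ = [
    "PostestimationReport",
    "link_test",
    "box_tidwell_test",
    "hosmer_lemeshow",
    "variance_inflation",
    "pseudo_r2",
    "info_criteria",
    "lr_test",
    "romano_wolf_adjust",
    "roc_auc",
    "compare_auc",
    "postestimation_report",
    "select_model",
]


def link_test(fit: LogitFit) -> float:
    """Specification (link) test: p-value of the squared linear predictor.

    Refits the outcome on (linear predictor, its square); a significant
    squared term indicates the link/linear-predictor specification is wrong.
    """
    lp = fit.linear_predictor()
    if np.ptp(lp) < 1e-12:
        raise ValueError("constant linear predictor; link test undefined")
    aug = np.column_stack([lp, lp ** 2])
    refit = fit_logit(fit.outcome, aug, weights=fit.weights)
    return float(refit.wald_p()[2])


def box_tidwell_test(
    fit: LogitFit,
    continuous_terms: Sequence[str],
    shift: float = 1.0,
) -> dict:
    """Box-Tidwell nonlinearity check for continuous terms.

    For each tested term x the design is augmented with x*ln(x + shift) and
    the Wald p of the augmentation reported; ``shift`` (default +1, applied
    only inside the logarithm) accommodates scores containing zero.  Returns
    ``{"p": {term: p}, "shift": shift}``.
    """
    out: dict[str, float] = {}
    for term in continuous_terms:
        j = fit.terms.index(term)
        x = fit.design[:, j]
        if np.any(x + shift <= 0):
            raise ValueError(
                f"term {term!r} has values <= {-shift}; configure a larger shift"
            )
        aug = np.column_stack([fit.design, x * np.log(x + shift)])
        refit = fit_logit(fit.outcome, aug, weights=fit.weights,
                          add_intercept=False)
        out[term] = float(refit.wald_p()[-1])
    return {"p": out, "shift": shift}


def hosmer_lemeshow(fit: LogitFit, groups: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow calibration chi-square.

    Units are binned by fitted-probability quantiles with tied probabilities
    kept in one bin, so the effective group count can be below ``groups``
    (e.g. few distinct covariate patterns); df = actual groups - 2.
    """
    if groups < 3:
        raise ValueError("groups must be >= 3")
    p = np.repeat(fit.fitted, fit.weights.astype(int)) \
        if not np.allclose(fit.weights, 1.0) else fit.fitted
    y = np.repeat(fit.outcome, fit.weights.astype(int)) \
        if not np.allclose(fit.weights, 1.0) else fit.outcome
    if np.unique(p).size < 3:
        raise ValueError("fewer than 3 distinct fitted probabilities")
    edges = np.unique(np.percentile(p, np.arange(1, groups) * 100.0 / groups))
    bin_id = np.searchsorted(edges, p, side="left")
    chi2 = 0.0
    g = 0
    for b in np.unique(bin_id):
        m = bin_id == b
        n_b = m.sum()
        o1 = y[m].sum()
        e1 = p[m].sum()
        if e1 > 0:
            chi2 += (o1 - e1) ** 2 / e1
        if n_b - e1 > 0:
            chi2 += ((n_b - o1) - (n_b - e1)) ** 2 / (n_b - e1)
        g += 1
    df = g - 2
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def variance_inflation(design) -> dict:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    ``design`` is an array or DataFrame of non-constant terms (no intercept
    column needed; one is added to each auxiliary regression).  Aliased terms
    get ``inf``.  Returns ``{"vif": {term: v}, "mean": mean}``.
    """
    import pandas as pd

    if isinstance(design, pd.DataFrame):
        X = design.to_numpy(dtype=float)
        names = [str(c) for c in design.columns]
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("need >= 2 terms for VIF")
    vifs: dict[str, float] = {}
    for j, name in enumerate(names):
        yj = X[:, j]
        others = np.column_stack(
            [np.ones(X.shape[0])] + [X[:, l] for l in range(X.shape[1]) if l != j]
        )
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError(f"term {name!r} is constant")
        r2 = 1.0 - ss_res / ss_tot
        vifs[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    finite = [v for v in vifs.values() if np.isfinite(v)]
    mean = float(np.mean(list(vifs.values()))) if len(finite) == len(vifs) \
        else float("inf")
    return {"vif": vifs, "mean": mean}


def pseudo_r2(fit: LogitFit) -> tuple[float, float, float]:
    """(McFadden, Cox-Snell, Nagelkerke) pseudo R-squared."""
    ll, ll0, n = fit.loglik, fit.loglik_null, fit.n
    mcf = 1.0 - ll / ll0 if ll0 != 0 else 0.0
    cs = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
    nag = cs / (1.0 - np.exp(2.0 * ll0 / n)) if ll0 != 0 else 0.0
    return float(mcf), float(cs), float(nag)


def info_criteria(fit: LogitFit) -> tuple[float, float]:
    """(AIC, BIC) = (-2 ll + 2k, -2 ll + k ln n)."""
    return (float(-2.0 * fit.loglik + 2.0 * fit.k),
            float(-2.0 * fit.loglik + fit.k * np.log(fit.n)))


def lr_test(nested: LogitFit, full: LogitFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested model against a fuller one."""
    if not set(nested.terms) <= set(full.terms):
        raise ValueError("models are not nested (terms differ)")
    if abs(nested.n - full.n) > 1e-9:
        raise ValueError("models were fit on different unit sets")
    chi2 = max(0.0, 2.0 * (full.loglik - nested.loglik))
    df = full.k - nested.k
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), int(df), p


def romano_wolf_adjust(
    statistics: Sequence[float],
    resampler: Callable[[np.random.Generator], np.ndarray],
    reps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Romano-Wolf stepdown bootstrap adjustment for a family of hypotheses.

    ``statistics`` are the observed absolute test statistics (larger = more
    evidence).  ``resampler(rng)`` returns one bootstrap draw of the
    statistics *recentred at the null* (e.g. pairs-bootstrap t statistics
    minus their observed values).  Adjusted p-values satisfy
    adjusted >= raw and are monotone in the stepdown order.
    """
    import warnings

    stat = np.abs(np.asarray(statistics, dtype=float))
    k = stat.size
    if k == 0:
        raise ValueError("need at least one hypothesis")
    if reps < 100:
        warnings.warn("fewer than 100 bootstrap resamples; adjustment is crude")
    rng = np.random.default_rng(seed)
    null = np.empty((reps, k))
    for r in range(reps):
        null[r] = np.abs(np.asarray(resampler(rng), dtype=float))

    order = np.argsort(-stat)            # most significant first
    adj = np.empty(k)
    prev = 0.0
    remaining = list(order)
    for j in order:
        max_null = null[:, remaining].max(axis=1)
        p = (1.0 + np.sum(max_null >= stat[j])) / (reps + 1.0)
        prev = max(prev, p)              # enforce stepdown monotonicity
        adj[j] = prev
        remaining.remove(j)
    return adj


def _delong_components(y: np.ndarray, score: np.ndarray):
    """DeLong placement values: (auc, V10 per event, V01 per non-event)."""
    pos = score[y == 1]
    neg = score[y == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    # placement of each positive among negatives and vice versa
    order = np.argsort(neg, kind="mergesort")
    neg_sorted = neg[order]
    v10 = (np.searchsorted(neg_sorted, pos, side="left")
           + 0.5 * (np.searchsorted(neg_sorted, pos, side="right")
                    - np.searchsorted(neg_sorted, pos, side="left"))) / n
    order = np.argsort(pos, kind="mergesort")
    pos_sorted = pos[order]
    v01 = 1.0 - (np.searchsorted(pos_sorted, neg, side="left")
                 + 0.5 * (np.searchsorted(pos_sorted, neg, side="right")
                          - np.searchsorted(pos_sorted, neg, side="left"))) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(fit: LogitFit, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC of the fitted probabilities with a DeLong-variance Wald CI.

    AUC is the concordance probability over event/non-event pairs with 0.5
    credit for ties.
    """
    w = fit.weights
    if np.allclose(w, 1.0):
        y, s = fit.outcome, fit.fitted
    else:
        reps = w.astype(int)
        y, s = np.repeat(fit.outcome, reps), np.repeat(fit.fitted, reps)
    auc, v10, v01 = _delong_components(y, s)
    var = (np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)
    z = stats.norm.isf(alpha / 2.0)
    half = z * np.sqrt(var)
    return auc, (float(auc - half), float(auc + half))


def compare_auc(fit_a: LogitFit, fit_b: LogitFit) -> tuple[float, int, float]:
    """DeLong paired test of equal AUCs for two models on the same units."""
    wa, wb = fit_a.weights, fit_b.weights
    def _expanded(fit):
        if np.allclose(fit.weights, 1.0):
            return fit.outcome, fit.fitted
        reps = fit.weights.astype(int)
        return np.repeat(fit.outcome, reps), np.repeat(fit.fitted, reps)
    ya, sa = _expanded(fit_a)
    yb, sb = _expanded(fit_b)
    if ya.size != yb.size or not np.array_equal(ya, yb):
        raise ValueError("models must be fit on the same units and outcome")
    auc_a, v10a, v01a = _delong_components(ya, sa)
    auc_b, v10b, v01b = _delong_components(yb, sb)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    d = auc_a - auc_b
    if var <= 0:
        chi2 = 0.0 if abs(d) < 1e-12 else np.inf
    else:
        chi2 = d * d / var
    return float(chi2), 1, float(stats.chi2.sf(chi2, 1))


@dataclass
class PostestimationReport:
    """All Table-2-style diagnostics for one candidate model."""

    name: str
    link_test_p: float
    box_tidwell_p: dict[str, float]
    box_tidwell_shift: float
    hl_chi2: float
    hl_df: int
    hl_p: float
    mean_vif: float
    deviance: float
    lr_chi2: float
    lr_df: int
    lr_p: float
    mcfadden: float
    cox_snell: float
    nagelkerke: float
    aic: float
    bic: float
    auc: float
    auc_ci: tuple[float, float]
    romano_wolf_p: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["auc_ci"] = list(self.auc_ci)
        return d


def postestimation_report(
    name: str,
    fit: LogitFit,
    continuous_terms: Sequence[str],
    hl_groups: int = 10,
    bt_shift: float = 1.0,
) -> PostestimationReport:
    """Run the full diagnostic battery on one fitted model."""
    null = fit_logit(fit.outcome, np.empty((fit.outcome.size, 0)),
                     weights=fit.weights)
    lr_chi2, lr_df, lr_p = lr_test(null, fit)
    mcf, cs, nag = pseudo_r2(fit)
    aic, bic = info_criteria(fit)
    hl_chi2, hl_df, hl_p = hosmer_lemeshow(fit, groups=hl_groups)
    bt = box_tidwell_test(fit, continuous_terms, shift=bt_shift)
    nonconst = fit.design[:, 1:] if fit.terms[0] == "const" else fit.design
    vif = variance_inflation(nonconst)["mean"] if nonconst.shape[1] >= 2 \
        else 1.0
    auc, auc_ci = roc_auc(fit)
    return PostestimationReport(
        name=name,
        link_test_p=link_test(fit),
        box_tidwell_p=bt["p"],
        box_tidwell_shift=bt["shift"],
        hl_chi2=hl_chi2, hl_df=hl_df, hl_p=hl_p,
        mean_vif=float(vif),
        deviance=fit.deviance,
        lr_chi2=lr_chi2, lr_df=lr_df, lr_p=lr_p,
        mcfadden=mcf, cox_snell=cs, nagelkerke=nag,
        aic=aic, bic=bic,
        auc=auc, auc_ci=auc_ci,
    )


def select_model(reports: Sequence[PostestimationReport]) -> dict:
    """Deterministic ranking by (lower AIC, lower BIC, higher AUC).

    Emits every criterion; declares a tie when models agree on all three.
    Invariant to the order in which reports are supplied.
    """
    if len(reports) < 2:
        raise ValueError("need >= 2 reports to rank")
    keyed = sorted(
        reports, key=lambda r: (round(r.aic, 10), round(r.bic, 10),
                                -round(r.auc, 10), r.name)
    )
    best_key = (round(keyed[0].aic, 10), round(keyed[0].bic, 10),
                -round(keyed[0].auc, 10))
    ties = [r.name for r in keyed
            if (round(r.aic, 10), round(r.bic, 10), -round(r.auc, 10)) == best_key]
    return {
        "ranking": [r.name for r in keyed],
        "selected": keyed[0].name,
        "tie": ties if len(ties) > 1 else None,
        "criteria": {r.name: {"aic": r.aic, "bic": r.bic, "auc": r.auc}
                     for r in reports},
    }
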