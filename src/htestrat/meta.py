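"""Subgroup-as-"study" meta-analytic heterogeneity of treatment effects.

Each risk-score stratum of a two-arm cohort is declared a "study".  Binary
outcomes are summarized by the risk difference (RD) and pooled with the
fixed-effects Mantel-Haenszel model; continuous outcomes by Hedges' g in the
fixed-effects inverse-variance model; both by random-effects REML.
Heterogeneity is quantified with Cochran's Q, the between-study variance
tau^2, and the Higgins-Thompson I^2 / H^2 computed from the typical
within-study variance

    s^2 = (k - 1) * sum(w) / (sum(w)^2 - sum(w^2)),  w = 1/v,

so that I^2 = 100 * tau^2 / (tau^2 + s^2) and H^2 = (tau^2 + s^2) / s^2
(reported for the REML model even when the Q-based estimate is zero).
Small-study effects are screened with the Egger regression test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GroupedCohort

__all__ = [
    "StudyRow",
    "MetaResult",
    "make_studies",
    "make_continuous_studies",
    "mh_fixed_rd",
    "iv_fixed_smd",
    "reml_random",
    "egger_test",
    "forest_data",
]


@dataclass
class StudyRow:
    """One stratum-as-study: arm sizes with events (binary) or mean/sd."""

    label: str
    n1: int
    n0: int
    effect: float
    variance: float
    e1: float | None = None     # events (binary) or mean (continuous)
    e0: float | None = None
    sd1: float | None = None
    sd0: float | None = None
    kind: str = "binary"


@dataclass
class MetaResult:
    """Pooled effect with heterogeneity statistics."""

    model: str                  # mh_fixed | iv_fixed | reml_random
    pooled: float
    se: float
    ci: tuple[float, float]
    q: float
    q_df: int
    q_p: float
    tau2: float
    i2: float                   # percent
    h2: float
    k: int
    weights: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["ci"] = list(self.ci)
        d["weights"] = None if self.weights is None else self.weights.tolist()
        return d


def make_studies(
    cohort: GroupedCohort,
    outcome: str,
    drop_empty_arm: bool = True,
) -> list[StudyRow]:
    """One binary StudyRow per score stratum (treated vs control).

    Risk-difference variance is p1(1-p1)/n1 + p0(1-p0)/n0 without continuity
    correction (zero-event cells contribute zero variance from that arm).
    Strata with an empty arm are dropped when ``drop_empty_arm``.
    """
    by_score: dict[int, dict[int, tuple[int, int]]] = {}
    for s in cohort.strata:
        by_score.setdefault(s.score, {})[s.arm] = (s.events.get(outcome, 0), s.n)
    rows = []
    for score in sorted(by_score):
        cell = by_score[score]
        (e1, n1) = cell.get(1, (0, 0))
        (e0, n0) = cell.get(0, (0, 0))
        if n1 == 0 or n0 == 0:
            if drop_empty_arm:
                continue
            raise ValueError(f"stratum {score} has an empty arm")
        p1, p0 = e1 / n1, e0 / n0
        rows.append(StudyRow(
            label=str(score), n1=n1, n0=n0, e1=e1, e0=e0,
            effect=p1 - p0,
            variance=p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0,
            kind="binary",
        ))
    return rows


def make_continuous_studies(frame: pd.DataFrame, outcome: str,
                            score_col: str = "hti",
                            arm_col: str = "arm") -> list[StudyRow]:
    """Hedges'-g StudyRows per score stratum from unit-level data.

    g = J * (m1 - m0) / s_pooled with the small-sample correction
    J = 1 - 3/(4 df - 1), df = n1 + n0 - 2; variance by the standard
    large-sample formula (n1+n0)/(n1 n0) + g^2 / (2 (n1+n0)).
    """
    rows = []
    for score, grp in frame.groupby(score_col):
        y1 = grp.loc[grp[arm_col] == 1, outcome].to_numpy(dtype=float)
        y0 = grp.loc[grp[arm_col] == 0, outcome].to_numpy(dtype=float)
        if y1.size < 2 or y0.size < 2:
            continue
        n1, n0 = y1.size, y0.size
        df = n1 + n0 - 2
        sp2 = ((n1 - 1) * y1.var(ddof=1) + (n0 - 1) * y0.var(ddof=1)) / df
        if sp2 <= 0:
            raise ValueError(f"zero pooled SD in stratum {score}")
        J = 1.0 - 3.0 / (4.0 * df - 1.0)
        g = J * (y1.mean() - y0.mean()) / np.sqrt(sp2)
        v = (n1 + n0) / (n1 * n0) + g * g / (2.0 * (n1 + n0))
        rows.append(StudyRow(
            label=str(score), n1=n1, n0=n0,
            e1=float(y1.mean()), e0=float(y0.mean()),
            sd1=float(y1.std(ddof=1)), sd0=float(y0.std(ddof=1)),
            effect=float(g), variance=float(v), kind="continuous",
        ))
    return rows


def _hetero(y: np.ndarray, v: np.ndarray, tau2: float, mu_fixed: float):
    """(Q, df, p) against the fixed-effect mean, plus typical s2, I2, H2."""
    w = 1.0 / v
    q = float(np.sum(w * (y - mu_fixed) ** 2))
    df = y.size - 1
    k = y.size
    s2 = (k - 1) * np.sum(w) / (np.sum(w) ** 2 - np.sum(w ** 2)) if k > 1 else np.nan
    i2 = 100.0 * tau2 / (tau2 + s2) if k > 1 else 0.0
    h2 = (tau2 + s2) / s2 if k > 1 else 1.0
    return q, df, float(stats.chi2.sf(q, df)) if df > 0 else 1.0, s2, i2, h2


def _fixed_iv_mu(y, v):
    w = 1.0 / v
    return float(np.sum(w * y) / np.sum(w))


def mh_fixed_rd(studies: Sequence[StudyRow], alpha: float = 0.05) -> MetaResult:
    """Fixed-effects Mantel-Haenszel pooled risk difference.

    MH weights n1*n0/(n1+n0); the pooled-RD variance uses the
    Greenland-Robins estimator.
    """
    st = [s for s in studies if s.kind == "binary"]
    if not st:
        raise ValueError("no binary studies")
    n1 = np.array([s.n1 for s in st], float)
    n0 = np.array([s.n0 for s in st], float)
    e1 = np.array([s.e1 for s in st], float)
    e0 = np.array([s.e0 for s in st], float)
    rd = e1 / n1 - e0 / n0
    w = n1 * n0 / (n1 + n0)
    if np.all(w == 0):
        raise ValueError("all strata degenerate")
    pooled = float(np.sum(w * rd) / np.sum(w))
    # Greenland-Robins variance for the MH risk difference
    num = (e1 * (n1 - e1) * n0 ** 3 + e0 * (n0 - e0) * n1 ** 3) \
        / (n1 * n0 * (n1 + n0) ** 2)
    var = float(np.sum(num) / np.sum(w) ** 2)
    se = np.sqrt(var)
    z = stats.norm.isf(alpha / 2.0)
    v = np.array([s.variance for s in st], float)
    v = np.where(v <= 0, 1e-12, v)
    q, qdf, qp, s2, _, _ = _hetero(rd, v, 0.0, _fixed_iv_mu(rd, v))
    h2q = max(1.0, q / qdf) if qdf > 0 else 1.0
    i2q = 100.0 * (1.0 - 1.0 / h2q)
    return MetaResult(
        model="mh_fixed", pooled=pooled, se=float(se),
        ci=(pooled - z * se, pooled + z * se),
        q=q, q_df=qdf, q_p=qp, tau2=0.0, i2=i2q, h2=h2q, k=len(st),
        weights=w / w.sum(),
    )


def iv_fixed_smd(studies: Sequence[StudyRow], alpha: float = 0.05) -> MetaResult:
    """Fixed-effects inverse-variance pooling (Hedges'-g studies)."""
    st = list(studies)
    if not st:
        raise ValueError("no studies")
    y = np.array([s.effect for s in st], float)
    v = np.array([s.variance for s in st], float)
    if np.any(v <= 0):
        raise ValueError("nonpositive study variance")
    w = 1.0 / v
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = stats.norm.isf(alpha / 2.0)
    q, qdf, qp, s2, _, _ = _hetero(y, v, 0.0, pooled)
    h2q = max(1.0, q / qdf) if qdf > 0 else 1.0
    return MetaResult(
        model="iv_fixed", pooled=pooled, se=se,
        ci=(pooled - z * se, pooled + z * se),
        q=q, q_df=qdf, q_p=qp, tau2=0.0,
        i2=100.0 * (1.0 - 1.0 / h2q), h2=h2q, k=len(st),
        weights=w / w.sum(),
    )


def reml_tau2(y: np.ndarray, v: np.ndarray, tol: float = 1e-10,
              max_iter: int = 500) -> float:
    """Between-study variance by iterative REML (nonnegative)."""
    tau2 = max(0.0, float(np.var(y, ddof=1) - np.mean(v))) if y.size > 1 else 0.0
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        num = np.sum(w ** 2 * ((y - mu) ** 2 + 1.0 / np.sum(w) - v))
        new = max(0.0, float(num / np.sum(w ** 2)))
        if abs(new - tau2) < tol * (1.0 + tau2):
            return new
        tau2 = new
    raise RuntimeError("REML tau^2 iteration did not converge")


def reml_random(studies: Sequence[StudyRow], alpha: float = 0.05) -> MetaResult:
    """Random-effects REML pooling with Higgins-Thompson I^2/H^2."""
    st = list(studies)
    if len(st) < 2:
        raise ValueError("need >= 2 studies for a random-effects model")
    y = np.array([s.effect for s in st], float)
    v = np.array([s.variance for s in st], float)
    v = np.where(v <= 0, 1e-12, v)
    tau2 = reml_tau2(y, v)
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = stats.norm.isf(alpha / 2.0)
    q, qdf, qp, s2, i2, h2 = _hetero(y, v, tau2, _fixed_iv_mu(y, v))
    return MetaResult(
        model="reml_random", pooled=pooled, se=se,
        ci=(pooled - z * se, pooled + z * se),
        q=q, q_df=qdf, q_p=qp, tau2=tau2, i2=i2, h2=h2, k=len(st),
        weights=w / w.sum(),
    )


def egger_test(studies: Sequence[StudyRow]) -> tuple[float, float]:
    """Egger small-study-effects test: (intercept, two-sided p).

    Weighted regression of the effect on its standard error with weights
    1/v; the slope of the SE term is the Egger bias intercept of the
    standardized-effect-on-precision formulation.  Warns for k < 10.
    """
    import warnings

    st = list(studies)
    if len(st) < 3:
        raise ValueError("Egger test needs >= 3 studies")
    if len(st) < 10:
        warnings.warn("Egger test with fewer than 10 studies has low power")
    y = np.array([s.effect for s in st], float)
    v = np.array([s.variance for s in st], float)
    se = np.sqrt(v)
    if np.ptp(se) < 1e-12:
        raise ValueError("identical study variances; Egger regression degenerate")
    # WLS of y on [1, se] with weights 1/v; bias = coefficient on se
    X = np.column_stack([np.ones_like(se), se])
    W = 1.0 / v
    XtWX = X.T @ (X * W[:, None])
    beta = np.linalg.solve(XtWX, X.T @ (W * y))
    resid = y - X @ beta
    dof = len(st) - 2
    sigma2 = float(np.sum(W * resid ** 2) / dof)
    cov = sigma2 * np.linalg.inv(XtWX)
    tstat = beta[1] / np.sqrt(cov[1, 1])
    p = 2.0 * stats.t.sf(abs(tstat), dof)
    return float(beta[1]), float(p)


def forest_data(result: MetaResult, studies: Sequence[StudyRow],
                alpha: float = 0.05) -> pd.DataFrame:
    """Plot-ready forest table: per-study effect/CI/weight plus pooled row."""
    z = stats.norm.isf(alpha / 2.0)
    rows = []
    v = np.array([s.variance for s in studies], float)
    if result.model == "mh_fixed":
        w = np.array([s.n1 * s.n0 / (s.n1 + s.n0) for s in studies], float)
    else:
        w = 1.0 / (v + result.tau2)
    w = 100.0 * w / w.sum()
    for s, wi in zip(studies, w):
        half = z * np.sqrt(s.variance)
        rows.append({
            "label": s.label, "effect": s.effect,
            "ci_low": s.effect - half, "ci_high": s.effect + half,
            "weight_pct": float(wi), "pooled": False,
        })
    rows.append({
        "label": f"pooled ({result.model})", "effect": result.pooled,
        "ci_low": result.ci[0], "ci_high": result.ci[1],
        "weight_pct": 100.0, "pooled": True,
    })
    return pd.DataFrame(rows)
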