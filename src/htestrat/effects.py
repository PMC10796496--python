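"""Propensity-score estimation and Epanechnikov kernel-matching effects.

The propensity model is a binary logit of treatment assignment on covariates;
its linear predictor (log-odds "index") is the matching scale by default,
matching the convention of performing kernel matching on the logarithm of the
odds.  Each unit's counterfactual outcome is the Epanechnikov-kernel weighted
mean of opposite-arm outcomes within bandwidth of its index; units with an
empty kernel window fall back to their nearest opposite-arm neighbour (the
fallback count is reported).

From the matched counterfactuals: ATT (mean effect over the treated), ATC
(over the untreated), ATE (arm-size weighted combination, equal to the mean
unit effect), NATE (naive unadjusted mean difference) and the potential
outcome averages Y0, Y1 with Y1 - Y0 = ATE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .logit import LogitFit, fit_logit

__all__ = [
    "PropensityModel",
    "EffectEstimates",
    "epanechnikov",
    "estimate_propensity",
    "kernel_match",
    "estimate_effects",
]


def epanechnikov(u: np.ndarray) -> np.ndarray:
    """Epanechnikov kernel K(u) = 0.75 (1 - u^2) on |u| < 1, else 0."""
    u = np.asarray(u, dtype=float)
    return np.where(np.abs(u) < 1.0, 0.75 * (1.0 - u * u), 0.0)


@dataclass
class PropensityModel:
    """Treatment-assignment logit with per-unit index and score."""

    fit: LogitFit
    index: np.ndarray      # linear predictor (log-odds scale)
    score: np.ndarray      # probability scale

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.fit.terms, self.fit.params))


def estimate_propensity(frame: pd.DataFrame, covariates: Sequence[str],
                        arm_col: str = "arm") -> PropensityModel:
    """Fit the propensity logit of ``arm_col`` on ``covariates``.

    With no covariates the index is the constant log-odds of treatment.
    """
    arm = frame[arm_col].to_numpy(dtype=float)
    if arm.min() == arm.max():
        raise ValueError("both arms must be present")
    design = frame[list(covariates)] if covariates else np.empty((len(frame), 0))
    f = fit_logit(arm, design)
    index = f.linear_predictor()
    from scipy.special import expit
    return PropensityModel(fit=f, index=index, score=expit(index))


def kernel_match(
    outcome: np.ndarray,
    arm: np.ndarray,
    index: np.ndarray,
    bandwidth: float,
    scale: str = "index",
    score: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Kernel-matched opposite-arm counterfactual for every unit.

    Matching runs on ``index`` (log-odds, default) or ``score``
    (probability) with Epanechnikov weights K((x_j - x_i)/h) over opposite-arm
    units, normalized per unit.  Returns ``(counterfactual, n_fallback)``
    where ``n_fallback`` counts units matched to their single nearest
    neighbour because the kernel window was empty.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if scale == "index":
        x = np.asarray(index, dtype=float)
    elif scale == "probability":
        if score is None:
            raise ValueError("probability scale requires score values")
        x = np.asarray(score, dtype=float)
    else:
        raise ValueError("scale must be 'index' or 'probability'")
    y = np.asarray(outcome, dtype=float)
    t = np.asarray(arm, dtype=int)

    cf = np.empty_like(y)
    fallback = 0
    for arm_val in (0, 1):
        this = np.flatnonzero(t == arm_val)
        other = np.flatnonzero(t != arm_val)
        if other.size == 0:
            raise ValueError("no opposite-arm units to match against")
        # (n_this, n_other) weight matrix
        U = (x[other][None, :] - x[this][:, None]) / bandwidth
        W = epanechnikov(U)
        tot = W.sum(axis=1)
        empty = tot <= 0
        good = ~empty
        cf_this = np.empty(this.size)
        cf_this[good] = (W[good] @ y[other]) / tot[good]
        if np.any(empty):
            fallback += int(empty.sum())
            nearest = np.abs(U[empty]).argmin(axis=1)
            cf_this[empty] = y[other][nearest]
        cf[this] = cf_this
    return cf, fallback


@dataclass
class EffectEstimates:
    """Matched treatment-effect summary with normal-based bootstrap CIs."""

    ate: float
    att: float
    atc: float
    nate: float
    y0: float
    y1: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    reps: int = 0
    seed: int | None = None
    n_fallback: int = 0

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def _effects_from_matched(y, t, cf):
    treated = t == 1
    att = float(np.mean(y[treated] - cf[treated]))
    atc = float(np.mean(cf[~treated] - y[~treated]))
    n1, n0 = int(treated.sum()), int((~treated).sum())
    ate = (n1 * att + n0 * atc) / (n1 + n0)
    nate = float(np.mean(y[treated]) - np.mean(y[~treated]))
    y1 = float(np.mean(np.where(treated, y, cf)))
    y0 = float(np.mean(np.where(treated, cf, y)))
    return ate, att, atc, nate, y0, y1


def estimate_effects(
    frame: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    bandwidth: float | None = None,
    scale: str = "index",
    reps: int = 1000,
    seed: int = 0,
    arm_col: str = "arm",
) -> EffectEstimates:
    """Full kernel-matching effect pipeline on a unit-level cohort.

    Refits the propensity model inside every bootstrap resample.  With
    ``bandwidth=None`` the rule-of-thumb estimator on the propensity index is
    used (never below the index range, for stability on near-degenerate
    indices).
    """
    from .smoothing import rule_of_thumb_bandwidth

    y_all = frame[outcome].to_numpy(dtype=float)
    t_all = frame[arm_col].to_numpy(dtype=int)
    cov_all = frame[list(covariates)].to_numpy(dtype=float) if covariates \
        else np.empty((len(frame), 0))

    def analyze(idx: np.ndarray):
        y, t, C = y_all[idx], t_all[idx], cov_all[idx]
        if t.min() == t.max():
            raise ValueError("resample lost an arm")
        f = fit_logit(t.astype(float), C)
        index = f.linear_predictor()
        if bandwidth is None:
            if np.ptp(index) < 1e-12:
                h = 1.0                       # constant index: any h matches all
            else:
                h = rule_of_thumb_bandwidth(index)
        else:
            h = bandwidth
        from scipy.special import expit
        cf, nfb = kernel_match(y, t, index, h, scale=scale, score=expit(index))
        return _effects_from_matched(y, t, cf), nfb

    (ate, att, atc, nate, y0, y1), n_fallback = analyze(np.arange(len(frame)))

    est = EffectEstimates(ate=ate, att=att, atc=atc, nate=nate, y0=y0, y1=y1,
                          reps=reps, seed=seed, n_fallback=n_fallback)
    if reps >= 2:
        names = ["ate", "att", "atc", "nate", "y0", "y1"]
        point = dict(zip(names, (ate, att, atc, nate, y0, y1)))
        rng = np.random.default_rng(seed)
        draws = np.empty((reps, len(names)))
        n = len(frame)
        for r in range(reps):
            while True:
                idx = rng.integers(0, n, size=n)
                try:
                    draws[r] = analyze(idx)[0]
                    break
                except ValueError:
                    continue
        from scipy import stats as _stats
        z = _stats.norm.isf(0.025)
        sds = draws.std(axis=0, ddof=1)
        for name, sd in zip(names, sds):
            est.se[name] = float(sd)
            est.ci[name] = (point[name] - z * sd, point[name] + z * sd)
    return est
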