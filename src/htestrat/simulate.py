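"""Synthetic two-arm stroke cohorts with the structure the analyses assume.

The generator emulates the statistical skeleton of the trial cohort the
pipeline targets: Bernoulli treatment assignment; a per-arm HTI stratum
distribution; on-admission covariates back-filled so that the HTI recomputed
from (ASPECTS, NIHSS, HMCA, atrial fibrillation) reproduces the drawn value
exactly; binary outcomes following a treatment + HTI logistic structure with
symptomatic HT drawn as a sub-event of any HT; and day-90 mRS from a
proportional-odds model, with favorable functional outcome derived as
mRS <= 2.  The default configuration takes its HTI marginals from the
published per-arm stratum counts and its outcome coefficients from fitting
the reconstructed grouped cohort at call time (nothing hard-coded).

It does not emulate the joint distribution of DRAGON/SEDAN components with
HTI, covariate-outcome links beyond the score, or dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import special

from .cohort import PatientRecord
from .scores import HTI_ASPECTS_BANDS, HTI_NIHSS_BANDS, compute_hti

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "generate_null_cohort",
    "default_cerehetis_config",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    ``beta`` maps each binary outcome name to (intercept, treatment, score)
    log-odds; ``mrs_cutpoints`` are the six increasing thresholds c_j of
    P(mRS <= j) = expit(c_j - eta) with eta = mrs_beta . (arm, hti);
    ``effect_heterogeneity`` adds a score-by-treatment interaction to every
    binary outcome's linear predictor.
    """

    n: int = 238
    treat_frac: float = 91.0 / 238.0
    hti_probs: dict[int, np.ndarray] = field(default_factory=dict)
    beta: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    mrs_cutpoints: tuple[float, ...] = ()
    mrs_beta: tuple[float, float] = (0.0, 0.0)
    effect_heterogeneity: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for arm, p in self.hti_probs.items():
            p = np.asarray(p, float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"hti_probs[{arm}] must be a distribution")
        if len(self.mrs_cutpoints) != 6:
            raise ValueError("mrs_cutpoints must have 6 thresholds")
        if np.any(np.diff(self.mrs_cutpoints) <= 0):
            raise ValueError("mrs_cutpoints must be strictly increasing")
        if not 0.0 < self.treat_frac < 1.0:
            raise ValueError("treat_frac must be in (0, 1)")
        for name in ("sht", "any_ht", "ffo"):
            if name not in self.beta:
                raise ValueError(f"beta missing outcome {name!r}")


# Valid HTI component decompositions: points from ASPECTS band (0-3),
# NIHSS band (0-3), HMCA (0-1), AF on ECG (0-1).
_DECOMPOSITIONS: dict[int, list[tuple[int, int, int, int]]] = {}
for _a in range(4):
    for _n in range(4):
        for _h in range(2):
            for _f in range(2):
                _DECOMPOSITIONS.setdefault(_a + _n + _h + _f, []).append(
                    (_a, _n, _h, _f))

_ASPECTS_RANGE = {pts: rng for rng, pts in HTI_ASPECTS_BANDS.items()}
_NIHSS_RANGE = {pts: rng for rng, pts in HTI_NIHSS_BANDS.items()}


def _backfill_components(hti: int, rng: np.random.Generator):
    """Draw (aspects, nihss, hmca, af) consistent with a target HTI."""
    a_pts, n_pts, hmca, af = _DECOMPOSITIONS[hti][
        rng.integers(len(_DECOMPOSITIONS[hti]))]
    lo, hi = _ASPECTS_RANGE[a_pts]
    aspects = int(rng.integers(lo, hi + 1))
    lo, hi = _NIHSS_RANGE[n_pts]
    nihss = int(rng.integers(lo, hi + 1))
    return aspects, nihss, hmca, af


def _linpred(beta, arm, hti, interaction):
    b0, bt, bs = beta
    return b0 + bt * arm + bs * hti + interaction * arm * hti


def generate_cohort(config: GeneratorConfig,
                    seed: int | None = None) -> list[PatientRecord]:
    """Draw a cohort of ``config.n`` validated patient records.

    Identical config and seed give an identical cohort.  Symptomatic HT is a
    conditional sub-event of any HT, so sht <= any_ht record-wise; ffo is
    derived from the drawn mRS.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    inter = config.effect_heterogeneity

    records = []
    for i in range(config.n):
        arm = int(rng.random() < config.treat_frac)
        probs = np.asarray(config.hti_probs[arm], dtype=float)
        hti = int(rng.choice(probs.size, p=probs))
        aspects, nihss, hmca, af = _backfill_components(hti, rng)
        assert compute_hti(aspects, nihss, hmca, af) == hti

        p_any = special.expit(_linpred(config.beta["any_ht"], arm, hti, inter))
        p_sht = special.expit(_linpred(config.beta["sht"], arm, hti, inter))
        any_ht = int(rng.random() < p_any)
        p_cond = min(1.0, p_sht / p_any) if p_any > 0 else 0.0
        sht = int(any_ht and rng.random() < p_cond)

        eta = config.mrs_beta[0] * arm + config.mrs_beta[1] * hti
        cum = special.expit(np.asarray(config.mrs_cutpoints) - eta)
        u = rng.random()
        mrs = int(np.searchsorted(cum, u))

        age = float(np.clip(rng.normal(67.0, 10.0), 30.0, 99.0))
        glucose = float(np.clip(rng.lognormal(np.log(6.3), 0.25), 3.0, 30.0))
        records.append(PatientRecord(
            id=f"S{i:05d}", arm=arm, age=age,
            sex=int(rng.random() < 0.55), nihss=nihss, aspects=aspects,
            hmca=hmca, af_ecg=af, glucose=glucose,
            prestroke_mrs=int(rng.choice(3, p=[0.8, 0.15, 0.05])),
            onset_to_treatment=float(rng.uniform(45.0, 240.0)),
            sht=sht, any_ht=any_ht, mrs90=mrs, ffo=int(mrs <= 2),
        ))
        records[-1].validate(row=i)
    return records


def generate_null_cohort(config: GeneratorConfig,
                         seed: int | None = None) -> list[PatientRecord]:
    """As :func:`generate_cohort` with all treatment effects forced to zero."""
    null_beta = {k: (b0, 0.0, bs) for k, (b0, bt, bs) in config.beta.items()}
    null = replace(config, beta=null_beta,
                   mrs_beta=(0.0, config.mrs_beta[1]),
                   effect_heterogeneity=0.0)
    return generate_cohort(null, seed=seed)


#: Offsets of the remaining mRS cutpoints around the calibrated c_2
#: (chosen to give a plausible day-90 disability spread: most mass at
#: mRS 0-3, a small death fraction).
_MRS_CUT_OFFSETS = (-2.2, -1.0, 0.0, 1.2, 2.3, 3.6)


def default_cerehetis_config(n: int = 238, seed: int = 0) -> GeneratorConfig:
    """Configuration mimicking the published trial cohort.

    Per-arm HTI marginals come from the printed stratum counts; outcome
    coefficients are obtained by fitting treatment + HTI logits to the
    reconstructed grouped cohort at call time.  The mRS proportional-odds
    scale is calibrated so that P(mRS <= 2) reproduces the favorable-outcome
    logistic model at every (arm, HTI) cell: c_2 equals the FFO intercept
    and mrs_beta the negated FFO (treatment, score) coefficients.
    """
    from .cohort import printed_cerehetis_cohort
    from .logit import fit_logit

    cohort = printed_cerehetis_cohort()
    units = cohort.expand_units()
    X = units[["arm", "hti"]]
    beta = {}
    for name in ("sht", "any_ht", "ffo"):
        f = fit_logit(units[name].to_numpy(), X)
        beta[name] = tuple(float(b) for b in f.params)

    b0_ffo, bt_ffo, bs_ffo = beta["ffo"]
    cutpoints = tuple(b0_ffo + off for off in _MRS_CUT_OFFSETS)

    probs = {}
    for arm in (0, 1):
        counts = np.zeros(5)
        for s in cohort.strata:
            if s.arm == arm:
                counts[s.score] += s.n
        probs[arm] = counts / counts.sum()

    return GeneratorConfig(
        n=n,
        treat_frac=91.0 / 238.0,
        hti_probs=probs,
        beta=beta,
        mrs_cutpoints=cutpoints,
        mrs_beta=(-bt_ffo, -bs_ffo),
        seed=seed,
    )
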