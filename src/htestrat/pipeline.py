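"""End-to-end analysis pipeline and consolidated report bundle.

``run_pipeline`` executes the full risk-stratified HTE analysis in the order
of the underlying study: baseline two-arm comparison, logistic fits with the
postestimation battery, endpoint contingency tests, score-conditional
margins, kernel-matching treatment effects, subgroup meta-analytic
heterogeneity, and the matching-smoothing HTE report.  Every stage's
parameters (seed included) are recorded in the emitted bundle; the input
cohort is never mutated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (GroupedCohort, build_grouped_cohort, contingency_test,
                     printed_cerehetis_cohort, records_to_frame)
from .effects import estimate_effects, estimate_propensity
from .logit import conditional_margins, fit_logit
from .meta import (egger_test, forest_data, make_studies, mh_fixed_rd,
                   reml_random)
from .selection import postestimation_report, select_model
from .smoothing import hte_analyze

log = logging.getLogger("htestrat")

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]

_BINARY_OUTCOMES = ("sht", "any_ht", "ffo")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    input: str | None = None          # CSV path; None => printed fixture
    outcomes: tuple[str, ...] = _BINARY_OUTCOMES
    score: str = "hti"
    bootstrap_reps: int = 1000
    seed: int = 0
    hte_ci: str = "bootstrap"
    output_dir: str | None = None

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the global one (stable, documented).

        seed_stage = int(sha256(f"{seed}:{stage}")[:8], 16) % 2**31 — so each
        stage is individually reproducible from the global seed.
        """
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).hexdigest()
        return int(digest[:8], 16) % (2 ** 31)


def _load_units(config: PipelineConfig) -> tuple[pd.DataFrame, GroupedCohort]:
    if config.input is None:
        grouped = printed_cerehetis_cohort()
        units = grouped.expand_units()
        return units, grouped
    from .cohort import read_cohort
    from .scores import compute_hti
    records = read_cohort(config.input)
    units = records_to_frame(records)
    if "hti" not in units.columns or units.get("hti") is None:
        units["hti"] = [
            compute_hti(r.aspects, r.nihss, r.hmca, r.af_ecg) for r in records
        ]
    grouped = build_grouped_cohort(records, units["hti"].tolist())
    return units, grouped


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage; return the JSON-serializable report bundle."""
    units, grouped = _load_units(config)
    input_hash = hashlib.sha256(
        pd.util.hash_pandas_object(units, index=True).values.tobytes()
    ).hexdigest()
    bundle: dict = {
        "meta": {
            "version": __version__,
            "seed": config.seed,
            "bootstrap_reps": config.bootstrap_reps,
            "n": int(len(units)),
            "outcomes": list(config.outcomes),
            "score": config.score,
        }
    }

    # Baseline arm sizes and per-stratum layout (endpoint-table shape).
    log.info("stage=baseline n=%d", len(units))
    bundle["baseline"] = {
        "n_by_arm": units.groupby("arm").size().to_dict(),
        "score_distribution": {
            str(arm): grp[config.score].value_counts().sort_index().to_dict()
            for arm, grp in units.groupby("arm")
        },
    }

    # Endpoint 2x2 tests.
    endpoints = {}
    for out in config.outcomes:
        tot = grouped.arm_totals(out)
        (e1, n1), (e0, n0) = tot[1], tot[0]
        chi2, p = contingency_test(e1, n1 - e1, e0, n0 - e0)
        endpoints[out] = {
            "treated": {"events": e1, "n": n1},
            "control": {"events": e0, "n": n0},
            "chi2": chi2, "p": p,
        }
    bundle["endpoints"] = endpoints

    # Logistic fits + postestimation battery (model-selection-report shape).
    log.info("stage=models")
    X = units[["arm", config.score]]
    fits = {}
    reports = {}
    for out in config.outcomes:
        f = fit_logit(units[out].to_numpy(), X)
        fits[out] = f
        reports[out] = postestimation_report(out, f,
                                             continuous_terms=[config.score])
    bundle["models"] = {k: f.to_dict() for k, f in fits.items()}
    bundle["postestimation"] = {k: r.to_dict() for k, r in reports.items()}

    # Score-conditional margins, Sidak corrected across the whole table.
    levels = sorted(units[config.score].unique())
    if config.input is None:
        levels = [0, 1, 2, 3, 4]
    n_intervals = 2 * len(levels) * len(config.outcomes)
    margins = {}
    for out in config.outcomes:
        ms = conditional_margins(fits[out], levels, correction="sidak",
                                 m_intervals=n_intervals,
                                 arm_term="arm", score_term=config.score)
        margins[out] = ms.to_dict()
    bundle["margins"] = margins

    # Kernel-matching treatment effects.
    log.info("stage=effects reps=%d", config.bootstrap_reps)
    eff = {}
    for out in config.outcomes:
        eff[out] = estimate_effects(
            units, out, [config.score],
            reps=config.bootstrap_reps,
            seed=config.stage_seed(f"effects:{out}"),
        ).to_dict()
    prop = estimate_propensity(units, [config.score])
    bundle["propensity"] = {k: float(v) for k, v in prop.coefficients.items()}
    bundle["effects"] = eff

    # Subgroup meta-analytic heterogeneity.
    log.info("stage=meta")
    meta = {}
    for out in config.outcomes:
        studies = make_studies(grouped, out, drop_empty_arm=True)
        res_f = mh_fixed_rd(studies)
        res_r = reml_random(studies)
        try:
            egger_b, egger_p = egger_test(studies)
        except ValueError:
            egger_b, egger_p = float("nan"), float("nan")
        meta[out] = {
            "n_studies": len(studies),
            "n": int(sum(s.n1 + s.n0 for s in studies)),
            "fixed": res_f.to_dict(),
            "random": res_r.to_dict(),
            "egger": {"bias": egger_b, "p": egger_p},
            "forest_random": forest_data(res_r, studies).to_dict("records"),
        }
    bundle["meta_heterogeneity"] = meta

    # Matching-smoothing HTE (Table-5-style report).
    log.info("stage=hte ci=%s", config.hte_ci)
    hte = {}
    for out in config.outcomes:
        curve, score_effects, diag = hte_analyze(
            units, out, covariates=[config.score], score_col=config.score,
            ci=config.hte_ci, reps=config.bootstrap_reps,
            seed=config.stage_seed(f"hte:{out}"),
        )
        hte[out] = {
            "diagnostics": diag,
            "score_effects": [e.to_dict() for e in score_effects],
            "curve": curve.to_frame().to_dict("records"),
        }
    bundle["hte"] = hte

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("baseline", "endpoints", "postestimation", "margins",
                     "effects", "meta_heterogeneity", "hte"):
            (outdir / f"{name}.json").write_text(
                json.dumps(bundle[name], indent=1, sort_keys=True))
        (outdir / "bundle.json").write_text(
            json.dumps(bundle, indent=1, sort_keys=True))

    bundle["meta"]["input_hash"] = input_hash
    final_hash = hashlib.sha256(
        pd.util.hash_pandas_object(units, index=True).values.tobytes()
    ).hexdigest()
    if final_hash != input_hash:
        raise RuntimeError("pipeline mutated the input cohort")
    return bundle


def render_report(bundle: dict) -> str:
    """Human-readable single-document summary of a report bundle."""
    m = bundle["meta"]
    lines = [
        "Risk-stratified heterogeneous treatment effect report",
        f"  version {m['version']}  seed {m['seed']}  "
        f"bootstrap reps {m['bootstrap_reps']}  n {m['n']}",
        f"  config hash {m.get('input_hash', '?')[:12]}",
        "",
    ]
    if not m["outcomes"]:
        lines.append("no outcomes requested")
        return "\n".join(lines)
    lines.append("Endpoints (treated vs control):")
    for out, e in bundle["endpoints"].items():
        lines.append(
            f"  {out:8s} {e['treated']['events']}/{e['treated']['n']} vs "
            f"{e['control']['events']}/{e['control']['n']}  "
            f"chi2={e['chi2']:.3f} p={e['p']:.3f}")
    lines.append("")
    lines.append("Model fit (treatment + score logit):")
    for out, r in bundle["postestimation"].items():
        lines.append(
            f"  {out:8s} AIC={r['aic']:.2f} BIC={r['bic']:.2f} "
            f"AUC={r['auc']:.2f} McFadden={r['mcfadden']:.3f}")
    lines.append("")
    lines.append("Heterogeneity (risk differences by score stratum):")
    for out, h in bundle["meta_heterogeneity"].items():
        r = h["random"]
        lines.append(
            f"  {out:8s} k={h['n_studies']} REML tau2={r['tau2']:.5f} "
            f"I2={r['i2']:.1f}% H2={r['h2']:.2f}")
    lines.append("")
    lines.append("Matching-smoothing treatment effects by score:")
    for out, h in bundle["hte"].items():
        for e in h["score_effects"]:
            lines.append(
                f"  {out:8s} score={e['score']} index={e['propensity']:+.3f} "
                f"TE={e['te']:+.3f} CI=({e['ci'][0]:+.3f}, {e['ci'][1]:+.3f}) "
                f"p={e['p']:.3f}")
    return "\n".join(lines)
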