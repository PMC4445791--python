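"""The two-step biological/lived health analysis pipeline.

Step 1 scores biological health from the biological items with a
covariate-free multilevel IRT model (intercept + dwelling random effects
only).  Step 2 models lived health on environmental covariates while
controlling for the step-1 biological score, entered as a known predictor
with its error fixed to zero.  An empty lived-health model (intercept +
random effects) provides the baselines for the intraclass correlation and
the proportions of person- and dwelling-level variance explained, and a
third fit without the biological-health control supplies the DIC comparison
for the value of that control.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as diag
from .data import (AidUseTable, CovariateSet, DwellingIndex, ItemBank,
                   ResponseMatrix, collapse_categories,
                   equate_lived_with_biological, filter_respondents,
                   load_aid_use, load_dwellings, load_responses, load_weights,
                   weighted_descriptives)
from .model import MLIRTModel, MLIRTResults

__all__ = ["PipelineConfig", "PipelineResult", "step1_biological",
           "step2_lived", "fit_empty_model", "icc", "variance_explained",
           "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    bundle_dir: str | Path
    item_bank_bio: ItemBank
    item_bank_lived: ItemBank
    collapse_mapping: dict[int, int] | None = None
    n_iterations: int = 5000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    link: str = "probit"
    ld_threshold: float = 0.25
    mono_tol: float = 0.03
    min_bin_size: int = 50
    robustness_min_correlation: float = 0.95
    robustness_max_mad: float = 0.1
    run_checks: bool = True
    output_dir: str | Path | None = None


@dataclass
class PipelineResult:
    bio_scores: pd.Series
    step1_summary: pd.DataFrame
    step2_summary: pd.DataFrame
    step2_results: MLIRTResults
    empty_summary: pd.DataFrame
    icc: float
    variance_explained_person: float
    variance_explained_dwelling: float
    dic: dict[str, float]
    diagnostics_bio: diag.DiagnosticsReport | None
    diagnostics_lived: diag.DiagnosticsReport | None
    robustness: dict[str, diag.RobustnessResult] = field(default_factory=dict)
    descriptives: pd.DataFrame | None = None
    n_persons: int = 0
    n_dwellings: int = 0

    def report_dict(self) -> dict:
        return {
            "n_persons": self.n_persons,
            "n_dwellings": self.n_dwellings,
            "icc": self.icc,
            "variance_explained": {
                "person": self.variance_explained_person,
                "dwelling": self.variance_explained_dwelling,
            },
            "dic": self.dic,
            "step2_fixed_effects": {
                row: {"mean": round(float(r["mean"]), 3),
                      "sd": round(float(r["sd"]), 3),
                      "hpd": [round(float(r["hpd_lower"]), 3),
                              round(float(r["hpd_upper"]), 3)]}
                for row, r in self.step2_summary.iterrows()
                if not row.startswith(("a[", "kappa"))
            },
            "diagnostics": {
                "biological": (self.diagnostics_bio.to_dict()
                               if self.diagnostics_bio else None),
                "lived": (self.diagnostics_lived.to_dict()
                          if self.diagnostics_lived else None),
            },
            "robustness": {k: vars(v) for k, v in self.robustness.items()},
        }


# ---------------------------------------------------------------------------
# individual steps


def step1_biological(rm_bio: ResponseMatrix, dwellings: DwellingIndex,
                     *, n_iterations=5000, burn_in=1000, thin=1, seed=0,
                     link="probit"):
    """Score biological health: covariate-free MLIRT with dwelling effects.

    Returns ``(scores, results)`` with standardized posterior-mean scores
    (higher = worse biological health).
    """
    model = MLIRTModel(rm_bio, dwellings, link=link)
    res = model.fit(n_iterations=n_iterations, burn_in=burn_in, thin=thin,
                    seed=seed)
    return res.scores, res


def step2_lived(rm_lived: ResponseMatrix, bio_scores: pd.Series,
                covariates: CovariateSet, dwellings: DwellingIndex,
                *, n_iterations=5000, burn_in=1000, thin=1, seed=0,
                link="probit") -> MLIRTResults:
    """Lived-health structural model controlling for biological health.

    The biological score joins the person-level design as a known predictor
    (error fixed to zero).  Persons must match between the responses and
    the score vector.
    """
    missing = [p for p in rm_lived.person_ids if p not in bio_scores.index]
    if missing:
        raise ValueError(f"biological scores missing for {len(missing)} "
                         f"person(s), e.g. {missing[:3]}")
    X = covariates.person_design.loc[rm_lived.person_ids].copy()
    X.insert(0, "bio_health", bio_scores.loc[rm_lived.person_ids].to_numpy())
    model = MLIRTModel(rm_lived, dwellings, person_covariates=X,
                       dwelling_covariates=covariates.dwelling_design,
                       fixed_covariates=("bio_health",), link=link)
    return model.fit(n_iterations=n_iterations, burn_in=burn_in, thin=thin,
                     seed=seed)


def fit_empty_model(rm: ResponseMatrix, dwellings: DwellingIndex,
                    *, n_iterations=5000, burn_in=1000, thin=1, seed=0,
                    link="probit") -> MLIRTResults:
    """Intercept + dwelling random effect only: the variance baseline."""
    model = MLIRTModel(rm, dwellings, link=link)
    return model.fit(n_iterations=n_iterations, burn_in=burn_in, thin=thin,
                     seed=seed)


def icc(tau2: float, sigma2: float) -> float:
    """Share of latent-score variance attributable to dwellings."""
    if tau2 < 0 or sigma2 < 0:
        raise ValueError("variances must be nonnegative")
    if tau2 + sigma2 == 0:
        raise ValueError("both variance components are zero")
    return tau2 / (tau2 + sigma2)


def variance_explained(empty_results: MLIRTResults,
                       full_results: MLIRTResults) -> tuple[float, float]:
    """Proportional reduction in residual variance, by level.

    person level: (sigma2_0 - sigma2_1) / sigma2_0;
    dwelling level: (tau2_0 - tau2_1) / tau2_0.
    Negative proportions are reported as-is with a warning.
    """
    s0, s1 = empty_results.sigma2, full_results.sigma2
    t0, t1 = empty_results.tau2, full_results.tau2
    if s0 <= 0 or t0 <= 0:
        raise ValueError("empty-model baseline variance is zero")
    person = (s0 - s1) / s0
    dwelling = (t0 - t1) / t0
    if person < 0 or dwelling < 0:
        warnings.warn("negative variance explained (covariates increased a "
                      "residual variance)", RuntimeWarning, stacklevel=2)
    return person, dwelling


# ---------------------------------------------------------------------------
# orchestration


def _load_covariates(bundle: Path) -> CovariateSet:
    Xp = pd.read_csv(bundle / "covariates_person.csv",
                     dtype={"person_id": str}).set_index("person_id")
    Wd = pd.read_csv(bundle / "covariates_dwelling.csv",
                     dtype={"dwelling_id": str}).set_index("dwelling_id")
    return CovariateSet(person_design=Xp, dwelling_design=Wd)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis on a CSV bundle.

    Stages: load -> collapse -> filter respondents -> equate lived with
    biological -> assumption checks -> item selection (+ robustness re-fit
    when items are dropped) -> step-1 biological scoring -> step-2 lived
    structural model -> empty model -> ICC, variance explained and the DIC
    triple (empty / full / no biological control).
    """
    stage = "load"
    try:
        bundle = Path(config.bundle_dir)
        rm_bio = load_responses(bundle / "responses_biological.csv",
                                config.item_bank_bio)
        # non-aid users have no observed lived answers yet; keep their rows
        # so the equating stage can fill them from the biological matrix
        rm_lived = load_responses(bundle / "responses_lived.csv",
                                  config.item_bank_lived,
                                  drop_all_missing=False)
        dwellings = load_dwellings(bundle / "dwellings.csv")
        covariates = _load_covariates(bundle)
        aid = load_aid_use(bundle / "aid_use.csv")
        weights = (load_weights(bundle / "weights.csv")
                   if (bundle / "weights.csv").exists() else None)

        stage = "collapse"
        if config.collapse_mapping is not None:
            rm_bio = collapse_categories(rm_bio, config.collapse_mapping)
            rm_lived = collapse_categories(rm_lived, config.collapse_mapping)

        stage = "filter"
        kept, n_kept = filter_respondents(rm_bio)
        rm_bio = rm_bio.take_persons(kept)
        common = [p for p in kept if p in set(rm_lived.person_ids)]
        rm_bio = rm_bio.take_persons(common)
        rm_lived = rm_lived.take_persons(common)
        logger.info("retained %d respondents with any difficulty", len(common))

        stage = "equate"
        rm_lived = equate_lived_with_biological(rm_bio, rm_lived, aid)

        stage = "descriptives"
        descr = None
        if weights is not None:
            w = weights.loc[common]
            descr = weighted_descriptives(
                covariates.person_design.loc[common], w)

        stage = "assumption checks"
        report_bio = report_lived = None
        retained_bio = rm_bio.item_bank.item_ids
        retained_lived = rm_lived.item_bank.item_ids
        robustness: dict[str, diag.RobustnessResult] = {}
        short = dict(n_iterations=max(300, config.n_iterations // 5),
                     burn_in=max(100, config.burn_in // 5),
                     seed=config.seed + 90)
        if config.run_checks:
            report_bio = diag.run_diagnostics(
                rm_bio, ld_threshold=config.ld_threshold,
                min_bin_size=config.min_bin_size, mono_tol=config.mono_tol)
            report_lived = diag.run_diagnostics(
                rm_lived, ld_threshold=config.ld_threshold,
                min_bin_size=config.min_bin_size, mono_tol=config.mono_tol)
            # provisional discriminations for the within-subset retention rule
            for rm, report, label in ((rm_bio, report_bio, "biological"),
                                      (rm_lived, report_lived, "lived")):
                need_fit = report.ld_subsets or any(
                    v.passed is False for v in report.monotonicity.values())
                if need_fit:
                    prov = MLIRTModel(rm, dwellings, link=config.link).fit(
                        **short)
                    retained = diag.select_items(report, prov.discrimination)
                else:
                    retained = diag.select_items(
                        report, pd.Series(1.0, index=report.item_ids))
                if label == "biological":
                    retained_bio = retained
                else:
                    retained_lived = retained
            stage = "robustness"
            for rm, retained, label in ((rm_bio, retained_bio, "biological"),
                                        (rm_lived, retained_lived, "lived")):
                if len(retained) < rm.n_items:
                    with_all = MLIRTModel(rm, dwellings, link=config.link) \
                        .fit(**short).scores
                    without = MLIRTModel(rm.take_items(retained), dwellings,
                                         link=config.link).fit(**short).scores
                    robustness[label] = diag.robustness_check(
                        with_all, without,
                        config.robustness_min_correlation,
                        config.robustness_max_mad)
        rm_bio_final = rm_bio.take_items(retained_bio)
        rm_lived_final = rm_lived.take_items(retained_lived)

        stage = "step 1 (biological score)"
        fit_kw = dict(n_iterations=config.n_iterations, burn_in=config.burn_in,
                      thin=config.thin)
        bio_scores, res1 = step1_biological(rm_bio_final, dwellings,
                                            seed=config.seed,
                                            link=config.link, **fit_kw)

        stage = "step 2 (lived structural model)"
        res2 = step2_lived(rm_lived_final, bio_scores, covariates, dwellings,
                           seed=config.seed + 1, link=config.link, **fit_kw)

        stage = "empty model"
        res_empty = fit_empty_model(rm_lived_final, dwellings,
                                    seed=config.seed + 2, link=config.link,
                                    **fit_kw)

        stage = "no-biological-control model"
        model_nobio = MLIRTModel(rm_lived_final, dwellings,
                                 person_covariates=covariates.person_design,
                                 dwelling_covariates=covariates.dwelling_design,
                                 link=config.link)
        res_nobio = model_nobio.fit(seed=config.seed + 3, **fit_kw)

        stage = "summaries"
        ve_p, ve_d = variance_explained(res_empty, res2)
        result = PipelineResult(
            bio_scores=bio_scores,
            step1_summary=res1.summary(),
            step2_summary=res2.summary(),
            step2_results=res2,
            empty_summary=res_empty.summary(),
            icc=icc(res_empty.tau2, res_empty.sigma2),
            variance_explained_person=ve_p,
            variance_explained_dwelling=ve_d,
            dic={"empty": res_empty.dic()[0],
                 "full": res2.dic()[0],
                 "no_biological_control": res_nobio.dic()[0]},
            diagnostics_bio=report_bio, diagnostics_lived=report_lived,
            robustness=robustness, descriptives=descr,
            n_persons=len(common),
            n_dwellings=len({dwellings.dwelling_of(p) for p in common}))

        if config.output_dir is not None:
            _write_outputs(result, Path(config.output_dir), config)
        return result
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def _write_outputs(result: PipelineResult, outdir: Path,
                   config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    payload = result.report_dict()
    payload["seed"] = config.seed
    (outdir / "report.json").write_text(json.dumps(payload, indent=1))
    result.step1_summary.round(3).to_csv(outdir / "summary_step1.csv")
    result.step2_summary.round(3).to_csv(outdir / "summary_step2.csv")
    (outdir / "dic.json").write_text(json.dumps(result.dic, indent=1))
    if result.descriptives is not None:
        result.descriptives.round(3).to_csv(outdir / "descriptives.csv",
                                            index=False)
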