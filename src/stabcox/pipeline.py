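"""End-to-end orchestration of the variable-discovery workflow.

Stage order: cohort input (file or synthetic) -> optional outlier filter ->
matched derivation/confirmation split -> quintile encoding with thresholds
from the total cohort -> per-outcome CV + stability selection on the
derivation set -> univariate confirmation on the withheld set -> penalized
spline curves -> bootstrap out-of-bag time-dependent AUC.  Every stage seed
derives deterministically from the master seed, and confirmation subjects
never enter selection (asserted at run time).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CauseCode, CohortTable, read_cohort_csv, write_cohort_csv
from .coxnet import ElasticNetConfig
from .encoding import encode_cohort
from .spline import PSplineConfig, PSplineCox, outlier_filter
from .split import best_matched_split
from .stability import StabilityConfig, StabilitySelection
from .stats import baseline_table, cause_specific_outcome, confirmation_table
from .synthetic import SyntheticSpec, default_isar_like_spec, generate_cohort
from .tdroc import OutcomeModelSpec, TDROCConfig, bootstrap_oob_auc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

OUTCOME_CODES = {
    "all-cause": "all-cause",
    "cardiovascular": CauseCode.CARDIOVASCULAR,
    "infection": CauseCode.INFECTION,
}

ALL_STAGES = ("split", "stability", "confirm", "spline", "auc")


@dataclass
class PipelineConfig:
    """Inputs, sub-configs and seeds for one pipeline run.

    Exactly one of (``cohort_csv`` + ``schema_json``) or ``synthetic_spec``
    must be provided.
    """

    outdir: str = "stabcox_run"
    cohort_csv: str | None = None
    schema_json: str | None = None
    synthetic_spec: SyntheticSpec | None = None
    outcomes: tuple[str, ...] = ("all-cause", "cardiovascular", "infection")
    n_splits: int = 1000
    split_ratio: float = 2.0 / 3.0
    en_config: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    stability_config: StabilityConfig = field(default_factory=StabilityConfig)
    pspline_config: PSplineConfig = field(default_factory=PSplineConfig)
    tdroc_config: TDROCConfig = field(default_factory=TDROCConfig)
    spline_variables: list = field(default_factory=list)  # (variable, transform)
    auc_models: list = field(default_factory=list)  # OutcomeModelSpec
    outlier_rules: list = field(default_factory=list)
    master_seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        file_input = self.cohort_csv is not None
        if file_input == (self.synthetic_spec is not None):
            raise ValueError("provide exactly one of cohort files or a synthetic spec")
        if file_input and self.schema_json is None:
            raise ValueError("cohort_csv requires schema_json")
        bad = set(self.outcomes) - set(OUTCOME_CODES)
        if bad:
            raise ValueError(f"unknown outcomes: {sorted(bad)}")

    def stage_rng(self, stage: str, extra: int = 0) -> np.random.Generator:
        """Counter-based per-stage seeding so stages can re-run in isolation."""
        counter = {name: i for i, name in enumerate(
            ("cohort", "split", "encode", "stability", "confirm", "spline", "auc"))}[stage]
        return np.random.default_rng(np.random.SeedSequence((self.master_seed, counter, extra)))

    def smoke(self) -> "PipelineConfig":
        """Reduced-size copy for quick end-to-end runs."""
        cfg = dataclasses.replace(
            self,
            n_splits=50,
            en_config=dataclasses.replace(self.en_config, folds=5, n_alphas=5,
                                          path_length=40, lambda_min_ratio=0.1),
            stability_config=dataclasses.replace(self.stability_config, n_subsamples=10),
            tdroc_config=dataclasses.replace(self.tdroc_config, n_bootstrap=10,
                                             n_imputations=3),
        )
        return cfg


def _load_cohort(config: PipelineConfig) -> CohortTable:
    if config.synthetic_spec is not None:
        return generate_cohort(config.synthetic_spec)
    return read_cohort_csv(config.cohort_csv, config.schema_json)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages, writing a report bundle to ``outdir``.

    Returns a dict of in-memory results keyed by artifact name.  Stage
    failures abort with the stage name; partial artifacts are kept next to a
    ``FAILED`` marker naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "stages": list(config.stages),
        "outcomes": list(config.outcomes),
        "config": {
            "n_splits": config.n_splits,
            "split_ratio": config.split_ratio,
            "en": dataclasses.asdict(config.en_config),
            "stability": dataclasses.asdict(config.stability_config),
            "pspline": dataclasses.asdict(config.pspline_config),
            "tdroc": dataclasses.asdict(config.tdroc_config),
        },
    }
    stage = "cohort"
    try:
        cohort = _load_cohort(config)
        if config.outlier_rules:
            cohort, removal_log = outlier_filter(cohort, config.outlier_rules)
            manifest["outliers_removed"] = [
                {"subject_id": str(r["subject_id"]), "rule": [list(map(str, c)) for c in r["rule"]]}
                for r in removal_log
            ]
        write_cohort_csv(cohort, out / "cohort.csv", out / "schema.json")
        results["cohort"] = cohort

        stage = "split"
        matching = [s for s in cohort.schema if s.matching_variable]
        assignment = best_matched_split(
            cohort, config.n_splits, config.split_ratio, matching,
            config.stage_rng("split"))
        assignment.to_frame(cohort).to_csv(out / "split_assignment.csv")
        table1 = baseline_table(cohort, assignment.derivation_flags, matching)
        table1.to_csv(out / "table1_baseline.csv", index=False)
        results["assignment"] = assignment
        results["table1"] = table1

        derivation = cohort.subset(assignment.derivation_flags)
        confirmation = cohort.subset(~assignment.derivation_flags)
        # derivation/confirmation firewall
        overlap = set(derivation.subject_ids) & set(confirmation.subject_ids)
        assert not overlap, f"derivation/confirmation overlap: {sorted(overlap)[:5]}"

        stage = "encode"
        rng_enc = config.stage_rng("encode")
        # quintile thresholds deliberately come from the total cohort
        design_deriv = encode_cohort(derivation, cohort.schema, cohort, rng_enc)
        design_conf = encode_cohort(confirmation, cohort.schema, cohort,
                                    config.stage_rng("encode", 1))
        results["design_derivation"] = design_deriv
        results["design_confirmation"] = design_conf

        stable_sets: dict = {}
        signs: dict = {}
        if "stability" in config.stages:
            stage = "stability"
            for i, outcome in enumerate(config.outcomes):
                y = cause_specific_outcome(derivation, OUTCOME_CODES[outcome])
                model = StabilitySelection(design_deriv, y,
                                           config=config.stability_config,
                                           en_config=config.en_config)
                fit = model.fit(config.stage_rng("stability", i))
                tag = outcome.replace("-", "_")
                fit.path.to_long_frame().to_csv(out / f"stability_path_{tag}.csv", index=False)
                (out / f"stable_selection_{tag}.json").write_text(
                    json.dumps({"alpha": fit.alpha, **fit.selection.to_json_dict()}, indent=2))
                stable_sets[outcome] = fit.selection
                for feat, sgn in fit.derivation_signs.items():
                    signs[(str(OUTCOME_CODES[outcome]), feat)] = sgn
                    signs[feat] = sgn
                results[f"stability_{outcome}"] = fit
            results["stable_sets"] = stable_sets

        if "confirm" in config.stages and stable_sets:
            stage = "confirm"
            stable_by_code = {OUTCOME_CODES[o]: sel.stable_features
                              for o, sel in stable_sets.items()}
            table2 = confirmation_table(stable_by_code, confirmation, design_conf, signs)
            table2.to_csv(out / "table2_confirmation.csv", index=False)
            results["table2"] = table2

        if "spline" in config.stages and config.spline_variables:
            stage = "spline"
            for var, transform in config.spline_variables:
                y_all = cause_specific_outcome(cohort, "all-cause")
                fit = PSplineCox(cohort.data[var].to_numpy(dtype=float), y_all,
                                 transform, config=config.pspline_config).fit()
                fit.curve().to_frame().to_csv(out / f"spline_curve_{var}.csv", index=False)
                lrt = fit.lrt_vs_linear()
                (out / f"spline_lrt_{var}.json").write_text(json.dumps(
                    {"variable": var, "edf": fit.edf, "statistic": lrt.statistic,
                     "p": lrt.p, "risk_sets": "cause-specific"}, indent=2))
                results[f"spline_{var}"] = fit

        if "auc" in config.stages and config.auc_models:
            stage = "auc"
            frames = []
            for i, model_spec in enumerate(config.auc_models):
                curve = bootstrap_oob_auc(model_spec, cohort, config.tdroc_config,
                                          config.stage_rng("auc", i))
                frames.append(curve.to_frame())
                results[f"auc_{model_spec.label or i}"] = curve
            pd.concat(frames, ignore_index=True).to_csv(out / "auc_curves.csv", index=False)

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc!r}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return results
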