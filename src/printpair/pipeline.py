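"""End-to-end orchestration of the synthetic study analysis.

Stages: simulate (images + panel) -> pair features -> collinearity screen
-> crossed logistic fit + AIC backward selection -> per-pair evaluation,
train/test split and threshold classifier -> JSON/CSV/PNG reports. A
single global seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence.spawn`` so each stage is individually
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import metrics as pm
from .glmm import ModelSpec, aic_backward_select, fit_glmm, lrt
from .synth import PanelConfig, StudyBundle, build_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    n_pairs: int = 200
    canvas: int = 256
    experts_per_pair: int = 10
    seed: int = 0
    block_size: int = 50
    r_threshold: float = 0.5
    vif_limit: float = 5.0
    test_fraction: float = 0.10
    backward_selection: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_pairs < 10:
            raise ValueError("n_pairs must be at least 10")
        if not 0.0 < self.test_fraction < 0.5:
            raise ValueError("test_fraction must lie in (0, 0.5)")
        if self.canvas < 96:
            raise ValueError("canvas must be at least 96 px")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


@dataclass
class RunReport:
    bundle: StudyBundle
    screened_features: pd.DataFrame
    screen_report: list[dict]
    fit: "object"
    selection_trace: list[dict]
    train_eval: ev.EvalReport
    train_classifier: ev.ClassifierResult
    test_classifier: ev.ClassifierResult
    summary: dict = field(default_factory=dict)


def run_all(config: RunConfig) -> RunReport:
    """Run the complete synthetic study and analysis."""
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    sim_seed = int(seeds[0].generate_state(1)[0] % (2**31 - 1))
    split_seed = int(seeds[1].generate_state(1)[0] % (2**31 - 1))

    logger.info("stage simulate: %d pairs, canvas %d, seed %d",
                config.n_pairs, config.canvas, sim_seed)
    bundle = build_study(
        n_pairs=config.n_pairs,
        canvas=config.canvas,
        panel=PanelConfig(experts_per_pair=config.experts_per_pair, seed=sim_seed + 1),
        seed=sim_seed,
        out_dir=config.out_dir,
    )
    trials = bundle.trials.data

    logger.info("stage screen: collinearity at |r|>%.2f, VIF<%g",
                config.r_threshold, config.vif_limit)
    screened, screen_report = pm.collinearity_filter(
        bundle.features, r_threshold=config.r_threshold, vif_limit=config.vif_limit
    )

    fixed = pm.continuous_columns(screened) + \
        [c for c in ("core_L", "core_K", "delta_L", "delta_K") if c in screened.columns] + \
        pm.interaction_columns(screened)
    # keep roughly >= 6 pairs per candidate predictor: small cohorts cannot
    # support the full main + interaction set without separation
    max_p = max(3, config.n_pairs // 6)
    if len(fixed) > max_p:
        mains = [c for c in fixed if not c.endswith("_LxK")]
        fixed = (mains if len(mains) <= max_p else mains[:max_p])
        logger.warning("restricting candidate predictors to %d of the full set",
                       len(fixed))
    spec = ModelSpec(response="correct", fixed=fixed, random=["printID"])
    logger.info("stage fit: %d fixed effects, printID intercept", len(fixed))
    from .glmm import SeparationError

    for _ in range(len(fixed)):
        try:
            if config.backward_selection:
                fit, trace = aic_backward_select(spec, trials, screened)
            else:
                fit, trace = fit_glmm(spec, trials, screened), []
            break
        except SeparationError as exc:
            # a (typically binary) predictor separates the response in a
            # small cohort; drop it and refit
            culprit = next((c for c in spec.fixed if f"'{c}'" in str(exc)), None)
            if culprit is None:
                raise
            logger.warning("dropping separated predictor %s", culprit)
            spec = ModelSpec(response="correct", random=["printID"],
                             fixed=[c for c in spec.fixed if c != culprit])
    else:
        raise RuntimeError("no non-separated predictors remain")
    null = fit_glmm(ModelSpec(response="correct", fixed=[], random=["printID"]),
                    trials, screened)
    predictors_lrt = lrt(fit, null)

    logger.info("stage evaluate: split %d%% held out", round(100 * config.test_fraction))
    per_pair, summary = ev.per_pair_accuracy(trials)
    train_ids, test_ids = ev.split_pairs(per_pair, config.test_fraction, seed=split_seed)

    train_trials = trials[trials["pair_id"].isin(train_ids)]
    test_pp = per_pair[per_pair["pair_id"].isin(test_ids)].reset_index(drop=True)
    train_fit = fit_glmm(fit.spec, train_trials, screened,
                         sigma0=np.array([np.sqrt(max(fit.var_print, 1e-4))]))
    train_eval = ev.evaluate_fit(train_fit, train_trials, screened,
                                 include_print_blup=True)
    test_pred = np.asarray(train_fit.predict(screened.loc[test_ids]))

    train_cls = ev.optimize_threshold(
        train_eval.per_pair["predicted"], train_eval.per_pair["observed"] == 1.0
    )
    test_cls = ev.apply_classifier(train_cls, test_pred, test_pp["observed"] == 1.0)

    summary.update(
        {
            "n_fixed_effects_final": len(fit.spec.fixed),
            "var_print": fit.var_print,
            "aic_final": fit.aic,
            "predictors_lrt_chi2": predictors_lrt.chi2,
            "predictors_lrt_df": predictors_lrt.df,
            "predictors_lrt_p": predictors_lrt.p,
            "r2_adj_train": train_eval.r2_adj,
            "rmse_train": train_eval.rmse,
            "threshold": train_cls.threshold,
            "classifier_train_accuracy": train_cls.accuracy,
            "classifier_test_accuracy": test_cls.accuracy,
            "n_train_pairs": len(train_ids),
            "n_test_pairs": len(test_ids),
        }
    )
    report = RunReport(
        bundle=bundle,
        screened_features=screened,
        screen_report=screen_report,
        fit=fit,
        selection_trace=trace,
        train_eval=train_eval,
        train_classifier=train_cls,
        test_classifier=test_cls,
        summary=summary,
    )
    if config.out_dir is not None:
        write_report(report, Path(config.out_dir))
    return report


def write_report(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.train_eval.per_pair.to_csv(out_dir / "per_pair_accuracy.csv", index=False)
    fit = report.fit
    model = {
        "fixed_effects": {k: float(v) for k, v in fit.beta.items()},
        "standard_errors": {k: float(v) for k, v in fit.se.items()},
        "var_print": fit.var_print,
        "var_expert": fit.var_expert,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "bic": fit.bic,
        "selection_trace": report.selection_trace,
        "collinearity_report": report.screen_report,
    }
    with open(out_dir / "model.json", "w") as fh:
        json.dump(model, fh, indent=2)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2)
    _plot_predicted_observed(report, out_dir / "predicted_vs_observed.png")
    logger.info("reports written to %s", out_dir)


def _plot_predicted_observed(report: RunReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.train_eval.per_pair
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(df["observed"], df["predicted"], s=18, alpha=0.7)
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.axhline(report.train_classifier.threshold, color="tab:red", lw=1,
               label=f"threshold {report.train_classifier.threshold:.2f}")
    ax.set_xlabel("observed pair accuracy")
    ax.set_ylabel("predicted pair accuracy")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
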