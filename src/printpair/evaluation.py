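"""Model assessment: per-pair accuracy, fit quality, validation split and
the perfect/non-perfect threshold classifier.

Observed accuracy for a pair is the fraction of examiners who judged it
correctly. A *perfect pair* is one every examiner got right (observed
accuracy exactly 1). The classifier flags a pair as perfect when its
model-predicted accuracy is at or above a threshold chosen to maximize
training classification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .glmm import FittedGLMM, ModelSpec, fit_glmm, lrt, predict_accuracy


@dataclass
class EvalReport:
    """Per-pair predicted vs observed accuracy with summary fit statistics."""

    per_pair: pd.DataFrame  # pair_id, observed, predicted
    r2_adj: float
    rmse: float
    n_pairs: int


@dataclass
class ClassifierResult:
    """Threshold classifier outcome on one pair set.

    Confusion counts are keyed ``(true class, predicted class)`` with
    classes ``perfect`` / ``nonperfect``.
    """

    threshold: float
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return sum(self.confusion.values())

    @property
    def accuracy(self) -> float:
        n = self.n_pairs
        correct = self.confusion.get(("perfect", "perfect"), 0) + \
            self.confusion.get(("nonperfect", "nonperfect"), 0)
        return correct / n if n else float("nan")


def per_pair_accuracy(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Observed accuracy per pair plus global summaries.

    Returns a per-pair table (observed accuracy, trial count, match status)
    and a summary dict with overall / match-only / non-match-only accuracy
    and the number of perfect (100%-accuracy) pairs.
    """
    g = trials.groupby("pair_id").agg(
        observed=("correct", "mean"),
        n_trials=("correct", "size"),
        is_match=("is_match", "first"),
    )
    summary = {
        "overall_accuracy": float(trials["correct"].mean()),
        "match_accuracy": float(trials.loc[trials["is_match"], "correct"].mean())
        if trials["is_match"].any() else float("nan"),
        "nonmatch_accuracy": float(trials.loc[~trials["is_match"], "correct"].mean())
        if (~trials["is_match"]).any() else float("nan"),
        "n_pairs": int(len(g)),
        "n_trials": int(len(trials)),
        "n_perfect_pairs": int((g["observed"] == 1.0).sum()),
    }
    return g.reset_index(), summary


def fit_quality(
    observed: np.ndarray | pd.Series,
    predicted: np.ndarray | pd.Series,
    n_predictors: int,
) -> tuple[float, float]:
    """Adjusted R² and RMSE of predicted vs observed per-pair accuracy.

    ``r2_adj = 1 - (1 - R²)(n - 1)/(n - k - 1)`` with ``k`` fixed-effect
    predictors. Degenerate observed variance yields ``r2_adj = nan``.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    n = len(obs)
    if n < n_predictors + 2:
        raise ValueError("need at least n_predictors + 2 pairs")
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan"), rmse
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)
    return float(r2_adj), rmse


def evaluate_fit(
    fit: FittedGLMM,
    trials: pd.DataFrame,
    features: pd.DataFrame,
    include_print_blup: bool = False,
) -> EvalReport:
    """Predicted vs observed per-pair accuracy for a fitted accuracy model."""
    per_pair, _ = per_pair_accuracy(trials)
    feats = features if features.index.name == "pair_id" else features.set_index("pair_id")
    rows = feats.loc[per_pair["pair_id"]]
    per_pair = per_pair.assign(
        predicted=np.asarray(predict_accuracy(fit, rows, include_print_blup))
    )
    r2_adj, rmse = fit_quality(per_pair["observed"], per_pair["predicted"],
                               len(fit.spec.fixed))
    return EvalReport(per_pair=per_pair, r2_adj=r2_adj, rmse=rmse, n_pairs=len(per_pair))


def split_pairs(
    per_pair: pd.DataFrame,
    test_fraction: float = 0.10,
    seed: int | np.random.Generator = 0,
    stratify_by_perfect: bool = True,
) -> tuple[pd.Index, pd.Index]:
    """Stratified train/test split of pair ids.

    Stratification preserves the perfect/non-perfect mix (each stratum
    contributes ``round(test_fraction * stratum size)`` test pairs, at
    least one). Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ids = pd.Index(per_pair["pair_id"])
    perfect = per_pair["observed"].to_numpy() == 1.0
    strata = [perfect, ~perfect] if stratify_by_perfect else [np.ones(len(ids), bool)]
    test_ids: list = []
    for stratum in strata:
        members = ids[stratum]
        if stratify_by_perfect and len(members) == 0:
            raise ValueError("a perfect/non-perfect stratum is empty; cannot stratify")
        n_test = max(1, round(test_fraction * len(members))) if len(members) else 0
        if n_test >= len(members) and len(members):
            raise ValueError("stratum too small for the requested test fraction")
        take = rng.choice(len(members), size=n_test, replace=False)
        test_ids.extend(members[np.sort(take)])
    test = pd.Index(test_ids)
    train = ids[~ids.isin(test)]
    return train, test


def _confusion(pred_perfect: np.ndarray, is_perfect: np.ndarray) -> dict:
    conf = {}
    for t, tname in ((True, "perfect"), (False, "nonperfect")):
        for p, pname in ((True, "perfect"), (False, "nonperfect")):
            conf[(tname, pname)] = int(((is_perfect == t) & (pred_perfect == p)).sum())
    return conf


def classify(predicted: np.ndarray, threshold: float) -> np.ndarray:
    """Pairs with predicted accuracy >= threshold are classified perfect."""
    return np.asarray(predicted, float) >= threshold


def optimize_threshold(
    predicted: np.ndarray | pd.Series, is_perfect: np.ndarray | pd.Series
) -> ClassifierResult:
    """Choose the classification threshold maximizing training accuracy.

    Candidate thresholds are the sorted unique predicted values plus 0 and
    1; ties favour the higher (more conservative) threshold, which flags
    more pairs as error-prone.
    """
    pred = np.asarray(predicted, float)
    perf = np.asarray(is_perfect, bool)
    if perf.all() or (~perf).all():
        raise ValueError("both classes must be present to optimize a threshold")
    candidates = np.unique(np.concatenate([pred, [0.0, 1.0]]))
    best_t, best_acc = 0.0, -1.0
    for t in candidates:  # ascending: later ties overwrite -> higher threshold wins
        acc = float(((pred >= t) == perf).mean())
        if acc >= best_acc:
            best_t, best_acc = float(t), acc
    return ClassifierResult(threshold=best_t,
                            confusion=_confusion(pred >= best_t, perf))


def apply_classifier(
    result: ClassifierResult,
    predicted: np.ndarray | pd.Series,
    is_perfect: np.ndarray | pd.Series,
) -> ClassifierResult:
    """Apply a training-derived threshold to held-out pairs."""
    pred = np.asarray(predicted, float)
    perf = np.asarray(is_perfect, bool)
    return ClassifierResult(
        threshold=result.threshold,
        confusion=_confusion(pred >= result.threshold, perf),
    )


def augment_with_difficulty(
    spec: ModelSpec,
    trials: pd.DataFrame,
    features: pd.DataFrame,
) -> tuple[ModelSpec, pd.DataFrame, dict]:
    """Add mean per-pair difficulty rating as a (standardized) fixed effect.

    Returns the augmented spec, a feature table with the new
    ``mean_difficulty`` column, and a comparison report (LRT and AIC of the
    augmented vs base model). The report flags the predictor as subjective:
    unlike the image metrics it depends on raters, so models meant to run
    on image content alone should exclude it.
    """
    if "difficulty" not in trials.columns or trials["difficulty"].isna().all():
        raise ValueError("difficulty ratings are missing from the trial table")
    mean_diff = trials.groupby("pair_id")["difficulty"].mean()
    sd = mean_diff.std(ddof=0)
    z = (mean_diff - mean_diff.mean()) / sd if sd > 0 else mean_diff * 0.0
    feats = features if features.index.name == "pair_id" else features.set_index("pair_id")
    feats = feats.copy()
    feats["mean_difficulty"] = z.reindex(feats.index)
    aug_spec = replace(spec, fixed=list(spec.fixed) + ["mean_difficulty"])

    base = fit_glmm(spec, trials, feats)
    aug = fit_glmm(aug_spec, trials, feats)
    report = {
        "lrt": lrt(aug, base),
        "aic_base": base.aic,
        "aic_augmented": aug.aic,
        "aic_improved": aug.aic < base.aic,
        "subjective_predictor": "mean_difficulty",
        "note": "difficulty ratings are subjective and rater-dependent; "
                "objective image metrics remain the primary predictors",
    }
    return aug_spec, feats, report
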