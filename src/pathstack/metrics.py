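"""Evaluation metrics and cross-validation harnesses.

Metrics: AUC (Mann–Whitney pair statistic), PRAUC (step-curve area),
balanced accuracy at a fixed probability threshold, and the Pearson
correlation between predicted probabilities and the 0/1 labels. The two
harnesses are a nested repeated stratified cross-validation of the full
two-stage pipeline (all selection — stage-1 screening, positivity,
de-correlation, unmapped ranking — re-run inside each outer training fold,
so outer-test labels are never touched), and a conventional top-N baseline
that ranks all features by |PCC| inside each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .annotation import FeaturePartition
from .learners import LearnerSpec, make_learner
from .stage1 import OmicsDataset, columnwise_pcc, pearson_correlation
from .stage2 import PipelineConfig, fit_pipeline

__all__ = [
    "roc_auc",
    "pr_auc",
    "balanced_accuracy",
    "prediction_label_pcc",
    "EvaluationReport",
    "repeated_nested_cv",
    "baseline_topn",
]

METRICS = ("auc", "prauc", "bac", "pcc")


def _check_binary(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


def roc_auc(scores, labels) -> float:
    """Probability a random case outranks a random control (ties count half)."""
    labels = _check_binary(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores, labels) -> float:
    """Area under the precision–recall step curve over distinct thresholds.

    Tied scores are grouped at a single threshold; the area is
    sum over thresholds of (recall step) × (precision at that threshold).
    """
    labels = _check_binary(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def balanced_accuracy(scores, labels, threshold: float = 0.5) -> float:
    """(sensitivity + specificity) / 2 with case predicted at score >= threshold."""
    labels = _check_binary(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    y = labels.astype(bool)
    sens = pred[y].mean()
    spec = (~pred[~y]).mean()
    return float((sens + spec) / 2)


def prediction_label_pcc(scores, labels) -> float:
    """Pearson correlation of predicted probabilities with 0/1 labels.

    NaN when the predictions are constant (recorded as missing upstream).
    """
    return pearson_correlation(np.asarray(scores, dtype=float),
                               np.asarray(labels, dtype=float))


@dataclass
class EvaluationReport:
    """Per-fold metric values plus summary statistics.

    ``summary`` rows carry the mean and two dispersion readings: the SD over
    all r×k folds and the SD over the r repetition means (which of the two a
    publication reports is often unstated, so both are kept). Undefined PCC
    values (constant predictions) are excluded from the mean with their
    count reported.
    """

    per_fold: pd.DataFrame  # columns: repetition, fold, metric, value
    config: dict = field(default_factory=dict)

    @property
    def summary(self) -> pd.DataFrame:
        rows = []
        for metric in METRICS:
            vals = self.per_fold.loc[self.per_fold["metric"] == metric, :]
            v = vals["value"]
            missing = int(v.isna().sum())
            rep_means = vals.dropna(subset=["value"]).groupby("repetition")["value"].mean()
            rows.append({
                "metric": metric,
                "mean": float(v.mean()),
                "sd_folds": float(v.std(ddof=1)) if v.notna().sum() > 1 else 0.0,
                "sd_repetitions": float(rep_means.std(ddof=1)) if len(rep_means) > 1 else 0.0,
                "n_folds": int(v.notna().sum()),
                "n_missing": missing,
            })
        return pd.DataFrame(rows)

    def mean(self, metric: str) -> float:
        s = self.summary.set_index("metric")
        return float(s.loc[metric, "mean"])


def _fold_metrics(scores, labels) -> dict[str, float]:
    return {
        "auc": roc_auc(scores, labels),
        "prauc": pr_auc(scores, labels),
        "bac": balanced_accuracy(scores, labels),
        "pcc": prediction_label_pcc(scores, labels),
    }


def repeated_nested_cv(
    ds: OmicsDataset,
    part: FeaturePartition,
    stage1_learner: LearnerSpec,
    stage2_learner: LearnerSpec,
    cfg: PipelineConfig,
    *,
    k: int = 5,
    r: int = 10,
    seed: int = 0,
    workers: int = 1,
) -> EvaluationReport:
    """Nested evaluation of the two-stage pipeline.

    Outer loop: r repetitions of stratified k-fold CV. For each outer fold
    the whole pipeline (stage-1 out-of-fold matrix, positivity and
    correlation filters, unmapped selection, stage-2 fit) is fit on the
    outer-training samples only; the outer-test samples are scored through
    the refit stage-1 models.
    """
    rows = []
    for rep in range(r):
        rs = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31 - 1))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        for fold, (tr, te) in enumerate(skf.split(ds.X, ds.y)):
            inner_cfg = PipelineConfig(
                stage1=_reseed(cfg.stage1, rs + fold),
                top_n=cfg.top_n,
                stage2_cutoff=cfg.stage2_cutoff,
                unmapped_mode=cfg.unmapped_mode,
            )
            model = fit_pipeline(ds.subset_samples(tr), part, stage1_learner,
                                 stage2_learner, inner_cfg, workers=workers)
            scores = model.predict_proba(ds.X[te], ds.feature_ids)
            for metric, value in _fold_metrics(scores, ds.y[te]).items():
                rows.append({"repetition": rep, "fold": fold,
                             "metric": metric, "value": value})
    report = EvaluationReport(per_fold=pd.DataFrame(rows))
    report.config = {
        "stage1_learner": stage1_learner.learner_id,
        "stage2_learner": stage2_learner.learner_id,
        "k": k, "r": r, "seed": seed,
        "B": cfg.stage1.B, "cutoff": cfg.stage1.cutoff,
        "top_n": cfg.top_n, "stage2_cutoff": cfg.stage2_cutoff,
    }
    return report


def _reseed(s1, seed: int):
    from .stage1 import Stage1Config

    return Stage1Config(B=s1.B, n_folds=s1.n_folds, cutoff=s1.cutoff,
                        fallback_k=s1.fallback_k, seed=seed, resampling=s1.resampling)


def baseline_topn(
    ds: OmicsDataset,
    learner: LearnerSpec,
    *,
    n_grid=(500, 1000, 2000, 5000, 10000, 15000),
    k: int = 5,
    r: int = 10,
    seed: int = 0,
) -> tuple[dict[int, EvaluationReport], int]:
    """Conventional baseline: top-N features by |PCC|, one model, r×k CV.

    Within each training fold all features are ranked by |PCC| with the
    labels and the top N retained before fitting. Returns one report per N
    (N above the feature count is clamped with a warning) and the N with
    the best mean AUC.
    """
    import warnings

    n_features = ds.X.shape[1]
    reports: dict[int, EvaluationReport] = {}
    for n in n_grid:
        if n < 1:
            raise ValueError("n_grid values must be >= 1")
        n_eff = min(n, n_features)
        if n_eff < n:
            warnings.warn(f"top-N {n} exceeds feature count {n_features}; clamped")
        rows = []
        for rep in range(r):
            rs = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31 - 1))
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
            for fold, (tr, te) in enumerate(skf.split(ds.X, ds.y)):
                absr = np.abs(columnwise_pcc(ds.X[tr], ds.y[tr]))
                absr = np.where(np.isnan(absr), -np.inf, absr)
                top = np.lexsort((np.arange(n_features), -absr))[:n_eff]
                est = make_learner(learner, random_state=rs + fold)
                est.fit(ds.X[np.ix_(tr, top)], ds.y[tr])
                proba = est.predict_proba(ds.X[np.ix_(te, top)])
                cls1 = int(np.flatnonzero(est.classes_ == 1)[0])
                scores = proba[:, cls1]
                for metric, value in _fold_metrics(scores, ds.y[te]).items():
                    rows.append({"repetition": rep, "fold": fold,
                                 "metric": metric, "value": value})
        rep_obj = EvaluationReport(per_fold=pd.DataFrame(rows))
        rep_obj.config = {"learner": learner.learner_id, "top_n": n, "k": k,
                          "r": r, "seed": seed}
        reports[n] = rep_obj
    best_n = max(reports, key=lambda n: reports[n].mean("auc"))
    return reports, best_n
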