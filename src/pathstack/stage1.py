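"""Stage 1: compress raw omics features into pathway-level scores.

For every pathway, the features mapped to it are reduced to a single
meta-feature per sample: the mean out-of-fold class-1 probability over B
repetitions of seeded, stratified k-fold cross-validation. Within each
training fold, features are first screened by absolute Pearson correlation
with the outcome; the learner is then fit on the surviving features and
scores the held-out fold. Because feature selection runs strictly inside
each training fold, the out-of-fold scores carry no information about a
sample's own label.

Fold partitions are seeded by (global seed, pathway index, repetition
index), so pathways are independent of each other and of execution order:
running with one worker or many gives bitwise-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from sklearn.model_selection import StratifiedKFold

from .annotation import FeaturePartition
from .learners import LearnerSpec, make_learner

__all__ = [
    "OmicsDataset",
    "Stage1Config",
    "PathwayFeatureMatrix",
    "pearson_correlation",
    "columnwise_pcc",
    "select_pathway_features",
    "stage1_pathway_score",
    "build_stage1_matrix",
    "fit_stage1_state",
    "transform_new_samples",
    "Stage1State",
]


@dataclass
class OmicsDataset:
    """Samples × features matrix with binary labels (0 control, 1 case)."""

    X: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples × features)")
        if self.X.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("X shape does not match sample/feature id counts")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("label vector length mismatch")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be coded 0/1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def subset_samples(self, idx) -> "OmicsDataset":
        idx = np.asarray(idx)
        return OmicsDataset(
            X=self.X[idx],
            y=self.y[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=self.feature_ids,
        )


@dataclass(frozen=True)
class Stage1Config:
    """Controls for the pathway-compression stage.

    B : repetitions of the resampling loop (scores are averaged over B)
    n_folds : folds per repetition (stratified)
    cutoff : within-pathway |PCC| screening threshold; the grid explored in
        practice is {0, 0.05, 0.1, 0.2, 0.3, 0.5}
    fallback_k : features kept when none pass the cutoff (top-|PCC|)
    resampling : "cv" (every sample scored once per repetition) or
        "bootstrap" (out-of-bag scoring; samples average over the
        repetitions in which they were out-of-bag)
    """

    B: int = 5
    n_folds: int = 5
    cutoff: float = 0.3
    fallback_k: int = 10
    seed: int = 0
    resampling: str = "cv"

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0 <= self.cutoff < 1):
            raise ValueError("cutoff must be in [0, 1)")
        if self.fallback_k < 1:
            raise ValueError("fallback_k must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.resampling not in ("cv", "bootstrap"):
            raise ValueError("resampling must be 'cv' or 'bootstrap'")


@dataclass
class PathwayFeatureMatrix:
    """Samples × pathways matrix of mean out-of-fold scores in [0, 1]."""

    S: np.ndarray
    pathway_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape[1] != len(self.pathway_ids):
            raise ValueError("column count does not match pathway ids")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("scores must be finite")
        if self.S.min() < -1e-12 or self.S.max() > 1 + 1e-12:
            raise ValueError("scores must lie in [0, 1]")


# ---------------------------------------------------------------------------
# correlation screening


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def columnwise_pcc(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """PCC of every column of ``X`` with ``y`` (NaN for constant columns)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    sy = np.sqrt(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    return np.clip(r, -1.0, 1.0)


def select_pathway_features(X_k, y, cutoff: float, fallback_k: int) -> np.ndarray:
    """Indices of features with |PCC| above ``cutoff``, with top-k fallback.

    Returns indices in original order. If no feature passes the cutoff, the
    ``fallback_k`` features with largest |PCC| are returned (ties broken by
    original order); fewer than ``fallback_k`` features means all of them.
    """
    X_k = np.atleast_2d(np.asarray(X_k, dtype=float))
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class fold: cannot screen features")
    r = np.abs(columnwise_pcc(X_k, y))
    r_rank = np.where(np.isnan(r), -np.inf, r)
    passing = np.flatnonzero(r_rank > cutoff)
    if passing.size:
        return passing
    order = np.lexsort((np.arange(len(r_rank)), -r_rank))  # |PCC| desc, then index
    return np.sort(order[: min(fallback_k, len(r_rank))])


# ---------------------------------------------------------------------------
# out-of-fold pathway scores


def _fold_seed(seed: int, pathway_index: int, rep: int) -> int:
    ss = np.random.SeedSequence([seed, pathway_index, rep])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _fit_score_fold(X_train, y_train, X_test, learner: LearnerSpec,
                    cfg: Stage1Config, rs: int) -> np.ndarray:
    """Screen features on the training fold, fit, score the held-out fold."""
    sel = select_pathway_features(X_train, y_train, cfg.cutoff, cfg.fallback_k)
    # constant-in-fold features carry no information and break some learners
    keep = sel[X_train[:, sel].std(axis=0) > 0]
    if keep.size == 0:
        return np.full(X_test.shape[0], y_train.mean())
    est = make_learner(learner, random_state=rs)
    est.fit(X_train[:, keep], y_train)
    proba = est.predict_proba(X_test[:, keep])
    cls1 = int(np.flatnonzero(est.classes_ == 1)[0])
    return np.clip(proba[:, cls1], 0.0, 1.0)


def stage1_pathway_score(
    X_k,
    y,
    learner: LearnerSpec,
    cfg: Stage1Config,
    *,
    pathway_index: int = 0,
    return_repetitions: bool = False,
):
    """Mean out-of-fold class-1 score for one pathway's feature block.

    Each of the B repetitions partitions the samples into stratified
    ``n_folds`` folds (seeded by global seed, pathway index and repetition);
    every sample receives one out-of-fold score per repetition and the final
    score is the mean over repetitions. With ``resampling='bootstrap'``
    each repetition instead draws a bootstrap sample and only out-of-bag
    samples are scored, averaging over the repetitions where a sample was
    out-of-bag (samples never out-of-bag fall back to the overall case rate).
    """
    X_k = np.atleast_2d(np.asarray(X_k, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    M = X_k.shape[0]
    reps = np.empty((M, cfg.B))
    oob_mask = np.zeros((M, cfg.B), dtype=bool)
    for b in range(cfg.B):
        rs = _fold_seed(cfg.seed, pathway_index, b)
        if cfg.resampling == "cv":
            skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=rs)
            for fold, (tr, te) in enumerate(skf.split(X_k, y)):
                try:
                    reps[te, b] = _fit_score_fold(
                        X_k[tr], y[tr], X_k[te], learner, cfg, rs + fold + 1
                    )
                except Exception as exc:  # noqa: BLE001 - annotate context
                    raise RuntimeError(
                        f"learner {learner.learner_id!r} failed on pathway index "
                        f"{pathway_index}, repetition {b}, fold {fold}: {exc}"
                    ) from exc
            oob_mask[:, b] = True
        else:  # bootstrap
            rng = np.random.default_rng(rs)
            boot = rng.integers(0, M, size=M)
            if len(np.unique(y[boot])) < 2:  # resample until both classes present
                while len(np.unique(y[boot])) < 2:
                    boot = rng.integers(0, M, size=M)
            oob = np.setdiff1d(np.arange(M), boot)
            reps[:, b] = np.nan
            if oob.size:
                reps[oob, b] = _fit_score_fold(
                    X_k[boot], y[boot], X_k[oob], learner, cfg, rs + 1
                )
                oob_mask[oob, b] = True
    if cfg.resampling == "cv":
        mean = reps.mean(axis=1)
    else:
        with np.errstate(invalid="ignore"):
            sums = np.where(oob_mask, reps, 0.0).sum(axis=1)
            counts = oob_mask.sum(axis=1)
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), y.mean())
    if return_repetitions:
        return mean, reps
    return mean


def build_stage1_matrix(
    ds: OmicsDataset,
    part: FeaturePartition,
    learner: LearnerSpec,
    cfg: Stage1Config,
    *,
    workers: int = 1,
) -> PathwayFeatureMatrix:
    """Out-of-fold pathway-score matrix, one column per pathway.

    Pathways are embarrassingly parallel; per-pathway seeds make the result
    invariant to worker count and execution order.
    """
    if not part.mapped:
        raise ValueError("empty feature partition")
    findex = ds.feature_index()
    jobs = []
    for k, (pid, feats) in enumerate(part.mapped.items()):
        if not feats:
            raise ValueError(f"pathway {pid} has zero mapped features")
        cols = [findex[f] for f in feats]
        jobs.append((k, pid, cols))
    scores = Parallel(n_jobs=workers)(
        delayed(stage1_pathway_score)(
            ds.X[:, cols], ds.y, learner, cfg, pathway_index=k
        )
        for k, _pid, cols in jobs
    )
    S = np.column_stack(scores)
    return PathwayFeatureMatrix(S=S, pathway_ids=[pid for _, pid, _ in jobs],
                                sample_ids=list(ds.sample_ids))


# ---------------------------------------------------------------------------
# full-fit state for scoring new samples


@dataclass
class Stage1State:
    """Per-pathway feature subsets and learners refit on the full training set."""

    pathway_ids: list[str]
    selected_features: dict[str, list[str]]
    models: dict[str, object]
    feature_ids: list[str]
    priors: dict[str, float]


def fit_stage1_state(
    ds: OmicsDataset,
    part: FeaturePartition,
    learner: LearnerSpec,
    cfg: Stage1Config,
) -> Stage1State:
    """Refit one learner per pathway on all training samples (for transform)."""
    findex = ds.feature_index()
    selected: dict[str, list[str]] = {}
    models: dict[str, object] = {}
    priors: dict[str, float] = {}
    for k, (pid, feats) in enumerate(part.mapped.items()):
        if not feats:
            raise ValueError(f"pathway {pid} has zero mapped features")
        cols = np.array([findex[f] for f in feats])
        sel = select_pathway_features(ds.X[:, cols], ds.y, cfg.cutoff, cfg.fallback_k)
        keep = sel[ds.X[:, cols[sel]].std(axis=0) > 0]
        priors[pid] = float(ds.y.mean())
        if keep.size == 0:
            selected[pid] = []
            models[pid] = None
            continue
        est = make_learner(learner, random_state=_fold_seed(cfg.seed, k, cfg.B))
        est.fit(ds.X[:, cols[keep]], ds.y)
        selected[pid] = [feats[i] for i in keep]
        models[pid] = est
    return Stage1State(
        pathway_ids=list(part.mapped),
        selected_features=selected,
        models=models,
        feature_ids=list(ds.feature_ids),
        priors=priors,
    )


def transform_new_samples(state: Stage1State, X_new, feature_ids) -> PathwayFeatureMatrix:
    """Pathway scores for new samples from the refit stage-1 models.

    ``feature_ids`` must cover every feature selected during fitting; labels
    of the new samples are never consulted.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    findex = {f: i for i, f in enumerate(feature_ids)}
    missing = sorted(set(state.feature_ids) - findex.keys())
    if missing:
        raise ValueError(f"missing features in new data: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    cols = []
    for pid in state.pathway_ids:
        model = state.models[pid]
        feats = state.selected_features[pid]
        if model is None or not feats:
            cols.append(np.full(X_new.shape[0], state.priors[pid]))
            continue
        idx = [findex[f] for f in feats]
        proba = model.predict_proba(X_new[:, idx])
        cls1 = int(np.flatnonzero(model.classes_ == 1)[0])
        cols.append(np.clip(proba[:, cls1], 0.0, 1.0))
    return PathwayFeatureMatrix(S=np.column_stack(cols),
                                pathway_ids=list(state.pathway_ids))
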