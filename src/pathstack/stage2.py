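"""Stage 2: assemble the reduced design and fit the final classifier.

The stage-2 design concatenates (a) pathway-level scores that survive a
positive-association filter and a greedy de-correlation pass, with (b) the
top unmapped raw features ranked by absolute correlation with the outcome.
Pathway columns must correlate *positively* with the outcome: under pure
noise, out-of-fold scores inversely associated with the label arise by
chance and carry no reusable signal, so they are discarded. Unmapped
features are kept by |PCC| regardless of sign — the positivity rule applies
to pathway-level scores only.

All selection statistics are computed on the training samples handed in;
callers evaluating by cross-validation must pass training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotation import FeaturePartition
from .learners import LearnerSpec, make_learner
from .stage1 import (
    OmicsDataset,
    PathwayFeatureMatrix,
    Stage1Config,
    Stage1State,
    build_stage1_matrix,
    columnwise_pcc,
    fit_stage1_state,
    transform_new_samples,
)

__all__ = [
    "UnmappedSelection",
    "Stage2Dataset",
    "PipelineConfig",
    "positive_filter",
    "prune_correlated",
    "select_unmapped",
    "assemble_stage2",
    "fit_pipeline",
    "FittedPipeline",
]


@dataclass
class UnmappedSelection:
    top_n: int
    selected_ids: list[str]
    scores: np.ndarray  # |PCC| with the outcome, same order as selected_ids


@dataclass
class Stage2Dataset:
    Z: np.ndarray
    column_ids: list[str]
    column_roles: list[str]  # "pathway" | "unmapped"
    y: np.ndarray


TOP_N_GRID = (0, 100, 300, 500, 1000)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end configuration of the two-stage pipeline.

    ``top_n`` follows the grid {0, 100, 300, 500, 1000}; ``None`` (the
    default) selects the value from that grid by stratified cross-validated
    AUC on the training data, treating it as a hyperparameter of the
    framework. ``stage2_cutoff`` follows {0.8, 1.0}, where 1.0 disables
    pruning entirely (no absolute correlation exceeds 1).
    """

    stage1: Stage1Config = field(default_factory=Stage1Config)
    top_n: int | None = None
    stage2_cutoff: float = 0.8
    unmapped_mode: str = "all"  # "strict" or "all"
    top_n_grid: tuple[int, ...] = TOP_N_GRID

    def __post_init__(self):
        if self.top_n is not None and self.top_n < 0:
            raise ValueError("top_n must be >= 0")
        if not (0 < self.stage2_cutoff <= 1.0):
            raise ValueError("stage2_cutoff must be in (0, 1]")


def positive_filter(S: np.ndarray, y) -> np.ndarray:
    """Indices of columns with strictly positive PCC against the outcome.

    Constant columns (undefined correlation) are treated as non-positive.
    """
    r = columnwise_pcc(np.asarray(S, dtype=float), np.asarray(y, dtype=float))
    return np.flatnonzero(np.nan_to_num(r, nan=-1.0) > 0)


def prune_correlated(S: np.ndarray, y, cutoff: float) -> np.ndarray:
    """Greedy de-correlation of (already positive) columns.

    Columns are visited in descending outcome-PCC order (ties by original
    position); a column is kept iff its |PCC| with every already-kept column
    is <= ``cutoff``. With ``cutoff == 1.0`` nothing is pruned. Returned
    indices are in original column order.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[1]
    if n == 0:
        return np.array([], dtype=int)
    r = np.nan_to_num(columnwise_pcc(S, np.asarray(y, dtype=float)), nan=-np.inf)
    visit = np.lexsort((np.arange(n), -r))
    kept: list[int] = []
    for j in visit:
        ok = True
        for i in kept:
            rij = columnwise_pcc(S[:, [j]], S[:, i])[0]
            if np.abs(np.nan_to_num(rij, nan=0.0)) > cutoff:
                ok = False
                break
        if ok:
            kept.append(j)
    return np.sort(np.array(kept, dtype=int))


def select_unmapped(X_unmapped: np.ndarray, feature_ids, y, top_n: int) -> UnmappedSelection:
    """Top-``top_n`` unmapped features by |PCC| with the outcome.

    Ties (and NaN correlations, ranked last) break by original order.
    """
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    feature_ids = list(feature_ids)
    if top_n == 0 or not feature_ids:
        return UnmappedSelection(top_n=top_n, selected_ids=[], scores=np.array([]))
    r = np.abs(columnwise_pcc(np.asarray(X_unmapped, dtype=float), np.asarray(y, dtype=float)))
    r_rank = np.where(np.isnan(r), -np.inf, r)
    order = np.lexsort((np.arange(len(r_rank)), -r_rank))[: min(top_n, len(r_rank))]
    return UnmappedSelection(
        top_n=top_n,
        selected_ids=[feature_ids[i] for i in order],
        scores=np.where(np.isfinite(r_rank[order]), r_rank[order], np.nan),
    )


def assemble_stage2(
    S: PathwayFeatureMatrix,
    X_unmapped: np.ndarray,
    selection: UnmappedSelection,
    y,
    cutoff: float,
) -> Stage2Dataset:
    """Combine filtered pathway columns with selected unmapped columns.

    Pathway columns pass through :func:`positive_filter` then
    :func:`prune_correlated`; unmapped columns are appended unmodified.
    """
    y = np.asarray(y)
    pos = positive_filter(S.S, y)
    Spos = S.S[:, pos]
    keep_rel = prune_correlated(Spos, y, cutoff)
    keep = pos[keep_rel]
    blocks, ids, roles = [], [], []
    if keep.size:
        blocks.append(S.S[:, keep])
        ids.extend(S.pathway_ids[i] for i in keep)
        roles.extend(["pathway"] * keep.size)
    if selection.selected_ids:
        blocks.append(np.atleast_2d(np.asarray(X_unmapped, dtype=float)))
        ids.extend(selection.selected_ids)
        roles.extend(["unmapped"] * len(selection.selected_ids))
    if not blocks:
        raise ValueError("empty stage-2 design: no pathway or unmapped columns survived")
    return Stage2Dataset(Z=np.column_stack(blocks), column_ids=ids, column_roles=roles, y=y)


def _select_top_n(S, X_un, unmapped_ids, y, cfg: PipelineConfig,
                  stage2_learner: LearnerSpec, n_folds: int = 5) -> int:
    """Choose top_n from the grid by stratified CV AUC on the training data.

    The stage-1 scores entering the candidate designs are the out-of-fold
    scores; unmapped ranking, positivity and pruning are re-run inside each
    training split. Ties favour the smaller grid value (fewer features).
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y)
    grid = sorted(set(cfg.top_n_grid))
    if X_un.shape[1] == 0 or len(grid) == 1:
        return grid[0] if grid else 0
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.stage1.seed)
    aucs = {n: [] for n in grid}
    for tr, te in skf.split(S.S, y):
        S_tr = PathwayFeatureMatrix(S=S.S[tr], pathway_ids=list(S.pathway_ids))
        for n in grid:
            sel = select_unmapped(X_un[tr], unmapped_ids, y[tr], n)
            un_index = {f: i for i, f in enumerate(unmapped_ids)}
            cols = [un_index[f] for f in sel.selected_ids]
            try:
                d2 = assemble_stage2(S_tr, X_un[np.ix_(tr, cols)], sel, y[tr],
                                     cfg.stage2_cutoff)
            except ValueError:
                aucs[n].append(0.5)
                continue
            est = make_learner(stage2_learner, random_state=cfg.stage1.seed)
            est.fit(d2.Z, y[tr])
            pcol = {p: i for i, p in enumerate(S.pathway_ids)}
            blocks = []
            pkeep = [pcol[c] for c, r in zip(d2.column_ids, d2.column_roles)
                     if r == "pathway"]
            if pkeep:
                blocks.append(S.S[np.ix_(te, pkeep)])
            if cols:
                blocks.append(X_un[np.ix_(te, cols)])
            Z_te = np.column_stack(blocks)
            cls1 = int(np.flatnonzero(est.classes_ == 1)[0])
            aucs[n].append(roc_auc_score(y[te], est.predict_proba(Z_te)[:, cls1]))
    means = {n: float(np.mean(v)) for n, v in aucs.items()}
    best = max(means.values())
    return min(n for n, m in means.items() if m >= best - 1e-12)


# ---------------------------------------------------------------------------
# end-to-end fit / predict


@dataclass
class FittedPipeline:
    """Everything needed to score new samples.

    Holds the refit stage-1 state, the stage-2 column choice (retained
    pathway ids and selected unmapped feature ids) and the fitted stage-2
    learner. New samples are scored by transforming raw features into
    pathway scores, slicing the retained columns, appending the unmapped
    raw values, and applying the stage-2 learner.
    """

    stage1_state: Stage1State
    stage2_model: object
    pathway_columns: list[str]
    unmapped_columns: list[str]
    config: PipelineConfig
    stage1_matrix: PathwayFeatureMatrix  # OOF scores on the training samples
    column_roles: list[str]

    def predict_proba(self, X_new, feature_ids) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        findex = {f: i for i, f in enumerate(feature_ids)}
        missing = [f for f in self.unmapped_columns if f not in findex]
        if missing:
            raise ValueError(f"missing unmapped features in new data: {missing[:10]}")
        if self.pathway_columns == ["__prior__"]:
            Z = np.zeros((X_new.shape[0], 1))
            proba = self.stage2_model.predict_proba(Z)
            cls1 = int(np.flatnonzero(self.stage2_model.classes_ == 1)[0])
            return np.clip(proba[:, cls1], 0.0, 1.0)
        S_new = transform_new_samples(self.stage1_state, X_new, feature_ids)
        pcol = {p: i for i, p in enumerate(S_new.pathway_ids)}
        blocks = []
        if self.pathway_columns:
            blocks.append(S_new.S[:, [pcol[p] for p in self.pathway_columns]])
        if self.unmapped_columns:
            blocks.append(X_new[:, [findex[f] for f in self.unmapped_columns]])
        Z = np.column_stack(blocks)
        proba = self.stage2_model.predict_proba(Z)
        cls1 = int(np.flatnonzero(self.stage2_model.classes_ == 1)[0])
        return np.clip(proba[:, cls1], 0.0, 1.0)


def fit_pipeline(
    ds: OmicsDataset,
    part: FeaturePartition,
    stage1_learner: LearnerSpec,
    stage2_learner: LearnerSpec,
    cfg: PipelineConfig,
    *,
    workers: int = 1,
) -> FittedPipeline:
    """Fit the full two-stage pipeline on a training set.

    Stage-1 scores used for stage-2 selection and fitting are the
    out-of-fold scores, so the stage-2 learner never sees in-sample
    stage-1 predictions.
    """
    S = build_stage1_matrix(ds, part, stage1_learner, cfg.stage1, workers=workers)
    findex = ds.feature_index()
    unmapped_ids = part.unmapped(cfg.unmapped_mode)
    X_un = ds.X[:, [findex[f] for f in unmapped_ids]] if unmapped_ids else np.empty((ds.n_samples, 0))
    top_n = cfg.top_n
    if top_n is None:
        top_n = _select_top_n(S, X_un, unmapped_ids, ds.y, cfg, stage2_learner)
    selection = select_unmapped(X_un, unmapped_ids, ds.y, top_n)
    un_index = {f: i for i, f in enumerate(unmapped_ids)}
    sel_idx = [un_index[f] for f in selection.selected_ids]
    try:
        d2 = assemble_stage2(S, X_un[:, sel_idx], selection, ds.y, cfg.stage2_cutoff)
    except ValueError:
        # nothing survived the filters (e.g. all pathway columns constant or
        # negatively associated, no unmapped selected): fall back to the
        # class prior so prediction stays well-defined
        d2 = Stage2Dataset(Z=np.zeros((ds.n_samples, 1)), column_ids=["__prior__"],
                           column_roles=["pathway"], y=ds.y)
        warnings.warn("empty stage-2 design; falling back to the class prior")
    est = make_learner(stage2_learner, random_state=cfg.stage1.seed)
    est.fit(d2.Z, ds.y)
    state = fit_stage1_state(ds, part, stage1_learner, cfg.stage1)
    return FittedPipeline(
        stage1_state=state,
        stage2_model=est,
        pathway_columns=[c for c, r in zip(d2.column_ids, d2.column_roles) if r == "pathway"],
        unmapped_columns=[c for c, r in zip(d2.column_ids, d2.column_roles) if r == "unmapped"],
        config=cfg,
        stage1_matrix=S,
        column_roles=list(d2.column_roles),
    )
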