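"""Pathway-module discovery on the pathway-level score matrix.

Pathway score columns are clustered — in control samples only — with a
weighted-correlation-network approach: soft-thresholded absolute
correlation adjacency, topological overlap similarity, average-linkage
hierarchical clustering with a static tree cut, and iterative merging of
modules whose eigenvectors are highly correlated. Each resulting module is
summarised per sample by its eigenvector (first left singular vector of
the standardized member columns, computed on the full sample), tested for
case–control difference by a Wilcoxon rank-sum test, and scored for
biological coherence by the explanatory fraction: the largest share of the
module's pathways tracing back to one common non-root ontology ancestor.
The (minModuleSize, mergeCutHeight) pair is chosen on a grid to maximise
the mean explanatory fraction over assigned modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stage1 import columnwise_pcc, pearson_correlation

__all__ = [
    "ModuleGridConfig",
    "ModuleAssignment",
    "ModuleReport",
    "soft_adjacency",
    "topological_overlap",
    "cluster_modules",
    "module_eigenvector",
    "module_phenotype_test",
    "explanatory_fraction",
    "grid_select",
    "significant_modules",
]


@dataclass(frozen=True)
class ModuleGridConfig:
    """Grid of clustering controls.

    beta : soft-threshold exponent of the unsigned adjacency (default 6,
        the conventional unsigned-network choice)
    min_module_sizes / merge_cut_heights : the grid searched by
        :func:`grid_select`; modules merge when their eigenvector
        correlation is >= 1 − mergeCutHeight
    cut_quantile : static tree-cut height as a quantile of the pairwise
        topological-overlap dissimilarities
    """

    beta: float = 6.0
    min_module_sizes: tuple[int, ...] = (5, 10, 15)
    merge_cut_heights: tuple[float, ...] = (0.1, 0.2, 0.3)
    cut_quantile: float = 0.99
    seed: int = 0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not self.min_module_sizes or not self.merge_cut_heights:
            raise ValueError("grids must be nonempty")
        if any(not (0 < h < 1) for h in self.merge_cut_heights):
            raise ValueError("merge_cut_heights must lie in (0, 1)")


@dataclass
class ModuleAssignment:
    """Disjoint modules over pathway ids plus the unassigned ('grey') set."""

    modules: dict[str, list[str]]
    unassigned: list[str]

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def module_of(self) -> dict[str, str]:
        out = {p: m for m, members in self.modules.items() for p in members}
        out.update({p: "grey" for p in self.unassigned})
        return out


@dataclass
class ModuleReport:
    """Per-module summaries at the selected grid point."""

    assignment: ModuleAssignment
    table: pd.DataFrame  # module_id, size, wilcoxon_p, explanatory_fraction, dominant_ancestor
    eigenvectors: pd.DataFrame  # samples × modules
    mean_fraction: float
    chosen_min_module_size: int
    chosen_merge_cut_height: float
    grid_scores: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# network construction


def soft_adjacency(S_controls: np.ndarray, beta: float = 6.0) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned soft-threshold adjacency a_ij = |PCC(col_i, col_j)|^beta.

    Constant columns are removed with a warning. Returns the adjacency and
    the indices of the retained columns; the diagonal is 1 by convention.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    S = np.atleast_2d(np.asarray(S_controls, dtype=float))
    if S.shape[0] < 3:
        raise ValueError("need at least 3 samples to correlate columns")
    keep = np.flatnonzero(S.std(axis=0) > 0)
    if keep.size < S.shape[1]:
        warnings.warn(f"removed {S.shape[1] - keep.size} constant column(s)")
    C = np.corrcoef(S[:, keep], rowvar=False)
    C = np.atleast_2d(C)
    A = np.abs(np.clip(C, -1, 1)) ** beta
    np.fill_diagonal(A, 1.0)
    return A, keep


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of an adjacency matrix.

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)
    with connectivity k_i = Σ_{u≠i} a_iu; TOM_ii = 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0  # diagonal of A0 is 0, so u=i and u=j drop out automatically
    k = A0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A0) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# eigenvectors and clustering


def module_eigenvector(S: np.ndarray, cols) -> np.ndarray:
    """First left singular vector of a module's standardized columns.

    Columns are standardized to mean 0, SD 1 over all samples first; the
    unit-norm eigenvector's sign is chosen so that its correlation with the
    mean standardized column is non-negative.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    cols = np.asarray(list(cols), dtype=int)
    if cols.size == 0:
        raise ValueError("empty module")
    sub = S[:, cols]
    sd = sub.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("module contains constant column(s)")
    Z = (sub - sub.mean(axis=0)) / sd
    u, s, _vt = np.linalg.svd(Z, full_matrices=False)
    e = u[:, 0]
    ref = Z.mean(axis=1)
    r = pearson_correlation(e, ref)
    if np.isfinite(r) and r < 0:
        e = -e
    return e


def _static_cut(tom: np.ndarray, min_module_size: int, cut_quantile: float) -> list[list[int]]:
    n = tom.shape[0]
    if n < 2:
        return []
    d = 1.0 - tom
    condensed = squareform((d + d.T) / 2, checks=False)
    link = linkage(condensed, method="average")
    # cut just below the top of the dendrogram: branches merging within
    # cut_quantile of the tallest merge are treated as distinct modules
    height = cut_quantile * float(link[:, 2].max())
    labels = fcluster(link, t=height, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    return [sorted(m) for m in clusters.values() if len(m) >= min_module_size]


def cluster_modules(
    tom: np.ndarray,
    S_controls: np.ndarray,
    pathway_ids,
    min_module_size: int,
    merge_cut_height: float,
) -> ModuleAssignment:
    """Average-linkage clustering on 1 − TOM with eigenvector merging.

    Branches from a static cut (dissimilarity quantile height) of size >=
    ``min_module_size`` become initial modules; remaining pathways are left
    unassigned. Modules whose eigenvectors (computed on the clustering
    samples) correlate at >= 1 − ``merge_cut_height`` are then merged
    iteratively until stable. Module ids are ``ME1, ME2, ...`` by
    descending size; labels carry no cross-run identity.
    """
    tom = np.asarray(tom, dtype=float)
    if tom.shape[0] != len(list(pathway_ids)):
        raise ValueError("TOM size does not match pathway ids")
    return _cluster_at(tom, S_controls, pathway_ids, min_module_size,
                       merge_cut_height, cut_quantile=0.99)


def _cluster_at(tom, S_controls, pathway_ids, min_module_size, merge_cut_height,
                cut_quantile):
    pathway_ids = list(pathway_ids)
    if len(pathway_ids) < min_module_size:
        warnings.warn("fewer pathways than min_module_size: nothing assigned")
        return ModuleAssignment(modules={}, unassigned=list(pathway_ids))
    groups = _static_cut(np.asarray(tom, float), min_module_size, cut_quantile)
    merge_thresh = 1.0 - merge_cut_height
    while len(groups) > 1:
        eigs = np.column_stack([module_eigenvector(S_controls, g) for g in groups])
        C = np.abs(np.corrcoef(eigs, rowvar=False))  # unsigned network
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] < merge_thresh:
            break
        merged = sorted(groups[i] + groups[j])
        groups = [g for idx, g in enumerate(groups) if idx not in (i, j)] + [merged]
    groups = sorted(groups, key=lambda g: (-len(g), g))
    modules = {f"ME{k + 1}": [pathway_ids[i] for i in g] for k, g in enumerate(groups)}
    assigned = {i for g in groups for i in g}
    unassigned = [pathway_ids[i] for i in range(len(pathway_ids)) if i not in assigned]
    return ModuleAssignment(modules=modules, unassigned=unassigned)


# ---------------------------------------------------------------------------
# module statistics


def module_phenotype_test(eigenvector, y) -> float:
    """Two-sided Wilcoxon rank-sum P for case vs control eigenvector values.

    Exact null distribution when both groups have <= 25 samples and the
    values are tie-free; normal approximation with tie correction otherwise.
    """
    e = np.asarray(eigenvector, dtype=float)
    y = np.asarray(y, dtype=int)
    cases, controls = e[y == 1], e[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    no_ties = len(np.unique(e)) == e.size
    method = "exact" if (cases.size <= 25 and controls.size <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(cases, controls, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def explanatory_fraction(
    module_pathways,
    ancestors: dict[str, frozenset[str]],
) -> tuple[float, str | None]:
    """Largest share of a module's pathways sharing one non-root ancestor.

    Candidate ancestors are the union of members' proper ancestor sets (the
    ontology root is excluded upstream). Members absent from the ancestry
    map cover nothing but still count in the denominator. Ties go to the
    lexicographically smallest ancestor id; a module with no candidate
    ancestors scores 0.0.
    """
    members = list(module_pathways)
    if not members:
        raise ValueError("empty module")
    missing = [p for p in members if p not in ancestors]
    if missing:
        warnings.warn(f"{len(missing)} module member(s) absent from ancestry map")
    counts: dict[str, int] = {}
    for p in members:
        for a in ancestors.get(p, frozenset()):
            counts[a] = counts.get(a, 0) + 1
    if not counts:
        return 0.0, None
    best_count = max(counts.values())
    best_anc = min(a for a, c in counts.items() if c == best_count)
    return best_count / len(members), best_anc


def _mean_fraction(assignment: ModuleAssignment, ancestors) -> float:
    if not assignment.modules:
        return float("nan")
    fracs = [explanatory_fraction(m, ancestors)[0] for m in assignment.modules.values()]
    return float(np.mean(fracs))


def grid_select(
    S_controls: np.ndarray,
    S_full: np.ndarray,
    y,
    pathway_ids,
    cfg: ModuleGridConfig,
    ancestors: dict[str, frozenset[str]],
) -> ModuleReport:
    """Choose (minModuleSize, mergeCutHeight) by mean explanatory fraction.

    Clustering runs on control samples only; at the selected grid point the
    final report recomputes eigenvectors on the full sample and attaches a
    Wilcoxon phenotype P value per module. Ties on the objective go to the
    larger minModuleSize, then the smaller mergeCutHeight.
    """
    pathway_ids = list(pathway_ids)
    y = np.asarray(y, dtype=int)
    A, keep = soft_adjacency(S_controls, beta=cfg.beta)
    kept_ids = [pathway_ids[i] for i in keep]
    tom = topological_overlap(A)
    Sc = np.asarray(S_controls, dtype=float)[:, keep]
    Sf = np.asarray(S_full, dtype=float)[:, keep]

    rows = []
    best = None  # (mean_fraction, min_size, -cut_height is handled via key)
    assignments: dict[tuple[int, float], ModuleAssignment] = {}
    for ms in cfg.min_module_sizes:
        for h in cfg.merge_cut_heights:
            asg = _cluster_at(tom, Sc, kept_ids, ms, h, cfg.cut_quantile)
            assignments[(ms, h)] = asg
            mf = _mean_fraction(asg, ancestors)
            rows.append({"min_module_size": ms, "merge_cut_height": h,
                         "n_modules": asg.n_modules, "mean_fraction": mf})
            if asg.n_modules == 0 or np.isnan(mf):
                continue
            key = (mf, ms, -h)
            if best is None or key > best[0]:
                best = (key, ms, h)
    if best is None:
        raise ValueError("every grid point produced zero modules")
    _, ms, h = best
    asg = assignments[(ms, h)]
    col = {p: i for i, p in enumerate(kept_ids)}
    table_rows, eig_cols = [], {}
    for mid, members in asg.modules.items():
        cols = [col[p] for p in members]
        e = module_eigenvector(Sf, cols)
        frac, anc = explanatory_fraction(members, ancestors)
        table_rows.append({
            "module_id": mid,
            "size": len(members),
            "wilcoxon_p": module_phenotype_test(e, y),
            "explanatory_fraction": frac,
            "dominant_ancestor": anc,
        })
        eig_cols[mid] = e
    table = pd.DataFrame(table_rows)
    return ModuleReport(
        assignment=asg,
        table=table,
        eigenvectors=pd.DataFrame(eig_cols),
        mean_fraction=_mean_fraction(asg, ancestors),
        chosen_min_module_size=ms,
        chosen_merge_cut_height=h,
        grid_scores=pd.DataFrame(rows),
    )


def significant_modules(report: ModuleReport, alpha: float = 0.05,
                        min_fraction: float = 0.5) -> pd.DataFrame:
    """Modules with Wilcoxon P < alpha and fraction >= min_fraction, by P."""
    t = report.table
    sel = t[(t["wilcoxon_p"] < alpha) & (t["explanatory_fraction"] >= min_fraction)]
    return sel.sort_values(["wilcoxon_p", "module_id"], kind="mergesort",
                           ignore_index=True)
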