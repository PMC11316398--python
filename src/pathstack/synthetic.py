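"""Synthetic case–control omics data with planted pathway structure.

The generator emits a complete input bundle — toy ontology (gene sets plus
a parent–child ancestry table under a single root), feature→gene
annotation, and a samples × features matrix with balanced binary labels —
so the whole pipeline can run with no external downloads.

Generative model
----------------
Features mapped to a pathway share an exchangeable latent factor:
``x = sqrt(rho) * u_k + sqrt(1 - rho) * eps`` with unit marginal variance,
giving within-pathway correlation ``rho``. Planted pathways shift a
fraction of their features upward by ``effect_size`` (in SD units) in
cases. Module blocks give the latent factors of several pathways a shared
block factor (inducing correlated pathway-level signal) that itself may
differ between cases and controls, together with a shared toy ontology
ancestor — mirroring a biologically coherent, phenotype-associated module.
Unmapped features are independent noise.

Features are Gaussian by default; every downstream statistic used by the
pipeline (correlation, logistic regression, SVD, rank tests) is
distribution-generic. A logit-link beta mode squashes values into (0, 1)
for methylation-style realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .annotation import (
    FeaturePartition,
    Pathway,
    PathwayCollection,
    ancestors_from_edges,
    filter_pathways,
    partition_features,
)
from .stage1 import OmicsDataset

__all__ = ["SyntheticSpec", "make_toy_ontology", "make_omics", "permute_labels",
           "make_pathway_scores", "ROOT_ID"]

ROOT_ID = "GO:ROOT"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters of the synthetic cohort.

    Defaults describe the standard test fixture: a balanced 200-sample
    cohort, 60 pathways of 25 genes × 2 features each (~3000 mapped
    features plus 300 unmapped), 5 planted pathways shifting 30% of their
    features by 1 SD in cases, and moderate within-pathway correlation.
    """

    n_samples: int = 200
    n_pathways: int = 60
    genes_per_pathway: int = 25
    features_per_gene: int = 2
    n_unmapped_strict: int = 150
    n_unmapped_loose: int = 150
    n_planted: int = 5
    effect_size: float = 1.0
    frac_affected: float = 0.3
    within_pathway_rho: float = 0.3
    # each block: (tuple of pathway indices, shared ancestor id, block correlation)
    module_blocks: tuple = ()
    block_effect: float = 0.0  # case–control shift (SD units) of each block factor
    beta_link: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4 or self.n_samples % 2:
            raise ValueError("n_samples must be an even number >= 4 (balanced design)")
        if not (20 <= self.genes_per_pathway <= 200):
            raise ValueError("genes_per_pathway must lie in [20, 200] to pass the "
                             "pathway size filter by construction")
        if self.genes_per_pathway * self.features_per_gene < 10:
            raise ValueError("pathways must carry at least 10 features")
        if self.n_planted > self.n_pathways:
            raise ValueError("more planted pathways than pathways")
        if not (0 < self.frac_affected <= 1):
            raise ValueError("frac_affected must lie in (0, 1]")
        if not (0 <= self.within_pathway_rho < 1):
            raise ValueError("within_pathway_rho must lie in [0, 1)")
        for blk in self.module_blocks:
            paths, _anc, rho_b = blk
            if not (0 <= rho_b < 1):
                raise ValueError("block correlation must lie in [0, 1)")
            if any(i >= self.n_pathways for i in paths):
                raise ValueError("block pathway index out of range")

    @property
    def pathway_ids(self) -> list[str]:
        return [f"GO:P{i + 1:03d}" for i in range(self.n_pathways)]

    @property
    def planted_pathways(self) -> list[str]:
        return self.pathway_ids[: self.n_planted]


def make_toy_ontology(spec: SyntheticSpec) -> tuple[PathwayCollection, pd.DataFrame]:
    """Toy pathway collection and child→parent ancestry table.

    Every pathway satisfies the 20–200 gene / >=10 feature inclusion filter
    by construction. Pathways inside a module block share one intermediate
    ancestor below the root; all other pathways attach to the root directly.
    """
    pids = spec.pathway_ids
    pathways = []
    for k, pid in enumerate(pids):
        genes = tuple(
            f"G{k * spec.genes_per_pathway + j + 1:05d}"
            for j in range(spec.genes_per_pathway)
        )
        pathways.append(Pathway(pathway_id=pid, name=f"toy pathway {k + 1}", genes=genes))
    edges = []
    in_block: set[int] = set()
    for paths, anc, _rho in spec.module_blocks:
        for i in paths:
            edges.append((pids[i], anc))
            in_block.add(i)
        edges.append((anc, ROOT_ID))
    for i, pid in enumerate(pids):
        if i not in in_block:
            edges.append((pid, ROOT_ID))
    ancestry = pd.DataFrame(edges, columns=["child", "parent"])
    col = PathwayCollection(pathways=pathways,
                            ancestors=ancestors_from_edges(edges, root=ROOT_ID))
    return col, ancestry


def _block_of(spec: SyntheticSpec) -> dict[int, tuple[int, float]]:
    out = {}
    for b, (paths, _anc, rho_b) in enumerate(spec.module_blocks):
        for i in paths:
            out[i] = (b, rho_b)
    return out


def make_omics(spec: SyntheticSpec):
    """Generate the cohort: (OmicsDataset, annotation map, manifest dict).

    The manifest records every planted unit: planted pathway ids, affected
    feature ids, and module-block composition.
    """
    rng = np.random.default_rng(spec.seed)
    M = spec.n_samples
    y = np.zeros(M, dtype=int)
    y[rng.permutation(M)[: M // 2]] = 1

    n_mapped = spec.n_pathways * spec.genes_per_pathway * spec.features_per_gene
    rho = spec.within_pathway_rho
    blocks = _block_of(spec)
    g_block = {}
    ysign = 2.0 * y - 1.0  # ±1
    for b, (_paths, _anc, _rho_b) in enumerate(spec.module_blocks):
        raw = rng.standard_normal(M)
        if spec.block_effect:
            raw = (raw + spec.block_effect * ysign / 2) / np.sqrt(
                1 + spec.block_effect**2 / 4
            )
        g_block[b] = raw

    feature_ids: list[str] = []
    ann: dict[str, frozenset[str]] = {}
    cols = np.empty((M, n_mapped + spec.n_unmapped_loose + spec.n_unmapped_strict))
    affected: list[str] = []
    j = 0
    fpp = spec.genes_per_pathway * spec.features_per_gene
    for k in range(spec.n_pathways):
        if k in blocks:
            b, rho_b = blocks[k]
            u = np.sqrt(rho_b) * g_block[b] + np.sqrt(1 - rho_b) * rng.standard_normal(M)
        else:
            u = rng.standard_normal(M)
        eps = rng.standard_normal((M, fpp))
        block_x = np.sqrt(rho) * u[:, None] + np.sqrt(1 - rho) * eps
        planted = k < spec.n_planted
        n_aff = int(round(spec.frac_affected * fpp)) if planted else 0
        aff_idx = rng.permutation(fpp)[:n_aff] if n_aff else np.array([], dtype=int)
        if n_aff:
            block_x[np.ix_(y == 1, aff_idx)] += spec.effect_size
        for f in range(fpp):
            fid = f"cg{j + 1:07d}"
            gene = f"G{k * spec.genes_per_pathway + f // spec.features_per_gene + 1:05d}"
            feature_ids.append(fid)
            ann[fid] = frozenset({gene})
            if f in set(aff_idx):
                affected.append(fid)
            j += 1
        cols[:, j - fpp: j] = block_x
    # loosely unmapped: annotated to genes outside every pathway
    for i in range(spec.n_unmapped_loose):
        fid = f"cg{j + 1:07d}"
        feature_ids.append(fid)
        ann[fid] = frozenset({f"GX{i + 1:05d}"})
        cols[:, j] = rng.standard_normal(M)
        j += 1
    # strictly unmapped: no gene annotation at all
    for _ in range(spec.n_unmapped_strict):
        fid = f"cg{j + 1:07d}"
        feature_ids.append(fid)
        ann[fid] = frozenset()
        cols[:, j] = rng.standard_normal(M)
        j += 1

    if spec.beta_link:
        cols = expit(cols)  # logit-normal values in (0, 1), methylation-style

    ds = OmicsDataset(
        X=cols,
        y=y,
        sample_ids=[f"S{i + 1:04d}" for i in range(M)],
        feature_ids=feature_ids,
    )
    manifest = {
        "planted_pathways": spec.planted_pathways,
        "affected_features": affected,
        "module_blocks": [
            {"pathways": [spec.pathway_ids[i] for i in paths],
             "ancestor": anc, "correlation": rho_b}
            for paths, anc, rho_b in spec.module_blocks
        ],
        "seed": spec.seed,
    }
    return ds, ann, manifest


def default_partition(spec: SyntheticSpec, ds: OmicsDataset,
                      ann: dict[str, frozenset[str]]) -> tuple[PathwayCollection, FeaturePartition]:
    """Filtered pathway collection and feature partition for a generated cohort."""
    col, _ancestry = make_toy_ontology(spec)
    col = filter_pathways(col, ann, ds.feature_ids)
    return col, partition_features(col, ann, ds.feature_ids)


def permute_labels(ds: OmicsDataset, seed: int) -> OmicsDataset:
    """Shuffle labels (class counts preserved), leaving X untouched.

    If a draw happens to return the identity permutation (possible at tiny
    M), the generator reseeds until it differs.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n_samples)
    while ds.n_samples >= 5 and np.array_equal(ds.y[perm], ds.y):
        perm = rng.permutation(ds.n_samples)
    return OmicsDataset(X=ds.X, y=ds.y[perm], sample_ids=list(ds.sample_ids),
                        feature_ids=list(ds.feature_ids))


def make_pathway_scores(
    n_samples: int,
    blocks: list[tuple[int, float, float]],
    n_noise: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Synthetic pathway-level score matrix with planted correlated blocks.

    Each ``(size, within_correlation, phenotype_effect)`` block contributes
    ``size`` columns sharing a latent factor; the factor is shifted by
    ``phenotype_effect`` SD between cases and controls. ``n_noise``
    independent columns are appended. Columns are squashed through a
    sigmoid so they live in (0, 1) like out-of-fold probability scores.
    Returns (S, y, block column indices).
    """
    rng = np.random.default_rng(seed)
    y = np.zeros(n_samples, dtype=int)
    y[rng.permutation(n_samples)[: n_samples // 2]] = 1
    ysign = 2.0 * y - 1.0
    cols, members = [], []
    idx = 0
    for size, rho_b, effect in blocks:
        g = rng.standard_normal(n_samples) + effect * ysign / 2
        g = (g - g.mean()) / g.std()
        block_cols = []
        for _ in range(size):
            c = np.sqrt(rho_b) * g + np.sqrt(1 - rho_b) * rng.standard_normal(n_samples)
            cols.append(c)
            block_cols.append(idx)
            idx += 1
        members.append(block_cols)
    for _ in range(n_noise):
        cols.append(rng.standard_normal(n_samples))
        idx += 1
    S = expit(np.column_stack(cols) * 0.5)
    return S, y, members
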