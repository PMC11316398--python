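import numpy as np
import pytest

from pathstack import (
    LearnerSpec,
    Stage1Config,
    SyntheticSpec,
    default_partition,
    make_omics,
)


@pytest.fixture(scope="session")
def small_spec():
    """Compact cohort: quick to generate, enough signal to be detectable."""
    return SyntheticSpec(
        n_samples=80,
        n_pathways=12,
        genes_per_pathway=20,
        features_per_gene=1,
        n_unmapped_strict=30,
        n_unmapped_loose=30,
        n_planted=2,
        effect_size=1.0,
        frac_affected=0.3,
        within_pathway_rho=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    ds, ann, manifest = make_omics(small_spec)
    col, part = default_partition(small_spec, ds, ann)
    return {"spec": small_spec, "ds": ds, "ann": ann, "manifest": manifest,
            "col": col, "part": part}


@pytest.fixture(scope="session")
def default_cohort():
    """The standard planted fixture (200 samples, 60 pathways, 5 planted)."""
    spec = SyntheticSpec(seed=1)
    ds, ann, manifest = make_omics(spec)
    col, part = default_partition(spec, ds, ann)
    return {"spec": spec, "ds": ds, "ann": ann, "manifest": manifest,
            "col": col, "part": part}


@pytest.fixture()
def fast_stage1():
    return Stage1Config(B=1, n_folds=5, cutoff=0.3, fallback_k=10, seed=3)


@pytest.fixture()
def ridge():
    return LearnerSpec("ridge")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
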