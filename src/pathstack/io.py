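"""Delimited-text readers and writers for the pipeline's file dialects.

All on-disk formats are plain text: the omics matrix is a TSV with a
``sample_id`` first column and feature ids in the header; labels are a
two-column ``sample_id, label`` table; gene sets use the GMT dialect;
annotation and ancestry are two-column TSVs. Floats are written with a
fixed format so equal runs produce byte-identical files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stage1 import OmicsDataset, PathwayFeatureMatrix

FLOAT_FMT = "%.10g"


def read_omics(omics_path, labels_path, sep: str = "\t") -> OmicsDataset:
    """Read the omics matrix and labels, aligning samples by id."""
    df = pd.read_csv(omics_path, sep=sep, index_col=0)
    labels = pd.read_csv(labels_path, sep=sep, header=None,
                         names=["sample_id", "label"], dtype={"sample_id": str})
    labels = labels.set_index("sample_id")["label"]
    missing = [s for s in df.index if s not in labels.index]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    y = labels.loc[df.index].astype(int).to_numpy()
    return OmicsDataset(X=df.to_numpy(dtype=float), y=y,
                        sample_ids=[str(s) for s in df.index],
                        feature_ids=[str(c) for c in df.columns])


def write_omics(ds: OmicsDataset, omics_path, labels_path, sep: str = "\t") -> None:
    df = pd.DataFrame(ds.X, index=pd.Index(ds.sample_ids, name="sample_id"),
                      columns=ds.feature_ids)
    df.to_csv(omics_path, sep=sep, float_format=FLOAT_FMT)
    pd.DataFrame({"sample_id": ds.sample_ids, "label": ds.y}).to_csv(
        labels_path, sep=sep, header=False, index=False)


def write_gene_sets(col, path) -> None:
    with open(path, "w") as fh:
        for p in col:
            fh.write("\t".join([p.pathway_id, p.name, *p.genes]) + "\n")


def write_annotation(ann: dict[str, frozenset[str]], path, feature_order=None) -> None:
    order = feature_order if feature_order is not None else sorted(ann)
    with open(path, "w") as fh:
        for fid in order:
            genes = sorted(ann.get(fid, ()))
            if genes:
                for g in genes:
                    fh.write(f"{fid}\t{g}\n")
            else:
                fh.write(f"{fid}\t\n")


def write_ancestry(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", header=False, index=False)


def read_score_matrix(path, sep: str = "\t") -> PathwayFeatureMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return PathwayFeatureMatrix(S=df.to_numpy(dtype=float),
                                pathway_ids=[str(c) for c in df.columns],
                                sample_ids=[str(s) for s in df.index])


def write_score_matrix(S: PathwayFeatureMatrix, path, sep: str = "\t") -> None:
    idx = S.sample_ids if S.sample_ids else list(range(S.S.shape[0]))
    pd.DataFrame(S.S, index=pd.Index(idx, name="sample_id"),
                 columns=S.pathway_ids).to_csv(path, sep=sep, float_format=FLOAT_FMT)


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def format_float(x: float) -> str:
    return FLOAT_FMT % x if np.isfinite(x) else "NA"
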