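"""Gene-set, annotation and ontology-ancestry handling.

This module reads the three metadata inputs of the pipeline — pathway gene
sets (GMT dialect), a feature→gene annotation table, and a parent–child
ontology edge table — filters pathways by gene-set size and mapped-feature
count, and partitions omics features into pathway-mapped and unmapped sets.

Conventions
-----------
* Gene identifier matching is exact, case-sensitive string equality; any
  aliasing or symbol normalization is expected upstream.
* "Strictly unmapped" features carry no gene annotation at all; "loosely
  unmapped" features map to genes but to no retained pathway.
* Ancestor sets are proper (a term is never its own ancestor) and always
  exclude the designated ontology root: a generic root term is an ancestor
  of everything and would make any coherence statistic trivial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "Pathway",
    "PathwayCollection",
    "FeaturePartition",
    "read_gene_sets",
    "read_annotation",
    "read_ancestry",
    "filter_pathways",
    "partition_features",
]


class GeneSetParseError(ValueError):
    """Raised for malformed gene-set / annotation / ancestry files."""


@dataclass
class Pathway:
    pathway_id: str
    name: str
    genes: tuple[str, ...]  # deduplicated, input order preserved
    mapped_features: tuple[str, ...] = ()

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class PathwayCollection:
    """Ordered collection of pathways with optional ancestry links."""

    pathways: list[Pathway] = field(default_factory=list)
    ancestors: dict[str, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    def get(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)


@dataclass
class FeaturePartition:
    """Assignment of every input feature to mapped / unmapped classes.

    A feature annotated to genes in several retained pathways appears under
    each of them in ``mapped``; the three *classes* (mapped anywhere,
    strictly unmapped, loosely unmapped) are nevertheless disjoint and
    jointly cover the input feature list.
    """

    mapped: dict[str, list[str]]
    unmapped_strict: list[str]
    unmapped_loose: list[str]

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.mapped)

    def unmapped(self, mode: str = "all") -> list[str]:
        """Unmapped features fed to stage 2 (``strict`` or ``all``)."""
        if mode == "strict":
            return list(self.unmapped_strict)
        if mode == "all":
            return self.unmapped_strict + self.unmapped_loose
        raise ValueError(f"unknown unmapped_mode {mode!r}")


# ---------------------------------------------------------------------------
# readers


def read_gene_sets(path) -> PathwayCollection:
    """Read pathway gene sets from a GMT-dialect file.

    Each tab-separated record is ``id, description, gene, gene, ...``.
    Genes are deduplicated per pathway with input order preserved.
    """
    pathways: list[Pathway] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetParseError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (id, description, >=1 gene), got {len(fields)}"
                )
            pid, name, *genes = fields
            if pid in seen:
                raise GeneSetParseError(f"{path}: line {lineno}: duplicate pathway id {pid!r}")
            seen.add(pid)
            deduped = tuple(dict.fromkeys(g for g in genes if g))
            if not deduped:
                raise GeneSetParseError(f"{path}: line {lineno}: record has no gene tokens")
            pathways.append(Pathway(pathway_id=pid, name=name, genes=deduped))
    return PathwayCollection(pathways=pathways)


def read_annotation(path, sep: str = "\t") -> dict[str, frozenset[str]]:
    """Read a feature→gene table into ``{feature_id: genes}``.

    One row per (feature, gene) pair. A feature with an empty second field is
    recorded with an empty gene set (no mapping relationship); features absent
    from the table are simply unknown to the map and treated the same way by
    :func:`partition_features`.
    """
    ann: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep=sep, header=None, names=["feature_id", "gene"],
                     dtype=str, keep_default_na=False, skip_blank_lines=True)
    if len(df.columns) != 2:
        raise GeneSetParseError(f"{path}: expected two columns (feature_id, gene)")
    for fid, gene in zip(df["feature_id"], df["gene"]):
        genes = ann.setdefault(fid, set())
        if gene:
            genes.add(gene)
    return {fid: frozenset(genes) for fid, genes in ann.items()}


def read_ancestry(path, root: str, sep: str = "\t") -> dict[str, frozenset[str]]:
    """Read child→parent ontology edges and return proper ancestor sets.

    The transitive closure of the parent relation is computed on the DAG;
    the node itself and the declared ``root`` term are excluded from every
    ancestor set. A cycle raises with one offending cycle listed.
    """
    df = pd.read_csv(path, sep=sep, header=None, names=["child", "parent"],
                     dtype=str, keep_default_na=False, skip_blank_lines=True)
    edges = list(zip(df["child"], df["parent"]))
    if any(not c or not p for c, p in edges):
        raise GeneSetParseError(f"{path}: empty child or parent id (check separator {sep!r})")
    return ancestors_from_edges(edges, root=root)


def ancestors_from_edges(edges, root: str) -> dict[str, frozenset[str]]:
    """Proper transitive ancestor sets from (child, parent) pairs."""
    g = nx.DiGraph()
    g.add_edges_from(edges)  # child -> parent
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        pretty = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
        raise GeneSetParseError(f"ancestry graph has a cycle: {pretty}")
    out: dict[str, frozenset[str]] = {}
    for node in g.nodes:
        anc = nx.descendants(g, node)  # edges point child->parent
        anc.discard(node)
        anc.discard(root)
        out[node] = frozenset(anc)
    return out


# ---------------------------------------------------------------------------
# filtering and partitioning


def filter_pathways(
    col: PathwayCollection,
    annotation: dict[str, frozenset[str]],
    feature_ids,
    *,
    min_genes: int = 20,
    max_genes: int = 200,
    min_features: int = 10,
) -> PathwayCollection:
    """Retain pathways by gene-set size and mapped-feature count.

    A pathway is kept when ``min_genes <= |genes| <= max_genes`` (bounds
    inclusive) and at least ``min_features`` of the supplied features map to
    one of its genes. ``mapped_features`` is filled on the retained pathways
    (all features whose gene set intersects the pathway's genes, input order).
    """
    if min_genes <= 0 or max_genes <= 0 or min_features <= 0:
        raise ValueError("size bounds must be positive")
    if min_genes > max_genes:
        raise ValueError("min_genes must not exceed max_genes")
    # invert annotation once: gene -> features carrying it (input order)
    gene2feat: dict[str, list[str]] = {}
    for fid in feature_ids:
        for gene in annotation.get(fid, ()):  # empty set ok
            gene2feat.setdefault(gene, []).append(fid)
    order = {fid: i for i, fid in enumerate(feature_ids)}
    kept: list[Pathway] = []
    for p in col:
        if not (min_genes <= len(p.genes) <= max_genes):
            continue
        feats: set[str] = set()
        for gene in p.genes:
            feats.update(gene2feat.get(gene, ()))
        if len(feats) < min_features:
            continue
        mapped = tuple(sorted(feats, key=order.__getitem__))
        kept.append(Pathway(p.pathway_id, p.name, p.genes, mapped_features=mapped))
    return PathwayCollection(pathways=kept, ancestors=dict(col.ancestors))


def partition_features(
    col: PathwayCollection,
    annotation: dict[str, frozenset[str]],
    feature_ids,
) -> FeaturePartition:
    """Partition features into pathway-mapped / strict / loose unmapped sets.

    ``col`` must already be filtered (``mapped_features`` populated). Features
    with at least one gene in a retained pathway are listed under every such
    pathway; features with genes but no retained pathway are loosely
    unmapped; features with no gene annotation are strictly unmapped.
    """
    feature_ids = list(feature_ids)
    if len(set(feature_ids)) != len(feature_ids):
        dupes = pd.Series(feature_ids)
        dupes = sorted(dupes[dupes.duplicated()].unique())
        raise ValueError(f"duplicate feature ids: {dupes[:5]}")
    fid_set = set(feature_ids)
    mapped_any: set[str] = set()
    mapped: dict[str, list[str]] = {}
    for p in col:
        feats = [f for f in p.mapped_features if f in fid_set]
        if not feats:
            warnings.warn(f"pathway {p.pathway_id} has no mapped features in input")
        mapped[p.pathway_id] = feats
        mapped_any.update(feats)
    strict, loose = [], []
    for fid in feature_ids:
        if fid in mapped_any:
            continue
        if annotation.get(fid):
            loose.append(fid)
        else:
            strict.append(fid)
    return FeaturePartition(mapped=mapped, unmapped_strict=strict, unmapped_loose=loose)
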