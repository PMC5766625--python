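"""Dichotomize the weighted network into edge lists, compute degrees,
identify module hubs, and export Cytoscape-loadable files."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .modules import GREY, ModuleSet
from .network import AdjacencyMatrix, TOMMatrix

__all__ = ["EdgeList", "build_edges", "degrees", "hub", "write_sif",
           "write_edge_tsv", "read_edge_tsv", "node_attribute_table"]


@dataclass
class EdgeList:
    """Undirected super-threshold edges within one module."""

    module: str
    nodes: list[str]                 # all module genes (so isolated genes keep degree 0)
    edges: pd.DataFrame              # columns: source, target, weight
    threshold: float
    weight_kind: str                 # "tom" | "adjacency"

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_edges(
    net: TOMMatrix | AdjacencyMatrix,
    modset: ModuleSet,
    label: str,
    threshold: float = 0.1,
) -> EdgeList:
    """Edges among the module's genes whose weight is >= threshold.

    The grey module is refused: its genes are not co-expressed, so a grey
    "network" is meaningless.
    """
    if label == GREY:
        raise ValidationError("grey module requested: genes in grey are not co-expressed")
    if not 0.0 <= threshold <= 1.0:
        raise DomainError(f"threshold must be in [0,1], got {threshold}")
    if isinstance(net, TOMMatrix):
        W, kind = net.tom, "tom"
    else:
        W, kind = net.a, "adjacency"
    genes = modset.genes_in(label)
    if not genes:
        raise ValidationError(f"module {label!r} is empty or unknown")
    pos = {g: i for i, g in enumerate(net.gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValidationError(f"module genes absent from network: {missing}")
    idx = np.array([pos[g] for g in genes])
    sub = W[np.ix_(idx, idx)]
    src, dst, wts = [], [], []
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    keep = sub[iu, ju] >= threshold
    for i, j in zip(iu[keep], ju[keep]):
        src.append(genes[i])
        dst.append(genes[j])
        wts.append(float(sub[i, j]))
    edges = pd.DataFrame({"source": src, "target": dst, "weight": wts})
    return EdgeList(module=label, nodes=list(genes), edges=edges,
                    threshold=float(threshold), weight_kind=kind)


def degrees(el: EdgeList) -> dict[str, int]:
    """Edge count per gene; genes with no incident edge get 0."""
    deg = {g: 0 for g in el.nodes}
    for s, t in zip(el.edges["source"], el.edges["target"]):
        deg[s] += 1
        deg[t] += 1
    return deg


def hub(el: EdgeList) -> str:
    """Gene with the largest degree in the module.

    Ties break by larger summed incident edge weight, then lexicographic
    gene id — fully deterministic.
    """
    if el.n_edges == 0:
        raise ValidationError(f"module {el.module!r} has no edges at threshold {el.threshold}")
    deg = degrees(el)
    wsum = {g: 0.0 for g in el.nodes}
    for s, t, w in zip(el.edges["source"], el.edges["target"], el.edges["weight"]):
        wsum[s] += w
        wsum[t] += w
    return min(el.nodes, key=lambda g: (-deg[g], -wsum[g], g))


def write_sif(el: EdgeList, path: str, interaction: str = "co") -> None:
    with open(path, "w") as fh:
        for s, t in zip(el.edges["source"], el.edges["target"]):
            fh.write(f"{s}\t{interaction}\t{t}\n")


def write_edge_tsv(el: EdgeList, path: str) -> None:
    el.edges.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_edge_tsv(path: str, module: str = "", threshold: float = 0.0,
                  weight_kind: str = "tom") -> EdgeList:
    edges = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    nodes = sorted(set(edges["source"]) | set(edges["target"]))
    return EdgeList(module=module, nodes=nodes, edges=edges,
                    threshold=threshold, weight_kind=weight_kind)


def node_attribute_table(
    el: EdgeList, gene_frame: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-node attributes (degree plus, when given, the gene-stats columns
    module/gs/mm) for Cytoscape import."""
    deg = degrees(el)
    df = pd.DataFrame({"gene_id": el.nodes, "degree": [deg[g] for g in el.nodes]})
    if gene_frame is not None:
        cols = [c for c in ("module", "gs", "mm") if c in gene_frame.columns]
        df = df.merge(gene_frame[["gene_id", *cols]], on="gene_id", how="left")
    return df
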