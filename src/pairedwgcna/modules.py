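"""Module detection: hierarchical clustering on dissTOM, tree cutting with a
minimum module size (small clusters fall into the reserved "grey" module),
module eigengenes, and module membership."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_io import ExpressionMatrix
from .errors import DomainError, ValidationError
from .network import TOMMatrix

__all__ = [
    "GREY",
    "MODULE_COLORS",
    "ModuleSet",
    "Eigengenes",
    "cluster_genes",
    "cut_tree",
    "module_eigengene",
    "compute_eigengenes",
    "module_membership",
    "eigengene_dendrogram",
    "merge_close_modules",
]

GREY = "grey"

# size-rank colour palette (largest module first); overflow -> "module<N>"
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


@dataclass
class ModuleSet:
    """gene -> module label partition; "grey" holds unassigned genes."""

    assignment: dict[str, str]
    labels: list[str] = field(default_factory=list)   # non-grey, size-rank order

    def __post_init__(self) -> None:
        if not self.labels:
            nongrey = [lab for lab in self.assignment.values() if lab != GREY]
            # size-rank order, ties by label for determinism
            counts = pd.Series(nongrey).value_counts()
            self.labels = sorted(counts.index, key=lambda l: (-counts[l], l))

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.assignment.values():
            out[lab] = out.get(lab, 0) + 1
        return out

    def genes_in(self, label: str) -> list[str]:
        return [g for g, lab in self.assignment.items() if lab == label]

    def all_labels(self) -> list[str]:
        labs = list(self.labels)
        if GREY in self.assignment.values():
            labs.append(GREY)
        return labs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.assignment), "module": list(self.assignment.values())}
        )


@dataclass
class Eigengenes:
    """Module eigengene (ME) per module: samples-length unit-variance vector,
    sign-oriented so the mean correlation with its module's genes is >= 0."""

    sample_ids: list[str]
    me: dict[str, np.ndarray]
    explained_variance_fraction: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {lab: v for lab, v in self.me.items()},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def cluster_genes(tomm: TOMMatrix) -> np.ndarray:
    """Average-linkage hierarchical clustering on dissTOM.

    Returns a scipy linkage matrix over genes in the TOM's gene order.
    """
    d = tomm.diss
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("dissTOM must be symmetric")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="average")


def cut_tree(
    Z: np.ndarray,
    gene_ids: list[str],
    method: str = "hybrid",
    cut_height: float | None = None,
    min_module_size: int = 30,
) -> ModuleSet:
    """Cut the gene dendrogram into modules.

    static : clusters are the branches below ``cut_height``.
    hybrid : static cut, then clusters smaller than ``min_module_size`` are
             reassigned to grey (the default; with the static method small
             clusters are also sent to grey, so the two differ only in name
             here — the full published dynamic-hybrid PAM stage is out of
             scope).

    Remaining clusters are labelled by size rank with the WGCNA colour
    palette (largest = "turquoise").  Ties in size break toward the cluster
    containing the lowest gene index.
    """
    if method not in ("static", "hybrid"):
        raise ValueError(f"unknown cut method {method!r}")
    if min_module_size < 2:
        raise DomainError("min_module_size must be >= 2")
    max_h = float(Z[:, 2].max()) if len(Z) else 0.0
    if cut_height is None:
        cut_height = 0.99 * max_h
    if cut_height < 0 or cut_height > max_h:
        raise DomainError(f"cut_height {cut_height} outside [0, {max_h}]")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(i)
    keep = {c: idx for c, idx in clusters.items() if len(idx) >= min_module_size}
    # size-rank order; ties toward the cluster holding the lowest gene index
    ranked = sorted(keep.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    assignment = {g: GREY for g in gene_ids}
    labels: list[str] = []
    for rank, (_, idx) in enumerate(ranked):
        lab = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.append(lab)
        for i in idx:
            assignment[gene_ids[i]] = lab
    return ModuleSet(assignment=assignment, labels=labels)


def _standardized(expr: ExpressionMatrix, genes: list[str]) -> np.ndarray:
    sub = expr.subset_genes(genes).values
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = [g for g, s in zip(genes, sd[:, 0]) if s == 0]
        raise ValidationError(f"zero-variance genes in module: {bad}")
    return (sub - mu) / sd


def module_eigengene(
    expr: ExpressionMatrix, modset: ModuleSet, label: str
) -> tuple[np.ndarray, float]:
    """First principal component of the module's standardized submatrix.

    Returns (ME, explained_variance_fraction).  ME has unit (ddof=1)
    variance and is oriented so its mean correlation with the module's
    genes is non-negative.  A single-gene module's ME is that gene's
    standardized profile.  The grey module is handled identically (its
    association is still tested downstream).
    """
    genes = modset.genes_in(label)
    if not genes:
        raise ValidationError(f"module {label!r} is empty or unknown")
    X = _standardized(expr, genes)               # genes x samples
    if len(genes) == 1:
        v = X[0]
        me = v / v.std(ddof=1)
        return me, 1.0
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    pc = Vt[0]                                   # sample scores direction
    frac = float(s[0] ** 2 / np.sum(s**2))
    me = pc / pc.std(ddof=1)
    # orient: mean correlation with module genes >= 0
    cors = _row_cor(X, me)
    if cors.mean() < 0:
        me = -me
    return me, frac


def _row_cor(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    num = Xc @ vc
    den = np.sqrt((Xc**2).sum(axis=1) * (vc**2).sum())
    return num / den


def compute_eigengenes(
    expr: ExpressionMatrix, modset: ModuleSet, include_grey: bool = True
) -> Eigengenes:
    labels = list(modset.labels)
    if include_grey and GREY in modset.assignment.values():
        labels.append(GREY)
    mes: dict[str, np.ndarray] = {}
    fracs: dict[str, float] = {}
    for lab in labels:
        me, frac = module_eigengene(expr, modset, lab)
        mes[lab] = me
        fracs[lab] = frac
    return Eigengenes(list(expr.sample_ids), mes, fracs)


def module_membership(
    expr: ExpressionMatrix, eig: Eigengenes, gene_id: str, label: str
) -> float:
    """Signed Pearson correlation between a gene's profile and a module ME."""
    if label not in eig.me:
        raise ValidationError(f"no eigengene for module {label!r}")
    if gene_id not in expr.gene_ids:
        raise ValidationError(f"unknown gene {gene_id!r}")
    x = expr.values[expr.gene_ids.index(gene_id)]
    if x.std(ddof=1) == 0:
        raise ValidationError(f"zero-variance gene {gene_id!r}")
    return float(np.corrcoef(x, eig.me[label])[0, 1])


def membership_table(expr: ExpressionMatrix, modset: ModuleSet, eig: Eigengenes) -> pd.DataFrame:
    """MM of every gene with its own module's eigengene."""
    rows = []
    for g, lab in modset.assignment.items():
        mm = module_membership(expr, eig, g, lab) if lab in eig.me else np.nan
        rows.append((g, lab, mm))
    return pd.DataFrame(rows, columns=["gene_id", "module", "mm"])


def eigengene_dendrogram(eig: Eigengenes) -> tuple[np.ndarray, list[str]]:
    """Average-linkage tree over module eigengenes with dissimilarity
    1 - cor(ME_a, ME_b) (signed convention: anticorrelated MEs sit at 2)."""
    labels = list(eig.me)
    if len(labels) < 2:
        raise ValidationError("eigengene dendrogram needs >= 2 modules")
    M = np.vstack([eig.me[lab] for lab in labels])
    d = 1.0 - np.corrcoef(M)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    Z = linkage(squareform(d, checks=False), method="average")
    return Z, labels


def merge_close_modules(
    expr: ExpressionMatrix,
    modset: ModuleSet,
    merge_cut: float = 0.25,
) -> ModuleSet:
    """Optionally merge modules whose eigengenes satisfy 1 - cor(ME) <
    merge_cut (off by default in the pipeline).  Merged groups are
    relabelled by size rank."""
    eig = compute_eigengenes(expr, modset, include_grey=False)
    labels = list(eig.me)
    if len(labels) < 2:
        return modset
    M = np.vstack([eig.me[lab] for lab in labels])
    d = 1.0 - np.corrcoef(M)
    parent = list(range(len(labels)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if d[i, j] < merge_cut:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(find(i), []).append(lab)
    merged_of = {lab: tuple(sorted(g)) for g in groups.values() for lab in g}
    sizes = modset.sizes
    group_sizes = {grp: sum(sizes[l] for l in grp) for grp in set(merged_of.values())}
    ranked = sorted(group_sizes, key=lambda g: (-group_sizes[g], g))
    new_label = {
        grp: (MODULE_COLORS[r] if r < len(MODULE_COLORS) else f"module{r + 1}")
        for r, grp in enumerate(ranked)
    }
    assignment = {
        g: (GREY if lab == GREY else new_label[merged_of[lab]])
        for g, lab in modset.assignment.items()
    }
    return ModuleSet(assignment=assignment)
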