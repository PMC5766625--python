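"""Full pipeline orchestration: QC -> network -> modules -> association ->
hubs, with every intermediate artifact persisted and a machine-readable
summary (JSON) whose hash is reproducible for identical (inputs, config)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .association import (gene_significance, gene_stats_frame,
                          mm_gs_scatter_table, module_significance,
                          module_trait_table)
from .data_io import (ExpressionMatrix, PairedDesign, drop_genes_with_missing,
                      read_design, read_expression, read_geo_series_matrix,
                      write_design, write_expression)
from .errors import PairedWGCNAError, ValidationError
from .hubs import build_edges, hub, node_attribute_table, write_edge_tsv, write_sif
from .modules import (GREY, cluster_genes, compute_eigengenes, cut_tree,
                      merge_close_modules)
from .network import adjacency, scale_free_scan, similarity, tom
from .qc import (exclude_pairs, flag_outlier_samples, pca_overview,
                 quantile_normalize, sample_tree, sample_tree_newick)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("pairedwgcna")


@dataclass
class RunConfig:
    """Every parameter of the pipeline with a documented default."""

    expression: str = ""                 # path to expression TSV/CSV
    design: str = ""                     # path to design TSV
    geo: bool = False                    # expression file is a GEO series matrix
    orientation: str = "genes-in-rows"
    quantile_normalize: bool = False     # optional array normalisation
    keep_genes: str = ""                 # optional keep-list file (one gene id per line)
    z_cut: float = 2.5                   # sample outlier merge-height z cut
    skip_qc: bool = False
    beta: int = 0                        # 0 = select by first-peak scale-free scan
    beta_grid: list[int] = field(default_factory=lambda: list(range(1, 21)))
    n_bins: int = 10
    cut_method: str = "hybrid"
    cut_height: float | None = None      # None = 0.99 * max merge height
    min_module_size: int = 30
    merge_cut: float = 0.0               # 0 = no ME-correlation module merging
    covariates: list[str] = field(default_factory=list)
    stage_coding: str = "numeric"
    edge_weight: str = "tom"             # "tom" | "adjacency"
    edge_threshold: float = 0.1
    seed: int = 0
    out_dir: str = "pairedwgcna_out"

    def validate(self) -> None:
        if not self.expression or not self.design:
            raise ValidationError("config must set 'expression' and 'design' paths")
        for pth, name in ((self.expression, "expression"), (self.design, "design")):
            if not Path(pth).exists():
                raise ValidationError(f"{name} path does not exist: {pth}")
        if self.keep_genes and not Path(self.keep_genes).exists():
            raise ValidationError(f"keep_genes path does not exist: {self.keep_genes}")
        if self.edge_weight not in ("tom", "adjacency"):
            raise ValidationError(f"edge_weight must be tom|adjacency, got {self.edge_weight!r}")


def load_config(path: str) -> RunConfig:
    """Read a TOML run configuration; unknown keys are rejected."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return str(obj)
        return float(f"{obj:.{ndigits}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _summary_hash(summary: dict) -> str:
    canon = json.dumps(_round_floats(summary), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _setup_logging(out: Path, verbose: bool) -> None:
    log.handlers.clear()
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(out / "run.log", mode="w")):
        h.setFormatter(fmt)
        log.addHandler(h)


def run_pipeline(config: RunConfig, verbose: bool = False) -> dict:
    """Execute all stages; returns the summary dict (also written to
    summary.json in the output directory).  A stage failure aborts with the
    stage name; artifacts produced so far remain on disk."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, verbose)
    log.info("pairedwgcna %s | seed=%d", __version__, config.seed)
    log.info("config: %s", json.dumps(_round_floats(dataclasses.asdict(config))))
    summary: dict = {"version": __version__, "config": dataclasses.asdict(config)}

    stage = "load"
    try:
        if config.geo:
            expr, meta = read_geo_series_matrix(config.expression)
            summary["geo_metadata_keys"] = sorted(meta)
        else:
            expr = read_expression(config.expression, config.orientation)
        design = read_design(config.design)
        design.check_against(expr)
        if config.keep_genes:
            keep = [ln.strip() for ln in Path(config.keep_genes).read_text().splitlines()
                    if ln.strip()]
            present = [g for g in expr.gene_ids if g in set(keep)]
            expr = expr.subset_genes(present)
            log.info("keep-list retained %d genes", expr.n_genes)
        expr = drop_genes_with_missing(expr)
        expr = expr.subset_samples(design.sample_ids)
        if config.quantile_normalize:
            expr = quantile_normalize(expr)
        log.info("loaded %d genes x %d samples, %d pairs",
                 expr.n_genes, expr.n_samples, design.n_pairs)

        stage = "qc"
        pca = pca_overview(expr, k=min(5, expr.n_samples - 1, expr.n_genes))
        pca.pc_scores.to_csv(out / "qc_pc_scores.tsv", sep="\t")
        Z, labels = sample_tree(expr)
        (out / "qc_sample_tree.nwk").write_text(sample_tree_newick(Z, labels) + "\n")
        if config.skip_qc:
            flagged: list[str] = []
            excluded: list[str] = []
        else:
            flagged = flag_outlier_samples(expr, z_cut=config.z_cut)
            expr, design, excluded = exclude_pairs(expr, design, flagged)
        (out / "qc_flagged_samples.tsv").write_text(
            "sample_id\n" + "".join(f"{s}\n" for s in flagged))
        summary["qc"] = {"flagged_samples": flagged, "excluded_pairs": excluded,
                         "n_samples_retained": expr.n_samples,
                         "n_pairs_retained": design.n_pairs}
        log.info("QC: flagged=%s excluded_pairs=%s retained %d samples",
                 flagged, excluded, expr.n_samples)
        write_expression(expr, out / "expression_retained.tsv")
        write_design(design, out / "design_retained.tsv")

        stage = "network"
        sim = similarity(expr)
        if config.beta >= 1:
            chosen_beta = int(config.beta)
            scan = None
        else:
            scan = scale_free_scan(sim, config.beta_grid, config.n_bins)
            scan.to_frame().to_csv(out / "scale_free_scan.tsv", sep="\t", index=False)
            chosen_beta = scan.chosen_beta
        adj = adjacency(sim, chosen_beta)
        tomm = tom(adj)
        r2_at_beta = (float(scan.r2[scan.beta_grid.index(chosen_beta)])
                      if scan is not None else None)
        summary["network"] = {"beta": chosen_beta, "r2": r2_at_beta,
                              "mean_connectivity": float(adj.connectivity().mean())}
        log.info("network: beta=%d r2=%s", chosen_beta, r2_at_beta)

        stage = "modules"
        Zg = cluster_genes(tomm)
        modset = cut_tree(Zg, expr.gene_ids, method=config.cut_method,
                          cut_height=config.cut_height,
                          min_module_size=config.min_module_size)
        if config.merge_cut > 0 and len(modset.labels) > 1:
            modset = merge_close_modules(expr, modset, config.merge_cut)
        modset.to_frame().to_csv(out / "modules.tsv", sep="\t", index=False)
        eig = compute_eigengenes(expr, modset, include_grey=True)
        eig.to_frame().to_csv(out / "eigengenes.tsv", sep="\t")
        summary["modules"] = {"sizes": modset.sizes, "labels": modset.all_labels()}
        log.info("modules: %s", modset.sizes)

        stage = "association"
        trait = module_trait_table(eig, design, config.covariates, config.stage_coding)
        trait.to_csv(out / "module_trait.tsv", sep="\t", index=False)
        genestats = gene_significance(expr, design, config.covariates, config.stage_coding)
        gframe = gene_stats_frame(genestats, modset, expr, eig)
        gframe.to_csv(out / "gene_stats.tsv", sep="\t", index=False)
        ms = module_significance(genestats, modset)
        ms.to_csv(out / "module_significance.tsv", sep="\t", index=False)
        _, mmgs = mm_gs_scatter_table(expr, genestats, modset, eig)
        mmgs.to_csv(out / "mm_gs_correlation.tsv", sep="\t", index=False)
        summary["association"] = {
            "module_trait": trait[["module", "estimate", "t", "df", "p"]]
            .to_dict(orient="records"),
            "module_significance": ms.to_dict(orient="records"),
        }
        log.info("association: top module %s (t=%.3f)",
                 trait.iloc[0]["module"], trait.iloc[0]["t"])

        stage = "hubs"
        net = tomm if config.edge_weight == "tom" else adj
        hubs_found: dict[str, dict] = {}
        for lab in modset.labels:          # grey deliberately excluded
            el = build_edges(net, modset, lab, config.edge_threshold)
            write_edge_tsv(el, out / f"edges_{lab}.tsv")
            write_sif(el, out / f"edges_{lab}.sif")
            node_attribute_table(el, gframe).to_csv(
                out / f"nodes_{lab}.tsv", sep="\t", index=False)
            if el.n_edges:
                h = hub(el)
                hubs_found[lab] = {"hub": h, "n_edges": el.n_edges,
                                   "hub_degree": sum(
                                       1 for s, t in zip(el.edges["source"], el.edges["target"])
                                       if h in (s, t))}
            else:
                hubs_found[lab] = {"hub": None, "n_edges": 0, "hub_degree": 0}
        summary["hubs"] = hubs_found
        log.info("hubs: %s", {k: v["hub"] for k, v in hubs_found.items()})
    except Exception as exc:
        log.error("stage %r failed: %s", stage, exc)
        raise PairedWGCNAError(f"pipeline stage {stage!r} failed: {exc}") from exc

    hashable = {k: v for k, v in summary.items() if k != "hash"}
    cfg_no_out = dict(hashable["config"])
    cfg_no_out.pop("out_dir", None)        # hash must not depend on where we write
    hashable["config"] = cfg_no_out
    summary["hash"] = _summary_hash(hashable)
    (out / "summary.json").write_text(json.dumps(_round_floats(summary), indent=2) + "\n")
    log.info("done; summary hash %s", summary["hash"])
    return summary
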