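"""End-to-end orchestration: simulate -> quantify -> preprocess -> normalize ->
differential expression -> PPI clustering -> signature survival.

Every stage reads and writes plain TSV under the output directory and the run
is summarised in ``manifest.json`` (seed, parameters, per-stage row counts),
which suffices to reproduce every output exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, network, simulate, survival
from .diffexp import PermutationConfig, de_table
from .normalize import (
    compare_normalizations,
    normalize_median_median,
    normalize_median_polish,
    normalize_rowwise,
)
from .preprocess import filter_completeness, impute_left_censored
from .quant import quantify_batches

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "preprocess", "normalize", "diffexp",
          "network", "signature")


@dataclass
class PipelineConfig:
    """All tunable stage parameters with study-design defaults."""

    n_samples: int = 60
    plex: int = 6
    exact_counts: bool = True
    n_proteins: int = 1000
    n_de: int = 50
    batch_sd: float = 0.5
    sigma: float = 0.5
    censor_midpoint: float = 17.0
    censor_steepness: float = 0.8
    min_frac: float = 0.70
    downshift: float = 1.8
    width: float = 0.3
    method: str = "median-polish"
    norm_tol: float = 1e-6
    norm_max_iter: int = 20
    n_perm: int = 250
    fdr_threshold: float = 0.05
    pooling: str = "global"
    min_conf: float = 0.4
    n_expr_samples: int = 400
    seed: int = 0
    skip: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full flow (any suffix skippable); returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = simulate.spawn_seeds(config.seed, 9)
    manifest: dict = {
        "tmtdea_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    config.to_yaml(outdir / "config.yaml")
    skip = set(config.skip)
    for unknown in skip - set(STAGES):
        raise ValueError(f"unknown stage to skip: {unknown}")

    def record(stage, t0, **counts):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **counts}
        logger.info("stage %-10s %s", stage, counts)

    # --- simulate -------------------------------------------------------
    t0 = time.time()
    cohort = simulate.generate_cohort(
        config.n_samples, seed=seeds[0], exact_counts=config.exact_counts
    )
    design, cohort = simulate.assign_batches(cohort, plex=config.plex, seed=seeds[1])
    tables, truth = simulate.generate_proteome(
        design, cohort, n_proteins=config.n_proteins, n_de=config.n_de,
        batch_sd=config.batch_sd, sigma=config.sigma, seed=seeds[2],
    )
    tables = simulate.apply_missingness(
        tables, censor_midpoint=config.censor_midpoint,
        censor_steepness=config.censor_steepness, seed=seeds[3],
    )
    io.write_cohort(cohort, outdir / "cohort.tsv")
    io.write_batch_tables(tables, outdir / "batches")
    io.write_table(truth.effects, outdir / "ground_truth_effects.tsv",
                   index_label="protein")
    record("simulate", t0, n_samples=len(cohort), n_batches=design.n_batches,
           n_proteins=config.n_proteins, n_de=config.n_de)
    if "quantify" in skip:
        return _finish(manifest, outdir)

    # --- quantify -------------------------------------------------------
    t0 = time.time()
    rm = quantify_batches(tables, cohort)
    io.write_ratio_matrix(rm, outdir / "ratios_raw.tsv")
    record("quantify", t0, n_proteins=len(rm.protein_ids), n_samples=len(rm.sample_ids))
    if "preprocess" in skip:
        return _finish(manifest, outdir)

    # --- preprocess -----------------------------------------------------
    t0 = time.time()
    filtered = filter_completeness(rm, min_frac=config.min_frac)
    complete = impute_left_censored(
        filtered, downshift=config.downshift, width=config.width, seed=seeds[4]
    )
    io.write_ratio_matrix(complete, outdir / "ratios_imputed.tsv")
    record("preprocess", t0, n_proteins_in=len(rm.protein_ids),
           n_proteins_kept=len(complete.protein_ids))
    if "normalize" in skip:
        return _finish(manifest, outdir)

    # --- normalize ------------------------------------------------------
    t0 = time.time()
    reports = compare_normalizations(
        complete, linear_tables=tables, cohort=cohort,
        tol=config.norm_tol, max_iter=config.norm_max_iter,
    )
    rep_df = pd.DataFrame(
        [
            {"method": r.method, "score_before": r.score_before,
             "score_after": r.score_after, "n_iter": r.n_iter, "note": r.note}
            for r in reports
        ]
    )
    io.write_table(rep_df.set_index("method"), outdir / "normalization_report.tsv")
    pd.DataFrame(
        {r.method: r.batch_medians_after for r in reports}
    ).to_csv(outdir / "batch_medians.tsv", sep="\t", index_label="batch")
    if config.method == "median-polish":
        normalized, _ = normalize_median_polish(
            complete, tol=config.norm_tol, max_iter=config.norm_max_iter
        )
    elif config.method == "median-median":
        normalized = normalize_median_median(complete)
    elif config.method == "rowwise":
        normalized = normalize_rowwise(complete)
    elif config.method == "raw":
        normalized = complete
    else:
        raise ValueError(f"unknown normalization method {config.method!r}")
    io.write_ratio_matrix(normalized, outdir / "ratios_normalized.tsv")
    record("normalize", t0, method=config.method,
           best_method=reports[0].method,
           score_raw=round(next(r for r in reports if r.method == "raw").score_after, 4),
           score_best=round(reports[0].score_after, 4))
    if "diffexp" in skip:
        return _finish(manifest, outdir)

    # --- differential expression ---------------------------------------
    t0 = time.time()
    pconfig = PermutationConfig(
        n_perm=config.n_perm, seed=seeds[5], fdr_threshold=config.fdr_threshold,
        pooling=config.pooling,
    )
    de = de_table(normalized, cohort, pconfig)
    io.write_table(de, outdir / "de_table.tsv")
    hits = de.index[de["significant"]].tolist()
    record("diffexp", t0, n_tested=len(de), n_significant=len(hits))
    # the first six true DE proteins among the hits anchor the dense module
    cluster_seed = [p for p in truth.de_proteins if p in hits][:6]
    top = cluster_seed
    if "network" not in skip:
        # --- network ----------------------------------------------------
        t0 = time.time()
        edges = simulate.generate_ppi_edges(hits, cluster_seed, seed=seeds[6])
        edges_path = outdir / "ppi_edges.tsv"
        edges.to_csv(edges_path, sep="\t", index=False)
        net = network.filter_edges(
            network.load_edges(edges_path), min_conf=config.min_conf
        )
        clusters = network.extract_clusters(net, hits) if hits else []
        pd.DataFrame(
            [
                {"cluster": i + 1, "members": ",".join(c.members),
                 "density": c.density, "mean_score": c.mean_score,
                 "n_edges": c.n_edges}
                for i, c in enumerate(clusters)
            ]
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        if clusters:
            top = list(clusters[0].members)
        record("network", t0, n_nodes=net.number_of_nodes(),
               n_edges=net.number_of_edges(), top_cluster_size=len(top))
    if "signature" in skip:
        return _finish(manifest, outdir)

    # --- signature + survival ------------------------------------------
    t0 = time.time()
    sig_genes = top or truth.de_proteins[:6] or list(truth.baseline.index[:6])
    expr_raw = simulate.generate_expression(
        config.n_expr_samples, sig_genes, seed=seeds[7]
    )
    expr = pd.DataFrame(
        survival.log2p1(expr_raw.to_numpy()),
        index=expr_raw.index, columns=expr_raw.columns,
    )
    scores = survival.signature_score(expr, sig_genes)
    surv_table = simulate.generate_survival(scores, seed=seeds[8])
    comparison = survival.survival_comparison(surv_table)
    surv_table["quartile"] = comparison["groups"]
    io.write_table(surv_table, outdir / "survival.tsv")
    io.write_table(scores.to_frame("score"), outdir / "signature_scores.tsv",
                   index_label="sample_id")
    km = pd.concat(
        [comparison["km_lower"].assign(group="lower"),
         comparison["km_upper"].assign(group="upper")]
    )
    km.to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    record("signature", t0, n_patients=len(surv_table),
           signature=",".join(sig_genes),
           logrank_stat=round(comparison["logrank_stat"], 4),
           logrank_p=round(comparison["logrank_p"], 6))
    return _finish(manifest, outdir)


def _finish(manifest: dict, outdir: Path) -> dict:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
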