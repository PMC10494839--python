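"""Config-driven orchestration: preprocess -> PCA -> intrinsic dimension ->
manifold sweep -> clustering sweep -> validity gate -> selection -> density.

The run report answers one question — does this abundance table contain
balanced, stable, distinct clusters, or does it lie on a continuous
low-dimensional manifold? — and carries the per-stage tables (dimensionality,
reconstruction quality, per-partition metrics) needed to audit the verdict.

Multiple input tables are analyzed separately, never merged: differing
collection and processing pipelines produce batch effects that would
masquerade as clusters.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import synthetic
from .clustering import (DistanceMatrix, Partition, hdbscan_cluster, pam,
                         spectral, sweep_clusterings)
from .density import high_density_regions, kde_density, project_viz, top_taxa_per_region
from .intrinsic_dim import estimate_intrinsic_dim
from .linear import fit_pca, inverse_pca, pca_loadings
from .manifold import DEFAULT_GRIDS, discard_worst, loo_knn_reconstruct, sweep_hyperparams
from .preprocess import (AbundanceTable, aggregate_taxonomy, filter_taxa,
                         normalize_tss, pairwise_distances, read_abundance_table,
                         remove_dominated)
from .validity import (DEFAULT_THRESHOLDS, PartitionMetrics, gate,
                       prediction_strength, score_partition, select_best)

__all__ = ["RunConfig", "validate_config", "run_framework"]

logger = logging.getLogger("enteromap")


@dataclass
class RunConfig:
    """Fully explicit description of one framework run."""

    # input: either a table on disk or a synthetic generator spec
    input_path: str | None = None
    orientation: str = "samples-in-rows"
    lineage_column: str | None = None
    synthetic_spec: dict | None = None          # {"kind": ..., generator args}

    level: str | None = None                    # Genus | Family | Order | None
    min_prevalence: float = 0.01
    min_std: float = 0.001
    dominated_threshold: float | None = None    # None = sensitivity variant off
    dominated_policy: str = "drop-sample"

    pca_variance: float = 0.99
    id_k_range: tuple[int, int] = (5, 100)
    id_n_boot: int = 50
    d_target: int | None = None                 # None = use the MLE estimate

    embedding_methods: tuple[str, ...] = ("isomap", "umap")
    embedding_grids: dict = field(default_factory=dict)
    discard_fraction: float = 0.10
    discard_step: float = 0.02

    clustering_grids: dict = field(default_factory=dict)
    include_distance_representations: bool = False
    distance_metrics: tuple[str, ...] = ("manhattan",)

    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    ps_repeats: int = 10
    ps_policy: str = "lazy"                     # lazy | all | never

    density_enabled: bool = True
    density_method: str = "umap"
    density_dims: int = 2

    seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


_TUPLE_KEYS = {"id_k_range", "embedding_methods", "distance_metrics"}


def validate_config(cfg: dict | RunConfig) -> RunConfig:
    """Normalize a raw mapping into a RunConfig; reject unknown or bad keys."""
    if isinstance(cfg, RunConfig):
        d = cfg.to_dict()
    else:
        d = dict(cfg)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_KEYS & set(d):
        if d[key] is not None:
            d[key] = tuple(d[key])
    out = RunConfig(**d)
    if out.input_path is None and out.synthetic_spec is None:
        raise ValueError("config needs input_path or synthetic_spec")
    if out.input_path is not None and out.synthetic_spec is not None:
        raise ValueError("give either input_path or synthetic_spec, not both")
    if not 0.0 < out.pca_variance <= 1.0:
        raise ValueError("pca_variance must lie in (0, 1]")
    if out.min_prevalence < 0 or out.min_std < 0:
        raise ValueError("filter thresholds must be nonnegative")
    if not 0 < out.discard_fraction <= 0.10:
        raise ValueError("discard_fraction must lie in (0, 0.10]")
    for m in out.embedding_methods:
        if m not in DEFAULT_GRIDS:
            raise ValueError(f"unknown embedding method {m!r}")
    if out.ps_policy not in ("lazy", "all", "never"):
        raise ValueError("ps_policy must be lazy, all or never")
    for key, val in out.thresholds.items():
        if key not in DEFAULT_THRESHOLDS:
            raise ValueError(f"unknown threshold {key!r}")
        if val is None or val != val:
            raise ValueError(f"threshold {key!r} must be a number")
    return out


def _load_input(cfg: RunConfig) -> tuple[AbundanceTable, dict]:
    """Build the abundance table; returns (table, ground_truth)."""
    if cfg.synthetic_spec is not None:
        spec = dict(cfg.synthetic_spec)
        kind = spec.pop("kind")
        spec.setdefault("seed", cfg.seed)
        gen = {"clustered": synthetic.generate_clustered,
               "manifold": synthetic.generate_manifold,
               "gradient": synthetic.generate_gradient}[kind]
        dropout = spec.pop("dropout", 0.0)
        ds = gen(**spec)
        if dropout:
            ds = synthetic.add_zero_inflation(ds, dropout, seed=spec["seed"] + 1)
        table = AbundanceTable(sample_ids=ds.sample_names(),
                               taxon_ids=ds.taxon_names(),
                               matrix=ds.abundances)
        truth = {"labels": ds.labels, "latent": ds.latent, "d_true": ds.d_true}
        return table, truth
    table = read_abundance_table(cfg.input_path, orientation=cfg.orientation,
                                 lineage_column=cfg.lineage_column)
    truth_path = Path(cfg.input_path).with_suffix(".truth.json")
    truth = synthetic.read_ground_truth(truth_path) if truth_path.exists() else {}
    return table, truth


def _make_ps_clusterer(p: Partition):
    """Re-fit the partition's method/hyperparameters on a data subset."""
    hp = p.hyperparams
    if p.method == "pam":
        return lambda X, s: pam(X, k=hp["k"], seed=s)
    if p.method == "spectral":
        if hp.get("affinity") == "rbf":
            return lambda X, s: spectral(X, k=hp["k"], affinity="rbf",
                                         gamma=hp["gamma"], seed=s)
        return lambda X, s: spectral(
            X, k=hp["k"], affinity="knn",
            n_neighbors=min(hp["n_neighbors"], X.shape[0] - 1), seed=s)
    if p.method == "hdbscan":
        return lambda X, s: hdbscan_cluster(
            X, min_cluster_size=min(hp["min_cluster_size"], X.shape[0] // 2 or 2),
            min_samples=min(hp["min_samples"], X.shape[0] - 1))
    return None


def _needs_ps(m: PartitionMetrics, th: dict) -> bool:
    """Would prediction strength change this partition's verdict contribution?"""
    density_candidate = m.dbcv is not None and m.dbcv > th["dbcv"]
    return density_candidate and m.balanced


def run_framework(cfg: dict | RunConfig) -> dict:
    """Execute the full framework and return the run report."""
    cfg = validate_config(cfg)
    t0 = time.time()
    report: dict = {"config": cfg.to_dict(), "stage_seconds": {}}

    def _tick(stage: str, start: float) -> None:
        report["stage_seconds"][stage] = round(time.time() - start, 2)
        logger.info("stage %s finished in %.1fs", stage, time.time() - start)

    # ---------------------------------------------------------- preprocess
    s = time.time()
    table, truth = _load_input(cfg)
    n_raw, d_raw = table.n, table.d
    if cfg.level is not None and table.lineages is not None:
        table = aggregate_taxonomy(table, cfg.level)
    table = normalize_tss(table)
    table, dropped = filter_taxa(table, cfg.min_prevalence, cfg.min_std)
    if cfg.dominated_threshold is not None:
        table = remove_dominated(table, cfg.dominated_threshold, cfg.dominated_policy)
        table = normalize_tss(table)
    report["preprocess"] = {"n_raw": n_raw, "d_raw": d_raw, "n": table.n,
                            "d": table.d, "n_taxa_dropped": len(dropped)}
    _tick("preprocess", s)

    # ----------------------------------------------------------------- pca
    s = time.time()
    model, scores = fit_pca(table, cfg.pca_variance)
    recon = inverse_pca(model, scores)
    pca_mae = float(np.median(np.abs(table.matrix - recon).sum(axis=1)))
    report["pca"] = {"d_pca": model.d_pca, "mae": pca_mae,
                     "loadings": dict(zip(table.taxon_ids,
                                          np.round(pca_loadings(model), 6)))}
    _tick("pca", s)

    # ------------------------------------------------------- intrinsic dim
    s = time.time()
    k_hi = min(cfg.id_k_range[1], table.n - 2)
    est = estimate_intrinsic_dim(scores, k_range=(cfg.id_k_range[0], k_hi),
                                 n_boot=cfg.id_n_boot, seed=cfg.seed + 1)
    d_target = cfg.d_target if cfg.d_target is not None else est.d_mle
    d_target = int(min(max(d_target, 1), model.d_pca))
    report["intrinsic_dim"] = {"d_mle": est.d_mle, "d_target": d_target,
                               "bootstrap_median": float(np.median(est.bootstrap_draws))}
    _tick("intrinsic_dim", s)

    # ------------------------------------------------------- manifold sweep
    s = time.time()
    representations: dict[str, np.ndarray | DistanceMatrix] = {"pca": scores}
    kept_map: dict[str, np.ndarray] = {"pca": np.arange(table.n)}
    embedding_rows = []
    for method in cfg.embedding_methods:
        grid = cfg.embedding_grids.get(method)
        emb = sweep_hyperparams(scores, method, grid, d_target,
                                seed=cfg.seed + 2, X_score=table.matrix)
        emb = discard_worst(table.matrix, emb, max_fraction=cfg.discard_fraction,
                            step=cfg.discard_step)
        representations[method] = emb.coords
        kept_map[method] = emb.kept_indices
        embedding_rows.append(dict(method=method, hyperparams=emb.hyperparams,
                                   mae=emb.mae, q_loc=emb.q_loc, q_glob=emb.q_glob,
                                   n_kept=len(emb.kept_indices)))
    if cfg.include_distance_representations:
        for metric in cfg.distance_metrics:
            dm = pairwise_distances(table, metric)
            representations[f"dist_{metric}"] = dm
            kept_map[f"dist_{metric}"] = np.arange(table.n)
    report["embeddings"] = embedding_rows
    _tick("manifold", s)

    # ------------------------------------------------------ clustering sweep
    s = time.time()
    partitions = sweep_clusterings(representations, cfg.clustering_grids,
                                   seed=cfg.seed + 3)
    _tick("clustering", s)

    # --------------------------------------------------------- validity gate
    s = time.time()
    scored: list[tuple[Partition, PartitionMetrics]] = []
    for p in partitions:
        rep = representations[p.representation_id]
        if isinstance(rep, DistanceMatrix):
            from .validity import dbcv as _dbcv, partition_entropy

            m = PartitionMetrics(k=p.k, entropy=partition_entropy(p.labels))
            masses = p.masses
            m.min_mass = float(masses.min()) if masses.size else 0.0
            if p.k >= 1 and (p.labels >= 0).any():
                m.dbcv = _dbcv(None, p.labels, precomputed=rep.values, dim=table.d)
            m = gate(m, cfg.thresholds)
        else:
            m = score_partition(np.asarray(rep), p, ps_clusterer=None,
                                thresholds=cfg.thresholds)
            compute_ps = cfg.ps_policy == "all" or (
                cfg.ps_policy == "lazy" and _needs_ps(m, cfg.thresholds))
            if compute_ps:
                clusterer = _make_ps_clusterer(p)
                if clusterer is not None:
                    m.prediction_strength = prediction_strength(
                        np.asarray(rep), clusterer, n_repeats=cfg.ps_repeats,
                        seed=cfg.seed + 4)
            m = gate(m, cfg.thresholds)
        scored.append((p, m))
    selection = select_best(scored)
    _tick("validity", s)

    metrics_table = pd.DataFrame([
        dict(representation=p.representation_id, method=p.method,
             hyperparams=json.dumps({k: v for k, v in p.hyperparams.items()
                                     if k != "medoids"}),
             k=p.k, davies_bouldin=m.davies_bouldin, silhouette=m.silhouette,
             dbcv=m.dbcv, prediction_strength=m.prediction_strength,
             entropy=round(m.entropy, 4), min_mass=round(m.min_mass, 4),
             noise_fraction=round(p.noise_fraction, 4),
             pass_density_pair=m.pass_density_pair,
             pass_convex_pair=m.pass_convex_pair, balanced=m.balanced,
             pass_all=m.pass_all)
        for p, m in scored])
    report["metrics_table"] = metrics_table
    report["verdict"] = selection["verdict"]
    report["n_partitions"] = len(scored)
    report["n_passing"] = selection["n_passing"]

    if selection["selected"] is not None:
        sel_p: Partition = selection["selected"]["partition"]
        report["selected"] = dict(representation=sel_p.representation_id,
                                  method=sel_p.method, k=sel_p.k,
                                  entropy=selection["selected"]["entropy"])
        if truth.get("labels") is not None:
            kept = kept_map[sel_p.representation_id]
            ari = adjusted_rand_score(np.asarray(truth["labels"])[kept], sel_p.labels)
            report["selected"]["ari_vs_truth"] = float(ari)
    if truth.get("d_true") is not None:
        report["intrinsic_dim"]["d_true"] = int(truth["d_true"])

    # ------------------------------------------------------ density analysis
    if cfg.density_enabled:
        s = time.time()
        dmap = project_viz(scores, method=cfg.density_method,
                           dims=cfg.density_dims, seed=cfg.seed + 5)
        if dmap.coords.shape[0] > 100:
            dmap = kde_density(dmap)
            dmap = high_density_regions(dmap)
            regions = dmap.region_labels
            report["density"] = {
                "bandwidth": dmap.bandwidth,
                "n_regions": int(len(set(regions[regions >= 0]))),
                "high_density_fraction": float(np.mean(regions >= 0)),
                "top_taxa": top_taxa_per_region(table, dmap),
            }
            report["_density_map"] = dmap
        _tick("density", s)

    report["total_seconds"] = round(time.time() - t0, 2)
    if cfg.output_dir is not None:
        _write_outputs(cfg, report, table)
    return report


def _write_outputs(cfg: RunConfig, report: dict, table: AbundanceTable) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["metrics_table"].to_csv(out / "partition_metrics.tsv", sep="\t", index=False)
    table.write_tsv(out / "preprocessed_table.tsv")
    if "density" in report:
        report["density"]["top_taxa"].to_csv(out / "region_top_taxa.tsv",
                                             sep="\t", index=False)
    manifest = {k: v for k, v in report.items()
                if k not in ("metrics_table", "density", "_density_map")}
    if "density" in report:
        manifest["density"] = {k: v for k, v in report["density"].items()
                               if k != "top_taxa"}
    manifest["pca"] = dict(manifest["pca"], loadings="see pca_loadings.tsv")
    pd.Series(report["pca"]["loadings"]).rename("loading").to_csv(
        out / "pca_loadings.tsv", sep="\t")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
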