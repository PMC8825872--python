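"""End-to-end pipeline: preprocess → graph → train → cluster → interpret.

A ``RunConfig`` fully determines a run: all randomness flows from its
single seed and every artifact written records the config hash, so reruns
with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from . import io as _io
from .clustering import (cluster_latent, default_min_cluster_size,
                         rescue_small_clusters, silhouette_coefficient)
from .graph import build_graph, load_custom_graph, save_graph
from .interpret import ranked_genes, weight_products
from .preprocess import log_normalize, minmax_scale, select_hvg, DEFAULT_TARGET_SUM
from .train import TrainingConfig, fit

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("scvgae")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML round-trippable.

    ``graph_source`` is 'knn', 'pknn' (Pearson KNN) or 'custom' (then
    ``graph_path`` must point to an edge-list TSV).
    """

    input_path: str = ""
    input_format: str | None = None
    outdir: str = "scvgae_run"
    graph_source: str = "knn"
    graph_path: str | None = None
    k: int = 5
    khvg: int | None = None
    n_hvg: int | None = 250
    use_pca: int | None = None
    target_sum: float = DEFAULT_TARGET_SUM
    inner_dims: tuple = (32,)
    n_heads: int = 2
    latent_dim: int = 16
    layer_kind: str = "gat"
    reg_kind: str = "kl"
    use_feature_recon: bool = False
    epochs: int = 200
    learning_rate: float = 1e-2
    seed: int = 0
    holdout_fraction: float = 0.1
    min_cluster_size: int | None = None
    rescue_min_size: int | None = None
    verbosity: str = "info"

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            k=self.k, khvg=self.khvg, n_hvg=self.n_hvg,
            inner_dims=tuple(self.inner_dims), n_heads=self.n_heads,
            latent_dim=self.latent_dim, layer_kind=self.layer_kind,
            reg_kind=self.reg_kind, use_feature_recon=self.use_feature_recon,
            epochs=self.epochs, learning_rate=self.learning_rate,
            seed=self.seed, holdout_fraction=self.holdout_fraction)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["inner_dims"] = list(d["inner_dims"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "inner_dims" in raw:
            raw["inner_dims"] = tuple(raw["inner_dims"])
        return cls(**raw)

    def digest(self) -> str:
        d = asdict(self)
        d["inner_dims"] = list(d["inner_dims"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, expression=None) -> Path:
    """Execute the full workflow and write all artifacts to ``outdir``.

    ``expression`` may be a pre-loaded ``ExpressionMatrix``; otherwise
    ``config.input_path`` is read. Returns the artifact directory.
    Artifacts: processed features, graph edge list, embeddings CSV, cluster
    labels CSV, metrics JSON, attention TSV, gene report TSV, run log and
    the resolved config.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"config {config.digest()}"
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    try:
        return _run(config, expression, outdir, tag)
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _run(config: RunConfig, expression, outdir: Path, tag: str) -> Path:
    config.to_yaml(outdir / "config.yaml")

    log.info("%s", tag)
    if expression is None:
        expression = _stage("read")(_io.read_expression)(
            config.input_path, config.input_format)
    log.info("loaded %d cells x %d genes", expression.n_cells, expression.n_genes)

    # preprocess
    @_stage("preprocess")
    def _preprocess(matrix):
        logged = log_normalize(matrix, config.target_sum)
        # HVGs are picked on the log-normalized matrix (dispersion measured
        # on the count scale) before per-gene min-max scaling
        if config.n_hvg is not None and config.n_hvg < logged.n_genes:
            features = minmax_scale(logged.subset_genes(
                select_hvg(logged, config.n_hvg)))
        else:
            features = minmax_scale(logged)
        return logged, features

    logged, features = _preprocess(expression)
    _io.write_expression(features, outdir / "features.csv",
                         header_comment=tag)

    # graph
    @_stage("graph")
    def _graph():
        if config.graph_source == "custom":
            if not config.graph_path:
                raise ValueError("graph_source 'custom' requires graph_path")
            return load_custom_graph(config.graph_path, expression.n_cells)
        metric = "pearson" if config.graph_source == "pknn" else "euclidean"
        base = logged
        if config.khvg is not None and config.khvg < logged.n_genes:
            base = logged.subset_genes(select_hvg(logged, config.khvg))
        return build_graph(minmax_scale(base), k=config.k, metric=metric,
                           use_pca=config.use_pca)

    graph = _graph()
    save_graph(graph, outdir / "graph_edges.tsv", header_comment=tag)
    log.info("graph: %d nodes, %d edges", graph.n_nodes, graph.n_edges)

    # train
    model, embedding, records, history = _stage("train")(fit)(
        features.values, graph, config.training_config())
    mu = embedding.Z.detach()
    _io.write_embedding_csv(mu, expression.cell_ids, outdir / "embedding.csv",
                            header_comment=tag)
    with open(outdir / "training_history.json", "w") as fh:
        json.dump({"_config": config.digest(), **asdict(history)}, fh, indent=1)
    log.info("trained %d epochs; final loss %.4f", config.epochs, history.loss[-1])

    # cluster
    @_stage("cluster")
    def _cluster():
        mcs = config.min_cluster_size or default_min_cluster_size(len(mu))
        assignment = cluster_latent(mu, min_cluster_size=mcs)
        if config.rescue_min_size:
            assignment = rescue_small_clusters(assignment, mu,
                                               config.rescue_min_size)
        return assignment

    assignment = _cluster()
    _io.write_labels_csv(assignment.labels, expression.cell_ids,
                         outdir / "labels.csv", header_comment=tag)

    metrics = {
        "_config": config.digest(),
        "n_clusters": assignment.n_clusters,
        "n_noise": assignment.n_noise,
        "final_loss": history.loss[-1],
        "holdout_auc": history.holdout_auc[-1],
    }
    if assignment.n_clusters >= 2:
        metrics["silhouette"] = silhouette_coefficient(mu, assignment)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1)

    # interpretability
    @_stage("interpret")
    def _interpret():
        if config.layer_kind == "gcn":
            return None, None
        w = model.stacked_weights()
        products = weight_products(w["inner"], w["mu"], w["sigma"])
        report = ranked_genes(products, mu, assignment)
        return products, report

    products, report = _interpret()
    if records:
        _io.write_attention_tsv(records, outdir / "attention.tsv",
                                header_comment=tag)
    if report is not None:
        _io.write_gene_report_tsv(report, features.gene_ids, products,
                                  outdir / "gene_report.tsv", header_comment=tag)
    log.info("done: %d clusters, %d noise cells", assignment.n_clusters,
             assignment.n_noise)
    return outdir
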