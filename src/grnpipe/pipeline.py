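"""End-to-end orchestration: simulate/load -> preprocess -> GRNs -> train ->
validate -> query scoring -> GRN status -> NIS.

``compute_pipeline`` runs every stage in memory (deterministic under the
single global seed, which fans out to per-stage seeds); ``run_pipeline``
additionally writes the artifact directory with the resolved config hash
embedded in every output file, so re-running any stage from the same config
reproduces identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import grnpipe
from grnpipe.synthetic import (
    SimulationConfig,
    generate_gold_standard,
    simulate_corpus,
    simulate_query,
    write_gold_standard,
)
from grnpipe.preprocess import normalize_total, qc_filter
from grnpipe.grn import (
    class_template_scores,
    reconstruct_network,
    detect_communities,
    assign_subnetworks,
    grn_metrics,
    export_network,
)
from grnpipe.classify import (
    ClassifierConfig,
    split_half,
    train_classifiers,
    classify,
    evaluate_all,
)
from grnpipe.status import fit_training_stats, status_all, status_report
from grnpipe.influence import network_influence
from grnpipe.tables import write_expression, write_sample_table, write_tsv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters in one document.

    A single global ``seed`` fans out deterministically to per-stage seeds;
    every output file embeds the hash of the resolved config.
    """

    seed: int = 0
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    normalize_scale: float = 1e5
    qc_k_mad: float = 5.0
    z_threshold: float = 2.0
    community_method: str = "infomap"
    top_k: int = 100
    alpha: float = 0.05
    n_trees: int = 1000
    n_boot: int = 200
    z_cap: float = 3.0
    sigma_floor_rel: float = 1e-3
    query_attenuation: float = 1.0
    query_n_per_class: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def resolved(self) -> dict:
        d = asdict(self)
        d["simulation"] = asdict(self.sim_config())
        return d

    def sim_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        return SimulationConfig(**sim)

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: int) -> int:
        return int(np.random.SeedSequence([self.seed, 100, stage]).generate_state(1)[0])


def compute_pipeline(config: RunConfig) -> dict:
    """Run every pipeline stage in memory and return the results dict.

    Any stage failure aborts with the stage name and the config hash.
    """
    chash = config.config_hash()
    stage = "setup"
    try:
        sim = config.sim_config()

        stage = "simulate"
        gold, truth = generate_gold_standard(sim)
        table, expr_raw = simulate_corpus(sim, truth)

        stage = "preprocess"  # same methodology for training and query
        kept, excluded, qc_report = qc_filter(expr_raw, config.qc_k_mad)
        expr = normalize_total(expr_raw[kept], config.normalize_scale)
        table_kept = table[table["sample_id"].isin(kept)].reset_index(drop=True)
        labels = table_kept.set_index("sample_id")["description"]

        # GRN reconstruction uses the full training corpus; the half split
        # below only feeds forest training and validation.
        stage = "build-grn"
        templates = class_template_scores(expr, labels)
        net = reconstruct_network(expr, gold, config.z_threshold)
        partition = detect_communities(
            net, seed=config.stage_seed(2), method=config.community_method
        )
        class_grns = assign_subnetworks(
            partition, templates, net, top_k=config.top_k, alpha=config.alpha
        )

        stage = "train"
        plan = split_half(table_kept, seed=config.stage_seed(1))
        expr_train = expr[plan.train_ids]
        expr_valid = expr[plan.valid_ids]
        clf_config = ClassifierConfig(
            n_trees=config.n_trees,
            top_k_templates=config.top_k,
            seed=config.stage_seed(3),
        )
        model = train_classifiers(expr_train, labels, class_grns, templates, clf_config)

        stage = "validate"
        evaluation = evaluate_all(
            model, expr_valid, labels, n_boot=config.n_boot, seed=config.stage_seed(4)
        )
        scores_valid = classify(model, expr_valid)
        metrics = grn_metrics(class_grns)

        stage = "status"
        stats = fit_training_stats(
            expr, labels, class_grns, config.z_cap, config.sigma_floor_rel
        )
        queries: dict[str, pd.DataFrame] = {}
        for cls in truth.classes:
            if cls not in stats.per_class:
                continue
            q = simulate_query(
                sim,
                truth,
                cls,
                attenuation=config.query_attenuation,
                n=config.query_n_per_class,
                seed=config.stage_seed(5),
            )
            queries[cls] = normalize_total(q, config.normalize_scale)
        all_samples = pd.concat([expr] + list(queries.values()), axis=1)
        status = status_all(all_samples, stats)
        groups = pd.Series("training", index=expr.columns, dtype=object)
        for cls, q in queries.items():
            groups = pd.concat([groups, pd.Series(f"query_{cls}", index=q.columns)])

        stage = "classify"
        scores_query = (
            classify(model, pd.concat(list(queries.values()), axis=1))
            if queries
            else None
        )

        stage = "nis"
        nis_tables = {
            cls: network_influence(q, cls, class_grns[cls], stats)
            for cls, q in queries.items()
        }
    except Exception as exc:
        logger.error("stage %r failed (config %s): %s", stage, chash, exc)
        raise RuntimeError(f"stage {stage!r} failed (config {chash}): {exc}") from exc

    return {
        "config_hash": chash,
        "truth": truth,
        "gold": gold,
        "sample_table": table,
        "qc_report": qc_report,
        "qc_excluded": excluded,
        "expr": expr,
        "split": plan,
        "labels": labels,
        "templates": templates,
        "network": net,
        "partition": partition,
        "class_grns": class_grns,
        "model": model,
        "evaluation": evaluation,
        "scores_validation": scores_valid,
        "scores_query": scores_query,
        "metrics": metrics,
        "stats": stats,
        "status": status,
        "status_groups": groups,
        "queries": queries,
        "nis": nis_tables,
    }


def write_artifacts(config: RunConfig, result: dict, outdir) -> None:
    """Write the full artifact directory for a computed pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = result["config_hash"]

    write_sample_table(result["sample_table"], outdir / "sample_table.csv")
    write_expression(result["expr"], outdir / "expression.tsv", chash)
    write_gold_standard(result["gold"], outdir / "gold_standard.tsv")
    result["truth"].to_yaml(outdir / "ground_truth.yaml")
    write_tsv(result["qc_report"], outdir / "qc_report.tsv", chash)

    write_tsv(
        result["scores_validation"].rename_axis("class").reset_index(),
        outdir / "scores_validation.tsv",
        chash,
    )
    if result["scores_query"] is not None:
        write_tsv(
            result["scores_query"].rename_axis("class").reset_index(),
            outdir / "scores_query.tsv",
            chash,
        )

    evaluation = result["evaluation"]
    (outdir / "pr_curves").mkdir(exist_ok=True)
    for cls, curve in evaluation["curves"].items():
        write_tsv(curve.to_frame(), outdir / "pr_curves" / f"{cls}.tsv", chash)
    auc = pd.DataFrame(
        {
            "class": list(evaluation["aupr"]),
            "aupr": list(evaluation["aupr"].values()),
            "auroc": list(evaluation["auroc"].values()),
            "ci_low": [evaluation["ci"][c][0] for c in evaluation["aupr"]],
            "ci_high": [evaluation["ci"][c][1] for c in evaluation["aupr"]],
        }
    )
    write_tsv(auc, outdir / "auc_summary.tsv", chash)

    (outdir / "networks").mkdir(exist_ok=True)
    for cls, grn in result["class_grns"].items():
        export_network(grn, outdir / "networks" / f"{cls}.graphml")
    write_tsv(result["metrics"].summary, outdir / "grn_metrics.tsv", chash)

    write_tsv(
        result["status"].rename_axis("class").reset_index(),
        outdir / "grn_status.tsv",
        chash,
    )
    write_tsv(
        status_report(result["status"], result["status_groups"]),
        outdir / "status_report.tsv",
        chash,
    )

    (outdir / "nis").mkdir(exist_ok=True)
    for cls, nis in result["nis"].items():
        write_tsv(nis, outdir / "nis" / f"{cls}.tsv", chash)

    meta = {
        "version": grnpipe.__version__,
        "config": config.resolved(),
        "config_hash": chash,
        "community_method": config.community_method,
        "qc_excluded": result["qc_excluded"],
        "mean_aupr": evaluation["mean_aupr"],
        "mean_auroc": evaluation["mean_auroc"],
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Compute every stage and write the artifact directory.

    Emits: sample table + expression + gold standard, validation/query score
    matrices, per-class precision-sensitivity curves + AUC summary,
    per-class GraphML networks + structure metrics, GRN-status tables, NIS
    tables, and run metadata with the resolved config hash and log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("grnpipe")
    root.addHandler(handler)
    t0 = _time.time()
    try:
        logger.info(
            "run start: config_hash=%s seed=%d", config.config_hash(), config.seed
        )
        result = compute_pipeline(config)
        write_artifacts(config, result, outdir)
        logger.info("run done in %.1fs", _time.time() - t0)
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
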