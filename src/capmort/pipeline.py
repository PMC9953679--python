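"""End-to-end orchestration: simulate -> preprocess -> cohort stats ->
differential expression -> GSEA -> survival screen -> PPI hubs.

One global seed is fanned out to stages through a counter-based child-seed
scheme (each stage has a fixed index), so toggling a stage off never
shifts the randomness of the others.  Every run writes a JSON manifest
with parameters, per-output SHA-256 checksums, and timings; identical
config + seed yields identical output checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from capmort import (
    cohort_stats,
    diffexpr,
    gsea as gsea_mod,
    network as network_mod,
    preprocess,
    survival as survival_mod,
    synthdata,
)

__all__ = ["PipelineConfig", "run_pipeline"]

# fixed stage indices for child-seed derivation
_STAGE_IDX = {
    "simulate": 0,
    "preprocess": 1,
    "cohort": 2,
    "de": 3,
    "gsea": 4,
    "survival": 5,
    "network": 6,
}


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_IDX[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Nested per-stage configuration with one global seed.

    ``stages`` toggles each stage; disabled stages leave no outputs.
    """

    seed: int = 0
    out_dir: str = "capmort_run"
    stages: dict = field(
        default_factory=lambda: {k: True for k in _STAGE_IDX}
    )
    cohort: synthdata.CohortConfig = field(default_factory=synthdata.CohortConfig)
    expression: synthdata.ExpressionConfig = field(
        default_factory=lambda: synthdata.ExpressionConfig(n_genes=2000, n_de=50)
    )
    subsampling: diffexpr.SubsamplingConfig = field(
        default_factory=diffexpr.SubsamplingConfig
    )
    max_follow_days: float = 30.0
    n_perm: int = 1000
    n_gene_sets: int = 50
    p_threshold: float = 0.05
    min_count: int = 250
    survival_alpha: float = 0.05
    survival_max_genes: int = 100
    hub_top_k: int = 10
    edges_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML file of flat, dotted keys
        (e.g. ``expression.n_genes: 2000``, ``stages.gsea: false``)."""
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in flat.items():
            parts = key.split(".")
            target = cfg
            for p in parts[:-1]:
                target = getattr(target, p) if not isinstance(target, dict) else target[p]
            last = parts[-1]
            if isinstance(target, dict):
                target[last] = value
            elif hasattr(target, last):
                setattr(target, last, value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    Outputs (TSV tables and ``manifest.json``) are written under
    ``config.out_dir``.  A stage failure raises with the stage name; the
    partially written output keeps a ``.partial`` suffix.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    started = time.time()

    ann = matrix = truth = None
    de_table = None

    def record(stage: str, params: dict, outputs: dict[str, Path], t0: float):
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {name: _sha256(p) for name, p in outputs.items()},
            "files": {name: p.name for name, p in outputs.items()},
            "runtime_s": round(time.time() - t0, 3),
        }

    def run_stage(stage, fn):
        if not config.stages.get(stage, False):
            return
        t0 = time.time()
        before = {p.name for p in out_dir.iterdir()}
        try:
            params, outputs = fn(t0)
        except Exception as exc:
            for p in out_dir.iterdir():
                if p.is_file() and p.name not in before and not p.name.endswith(".partial"):
                    p.rename(p.with_name(p.name + ".partial"))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        record(stage, params, outputs, t0)

    # -- simulate ----------------------------------------------------------
    def _simulate(t0):
        nonlocal ann, matrix, truth
        cc = config.cohort
        cc.seed = child_seed(config.seed, "simulate")
        ann = synthdata.generate_cohort(cc)
        ec = config.expression
        ec.seed = cc.seed + 1
        matrix, truth = synthdata.generate_expression(ann, ec)
        ann = synthdata.generate_survival(
            ann, max_follow_days=config.max_follow_days, seed=cc.seed + 2
        )
        paths = {
            "annotation": out_dir / "annotation.tsv",
            "expression": out_dir / "expression.tsv",
            "truth": out_dir / "truth.tsv",
        }
        synthdata.write_tsv(ann, paths["annotation"])
        synthdata.write_tsv(matrix.round(6), paths["expression"])
        synthdata.write_tsv(truth, paths["truth"])
        return {"n_samples": cc.n_samples, "n_genes": ec.n_genes,
                "n_de": ec.n_de, "seed": cc.seed}, paths

    run_stage("simulate", _simulate)

    # -- preprocess --------------------------------------------------------
    def _preprocess(t0):
        nonlocal matrix
        matrix = preprocess.quantile_normalize(matrix)
        path = out_dir / "expression_norm.tsv"
        synthdata.write_tsv(matrix.round(6), path)
        return {"method": "quantile"}, {"normalized": path}

    run_stage("preprocess", _preprocess)

    # -- cohort stats ------------------------------------------------------
    def _cohort(t0):
        table1 = cohort_stats.build_table1(
            ann,
            [("age", "continuous"), ("septic_shock", "categorical"),
             ("psi_high_risk", "categorical")],
        )
        path = out_dir / "table1.tsv"
        table1.to_csv(path, sep="\t", index=False)
        return {"n": len(ann)}, {"table1": path}

    run_stage("cohort", _cohort)

    # -- differential expression -------------------------------------------
    def _de(t0):
        nonlocal de_table
        model = diffexpr.ModeratedDEModel.from_annotation(matrix, ann)
        res = model.fit()
        sc = config.subsampling
        sc.seed = child_seed(config.seed, "de")
        counts = diffexpr.stability_selection(matrix, ann, sc)
        records = res.summary(sort=False)
        records["Resampling_N"] = counts
        de_table = diffexpr.select_top_genes(
            records, p_threshold=config.p_threshold, min_count=config.min_count
        )
        paths = {"de_all": out_dir / "de_all.tsv", "de_table": out_dir / "de_table.tsv"}
        records.sort_values("p-Value", kind="stable").to_csv(paths["de_all"], sep="\t")
        de_table[["p-Value", "FoldChange", "Resampling_N"]].to_csv(
            paths["de_table"], sep="\t"
        )
        return {"n_iter": sc.n_iter, "alpha": sc.alpha,
                "min_count": config.min_count, "seed": sc.seed}, paths

    run_stage("de", _de)

    # -- GSEA ----------------------------------------------------------------
    def _gsea(t0):
        seed = child_seed(config.seed, "gsea")
        planted = None
        if truth is not None and truth["is_de"].any():
            planted = list(truth.index[truth["is_de"]][:30])
        collection = synthdata.generate_gene_sets(
            matrix.index, n_sets=config.n_gene_sets, seed=seed, planted=planted
        )
        res = gsea_mod.gsea_run(
            matrix, ann["outcome"], collection,
            n_perm=config.n_perm, seed=seed,
        )
        pos, neg = gsea_mod.filter_significant(res)
        paths = {
            "gsea_all": out_dir / "gsea_all.tsv",
            "gsea_positive": out_dir / "gsea_positive.tsv",
            "gsea_negative": out_dir / "gsea_negative.tsv",
        }
        res.to_csv(paths["gsea_all"], sep="\t")
        pos.to_csv(paths["gsea_positive"], sep="\t")
        neg.to_csv(paths["gsea_negative"], sep="\t")
        return {"n_perm": config.n_perm, "n_sets": len(collection), "seed": seed}, paths

    run_stage("gsea", _gsea)

    # -- survival screen -----------------------------------------------------
    def _survival(t0):
        genes = (
            de_table.index if de_table is not None and len(de_table)
            else matrix.index[: config.survival_max_genes]
        )
        genes = genes[: config.survival_max_genes]
        screen = survival_mod.survival_screen(
            matrix.loc[genes], ann, alpha=config.survival_alpha
        )
        path = out_dir / "survival_screen.tsv"
        screen.to_csv(path, sep="\t")
        return {"n_genes": len(genes), "alpha": config.survival_alpha}, {"screen": path}

    run_stage("survival", _survival)

    # -- PPI network ---------------------------------------------------------
    def _network(t0):
        seed = child_seed(config.seed, "network")
        if config.edges_path:
            graph = network_mod.load_edges(config.edges_path)
        else:
            # synthetic scale-free interactome over the gene universe
            base = nx.barabasi_albert_graph(matrix.shape[0], 3, seed=seed)
            mapping = dict(enumerate(matrix.index))
            graph = nx.relabel_nodes(base, mapping)
            graph.graph["provenance"] = "synthetic barabasi-albert"
        seeds = list(de_table.index) if de_table is not None else []
        sub = network_mod.seed_subnetwork(graph, seeds, order=1)
        if sub.number_of_nodes() == 0:
            sub = graph
        hubs = network_mod.rank_hubs(sub, k=config.hub_top_k)
        paths = {"hubs": out_dir / "hubs.tsv", "graph": out_dir / "subnetwork.json"}
        hubs.to_csv(paths["hubs"], sep="\t")
        with open(paths["graph"], "w") as fh:
            json.dump(nx.node_link_data(sub, edges="links"), fh, sort_keys=True)
        return {"order": 1, "top_k": config.hub_top_k,
                "n_seeds": len(seeds), "seed": seed}, paths

    run_stage("network", _network)

    manifest["runtime_s"] = round(time.time() - started, 3)
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
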