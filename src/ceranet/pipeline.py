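"""End-to-end orchestration: simulate -> DE -> network -> topology -> RWR
-> annotation, with a machine-readable run report.

The pipeline is configured by a single nested mapping (usually loaded
from YAML); each stage runs fail-fast, writes its outputs under the
configured directory, and contributes counts to the run report so
consistency across stage boundaries can be audited (e.g. the edge count
reported by the network stage equals the edge count the topology stage
consumed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .annotation import ora, pearson_select
from .de import PairedModeratedTTest, de_summary
from .io import (
    PairedExpressionSet,
    read_expression,
    read_gmt,
    read_interactions,
    read_seed_list,
    write_network,
)
from .network import CeRNANetworkBuilder, extract_subnetwork
from .rwr import RandomWalkRestart
from .simulate import SyntheticConfig, generate_dataset, write_fixture
from .topology import centralities, degree_distribution, hub_intersection, top_k

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "StageFailure"]

DEFAULT_CONFIG: dict[str, Any] = {
    "out_dir": "ceranet_run",
    "rng_seed": 0,
    "alpha_de": 0.05,
    "fc_threshold": 2.0,
    "alpha_cerna": 0.01,
    "universe_mode": "interaction-union",
    "k": 10,
    "rwr": {
        "restart_prob": 0.5,
        "tol": 1e-10,
        "max_iter": 10000,
        "n_permutations": 10000,
        "alpha": 0.01,
        "perm_seed": None,
    },
    "simulate": {},  # SyntheticConfig overrides; presence enables simulation
    "inputs": {},  # else: paths for mrna/lncrna/mirna/samples/interactions/seeds
    "gmt": None,
    "annotate_top": 2,
}


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a YAML config, layered over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _config_hash(cfg: dict) -> str:
    # the hash identifies the analysis, not where its files land
    hashed = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: dict[str, Any]) -> dict[str, Any]:
    """Execute every configured stage and return the run report.

    Stages run fail-fast; on failure the outputs of completed stages are
    retained and a ``FAILED`` marker naming the stage and cause is
    written to the output directory before the error propagates.
    """
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run_pipeline(cfg, out_dir)
    except StageFailure as exc:
        (out_dir / "FAILED").write_text(f"{exc.stage}\t{exc.cause}\n")
        raise


def _run_pipeline(cfg: dict[str, Any], out_dir: Path) -> dict[str, Any]:
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "parameters": {
            k: cfg[k]
            for k in ("alpha_de", "fc_threshold", "alpha_cerna", "universe_mode", "k")
        },
        "stages": {},
    }
    t_start = time.perf_counter()
    truth = None

    # ---- inputs ----------------------------------------------------------
    stage = "inputs"
    try:
        if cfg.get("simulate") is not None and cfg.get("simulate") != {} or not cfg.get("inputs"):
            sim_cfg = SyntheticConfig(
                **{"rng_seed": cfg.get("rng_seed", 0), **(cfg.get("simulate") or {})}
            )
            dataset = generate_dataset(sim_cfg)
            write_fixture(dataset, out_dir / "fixture")
            expr, interactions = dataset.expression, dataset.interactions
            seeds = dataset.truth.seed_genes
            truth = dataset.truth
            report["stages"]["simulate"] = {
                "config": asdict(sim_cfg),
                "n_interaction_edges": len(interactions),
            }
        else:
            paths = cfg["inputs"]
            matrices = {}
            sheet = None
            for cls in ("mrna", "lncrna", "mirna"):
                matrices[cls], sheet = read_expression(paths[cls], paths["samples"])
            expr = PairedExpressionSet(matrices=matrices, sample_sheet=sheet)
            interactions = read_interactions(paths["interactions"])
            seeds = read_seed_list(paths["seeds"])
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    # ---- differential expression ----------------------------------------
    stage = "de"
    try:
        de_results: dict[str, pd.DataFrame] = {}
        for cls in expr.classes:
            est = PairedModeratedTTest(
                alpha=cfg["alpha_de"], fc_threshold=cfg["fc_threshold"]
            ).fit(expr.paired_differences(cls))
            de_results[cls] = est.results_
            est.results_.to_csv(out_dir / f"de_{cls}.tsv", sep="\t")
        summary = de_summary(de_results)
        summary.to_csv(out_dir / "de_summary.tsv", sep="\t", index=False)
        report["stages"]["de"] = {
            row["rna_class"]: {
                "n_features": int(row["n_features"]),
                "n_significant": int(row["n_significant"]),
                "n_up": int(row["n_up"]),
                "n_down": int(row["n_down"]),
            }
            for _, row in summary.iterrows()
        }
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    # ---- ceRNA network ---------------------------------------------------
    stage = "network"
    try:
        sig = {
            cls: res.index[res["significant"]].tolist()
            for cls, res in de_results.items()
        }
        builder = CeRNANetworkBuilder(
            alpha=cfg["alpha_cerna"], universe_mode=cfg["universe_mode"]
        ).fit(interactions, sig.get("mirna", []), sig.get("mrna", []), sig.get("lncrna", []))
        network = builder.network_
        write_network(network, out_dir / "cerna_edges.tsv", fmt="edgelist")
        write_network(network, out_dir / "cerna_network.graphml", fmt="graphml")
        report["stages"]["network"] = {
            "n_candidate_pairs": int(len(builder.pairs_)),
            "n_edges": int(network.number_of_edges()),
            "n_lncrna": sum(
                1 for _, d in network.nodes(data=True) if d["node_class"] == "lncRNA"
            ),
            "n_mrna": sum(
                1 for _, d in network.nodes(data=True) if d["node_class"] == "mRNA"
            ),
            "universe_size": len(builder.universe_) if builder.universe_ is not None else None,
        }
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    # ---- topology --------------------------------------------------------
    stage = "topology"
    try:
        if network.number_of_nodes() < 2:
            raise ValueError("ceRNA network too small for topological analysis")
        rep = centralities(network)
        rep.table.to_csv(out_dir / "centralities.tsv", sep="\t", index=False)
        k = min(cfg["k"], network.number_of_nodes())
        hubs = sorted(hub_intersection(rep, k=k))
        tops = {m: top_k(rep, m, k) for m in ("degree", "betweenness", "closeness")}
        dist_fits = {}
        for cls in ("lncRNA", "mRNA"):
            _, fit = degree_distribution(rep, node_class=cls)
            dist_fits[cls] = fit
        report["stages"]["topology"] = {
            "n_edges": int(network.number_of_edges()),
            "k": k,
            "top_k": tops,
            "hubs": hubs,
            "degree_fit": dist_fits,
        }
        (out_dir / "hubs.txt").write_text("".join(f"{h}\n" for h in hubs))
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    # ---- RWR -------------------------------------------------------------
    stage = "rwr"
    try:
        rwr_cfg = cfg["rwr"]
        perm_seed = rwr_cfg.get("perm_seed")
        if perm_seed is None:
            perm_seed = cfg.get("rng_seed", 0)
        walker = RandomWalkRestart(
            restart_prob=rwr_cfg["restart_prob"],
            tol=rwr_cfg["tol"],
            max_iter=rwr_cfg["max_iter"],
            n_permutations=rwr_cfg["n_permutations"],
            perm_seed=perm_seed,
            alpha=rwr_cfg["alpha"],
        ).fit(network, seeds)
        walker.ranking_.to_csv(out_dir / "rwr_ranking.tsv", sep="\t", index=False)
        sig_lnc = walker.ranking_.loc[walker.ranking_["significant"], "lncrna_id"]
        report["stages"]["rwr"] = {
            "seeds": walker.seeds_,
            "n_permutations": rwr_cfg["n_permutations"],
            "n_iterations": walker.n_iter_,
            "significant_lncrnas": sig_lnc.tolist(),
        }
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    # ---- annotation (optional: needs a GMT) ------------------------------
    stage = "annotate"
    try:
        focal = hubs[: cfg.get("annotate_top", 2)] or sig_lnc.tolist()[:1]
        focal = [f for f in focal if network.nodes.get(f, {}).get("node_class") == "lncRNA"]
        ann_report = {}
        gmt = read_gmt(cfg["gmt"]) if cfg.get("gmt") else None
        for lnc in focal:
            competing = sorted(network.neighbors(lnc))
            sel = pearson_select(
                expr.matrices["lncrna"].loc[lnc],
                expr.matrices["mrna"].loc[competing],
            )
            sel.to_csv(out_dir / f"targets_{lnc}.tsv", sep="\t", index=False)
            selected = sel.loc[sel["selected"], "mrna_id"].tolist()
            entry = {"n_competing": len(competing), "n_selected": len(selected)}
            if gmt is not None and selected:
                enr = ora(selected, gmt, universe=expr.matrices["mrna"].index)
                enr.to_csv(out_dir / f"enrichment_{lnc}.tsv", sep="\t", index=False)
                entry["n_sets_tested"] = int(len(enr))
            ann_report[lnc] = entry
            sub = extract_subnetwork(network, lnc)
            write_network(sub, out_dir / f"subnetwork_{lnc}.graphml", fmt="graphml")
        report["stages"]["annotate"] = ann_report
    except Exception as exc:
        raise StageFailure(stage, exc) from exc

    report["wall_time_s"] = round(time.perf_counter() - t_start, 3)
    if truth is not None:
        report["truth_summary"] = {
            "hub_lncrnas": truth.hub_lncrnas,
            "disease_lncrnas": truth.disease_lncrnas,
            "seed_genes": truth.seed_genes,
            "n_planted_pairs": len(truth.planted_pairs),
        }
    (out_dir / "run_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=str) + "\n"
    )
    return report
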