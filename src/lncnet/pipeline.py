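"""End-to-end orchestration from a single YAML config.

Stages run in the published order: differential screen, hierarchical
clustering of the significant probes, gene-set enrichment of the
significant mRNA symbols, lncRNA-mRNA co-expression at |r| >= 0.99,
lncRNA-TF hypergeometric association, and (optionally) qPCR relative
quantification. Every threshold is a config key defaulting to the published
value; a run manifest records all parameters, seeds, package versions and
input checksums so identical config + seed reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    export_heatmap_table,
    hierarchical_cluster,
    pearson_distance_matrix,
    to_newick,
)
from .coexpress import coexpressed_partner_sets, coexpression_edges
from .core import LNCRNA, MRNA, ExpressionMatrix, ProbeAnnotation, ValidationError
from .diffexpr import screen, significant_ids
from .enrichment import enrich
from .io import (
    read_annotation,
    read_expression_matrix,
    read_gmt,
    write_expression_matrix,
    write_gmt,
    write_network,
    write_table,
)
from .qpcr import read_ct_table, relative_quantity
from .simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_functional_gmt,
    simulate_qpcr,
    simulate_tf_gmt,
)
from .tfnet import build_tripartite_network, hub_ranking, tf_enrichment

log = logging.getLogger("lncnet")

DEFAULT_THRESHOLDS = {
    "fc": 2.0,
    "p": 0.05,
    "r": 0.99,
    "tf_p": 0.01,
    "tf_fdr": 0.01,
}

DEFAULT_OPTIONS = {
    "test_mode": "pooled",
    "linkage": "average",
    "use_absolute_r": True,
    "joint_tf_fdr": True,
    "uppercase_symbols": False,
}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config_path: str | os.PathLike) -> Path:
    """Run the whole analysis; returns the output directory.

    The config names either input files (matrix/groups/annotation, optional
    GMT collections and Ct table) or ``simulate: true`` with a simulation
    block. All randomness derives from the single top-level ``seed``.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out_dir = Path(cfg.get("output_dir", "lncnet_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    thresholds = {**DEFAULT_THRESHOLDS, **(cfg.get("thresholds") or {})}
    options = {**DEFAULT_OPTIONS, **(cfg.get("options") or {})}
    inputs = cfg.get("inputs") or {}
    manifest: dict = {
        "package": "lncnet",
        "version": __version__,
        "config": str(config_path),
        "seed": seed,
        "thresholds": thresholds,
        "options": options,
        "inputs": {},
        "stages": {},
    }

    logging.basicConfig(
        filename=out_dir / "run.log", filemode="w", level=logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s", force=True,
    )

    # ---- stage: inputs -------------------------------------------------
    stage = "load"
    try:
        if cfg.get("simulate"):
            sim_kwargs = dict(cfg.get("simulation") or {})
            if "module_size" in sim_kwargs:
                sim_kwargs["module_size"] = tuple(sim_kwargs["module_size"])
            sim_kwargs.setdefault("seed", seed)
            sim_cfg = SimulationConfig(**sim_kwargs)
            matrix, annotation, truth = simulate_expression(sim_cfg)
            tf_sets = simulate_tf_gmt(sim_cfg, truth)
            functional = {"simulated": simulate_functional_gmt(sim_cfg, annotation)}
            write_expression_matrix(matrix, out_dir / "matrix.tsv")
            write_gmt(tf_sets, out_dir / "tf_sets.gmt")
            write_table(truth.de, out_dir / "truth_de.tsv")
            write_table(truth.modules, out_dir / "truth_modules.tsv")
            manifest["simulation"] = sim_kwargs
            ct_records = simulate_qpcr(
                n_case=20, n_control=10, true_log2_ratio=sim_cfg.de_shift, seed=seed + 1
            )
        else:
            matrix = read_expression_matrix(inputs["matrix"], inputs["groups"])
            annotation = read_annotation(inputs["annotation"])
            tf_sets = read_gmt(inputs["tf_gmt"]) if "tf_gmt" in inputs else None
            functional = {
                Path(p).stem: read_gmt(p) for p in inputs.get("functional_gmt", [])
            }
            ct_records = read_ct_table(inputs["ct_table"]) if "ct_table" in inputs else None
            for key, p in inputs.items():
                for f in (p if isinstance(p, list) else [p]):
                    manifest["inputs"][str(f)] = _checksum(Path(f))
        if options["uppercase_symbols"]:
            tab = annotation.table.copy()
            tab["gene_symbol"] = tab["gene_symbol"].str.upper()
            annotation = ProbeAnnotation(tab)
        log.info("loaded %d probes x %d samples", len(matrix.probe_ids), len(matrix.sample_ids))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: differential screen ------------------------------------
    stage = "de"
    try:
        de = screen(matrix, fc_threshold=thresholds["fc"], p_threshold=thresholds["p"],
                    test_mode=options["test_mode"])
        write_table(de, out_dir / "de.tsv")
        lnc_set = set(annotation.probes_of_class(LNCRNA))
        mrna_set = set(annotation.probes_of_class(MRNA))
        sig = significant_ids(de)
        sig_lnc = [p for p in sig if p in lnc_set]
        sig_mrna = [p for p in sig if p in mrna_set]
        manifest["stages"]["de"] = {
            "tested": len(de), "significant": len(sig),
            "significant_lncRNA": len(sig_lnc), "significant_mRNA": len(sig_mrna),
            "up": int((de["significant"] & (de["direction"] == "up")).sum()),
            "down": int((de["significant"] & (de["direction"] == "down")).sum()),
        }
        log.info("screen: %d/%d significant", len(sig), len(de))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: clustering ---------------------------------------------
    stage = "cluster"
    try:
        if len(sig) >= 2:
            sub = matrix.subset_probes(sig)
            probe_d = pearson_distance_matrix(sub.values)
            probe_Z, probe_order = hierarchical_cluster(probe_d, linkage=options["linkage"])
            sample_d = pearson_distance_matrix(sub.values.T)
            sample_Z, sample_order = hierarchical_cluster(sample_d, linkage=options["linkage"])
            export_heatmap_table(sub.values, probe_order, sample_order, out_dir / "heatmap.tsv")
            (out_dir / "tree_probes.nwk").write_text(to_newick(probe_Z, list(probe_d.index)) + "\n")
            (out_dir / "tree_samples.nwk").write_text(to_newick(sample_Z, list(sample_d.index)) + "\n")
            manifest["stages"]["cluster"] = {"probes": len(probe_order), "linkage": options["linkage"]}
        else:
            manifest["stages"]["cluster"] = {"skipped": "fewer than 2 significant probes"}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: functional enrichment ----------------------------------
    stage = "enrich"
    try:
        symbols = annotation.symbol_map()
        sig_symbols = sorted({symbols[p] for p in sig_mrna if p in symbols})
        manifest["stages"]["enrich"] = {}
        for name, collection in functional.items():
            try:
                res = enrich(sig_symbols, collection)
            except ValidationError as exc:
                manifest["stages"]["enrich"][name] = {"skipped": str(exc)}
                continue
            write_table(res, out_dir / f"enrich_{name}.tsv")
            manifest["stages"]["enrich"][name] = {
                "terms": len(res), "significant_p05": int((res["p_value"] < 0.05).sum()),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: co-expression ------------------------------------------
    stage = "coexpress"
    try:
        edges = coexpression_edges(
            matrix, sig_lnc, sig_mrna,
            threshold=thresholds["r"], use_absolute=options["use_absolute_r"],
        )
        write_table(edges, out_dir / "edges.tsv")
        partners = coexpressed_partner_sets(edges, symbol_map=symbols)
        manifest["stages"]["coexpress"] = {
            "edges": len(edges), "lncRNAs_with_partners": len(partners),
        }
        log.info("coexpression: %d edges at |r| >= %s", len(edges), thresholds["r"])
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: TF association -----------------------------------------
    stage = "tfnet"
    try:
        if tf_sets is not None and partners:
            measured = frozenset(symbols.values())
            assoc = tf_enrichment(
                partners, tf_sets, p_cut=thresholds["tf_p"], fdr_cut=thresholds["tf_fdr"],
                universe=measured, joint_fdr=options["joint_tf_fdr"],
            )
            write_table(assoc, out_dir / "tf_associations.tsv")
            graph = build_tripartite_network(assoc, edges, tf_sets, symbol_map=symbols)
            write_network(graph, out_dir / "tfnet.sif", fmt="sif")
            write_network(graph, out_dir / "tfnet.graphml", fmt="graphml")
            manifest["stages"]["tfnet"] = {
                "pairs_tested": len(assoc),
                "accepted": int(assoc["accepted"].sum()) if len(assoc) else 0,
                "hubs": hub_ranking(graph)[:5],
            }
        else:
            manifest["stages"]["tfnet"] = {"skipped": "no TF sets or no partner sets"}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage: qPCR ----------------------------------------------------
    stage = "qpcr"
    try:
        if ct_records:
            summary = relative_quantity(ct_records)
            write_table(summary.per_sample, out_dir / "rq.tsv")
            write_table(summary.group_stats, out_dir / "rq_groups.tsv")
            manifest["stages"]["qpcr"] = {
                "n": len(ct_records), "p_value": summary.p_value,
                "direction": summary.direction,
            }
        else:
            manifest["stages"]["qpcr"] = {"skipped": "no Ct data"}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    with open(out_dir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(manifest, default=str)), fh, sort_keys=False)
    return out_dir
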