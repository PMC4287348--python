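"""End-to-end orchestration: filter → TMM → DE → average → scale → PCA → SOM
→ validate → enrich → intersect, with a JSON run summary.

Every stage writes its outputs under the configured directory so any later
stage can be resumed from files; all randomness flows from one master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .assembly_stats import length_summary, read_lengths
from .cluster_validation import validate_cluster_numbers
from .cross_species import assign_foreign_nodes, intersection_chisq, null_distribution
from .differential_expression import bh_fdr, de_union, pairwise_de
from .enrichment import hypergeom_enrich, wallenius_enrich
from .io_formats import (
    read_best_hits,
    read_count_matrix,
    read_go_annotation,
    read_node_table,
    write_node_table,
)
from .normalization import cpm, filter_low_counts, tmm_factors
from .profiles_clustering import (
    average_replicates,
    node_summary,
    pca,
    scale_rows,
    train_som,
)

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "inputs": {
        "counts": None, "sheet": None, "go": None, "fasta": None,
        "blast": None, "foreign_nodes": None,
    },
    "output_dir": "atlas_out",
    "seed": 0,
    "min_total": 30,
    "fdr": 0.05,
    "dispersion": None,
    "grid": [3, 2],
    "topology": "hexagonal",
    "iterations": 100,
    "alpha": [0.05, 0.01],
    "validation": {
        "enabled": False,
        "grids": [[1, 2], [1, 3], [2, 2], [2, 3], [2, 4]],
        "runs": 100,
    },
    "enrichment": {"length_aware": True},
}


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping[str, Any]) -> dict:
    """Run every configured stage; returns (and writes) the run summary."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val

    inputs = {k: v for k, v in cfg["inputs"].items() if v}
    required = ["counts", "sheet"]
    missing = [k for k in required if k not in inputs]
    if missing:
        raise FileNotFoundError(f"config missing required input(s): {missing}")
    for name, p in inputs.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"input {name!r} not found: {p}")

    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "parameters": {k: cfg[k] for k in
                       ("min_total", "fdr", "grid", "topology", "iterations",
                        "alpha")},
        "input_checksums": {k: _sha256(Path(v)) for k, v in inputs.items()},
        "stages": {},
    }

    # --- counts, filter, normalize -------------------------------------
    cm = read_count_matrix(inputs["counts"], inputs["sheet"])
    summary["stages"]["input"] = {"transcripts": len(cm.transcript_ids),
                                  "samples": len(cm.sample_ids)}
    cm_f = filter_low_counts(cm, cfg["min_total"])
    summary["stages"]["filter"] = {"kept": len(cm_f.transcript_ids),
                                   "min_total": cfg["min_total"]}
    factors = tmm_factors(cm_f)
    nm = cpm(cm_f, factors)
    nm.values.to_csv(outdir / "cpm.tsv", sep="\t", index_label="transcript_id")
    factors.to_frame().to_csv(outdir / "tmm_factors.tsv", sep="\t",
                              index_label="sample_id")

    # --- pairwise DE ----------------------------------------------------
    de = pairwise_de(cm_f, factors, dispersion=cfg["dispersion"],
                     fdr_threshold=cfg["fdr"])
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    for pair, df in de.items():
        name = "-vs-".join(sorted(pair))
        df.to_csv(de_dir / f"{name}.tsv", sep="\t",
                  index_label="transcript_id")
    union = de_union(de, cm_f.organs, threshold=cfg["fdr"])
    (outdir / "de_union.txt").write_text("\n".join(union) + "\n")
    summary["stages"]["de"] = {"pairs": len(de), "union_size": len(union)}

    # --- profiles, PCA, SOM --------------------------------------------
    avg = average_replicates(nm.values.loc[union], cm_f.sample_sheet,
                             cm_f.organ_labels)
    spm = scale_rows(avg)
    pca_res = pca(spm.values)
    model = train_som(spm, grid=tuple(cfg["grid"]), topology=cfg["topology"],
                      n_iter=cfg["iterations"], alpha=tuple(cfg["alpha"]),
                      seed=seed)
    summ = node_summary(model, spm)
    summ.to_csv(outdir / "node_summary.tsv", sep="\t")
    per_gene = pd.concat(
        [avg.add_prefix("mean_cpm_"),
         spm.values.add_prefix("scaled_"),
         pca_res.scores,
         model.assignment, model.distance], axis=1)
    per_gene.to_csv(outdir / "cluster_table.tsv", sep="\t",
                    index_label="transcript_id")
    write_node_table(model.assignment, outdir / "nodes.tsv")
    node_sizes = model.assignment.value_counts().sort_index()
    summary["stages"]["som"] = {
        "grid": cfg["grid"],
        "node_sizes": {int(k): int(v) for k, v in node_sizes.items()},
        "scaled_rows_dropped": len(spm.dropped),
    }

    # --- cluster-number validation -------------------------------------
    if cfg["validation"]["enabled"]:
        vres = validate_cluster_numbers(
            spm, pca_res.scores,
            grids=[tuple(g) for g in cfg["validation"]["grids"]],
            n_runs=int(cfg["validation"]["runs"]),
            master_seed=seed, topology=cfg["topology"],
            n_iter=cfg["iterations"], alpha=tuple(cfg["alpha"]))
        vres.records.to_csv(outdir / "validation_fractions.tsv", sep="\t",
                            index=False)
        summary["stages"]["validation"] = {
            "recommended_k": vres.recommended_k,
            "medians": {int(k): float(v) for k, v in vres.medians.items()},
        }

    # --- assembly stats + GO enrichment --------------------------------
    lengths = None
    if "fasta" in inputs:
        lengths = read_lengths(inputs["fasta"])
        summary["stages"]["assembly"] = length_summary(lengths)
    if "go" in inputs:
        ann = read_go_annotation(inputs["go"])
        universe = list(spm.values.index)
        enrich_dir = outdir / "enrichment"
        enrich_dir.mkdir(exist_ok=True)
        n_sig = {}
        for unit in sorted(model.assignment.unique()):
            members = list(model.assignment.index[model.assignment == unit])
            if cfg["enrichment"]["length_aware"] and lengths is not None:
                res = wallenius_enrich(members, universe, ann, lengths,
                                       fdr_threshold=cfg["fdr"])
            else:
                res = hypergeom_enrich(members, universe, ann,
                                       fdr_threshold=cfg["fdr"])
            res.to_csv(enrich_dir / f"node_{unit}.tsv", sep="\t", index=False)
            n_sig[int(unit)] = int(res["significant"].sum())
        summary["stages"]["enrichment"] = {"significant_terms": n_sig}

    # --- cross-species intersection ------------------------------------
    if "blast" in inputs and "foreign_nodes" in inputs:
        hits = read_best_hits(inputs["blast"])
        membership = read_node_table(inputs["foreign_nodes"])
        gene_table, excluded = assign_foreign_nodes(
            hits, membership, source_nodes=model.assignment)
        null = null_distribution(membership)
        chi_summary, chi_long = intersection_chisq(gene_table, null)
        inter_dir = outdir / "intersection"
        inter_dir.mkdir(exist_ok=True)
        gene_table.to_csv(inter_dir / "gene_table.tsv", sep="\t", index=False)
        chi_summary["fdr"] = bh_fdr(chi_summary["p_value"].to_numpy())
        chi_summary.to_csv(inter_dir / "chisq.tsv", sep="\t", index=False)
        chi_long.to_csv(inter_dir / "observed_expected.tsv", sep="\t",
                        index=False)
        summary["stages"]["intersection"] = {
            "assigned_genes": len(gene_table),
            "excluded": excluded,
            "p_values": {str(r.source_node): float(r.p_value)
                         for r in chi_summary.itertuples()},
        }

    with open(outdir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
    return summary
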