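"""End-to-end orchestration: phospho processing -> annotation -> network
proximity -> TF activity -> integration outputs, from one declarative
configuration."""

from __future__ import annotations

import json
import logging
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity, annotate, network, phospho
from . import io as pio

log = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "return_probability": 0.5,
    "iterations": 15,
    "venn_ratio": 2.0,
    "phospho_fold": 1.5,
    "p_cut": 0.2,
    "top_k": 30,
    "top_sites": 50,
    "max_confidence": "D",
    "min_targets": 3,
    "aggregation": "min",
    "alternative": "less",
    "altered_direction": "both",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    return validate_config(config, base=Path(path).parent)


def validate_config(config: dict, base: Path | None = None) -> dict:
    config = dict(config)
    config["params"] = {**DEFAULT_PARAMS, **config.get("params", {})}
    for key, value in config["params"].items():
        if key in {"venn_ratio", "phospho_fold", "p_cut", "top_k", "top_sites",
                   "iterations", "return_probability", "min_targets"} and value <= 0:
            raise ValueError(f"parameter {key} must be positive, got {value}")
    inputs = config.get("inputs", {})
    required = {"network", "phospho_signals", "effects", "kinases", "regulons",
                "signature", "categories"}
    missing = required - set(inputs)
    if missing:
        raise ValueError(f"config lacks input path(s): {sorted(missing)}")
    for key, path in inputs.items():
        resolved = Path(path) if base is None else (base / path if not Path(path).is_absolute() else Path(path))
        if not resolved.exists():
            raise FileNotFoundError(f"input {key!r}: {resolved} does not exist")
        inputs[key] = str(resolved)
    config["inputs"] = inputs
    return config


def _stage(name):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - report the failing stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorator


def run_all(config: dict, output_dir: str | Path | None = None) -> dict:
    """Execute every stage and write the result bundle.

    Outputs: signed fold-change table, Venn JSON, annotation layer matrix
    and tree, proximity/distance matrices, per-gene ranking + TF selection
    JSONs, the closeness test and a run manifest.  Identical config + seed
    yields byte-identical numeric outputs.
    """
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    labels = config["labels"]
    outdir = Path(output_dir if output_dir is not None else config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config["inputs"]
    treatments = sorted(labels["treatments"])

    # --- phospho processing ------------------------------------------------
    adjusted, venn = _phospho_stage(inputs, labels, params, outdir)

    # --- annotation layers -------------------------------------------------
    _annotation_stage(inputs, params, adjusted, outdir)

    # --- network proximity + TF activity + integration ---------------------
    regulons = _regulon_stage(inputs, params)
    prox, seeds = _proximity_stage(inputs, params, adjusted, regulons, outdir)
    activities = _activity_stage(inputs, params, regulons, outdir)
    gene_reports = _integration_stage(
        config, params, labels, adjusted, regulons, prox, activities, outdir
    )
    closeness = _closeness_stage(params, labels, adjusted, regulons, prox, outdir)

    manifest = {
        "phosphonet_version": pkg_version("phosphonet"),
        "seed": config.get("seed"),
        "params": params,
        "labels": labels,
        "inputs": {k: str(Path(v).name) for k, v in inputs.items()},
        "genes_of_interest": config.get("genes_of_interest", []),
        "n_proximity_seeds": len(seeds),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {
        "adjusted": adjusted, "venn": venn, "proximity": prox,
        "activities": activities, "gene_reports": gene_reports,
        "closeness": closeness, "manifest": manifest,
    }


@_stage("phospho")
def _phospho_stage(inputs, labels, params, outdir):
    records = pio.read_phospho_signals(inputs["phospho_signals"])
    effects = pio.read_effects(inputs["effects"])
    fcs = phospho.compute_site_fold_changes(records, labels["control"], sorted(labels["treatments"]))
    adjusted = phospho.adjust_fold_change_signs(fcs, effects)
    venn = phospho.treatment_response_sets(
        adjusted, ratio_threshold=params["venn_ratio"], treatments=tuple(sorted(labels["treatments"]))
    )
    pio.write_table(adjusted, outdir / "signed_fold_changes.tsv")
    with open(outdir / "venn.json", "w") as fh:
        json.dump(venn.to_jsonable(), fh, indent=1, sort_keys=True)
    pio.write_table(phospho.summarize_venn(venn), outdir / "venn_counts.tsv")
    return adjusted, venn


@_stage("annotation")
def _annotation_stage(inputs, params, adjusted, outdir):
    categories = annotate.categories_from_gmt(pio.read_gmt(inputs["categories"]))
    kinases = pio.read_kinase_table(inputs["kinases"])
    effects = pio.read_effects(inputs["effects"])
    rows = annotate.top_sites(adjusted, n=params["top_sites"])
    matrix = annotate.annotate_functional_layers(rows, categories, kinases, effects)
    order, Z = annotate.cluster_rows(matrix)
    ordered = matrix.loc[order]
    flat = ordered.copy()
    flat.columns = [f"{cat}:{layer}" for cat, layer in ordered.columns]
    flat.index = [f"{p}_{s}" for p, s in ordered.index]
    flat.index.name = "phosphosite"
    pio.write_table(flat, outdir / "layer_matrix.tsv", index=True)
    labels_ = [f"{p}_{s}" for p, s in matrix.index]
    with open(outdir / "layer_tree.nwk", "w") as fh:
        fh.write(annotate.linkage_to_newick(Z, labels_) + "\n")
    return matrix


@_stage("regulons")
def _regulon_stage(inputs, params):
    table = pio.read_regulon_table(inputs["regulons"])
    return activity.build_regulons(table, max_confidence=params["max_confidence"])


@_stage("proximity")
def _proximity_stage(inputs, params, adjusted, regulons, outdir):
    net = network.build_signaling_network(pio.read_sif(inputs["network"]))
    walk = network.WalkParameters(
        return_probability=params["return_probability"], iterations=params["iterations"]
    )
    seeds = sorted(set(adjusted["protein"]))
    tfs = sorted(set(regulons["tf"]))
    prox = network.proximity_matrix(net, seeds, tfs, walk)
    pio.write_table(prox.probabilities, outdir / "proximity.tsv", index=True)
    dist = prox.distances.replace(np.inf, np.nan)
    pio.write_table(dist, outdir / "distance.tsv", index=True)
    return prox, list(prox.probabilities.index)


@_stage("tf_activity")
def _activity_stage(inputs, params, regulons, outdir):
    signature = pio.read_signature(inputs["signature"])
    activities = activity.estimate_tf_activities(
        signature, regulons, min_targets=params["min_targets"]
    )
    pio.write_table(activities, outdir / "tf_activities.tsv")
    return activities


@_stage("integration")
def _integration_stage(config, params, labels, adjusted, regulons, prox, activities, outdir):
    focal = labels.get("focal_treatment")
    focal_fcs = adjusted[adjusted["treatment"] == focal] if focal else adjusted
    rep = phospho.representative_site_per_protein(focal_fcs) if len(focal_fcs) else None
    fold_changes = (
        pd.Series(np.exp2(rep["log2fc"]).to_numpy(), index=rep["protein"]) if rep is not None else None
    )
    reports = {}
    for gene in config.get("genes_of_interest", []):
        gene = pio.normalize_symbol(gene)
        ranking = network.rank_proteins_by_gene_proximity(
            gene, prox, regulons, k=params["top_k"],
            fold_changes=fold_changes, aggregation=params["aggregation"],
        )
        selected = activity.select_gene_tfs(gene, activities, regulons, p_cut=params["p_cut"])
        increased = activity.tfs_with_phospho_increase(
            gene, regulons, focal_fcs, fold_threshold=params["phospho_fold"], treatment=focal
        )
        records = ranking.to_dict(orient="records")
        for row in records:  # JSON has no inf/nan
            for key, value in row.items():
                if isinstance(value, float) and not np.isfinite(value):
                    row[key] = None
        report = {
            "gene": gene,
            "top_proteins": records,
            "selected_tfs": selected.to_dict(orient="records"),
            "phospho_increase_tfs": sorted(increased),
        }
        with open(outdir / f"gene_{gene}.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        reports[gene] = report
    return reports


@_stage("closeness_test")
def _closeness_stage(params, labels, adjusted, regulons, prox, outdir):
    focal = labels.get("focal_treatment")
    focal_fcs = adjusted[adjusted["treatment"] == focal] if focal else adjusted
    tfs = sorted(set(regulons["tf"]))
    statistic, pvalue = network.compare_altered_vs_unaltered_distances(
        prox, focal_fcs, tfs,
        fold_threshold=params["phospho_fold"],
        alternative=params["alternative"],
        direction=params["altered_direction"],
    )
    result = {
        "U": statistic, "p": pvalue,
        "fold_threshold": params["phospho_fold"],
        "alternative": params["alternative"],
    }
    with open(outdir / "closeness_test.json", "w") as fh:
        json.dump(result, fh, indent=1, sort_keys=True)
    return result
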