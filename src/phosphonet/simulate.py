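"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is a pure function of the scenario (including its seed):
the same scenario yields bit-identical tables.  Ground truth is computed by
literal re-application of the planted rules inside the generator, never by
calling the analysis code, so end-to-end tests compare two independent
routes.

Background phosphosite log2 ratios are clipped below the response
thresholds (|log2fc| <= 0.45 < log2(1.5) < log2(2)), which makes the
planted Venn memberships and fold-change filters exactly recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_effects, write_gmt, write_sif, write_signature, write_table
from .network import SignalingNetwork

BACKGROUND_CLIP = 0.45  # log2 units, strictly below log2(1.5)
_RESIDUES = "STY"


@dataclass
class SyntheticScenario:
    """Sizes, planted effects and noise levels for one simulated study."""

    seed: int = 0
    n_nodes: int = 100
    n_edges: int = 300
    n_tfs: int = 3                      # TFs of the target gene (network nodes)
    n_assay_proteins: int = 25
    n_expression_genes: int = 300
    n_regulon_tfs: int = 12
    targets_per_tf: tuple[int, int] = (8, 20)
    planted_regulator_hops: int = 1
    n_planted_active_tfs: int = 1
    planted_active_effect: float = 3.0  # in signature-SD units
    active_tf_targets: int = 25
    noise_sd: float = 0.3
    fraction_unknown_effect_signs: float = 0.2
    plant_phospho_effects: bool = True
    graph_model: str = "preferential_attachment"  # or "erdos_renyi"
    target_gene: str = "TGT1"
    treatments: tuple[str, ...] = ("BMP8", "NE", "BMP8_NE")
    control_label: str = "CONTROL"
    focal_treatment: str = "BMP8"
    venn_ratio: float = 2.0
    phospho_fold: float = 1.5

    def __post_init__(self):
        if min(self.n_nodes, self.n_edges, self.n_tfs, self.n_assay_proteins) <= 0:
            raise ValueError("scenario sizes must be positive")
        if self.n_edges < self.n_nodes - 1:
            raise ValueError("need n_edges >= n_nodes - 1")
        if self.n_edges > self.n_nodes * (self.n_nodes - 1) // 2:
            raise ValueError("n_edges infeasible for this node count")
        if self.focal_treatment not in self.treatments:
            raise ValueError("focal treatment must be one of the treatments")

    def node_names(self) -> list[str]:
        return [f"N{i:04d}" for i in range(self.n_nodes)]

    def gene_universe(self) -> list[str]:
        genes = [f"E{i:04d}" for i in range(self.n_expression_genes)]
        return genes + [self.target_gene]


def _rng(scenario: SyntheticScenario, stream: int) -> np.random.Generator:
    return np.random.default_rng([scenario.seed, stream])


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def simulate_signaling_network(scenario: SyntheticScenario) -> tuple[SignalingNetwork, dict]:
    """Directed graph with the planted regulator wired upstream of the TFs.

    The regulator's only out-edges are its planted routes to the target
    gene's TFs (within ``planted_regulator_hops`` hops); the rest of the
    graph is preferential-attachment (or uniform) wiring with exactly the
    requested node and edge counts.
    """
    rng = _rng(scenario, 0)
    nodes = scenario.node_names()
    regulator = str(rng.choice(nodes))
    others = [n for n in nodes if n != regulator]
    tfs = sorted(map(str, rng.choice(others, size=scenario.n_tfs, replace=False)))

    edges: set[tuple[str, str]] = set()
    planted_paths: list[list[str]] = []
    if scenario.planted_regulator_hops == 1:
        for tf in tfs:
            edges.add((regulator, tf))
            planted_paths.append([regulator, tf])
    elif scenario.planted_regulator_hops == 2:
        pool = [n for n in others if n not in tfs]
        mids = rng.choice(pool, size=len(tfs), replace=False)
        for mid, tf in zip(mids, tfs):
            edges.add((regulator, str(mid)))
            edges.add((str(mid), tf))
            planted_paths.append([regulator, str(mid), tf])
    else:
        raise ValueError("planted_regulator_hops must be 1 or 2")
    if len(edges) > scenario.n_edges:
        raise ValueError("n_edges too small to hold the planted routes")

    # background wiring; regulator kept free of extra out-edges
    idx = {n: i for i, n in enumerate(nodes)}
    indeg = np.ones(len(nodes))
    for _, tgt in edges:
        indeg[idx[tgt]] += 1
    sources = [n for n in nodes if n != regulator]
    while len(edges) < scenario.n_edges:
        src = str(rng.choice(sources))
        if scenario.graph_model == "preferential_attachment":
            weights = indeg / indeg.sum()
            tgt = str(rng.choice(nodes, p=weights))
        elif scenario.graph_model == "erdos_renyi":
            tgt = str(rng.choice(nodes))
        else:
            raise ValueError(f"unknown graph model {scenario.graph_model!r}")
        if src == tgt or (src, tgt) in edges:
            continue
        edges.add((src, tgt))
        indeg[idx[tgt]] += 1

    net = SignalingNetwork(sorted(edges), nodes=nodes)
    truth = {
        "planted_regulator": regulator,
        "target_gene": scenario.target_gene,
        "target_gene_tfs": list(tfs),
        "planted_paths": planted_paths,
    }
    return net, truth


# ---------------------------------------------------------------------------
# phospho assay
# ---------------------------------------------------------------------------

def _sample_sites(rng: np.random.Generator, n: int) -> list[str]:
    positions = rng.choice(np.arange(1, 999), size=n, replace=False)
    residues = rng.choice(list(_RESIDUES), size=n)
    return sorted(f"{r}{p}" for r, p in zip(residues, positions))


def simulate_phosphoassay(
    scenario: SyntheticScenario, net: SignalingNetwork, truth: dict
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Phospho signals, effect signs and kinase annotations with planted truth.

    Planted responders get sign-adjusted log2 ratios beyond the Venn
    threshold; planted TFs of the target gene get raw increases beyond the
    fold filter; everything else is clipped background noise.
    """
    rng = _rng(scenario, 1)
    regulator = truth["planted_regulator"]
    tfs = truth["target_gene_tfs"]
    pool = [n for n in net.nodes if n != regulator and n not in tfs]
    assay = sorted(
        {regulator, *map(str, rng.choice(pool, size=scenario.n_assay_proteins - 1, replace=False))}
    )
    proteins = sorted({*assay, *tfs})

    # planted phospho TFs: at least one target-gene TF with a raw >1.5x increase
    planted_tfs: list[str] = []
    directions: dict[tuple[str, str], int] = {}
    if scenario.plant_phospho_effects:
        n_planted_tfs = max(1, len(tfs) // 2)
        planted_tfs = sorted(map(str, rng.choice(tfs, size=n_planted_tfs, replace=False)))
        # planted adjusted directions per (assay protein, treatment)
        for protein in assay:
            for treatment in scenario.treatments:
                u = rng.random()
                if u < 0.22:
                    directions[(protein, treatment)] = 1
                elif u < 0.37:
                    directions[(protein, treatment)] = -1
        directions[(regulator, scenario.focal_treatment)] = 1

    sign_choices = np.array([1, -1])
    rows = []  # protein site treatment raw sign adjusted
    for protein in proteins:
        n_sites = int(rng.integers(1, 5))
        sites = _sample_sites(rng, n_sites)
        signs = {}
        for site in sites:
            if rng.random() < scenario.fraction_unknown_effect_signs:
                signs[site] = 0
            else:
                signs[site] = int(rng.choice(sign_choices))
        planted_site = sites[0]
        if scenario.fraction_unknown_effect_signs < 1 and signs[planted_site] == 0:
            signs[planted_site] = int(rng.choice(sign_choices))
        for site in sites:
            for treatment in scenario.treatments:
                raw = float(np.clip(rng.normal(0, scenario.noise_sd), -BACKGROUND_CLIP, BACKGROUND_CLIP))
                if site == planted_site:
                    if protein in assay and (protein, treatment) in directions:
                        adj = directions[(protein, treatment)] * (1.0 + abs(rng.normal(0, 0.35)))
                        raw = adj * signs[site] if signs[site] != 0 else adj
                    elif protein in planted_tfs and treatment == scenario.focal_treatment:
                        raw = float(rng.uniform(0.7, 1.4))  # ratio 1.62 .. 2.64, increase
                rows.append({
                    "protein": protein, "site": site, "treatment": treatment,
                    "raw_log2fc": raw, "sign": signs[site],
                })
    planted = pd.DataFrame(rows)

    # intensities: control per (protein, site), treated = control * ratio
    base = {}
    for protein, site in planted[["protein", "site"]].drop_duplicates().itertuples(index=False):
        base[(protein, site)] = float(np.exp2(rng.normal(10, 1)))
    signal_rows = []
    for protein, site in sorted(base):
        signal_rows.append({
            "protein": protein, "site": site,
            "condition": scenario.control_label, "signal": base[(protein, site)],
        })
    for row in planted.itertuples(index=False):
        signal_rows.append({
            "protein": row.protein, "site": row.site, "condition": row.treatment,
            "signal": base[(row.protein, row.site)] * float(np.exp2(row.raw_log2fc)),
        })
    records = pd.DataFrame(signal_rows).sort_values(
        ["protein", "site", "condition"], ignore_index=True
    )

    # effect annotations (sign + regulated partners)
    effect_rows = []
    for (protein, site), group in planted.groupby(["protein", "site"]):
        partners = []
        if rng.random() < 0.5:
            n_partners = int(rng.integers(1, 4))
            chosen = rng.choice(net.nodes, size=n_partners, replace=False)
            labels = rng.choice(["induce", "disrupt"], size=n_partners)
            partners = sorted(zip(map(str, chosen), map(str, labels)))
        effect_rows.append({
            "protein": protein, "site": site,
            "sign": int(group["sign"].iloc[0]), "partners": tuple(partners),
        })
    effects = pd.DataFrame(effect_rows).sort_values(["protein", "site"], ignore_index=True)

    # kinase annotations
    kinase_rows = []
    sources = ["dbptm", "hprd", "phosphositeplus", "signor"]
    for protein, site in sorted(base):
        if rng.random() < 0.7:
            n_kin = int(rng.integers(1, 4))
            for kinase in sorted(map(str, rng.choice(net.nodes, size=n_kin, replace=False))):
                kinase_rows.append({
                    "protein": protein, "site": site, "kinase": kinase,
                    "source": str(rng.choice(sources)),
                })
    kinases = pd.DataFrame(kinase_rows, columns=["protein", "site", "kinase", "source"])

    # ground truth by literal re-application of the planted rules
    venn_cut = float(np.log2(scenario.venn_ratio))
    fold_cut = float(np.log2(scenario.phospho_fold))
    venn: dict[str, dict[str, set[str]]] = {"up": {}, "down": {}}
    protein_hits: dict[str, dict[str, set[str]]] = {"up": {}, "down": {}}
    for row in planted.itertuples(index=False):
        if row.sign == 0:
            continue
        adjusted = row.raw_log2fc * row.sign
        if adjusted >= venn_cut:
            protein_hits["up"].setdefault(row.protein, set()).add(row.treatment)
        if adjusted <= -venn_cut:
            protein_hits["down"].setdefault(row.protein, set()).add(row.treatment)
    for direction, hits in protein_hits.items():
        for protein, treatments in hits.items():
            combo = "+".join(t for t in sorted(scenario.treatments) if t in treatments)
            venn[direction].setdefault(combo, set()).add(protein)

    focal = planted[planted["treatment"] == scenario.focal_treatment]
    altered = sorted({
        row.protein for row in focal.itertuples(index=False)
        if abs(row.raw_log2fc) > fold_cut
    })
    phospho_increase_tfs = sorted({
        tf for tf in tfs
        if float(focal.loc[focal["protein"] == tf, "raw_log2fc"].max()) > fold_cut
    })

    assay_truth = {
        "assay_proteins": assay,
        "phospho_proteins": proteins,
        "planted_phospho_tfs": planted_tfs,
        "venn": {
            d: {combo: sorted(members) for combo, members in sorted(fields.items())}
            for d, fields in venn.items()
        },
        "altered_proteins": altered,
        "phospho_increase_tfs": phospho_increase_tfs,
    }
    return records, effects, kinases, assay_truth


# ---------------------------------------------------------------------------
# regulons and expression signature
# ---------------------------------------------------------------------------

def simulate_regulons(
    scenario: SyntheticScenario, net: SignalingNetwork, truth: dict
) -> tuple[pd.DataFrame, dict]:
    """TF -> target table with modes, graded confidence and planted structure.

    Every target-gene TF regulates the target gene at high confidence; one
    decoy TF regulates it at grade E only (removed by the <=D filter); a few
    duplicated rows exercise best-grade merging.
    """
    rng = _rng(scenario, 2)
    tfs = list(truth["target_gene_tfs"])
    pool = [n for n in net.nodes if n not in tfs and n != truth["planted_regulator"]]
    extra = sorted(map(str, rng.choice(pool, size=scenario.n_regulon_tfs - len(tfs), replace=False)))
    all_tfs = sorted({*tfs, *extra})
    active_tfs = sorted(map(str, rng.choice(all_tfs, size=scenario.n_planted_active_tfs, replace=False)))
    genes = [g for g in scenario.gene_universe() if g != scenario.target_gene]

    rows = []
    for tf in all_tfs:
        if tf in active_tfs:
            n_targets = scenario.active_tf_targets
        else:
            n_targets = int(rng.integers(*scenario.targets_per_tf))
        targets = sorted(map(str, rng.choice(genes, size=n_targets, replace=False)))
        for target in targets:
            rows.append({
                "tf": tf, "target": target,
                "mode": int(rng.choice([1, -1], p=[0.7, 0.3])),
                "confidence": str(rng.choice(list("ABCDE"), p=[0.15, 0.25, 0.25, 0.2, 0.15])),
            })
    for tf in tfs:
        rows.append({"tf": tf, "target": scenario.target_gene, "mode": 1,
                     "confidence": str(rng.choice(["A", "B"]))})
    decoy_tf = extra[0]
    rows.append({"tf": decoy_tf, "target": scenario.target_gene, "mode": 1, "confidence": "E"})
    # duplicated rows with a worse grade, to be merged away
    for row in [rows[0], rows[5]]:
        rows.append({**row, "confidence": "E"})
    table = pd.DataFrame(rows).sort_values(["tf", "target", "confidence"], ignore_index=True)

    # expected <=D regulon by literal predicate: best grade per pair, then filter
    best = {}
    for row in table.itertuples(index=False):
        key = (row.tf, row.target)
        if key not in best or row.confidence < best[key][0]:
            best[key] = (row.confidence, row.mode)
    expected = sorted(
        [tf, target, grade, mode]
        for (tf, target), (grade, mode) in best.items()
        if grade <= "D"
    )
    regulon_truth = {
        "regulon_tfs": all_tfs,
        "planted_active_tfs": active_tfs,
        "decoy_tf": decoy_tf,
        "expected_filtered_regulon": expected,
        "target_gene_tfs_after_filter": sorted(
            {tf for tf, target, grade, _ in expected if target == scenario.target_gene}
        ),
    }
    return table, regulon_truth


def simulate_expression_signature(
    scenario: SyntheticScenario, regulons: pd.DataFrame, regulon_truth: dict
) -> tuple[pd.Series, dict]:
    """Standard-normal background with planted active-TF target shifts."""
    rng = _rng(scenario, 3)
    genes = scenario.gene_universe()
    values = pd.Series(rng.normal(0, 1, size=len(genes)), index=genes, name="log2fc")
    for tf in regulon_truth["planted_active_tfs"]:
        sub = regulons[regulons["tf"] == tf]
        for target, mode in zip(sub["target"], sub["mode"]):
            values.loc[target] += scenario.planted_active_effect * mode
    sig_truth = {"planted_active_tfs": regulon_truth["planted_active_tfs"],
                 "effect_size": scenario.planted_active_effect}
    return values, sig_truth


def simulate_categories(
    scenario: SyntheticScenario, net: SignalingNetwork
) -> dict[str, tuple[str, set[str]]]:
    """Five functional category gene sets drawn from the node universe."""
    rng = _rng(scenario, 4)
    labels = {
        "A": "angiogenesis", "I": "inflammation",
        "L": "lipid metabolism and thermogenic activity",
        "N": "neurogenesis", "C": "cell cycle and survival",
    }
    return {
        code: (label, {str(g) for g in rng.choice(net.nodes, size=15, replace=False)})
        for code, label in labels.items()
    }


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def simulate_all(scenario: SyntheticScenario, outdir: str | Path) -> dict:
    """Write every pipeline input plus ``truth.json``; returns the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, net_truth = simulate_signaling_network(scenario)
    records, effects, kinases, assay_truth = simulate_phosphoassay(scenario, net, net_truth)
    regulons, regulon_truth = simulate_regulons(scenario, net, net_truth)
    signature, sig_truth = simulate_expression_signature(scenario, regulons, regulon_truth)
    categories = simulate_categories(scenario, net)

    write_sif(
        [(s, t, "activates") for s, t in sorted(net.graph.edges)],
        outdir / "network.sif",
    )
    write_table(records, outdir / "phospho_signals.tsv")
    write_effects(effects, outdir / "effects.tsv")
    write_table(kinases, outdir / "kinases.tsv")
    write_table(regulons, outdir / "regulons.tsv")
    write_signature(signature, outdir / "signature.tsv")
    write_gmt(categories, outdir / "categories.gmt")

    truth = {"scenario": asdict(scenario), **net_truth, **assay_truth,
             **regulon_truth, **sig_truth}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
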