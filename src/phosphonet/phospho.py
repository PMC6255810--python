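"""Phospho-antibody array processing.

Turns per-condition array intensities into per-site log2 fold changes,
applies curated regulatory effect signs (sites with unknown sign are
excluded from sign-adjusted outputs), picks one representative site per
protein and builds the up/down treatment response sets used for the Venn
summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FC_COLUMNS = ["protein", "site", "treatment", "log2fc"]


class ConfigurationError(ValueError):
    """Bad user-supplied parameter (unknown label, nonsensical threshold)."""


@dataclass
class VennSets:
    """Up/down response sets partitioned by exact treatment combination.

    ``membership[direction][combo]`` is the set of proteins responding in
    exactly the treatments in ``combo`` (a sorted tuple), for
    ``direction in {"up", "down"}``.
    """

    threshold: float
    treatments: tuple[str, ...]
    membership: dict[str, dict[tuple[str, ...], set[str]]] = field(default_factory=dict)

    def universe(self, direction: str) -> set[str]:
        return set().union(*self.membership[direction].values()) if self.membership[direction] else set()

    def counts(self) -> dict[str, dict[str, int]]:
        return {
            direction: {"+".join(combo): len(members) for combo, members in fields.items()}
            for direction, fields in self.membership.items()
        }

    def to_jsonable(self) -> dict:
        return {
            "threshold": self.threshold,
            "treatments": list(self.treatments),
            "membership": {
                direction: {"+".join(combo): sorted(members) for combo, members in fields.items()}
                for direction, fields in self.membership.items()
            },
            "counts": self.counts(),
            "totals": {d: len(self.universe(d)) for d in self.membership},
        }


def _nonempty_combinations(treatments: tuple[str, ...]):
    return chain.from_iterable(
        combinations(treatments, k) for k in range(1, len(treatments) + 1)
    )


def compute_site_fold_changes(
    records: pd.DataFrame,
    control_label: str,
    treatment_labels: list[str],
) -> pd.DataFrame:
    """Compute per-site log2 fold changes against the control condition.

    ``records`` has columns ``protein, site, condition, signal``; replicate
    rows for the same (protein, site, condition) are averaged before
    ratioing.  Sites whose control intensity is zero are dropped (a log2
    ratio is undefined there) and counted in the log.
    """
    if records.empty:
        log.warning("compute_site_fold_changes: empty input table")
        return pd.DataFrame(columns=FC_COLUMNS)
    known = set(records["condition"])
    for label in [control_label, *treatment_labels]:
        if label not in known:
            raise ConfigurationError(f"condition label {label!r} absent from input (has {sorted(known)})")

    mean = (
        records.groupby(["protein", "site", "condition"], as_index=False)["signal"]
        .mean()
    )
    wide = mean.pivot(index=["protein", "site"], columns="condition", values="signal")
    ctrl = wide[control_label]
    zero_ctrl = ~(ctrl > 0)
    if zero_ctrl.any():
        log.info("dropping %d site(s) with zero control signal", int(zero_ctrl.sum()))
    wide = wide.loc[~zero_ctrl]
    ctrl = ctrl.loc[~zero_ctrl]

    rows = []
    for treatment in treatment_labels:
        lfc = np.log2(wide[treatment] / ctrl)
        part = lfc.rename("log2fc").reset_index()
        part.insert(2, "treatment", treatment)
        rows.append(part.dropna(subset=["log2fc"]))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["protein", "site", "treatment"], ignore_index=True)


def adjust_fold_change_signs(fcs: pd.DataFrame, effects: pd.DataFrame) -> pd.DataFrame:
    """Apply curated effect signs: ``adjusted_log2fc = sign * log2fc``.

    Rows whose site has an unknown sign (sign 0) or no effect record at all
    are excluded; the count of exclusions is stored in
    ``result.attrs["n_excluded"]`` and logged.
    """
    if "log2fc" not in fcs.columns:
        raise ValueError("fold-change table lacks a log2fc column")
    merged = fcs.merge(
        effects[["protein", "site", "sign"]], on=["protein", "site"], how="left"
    )
    merged["sign"] = merged["sign"].fillna(0).astype(int)
    keep = merged["sign"] != 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.info("excluding %d row(s) without a known effect sign", n_excluded)
    out = merged.loc[keep].copy()
    out["adjusted_log2fc"] = out["sign"] * out["log2fc"]
    out = out.drop(columns="sign").reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    return out


def representative_site_per_protein(fcs: pd.DataFrame, value_col: str = "log2fc") -> pd.DataFrame:
    """Keep, per (protein, treatment), the site with the largest ``|value_col|``.

    Ranking uses the log2 scale so a 2x and a 0.5x change are equally
    extreme; ties break lexicographically by (protein, site).
    """
    if fcs.empty:
        raise ValueError("representative_site_per_protein: empty table")
    ranked = fcs.assign(_abs=fcs[value_col].abs()).sort_values(
        ["protein", "treatment", "_abs", "site"],
        ascending=[True, True, False, True],
    )
    out = ranked.drop_duplicates(["protein", "treatment"], keep="first")
    return out.drop(columns="_abs").sort_values(["protein", "treatment"], ignore_index=True)


def treatment_response_sets(
    fcs: pd.DataFrame,
    ratio_threshold: float = 2.0,
    treatments: tuple[str, ...] | None = None,
) -> VennSets:
    """Build the up/down Venn partition from sign-adjusted fold changes.

    A protein is "up" under a treatment when ANY of its sites has
    ``adjusted_log2fc >= log2(ratio_threshold)`` and "down" when any site has
    ``adjusted_log2fc <= -log2(ratio_threshold)``.  When sites of one
    protein pass in both directions under the same treatment, the direction
    of the dominant site (largest ``|adjusted_log2fc|``, ties broken by site
    name) wins, keeping up and down disjoint per treatment.  Membership is
    reported per exact treatment combination.
    """
    if ratio_threshold <= 1:
        raise ConfigurationError(f"ratio threshold must exceed 1, got {ratio_threshold}")
    if "adjusted_log2fc" not in fcs.columns:
        raise ValueError("treatment_response_sets requires sign-adjusted fold changes")
    if treatments is None:
        treatments = tuple(sorted(fcs["treatment"].unique()))
    cut = np.log2(ratio_threshold)

    hits: dict[str, dict[str, set[str]]] = {"up": {}, "down": {}}  # protein -> treatments
    for (protein, treatment), group in fcs.groupby(["protein", "treatment"]):
        passing = group[group["adjusted_log2fc"].abs() >= cut]
        if passing.empty:
            continue
        dominant = passing.assign(_abs=passing["adjusted_log2fc"].abs()).sort_values(
            ["_abs", "site"], ascending=[False, True]
        ).iloc[0]
        direction = "up" if dominant["adjusted_log2fc"] > 0 else "down"
        hits[direction].setdefault(protein, set()).add(treatment)

    venn = VennSets(threshold=ratio_threshold, treatments=treatments)
    for direction in ("up", "down"):
        fields: dict[tuple[str, ...], set[str]] = {
            tuple(combo): set() for combo in _nonempty_combinations(treatments)
        }
        for protein, members in hits[direction].items():
            combo = tuple(t for t in treatments if t in members)
            if combo:
                fields[combo].add(protein)
        venn.membership[direction] = fields
    return venn


def summarize_venn(venn: VennSets) -> pd.DataFrame:
    """Tidy per-field counts plus per-direction totals."""
    rows = []
    for direction, fields in venn.membership.items():
        for combo, members in sorted(fields.items()):
            rows.append({"direction": direction, "field": "+".join(combo), "count": len(members)})
        rows.append({"direction": direction, "field": "TOTAL", "count": len(venn.universe(direction))})
    return pd.DataFrame(rows, columns=["direction", "field", "count"])
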