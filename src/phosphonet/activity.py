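"""Regulon-based transcription factor activity estimation.

The expression signature is rank-transformed to normal scores
``q_g = Phi^-1(rank_g / (G + 1))``; a TF's normalized enrichment score is
``sum(mode_g * q_g) / sqrt(n_targets)`` over its regulon targets present in
the signature, with a two-sided normal p-value.  This is a deliberately
simplified analytic rank enrichment: no pleiotropy or shadow corrections
and no target-weight likelihoods.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, gmean

from .io import ParseError

log = logging.getLogger(__name__)

CONFIDENCE_ORDER = "ABCDE"  # A best


def normalize_expression(raw: pd.DataFrame, housekeepers: list[str]) -> pd.DataFrame:
    """Divide each sample (column) by the geometric mean of its housekeepers.

    ``raw`` is a genes x samples table of positive expression values.
    """
    missing = [h for h in housekeepers if h not in raw.index]
    if missing:
        raise ValueError(f"housekeeping gene(s) absent from the table: {missing}")
    hk = raw.loc[housekeepers]
    if (hk <= 0).any().any():
        raise ValueError("housekeeping genes must have positive values in every sample")
    divisor = gmean(hk, axis=0)
    return raw / divisor


def build_regulons(tf_target_table: pd.DataFrame, max_confidence: str = "D") -> pd.DataFrame:
    """Filter a ``tf target mode confidence`` table to grades up to a cutoff.

    Rows graded worse than ``max_confidence`` (A best, E worst) are removed;
    duplicate (tf, target) rows are merged keeping the best grade.  The
    result is idempotent under re-application.
    """
    if max_confidence not in CONFIDENCE_ORDER:
        raise ParseError(f"unknown confidence grade {max_confidence!r}")
    bad = set(tf_target_table["confidence"]) - set(CONFIDENCE_ORDER)
    if bad:
        raise ParseError(f"unknown confidence grade(s): {sorted(bad)}")
    df = tf_target_table.copy()
    df["_rank"] = df["confidence"].map(CONFIDENCE_ORDER.index)
    df = df[df["_rank"] <= CONFIDENCE_ORDER.index(max_confidence)]
    df = (
        df.sort_values(["tf", "target", "_rank", "mode"])
        .drop_duplicates(["tf", "target"], keep="first")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return df


def rank_scores(signature: pd.Series) -> pd.Series:
    """Normal scores of the signature ranks, symmetric about zero."""
    ranks = rankdata(signature.to_numpy(), method="average")
    q = norm.ppf(ranks / (len(signature) + 1))
    return pd.Series(q, index=signature.index, name="q")


def estimate_tf_activities(
    signature: pd.Series, regulons: pd.DataFrame, min_targets: int = 3
) -> pd.DataFrame:
    """Score every regulon against an expression signature.

    Returns a tf / nes / p / n_targets table sorted by TF.  Regulons with
    fewer than ``min_targets`` targets present in the signature are skipped
    with a logged warning.
    """
    if signature.empty:
        raise ValueError("empty expression signature")
    q = rank_scores(signature)
    rows = []
    skipped = 0
    for tf, group in regulons.groupby("tf"):
        present = group[group["target"].isin(q.index)]
        n = len(present)
        if n < min_targets:
            skipped += 1
            continue
        contrib = present["mode"].to_numpy() * q.loc[present["target"]].to_numpy()
        nes = contrib.sum() / np.sqrt(n)
        rows.append({"tf": tf, "nes": nes, "p": 2 * norm.sf(abs(nes)), "n_targets": n})
    if skipped:
        log.warning("skipped %d regulon(s) with fewer than %d scored targets", skipped, min_targets)
    return pd.DataFrame(rows, columns=["tf", "nes", "p", "n_targets"]).sort_values(
        "tf", ignore_index=True
    )


def select_gene_tfs(
    gene: str, activities: pd.DataFrame, regulons: pd.DataFrame, p_cut: float = 0.2
) -> pd.DataFrame:
    """TFs regulating ``gene`` with p below the display cutoff, ascending p.

    The cutoff is applied without multiple-testing correction.
    """
    tfs = set(regulons.loc[regulons["target"] == gene, "tf"])
    if not tfs:
        log.warning("gene %s is absent from every regulon", gene)
    sub = activities[activities["tf"].isin(tfs) & (activities["p"] < p_cut)]
    return sub.sort_values(["p", "tf"], ignore_index=True)


def tfs_with_phospho_increase(
    gene: str,
    regulons: pd.DataFrame,
    fcs: pd.DataFrame,
    fold_threshold: float = 1.5,
    treatment: str | None = None,
) -> set[str]:
    """TFs regulating ``gene`` whose best phosphosite fold change exceeds
    ``fold_threshold`` (ratio scale) under ``treatment``.

    ``fcs`` carries per-site ``log2fc``; the best site is the one with the
    largest log2 fold change.
    """
    tfs = set(regulons.loc[regulons["target"] == gene, "tf"])
    sub = fcs if treatment is None else fcs[fcs["treatment"] == treatment]
    best = sub.groupby("protein")["log2fc"].max()
    passing = set(best.index[np.exp2(best) > fold_threshold])
    return tfs & passing
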