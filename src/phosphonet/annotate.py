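"""Layered functional annotation of phosphosites.

Each measured phosphosite is scored against five functional categories on
three relation layers: the substrate itself ("self", binary), its upstream
kinases and the interaction partners regulated by the phosphorylation
event (both as the proportion of the relation set annotated with the
category).  Rows are ordered by complete-linkage hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

LAYERS = ("self", "kinases", "regulated")


@dataclass(frozen=True)
class FunctionalCategory:
    code: str
    label: str
    gene_set: frozenset[str]

    def __post_init__(self):
        if not self.gene_set:
            raise ValueError(f"category {self.code}: empty gene set")


def categories_from_gmt(sets: dict[str, tuple[str, set[str]]]) -> list[FunctionalCategory]:
    cats = [
        FunctionalCategory(code=name, label=desc, gene_set=frozenset(genes))
        for name, (desc, genes) in sets.items()
    ]
    codes = [c.code for c in cats]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate category codes in GMT")
    return sorted(cats, key=lambda c: c.code)


def lookup_kinases(protein: str, site: str, kinase_table: pd.DataFrame) -> set[str]:
    """Union of annotated upstream kinases over all sources for one site."""
    mask = (kinase_table["protein"] == protein) & (kinase_table["site"] == site)
    return set(kinase_table.loc[mask, "kinase"])


def lookup_regulated_partners(protein: str, site: str, effects: pd.DataFrame) -> set[tuple[str, str]]:
    """Partners whose interaction the phosphorylation induces or disrupts."""
    mask = (effects["protein"] == protein) & (effects["site"] == site)
    hits = effects.loc[mask, "partners"]
    out: set[tuple[str, str]] = set()
    for cell in hits:
        out.update(cell)
    return out


def annotate_functional_layers(
    rows: list[tuple[str, str]],
    categories: list[FunctionalCategory],
    kinase_table: pd.DataFrame,
    effects: pd.DataFrame,
) -> pd.DataFrame:
    """Annotation matrix for (protein, site) rows.

    Columns are a (category code, layer) MultiIndex.  "self" is 1 when the
    substrate is in the category set, else 0; "kinases"/"regulated" hold the
    proportion of the site's kinase / regulated-partner set annotated with
    the category (0 when that set is empty).
    """
    if not categories:
        raise ValueError("no functional categories supplied")
    index = pd.MultiIndex.from_tuples(rows, names=["protein", "site"])
    columns = pd.MultiIndex.from_product(
        [[c.code for c in categories], LAYERS], names=["category", "layer"]
    )
    matrix = pd.DataFrame(0.0, index=index, columns=columns)
    for protein, site in rows:
        kinases = lookup_kinases(protein, site, kinase_table)
        partners = {p for p, _ in lookup_regulated_partners(protein, site, effects)}
        for cat in categories:
            matrix.loc[(protein, site), (cat.code, "self")] = float(protein in cat.gene_set)
            if kinases:
                matrix.loc[(protein, site), (cat.code, "kinases")] = (
                    len(kinases & cat.gene_set) / len(kinases)
                )
            if partners:
                matrix.loc[(protein, site), (cat.code, "regulated")] = (
                    len(partners & cat.gene_set) / len(partners)
                )
    return matrix


def top_sites(fcs: pd.DataFrame, n: int = 50, value_col: str = "adjusted_log2fc") -> list[tuple[str, str]]:
    """Top-n (protein, site) rows by max ``|value_col|`` across treatments."""
    scored = (
        fcs.assign(_abs=fcs[value_col].abs())
        .groupby(["protein", "site"])["_abs"]
        .max()
        .reset_index()
        .sort_values(["_abs", "protein", "site"], ascending=[False, True, True])
    )
    return [(p, s) for p, s in zip(scored["protein"].head(n), scored["site"].head(n))]


def cluster_rows(matrix: pd.DataFrame) -> tuple[list, np.ndarray]:
    """Complete-linkage / Euclidean hierarchy over matrix rows.

    Returns the deterministic leaf order (tighter cluster first, then
    lexicographic by the smallest leaf label) and the scipy linkage matrix.
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least two rows")
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2:
        raise ValueError("rows must have equal length")
    Z = linkage(pdist(values, metric="euclidean"), method="complete")
    order = _leaf_order(Z, list(matrix.index))
    return [matrix.index[i] for i in order], Z


def _leaf_order(Z: np.ndarray, labels: list) -> list[int]:
    n = Z.shape[0] + 1
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h, _cnt) in enumerate(Z):
        node = n + k
        height[node] = float(h)
        children[node] = (int(a), int(b))

    def min_label(node: int) -> str:
        if node < n:
            return str(labels[node])
        a, b = children[node]
        return min(min_label(a), min_label(b))

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        key_a = (height[a], min_label(a))
        key_b = (height[b], min_label(b))
        first, second = (a, b) if key_a <= key_b else (b, a)
        return walk(first) + walk(second)

    return walk(n + Z.shape[0] - 1)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    n = Z.shape[0] + 1
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h, _cnt) in enumerate(Z):
        height[n + k] = float(h)
        children[n + k] = (int(a), int(b))

    def render(node: int, parent_height: float) -> str:
        length = parent_height - height[node]
        if node < n:
            return f"{labels[node]}:{length:.10g}"
        a, b = children[node]
        return f"({render(a, height[node])},{render(b, height[node])}):{length:.10g}"

    root = n + Z.shape[0] - 1
    return render(root, height[root]) + ";"
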