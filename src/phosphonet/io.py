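"""Readers and writers for the plain-text formats the pipeline consumes.

All tabular formats are TSV with a header line; gene sets are GMT; networks
are SIF (``source  relation  target``) or two-column TSV.  Gene symbols are
uppercased at ingest so every downstream join happens in one namespace.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SITE_PATTERN = re.compile(r"^[A-Z]\d+$")

_SIGN_ALIASES = {
    "+1": 1, "1": 1, "+": 1, "activating": 1,
    "-1": -1, "-": -1, "inhibitory": -1,
    "0": 0, "unknown": 0, "na": 0, "nan": 0, "": 0,
}


class ParseError(ValueError):
    """Malformed input row; carries the offending line number."""


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def _norm_symbols(series: pd.Series) -> pd.Series:
    return series.astype(str).str.strip().str.upper()


def validate_sites(sites: Iterable[str], where: str = "input") -> None:
    bad = [s for s in sites if not SITE_PATTERN.match(str(s))]
    if bad:
        raise ParseError(f"{where}: malformed phosphosite id(s): {bad[:5]}")


# ---------------------------------------------------------------------------
# phospho tables
# ---------------------------------------------------------------------------

def read_phospho_signals(path: str | Path) -> pd.DataFrame:
    """Read a ``protein  site  condition  signal`` table."""
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "site": str, "condition": str})
    required = {"protein", "site", "condition", "signal"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    df["protein"] = _norm_symbols(df["protein"])
    df["site"] = df["site"].str.strip().str.upper()
    validate_sites(df["site"], str(path))
    if (df["signal"] < 0).any():
        raise ParseError(f"{path}: negative intensities present")
    return df


def read_fold_changes(path: str | Path) -> pd.DataFrame:
    """Read a precomputed ``protein  site  treatment  fold_change`` table."""
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "site": str, "treatment": str})
    required = {"protein", "site", "treatment", "fold_change"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    df["protein"] = _norm_symbols(df["protein"])
    df["site"] = df["site"].str.strip().str.upper()
    validate_sites(df["site"], str(path))
    if (df["fold_change"] <= 0).any():
        raise ParseError(f"{path}: fold changes must be positive ratios")
    return df


def read_effects(path: str | Path) -> pd.DataFrame:
    """Read ``protein  site  sign  partners``.

    ``sign`` is +1 / -1 / unknown (stored as 0); ``partners`` is a
    semicolon-separated list of ``PARTNER:induce|disrupt`` items, possibly
    empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein", "site", "sign"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    df["protein"] = _norm_symbols(df["protein"])
    df["site"] = df["site"].str.strip().str.upper()
    validate_sites(df["site"], str(path))
    signs = []
    for i, raw in enumerate(df["sign"], start=2):
        key = str(raw).strip().lower()
        if key not in _SIGN_ALIASES:
            raise ParseError(f"{path}:{i}: unrecognized effect sign {raw!r}")
        signs.append(_SIGN_ALIASES[key])
    df["sign"] = signs
    partners = []
    raw_partners = df["partners"] if "partners" in df.columns else [""] * len(df)
    for i, cell in enumerate(raw_partners, start=2):
        cell = str(cell).strip()
        items = []
        if cell:
            for token in cell.split(";"):
                token = token.strip()
                if not token:
                    continue
                if ":" not in token:
                    raise ParseError(f"{path}:{i}: partner {token!r} lacks an induce/disrupt label")
                partner, label = token.rsplit(":", 1)
                label = label.strip().lower()
                if label not in {"induce", "disrupt"}:
                    raise ParseError(f"{path}:{i}: partner label {label!r} not in {{induce, disrupt}}")
                items.append((normalize_symbol(partner), label))
        partners.append(tuple(items))
    df["partners"] = partners
    if df.duplicated(["protein", "site"]).any():
        raise ParseError(f"{path}: duplicate (protein, site) effect records")
    return df


def write_effects(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["partners"] = [
        ";".join(f"{p}:{lab}" for p, lab in cell) for cell in out["partners"]
    ]
    out.to_csv(path, sep="\t", index=False)


def read_kinase_table(path: str | Path) -> pd.DataFrame:
    """Read ``protein  site  kinase  source`` rows (one kinase per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein", "site", "kinase", "source"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    df["protein"] = _norm_symbols(df["protein"])
    df["site"] = df["site"].str.strip().str.upper()
    df["kinase"] = _norm_symbols(df["kinase"])
    validate_sites(df["site"], str(path))
    return df


# ---------------------------------------------------------------------------
# networks, regulons, signatures, gene sets
# ---------------------------------------------------------------------------

def read_sif(path: str | Path) -> list[tuple[str, str, str | None]]:
    """Read a SIF / 2-3 column TSV edge list.

    Returns ``(source, target, relation)`` tuples; the relation is ``None``
    for 2-column rows.
    """
    edges: list[tuple[str, str, str | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                src, tgt = fields
                rel = None
            elif len(fields) == 3:
                src, rel, tgt = fields
            else:
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {len(fields)}")
            src, tgt = normalize_symbol(src), normalize_symbol(tgt)
            if not src or not tgt:
                raise ParseError(f"{path}:{lineno}: empty node symbol")
            edges.append((src, tgt, rel))
    return edges


def write_sif(edges: Iterable[tuple[str, str, str | None]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for src, tgt, rel in edges:
            fh.write(f"{src}\t{rel if rel is not None else 'interacts'}\t{tgt}\n")


def read_regulon_table(path: str | Path) -> pd.DataFrame:
    """Read ``tf  target  mode  confidence`` rows."""
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str, "confidence": str})
    required = {"tf", "target", "mode", "confidence"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    df["tf"] = _norm_symbols(df["tf"])
    df["target"] = _norm_symbols(df["target"])
    df["confidence"] = df["confidence"].str.strip().str.upper()
    df["mode"] = df["mode"].astype(int)
    if not df["mode"].isin([1, -1]).all():
        raise ParseError(f"{path}: regulation mode must be +1 or -1")
    return df


def read_signature(path: str | Path) -> pd.Series:
    """Read a ``gene  log2fc`` expression signature."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if not {"gene", "log2fc"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns ['gene', 'log2fc'], got {list(df.columns)}")
    genes = _norm_symbols(df["gene"])
    if genes.duplicated().any():
        raise ParseError(f"{path}: duplicate gene symbols in signature")
    values = df["log2fc"].to_numpy(float)
    if not np.isfinite(values).all():
        raise ParseError(f"{path}: signature values must be finite")
    return pd.Series(values, index=genes, name="log2fc")


def write_signature(sig: pd.Series, path: str | Path) -> None:
    sig.rename_axis("gene").rename("log2fc").to_frame().to_csv(path, sep="\t", float_format="%.10g")


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file; returns ``{set_name: (description, genes)}``."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT rows need name, description and >=1 gene")
            name, desc, *genes = fields
            sets[name.strip()] = (desc, {normalize_symbol(g) for g in genes if g.strip()})
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_symbol_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [normalize_symbol(line) for line in fh if line.strip()]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Deterministic TSV writer used for every numeric output."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
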