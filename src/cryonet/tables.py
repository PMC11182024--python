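"""I/O and preprocessing for ASV count tables, sample metadata, soil properties and trait maps.

The in-memory containers are plain pandas objects:

* **ASV table** — a samples x taxa ``DataFrame`` of non-negative integer counts.
  On disk the orientation is the field's usual taxa-rows layout (first column
  ``taxon_id``, one column per sample, tab-separated); BIOM v1 JSON is accepted
  read-only.
* **Sample metadata / soil properties** — tab-separated tables keyed by a
  ``sample_id`` column, loaded with ``sample_id`` as the index.
* **Trait map** — two-column tab-separated ``taxon_id``/``trait`` table; a taxon
  may appear on several rows (one per trait).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "read_asv_table",
    "write_asv_table",
    "read_sample_table",
    "write_sample_table",
    "read_trait_map",
    "write_trait_map",
    "validate_asv_table",
    "rarefy",
    "prevalence_filter",
    "relative_abundance",
    "annotate_traits",
]


class FormatError(ValueError):
    """An input file violates the table contract (duplicates, negative counts...)."""


def validate_asv_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the samples x taxa invariants and coerce counts to int64."""
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dupes}")
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate taxon ids: {dupes}")
    values = table.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.integer):
        numeric = values.astype(float)
        if not np.all(np.isfinite(numeric)):
            raise FormatError("counts must be finite")
        if np.any(numeric != np.round(numeric)):
            raise FormatError("counts must be integers")
        values = numeric
    if values.size and np.any(np.asarray(values, dtype=float) < 0):
        raise FormatError("counts must be non-negative")
    out = table.astype(np.int64)
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    return out


def _read_biom_json(path: Path) -> pd.DataFrame:
    """Minimal reader for BIOM v1 JSON (dense or sparse), observations = taxa."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [row["id"] for row in doc["rows"]]
    samples = [col["id"] for col in doc["columns"]]
    n_taxa, n_samples = doc["shape"]
    matrix = np.zeros((n_taxa, n_samples), dtype=np.int64)
    if doc.get("matrix_type", "sparse") == "dense":
        matrix = np.asarray(doc["data"])
    else:
        for i, j, value in doc["data"]:
            matrix[int(i), int(j)] = value
    table = pd.DataFrame(matrix.T, index=samples, columns=taxa)
    return validate_asv_table(table)


def read_asv_table(path) -> pd.DataFrame:
    """Read a taxa x samples TSV (or BIOM v1 ``.json``/``.biom``) into samples x taxa."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".json", ".biom"}:
        return _read_biom_json(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({s for s in header if header.count(s) > 1})
        raise FormatError(f"duplicate sample ids: {dupes}")
    raw = pd.read_csv(path, sep="\t", index_col=0, header=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    table = raw.T
    table.index.name = None
    table.columns.name = None
    return validate_asv_table(table)


def write_asv_table(table: pd.DataFrame, path) -> None:
    """Write samples x taxa counts as a taxa-rows TSV (round-trips with :func:`read_asv_table`)."""
    table = validate_asv_table(table)
    out = table.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_sample_table(path) -> pd.DataFrame:
    """Read a tab-separated per-sample table (metadata or soil properties) keyed by sample_id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id values")
    df["sample_id"] = df["sample_id"].astype(str)
    return df.set_index("sample_id")


def write_sample_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_trait_map(path) -> pd.DataFrame:
    """Read a two-column taxon_id / trait TSV; returns one row per (taxon, trait)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["taxon_id", "trait"]
    if list(df.columns[:2]) != expected:
        raise FormatError(f"trait map must have columns {expected}")
    if (df["trait"].fillna("") == "").any():
        raise FormatError("trait labels must be non-empty")
    return df[expected]


def write_trait_map(traits: pd.DataFrame, path) -> None:
    traits[["taxon_id", "trait"]].to_csv(path, sep="\t", index=False)


def rarefy(table: pd.DataFrame, depth: int, seed=None) -> pd.DataFrame:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a warning, matching
    standard rarefaction semantics. Depths used in the emulated study are
    32,582 reads (prokaryotes) and 11,975 reads (fungi).
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    table = validate_asv_table(table)
    rng = np.random.default_rng(seed)
    totals = table.sum(axis=1)
    keep = totals >= depth
    if not keep.all():
        dropped = table.index[~keep].tolist()
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below rarefaction depth {depth}: {dropped}",
            stacklevel=2,
        )
    rows = []
    for sample_id in table.index[keep]:
        counts = table.loc[sample_id].to_numpy(dtype=np.int64)
        rows.append(rng.multivariate_hypergeometric(counts, depth))
    return pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(keep.sum(), table.shape[1]),
        index=table.index[keep],
        columns=table.columns,
    )


def prevalence_filter(table: pd.DataFrame, min_prevalence: float = 0.5) -> pd.DataFrame:
    """Retain taxa present (count > 0) in strictly more than ``min_prevalence`` of samples.

    The default reproduces the ">50% relative frequency" retention rule used
    for co-occurrence network construction; prevalence (occurrence frequency
    across samples) is the interpretation adopted, with a strict inequality,
    so a taxon seen in exactly half the samples is removed.
    """
    if table.shape[0] == 0:
        raise ValueError("table has no samples")
    prevalence = (table > 0).mean(axis=0)
    return table.loc[:, prevalence > min_prevalence]


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; every row sums to 1. Zero-total samples are an error."""
    totals = table.sum(axis=1)
    if (totals == 0).any():
        bad = table.index[totals == 0].tolist()
        raise ValueError(f"zero-total sample(s): {bad}")
    return table.div(totals, axis=0)


def annotate_traits(table: pd.DataFrame, traits: pd.DataFrame):
    """Aggregate relative abundance by trait label (guild / predicted function).

    Returns ``(trait_table, assigned_fraction)`` where ``trait_table`` is a
    samples x traits DataFrame of summed relative abundances of the taxa
    carrying each trait, and ``assigned_fraction`` is the fraction of the
    table's taxa that carry at least one trait. Trait-map rows referencing
    taxa absent from the table are ignored with a warning.
    """
    rel = relative_abundance(table)
    known = traits["taxon_id"].isin(table.columns)
    if (~known).any():
        unknown = sorted(traits.loc[~known, "taxon_id"].unique())
        warnings.warn(f"trait map references unknown taxa (ignored): {unknown}", stacklevel=2)
    usable = traits.loc[known]
    labels = sorted(usable["trait"].unique())
    out = pd.DataFrame(0.0, index=table.index, columns=labels)
    for label in labels:
        members = usable.loc[usable["trait"] == label, "taxon_id"].unique()
        out[label] = rel[members].sum(axis=1)
    assigned = usable["taxon_id"].nunique()
    fraction = assigned / table.shape[1] if table.shape[1] else 0.0
    return out, fraction
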