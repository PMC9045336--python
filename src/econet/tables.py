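"""Count-table handling: IO, rarefaction, normalization, filtering and diversity.

The central objects are :class:`CountTable` (integer OTU x sample matrix with
per-sample metadata) and :class:`AbundanceTable` (per-sample relative
abundances).  All downstream analyses consume these.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "AbundanceTable",
    "CountTableParseError",
    "read_count_table",
    "write_count_table",
    "read_biom_v1",
    "read_metadata",
    "read_taxonomy",
    "rarefy",
    "to_relative",
    "prevalence_filter",
    "log_transform",
    "classify_abundance",
    "alpha_diversity",
    "DEFAULT_RAREFACTION_DEPTH",
    "ABUNDANT_MEAN_THRESHOLD",
    "LOCAL_LOW_THRESHOLD",
    "LOCAL_HIGH_THRESHOLD",
]

#: Default per-sample rarefaction depth (reads per sample).
DEFAULT_RAREFACTION_DEPTH = 14_666

#: Mean relative abundance above which a taxon is "abundant" (0.1%).
ABUNDANT_MEAN_THRESHOLD = 1e-3
#: Local relative-abundance floor used by the abundant/rare rules (0.01%).
LOCAL_LOW_THRESHOLD = 1e-4
#: Local relative-abundance ceiling used by the abundant/rare rules (1%).
LOCAL_HIGH_THRESHOLD = 1e-2


class CountTableParseError(ValueError):
    """Raised when a count-table file cannot be parsed."""


def _check_axes(df: pd.DataFrame) -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate OTU ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")


@dataclass
class CountTable:
    """Integer OTU x sample matrix with optional sample metadata and taxonomy.

    Parameters
    ----------
    data
        DataFrame with OTU ids as index and sample ids as columns; values are
        nonnegative integers.
    metadata
        Optional per-sample table indexed by sample id.  Expected columns are
        ``dph`` (integer days post-hatching), ``stage`` and ``tank`` labels,
        but arbitrary extra columns are preserved.
    taxonomy
        Optional per-OTU lineage strings indexed by OTU id.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_axes(self.data)
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.data = self.data.astype(np.int64)
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.metadata is not None:
            missing = set(self.data.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(
                    f"samples missing from metadata: {sorted(missing)}"
                )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "CountTable":
        sample_ids = list(sample_ids)
        meta = self.metadata.loc[sample_ids] if self.metadata is not None else None
        return CountTable(self.data[sample_ids].copy(), meta, self.taxonomy)


@dataclass
class AbundanceTable:
    """Relative-abundance OTU x sample matrix (each sample sums to 1)."""

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_axes(self.data)
        sums = self.data.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = [s for s, t in zip(self.data.columns, sums) if abs(t - 1) > 1e-9]
            raise ValueError(f"sample abundances must sum to 1; offending: {bad}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        sample_ids = list(sample_ids)
        meta = self.metadata.loc[sample_ids] if self.metadata is not None else None
        return AbundanceTable(self.data[sample_ids].copy(), meta, self.taxonomy)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_count_table(
    path,
    orientation: str = "otus_as_rows",
    metadata: pd.DataFrame | None = None,
    taxonomy: pd.Series | None = None,
) -> CountTable:
    """Read a TSV count table.

    The first column holds identifiers (a leading ``#OTU ID`` header cell is
    accepted).  ``orientation`` declares whether rows are OTUs or samples; the
    returned table is always OTU x sample.
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    raw.index = raw.index.astype(str)
    parsed = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise CountTableParseError(
                f"non-numeric value {raw.loc[row, col]!r} at row {row!r}, "
                f"column {col!r} in {path}"
            )
        parsed[col] = converted
    df = pd.DataFrame(parsed, index=raw.index)
    if orientation == "samples_as_rows":
        df = df.T
    return CountTable(df, metadata=metadata, taxonomy=taxonomy)


def write_count_table(table: CountTable, path) -> None:
    """Write a count table as TSV with a leading ``#OTU ID`` header cell."""
    df = table.data.copy()
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t")


def read_biom_v1(path) -> CountTable:
    """Read a BIOM v1 (JSON) table into a :class:`CountTable`."""
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(otu_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = np.asarray(doc["data"])
    taxonomy = None
    if any(r.get("metadata") and "taxonomy" in (r["metadata"] or {}) for r in doc["rows"]):
        taxonomy = pd.Series(
            {
                r["id"]: ";".join(r["metadata"]["taxonomy"])
                if isinstance(r.get("metadata", {}).get("taxonomy"), list)
                else str(r.get("metadata", {}).get("taxonomy"))
                for r in doc["rows"]
                if r.get("metadata")
            }
        )
    return CountTable(pd.DataFrame(mat, index=otu_ids, columns=sample_ids), taxonomy=taxonomy)


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata TSV (first column = sample id)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return meta


def read_taxonomy(path) -> pd.Series:
    """Read per-OTU taxonomy TSV (otu_id, lineage)."""
    tax = pd.read_csv(path, sep="\t", index_col=0)
    return tax.iloc[:, 0].astype(str)


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def rarefy(
    table: CountTable,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int | None = None,
) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning; a
    sample whose total equals ``depth`` is returned unchanged.  Deterministic
    for a given ``seed`` (multivariate hypergeometric draws).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.data.sum(axis=0)
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if not keep:
        raise ValueError(f"all samples have fewer than {depth} reads")
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
    cols = {}
    for s in keep:
        col = table.data[s].to_numpy()
        if totals[s] == depth:
            cols[s] = col
        else:
            cols[s] = rng.multivariate_hypergeometric(col, depth)
    out = pd.DataFrame(cols, index=table.data.index)
    meta = table.metadata.loc[keep] if table.metadata is not None else None
    return CountTable(out, metadata=meta, taxonomy=table.taxonomy)


def to_relative(table: CountTable) -> AbundanceTable:
    """Convert counts to per-sample relative abundances."""
    totals = table.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    rel = table.data / totals
    return AbundanceTable(rel, metadata=table.metadata, taxonomy=table.taxonomy)


def prevalence_filter(table, min_fraction: float = 0.2):
    """Keep OTUs detected (> 0) in at least ``min_fraction`` of samples.

    The boundary is inclusive: an OTU present in exactly 20% of samples is
    retained at ``min_fraction=0.2``.  Works on count and abundance tables
    alike; the sample set is unchanged.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    df = table.data
    prevalence = (df > 0).sum(axis=1) / df.shape[1]
    keep = prevalence[prevalence >= min_fraction].index
    if len(keep) == 0:
        warnings.warn("prevalence filter removed every OTU", stacklevel=2)
    out = df.loc[keep].copy()
    return type(table)(out, metadata=table.metadata, taxonomy=table.taxonomy)


def log_transform(
    table: AbundanceTable, pseudocount: float | None = None
) -> pd.DataFrame:
    """Natural-log transform of relative abundances.

    ``pseudocount=None`` uses half the smallest nonzero abundance in the
    whole table; pass an explicit value (including 0 for strictly positive
    tables) to override.
    """
    values = table.data.to_numpy(dtype=float)
    if pseudocount is None:
        nonzero = values[values > 0]
        if nonzero.size == 0:
            raise ValueError("table has no nonzero abundances")
        pseudocount = float(nonzero.min()) / 2.0
    with np.errstate(divide="ignore"):
        out = np.log(values + pseudocount)
    return pd.DataFrame(out, index=table.data.index, columns=table.data.columns)


def classify_abundance(
    table: AbundanceTable, scope=None
) -> pd.DataFrame:
    """Classify each OTU as abundant / rare / intermediate.

    Rules (relative abundances within ``scope`` samples, default all):

    * abundant: mean > 0.1%, or >= 0.01% in every sample and >= 1% in at
      least one sample;
    * rare: < 0.01% in at least one sample and never >= 1%;
    * intermediate: everything else.

    Returns a DataFrame indexed by OTU id with columns ``class`` and
    ``mean_abundance``.
    """
    sub = table.data if scope is None else table.data[list(scope)]
    if sub.shape[1] == 0:
        raise ValueError("scope must contain at least one sample")
    vals = sub.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    mn = vals.min(axis=1)
    mx = vals.max(axis=1)
    abundant = (mean > ABUNDANT_MEAN_THRESHOLD) | (
        (mn >= LOCAL_LOW_THRESHOLD) & (mx >= LOCAL_HIGH_THRESHOLD)
    )
    rare = (mn < LOCAL_LOW_THRESHOLD) & (mx < LOCAL_HIGH_THRESHOLD) & ~abundant
    labels = np.where(abundant, "abundant", np.where(rare, "rare", "intermediate"))
    return pd.DataFrame(
        {"class": labels, "mean_abundance": mean}, index=sub.index
    )


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample richness (observed OTUs) and Shannon index (nats)."""
    counts = table.data.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    richness = (counts > 0).sum(axis=0)
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=0)
    return pd.DataFrame(
        {"richness": richness.astype(int), "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
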