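"""Core tabular containers and TSV IO.

The package works on two tables: a genus-level relative-abundance table
(samples x genera) and a per-sample host-metadata table.  Both are thin
wrappers / conventions over :class:`pandas.DataFrame`; all files are
UTF-8, tab-delimited TSV with ``.`` decimal.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required host-metadata columns.  ``selenium_before`` / ``selenium_after``
#: are hair selenium content (e.g. ug/g) measured before and after the
#: supplementation period.
METADATA_COLUMNS = (
    "gender",
    "age",
    "bmi",
    "probiotics",
    "health_status",
    "batch",
    "region",
    "selenium_before",
    "selenium_after",
)

GENUS_PREFIX = "g__"

ROW_SUM_TOL = 1e-6


class AbundanceTable:
    """Samples x genera relative-abundance table.

    Values are non-negative fractions; every row sums to 1 (rows are
    renormalized on construction, with a logged notice when a row sum
    deviates from 1 by more than ``1e-6``).  Genus names follow the
    ``g__Name`` convention.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with genus columns, or anything
        DataFrame() accepts together with `sample_ids` / `genus_ids`.
    """

    def __init__(self, data, sample_ids: Sequence[str] | None = None,
                 genus_ids: Sequence[str] | None = None):
        df = pd.DataFrame(data, index=sample_ids, columns=genus_ids)
        df = df.astype(float)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate genus IDs: {dups}")
        if (df.values < 0).any():
            raise ValueError("abundance values must be non-negative")
        sums = df.sum(axis=1)
        if (sums <= 0).any():
            bad = df.index[sums <= 0].tolist()
            raise ValueError(f"all-zero abundance rows: {bad}")
        off = (sums - 1.0).abs() > ROW_SUM_TOL
        if off.any():
            logger.info("renormalizing %d/%d rows whose sums deviate from 1",
                        int(off.sum()), len(df))
        self.data = df.div(sums, axis=0)

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, g = self.shape
        return f"AbundanceTable({n} samples x {g} genera)"

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)])

    def subset_genera(self, genus_ids: Iterable[str],
                      renormalize: bool = False) -> pd.DataFrame:
        """Column subset as a plain DataFrame (a feature view, not a
        composition — rows no longer sum to 1 unless `renormalize`)."""
        sub = self.data.loc[:, list(genus_ids)].copy()
        if renormalize:
            sub = sub.div(sub.sum(axis=1), axis=0)
        return sub


def read_abundance(path) -> AbundanceTable:
    """Read an abundance TSV.

    Orientation is auto-detected via the ``g__`` prefix: genera may be
    either the columns (samples in rows, the canonical layout) or the
    rows (a common export layout); the latter is transposed on read.
    Integer counts are accepted and renormalized to relative abundance.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    col_hits = sum(c.startswith(GENUS_PREFIX) for c in df.columns)
    row_hits = sum(r.startswith(GENUS_PREFIX) for r in df.index)
    if row_hits > col_hits:
        df = df.T
    return AbundanceTable(df)


def write_abundance(table: AbundanceTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    """Read a host-metadata TSV indexed by sample id.

    Requires the fixed column set in :data:`METADATA_COLUMNS` (an optional
    ``stage`` column is carried through); validates uniqueness of sample
    ids and positivity of age/BMI.
    """
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in metadata: {dups}")
    for col in ("age", "bmi"):
        vals = pd.to_numeric(meta[col], errors="coerce")
        if (vals <= 0).any():
            bad = meta.index[vals <= 0].tolist()
            raise ValueError(f"non-positive {col} for samples {bad}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def align(table: AbundanceTable,
          meta: pd.DataFrame) -> tuple[AbundanceTable, pd.DataFrame]:
    """Pair abundance and metadata on their shared samples.

    Samples present on only one side are dropped with a logged count;
    the output tables carry identical sample order (the abundance
    table's order restricted to the intersection).
    """
    shared = [s for s in table.sample_ids if s in meta.index]
    if not shared:
        raise ValueError("no shared sample IDs between abundance and metadata")
    n_drop = (len(table.sample_ids) - len(shared)) + (len(meta.index) - len(shared))
    if n_drop:
        logger.info("align: dropped %d unpaired samples, kept %d",
                    n_drop, len(shared))
    return table.subset_samples(shared), meta.loc[shared]


def harmonize_features(tables: Sequence[AbundanceTable],
                       mode: Literal["union", "intersection"] = "union",
                       ) -> list[AbundanceTable]:
    """Put several abundance tables on a common, lexicographic genus set.

    ``union`` zero-fills genera absent from a table; ``intersection``
    keeps only genera *present* (nonzero in at least one sample) in every
    table, renormalizing rows.  Needed because a genus picked as a
    biomarker in one sequencing batch may be absent from another batch
    or city.
    """
    if len(tables) < 2:
        raise ValueError("harmonize_features needs at least 2 tables")
    present = [set(t.data.columns[(t.values > 0).any(axis=0)]) for t in tables]
    if mode == "union":
        genera = sorted(set().union(*(set(t.genus_ids) for t in tables)))
        out = []
        for t in tables:
            df = t.data.reindex(columns=genera, fill_value=0.0)
            out.append(AbundanceTable(df))
        return out
    if mode == "intersection":
        genera = sorted(set.intersection(*present))
        if not genera:
            raise ValueError("no genus present in every table")
        return [AbundanceTable(t.data.loc[:, genera]) for t in tables]
    raise ValueError(f"unknown mode {mode!r}")
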