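"""Community tables and their on-disk formats.

The central container is :class:`CountTable`, a samples x taxa matrix of
non-negative integer read counts with string identifiers on both axes.
:class:`AbundanceTable` holds the real-valued (transformed) analogue.
Tables are read and written as plain TSV (rows = samples, header row =
taxon ids) or as dense BIOM v1 JSON (rows = observations/taxa, columns =
samples, ``matrix_type: "dense"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class TableValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


def _check_ids(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise TableValidationError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer counts."""

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise TableValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.number):
            raise TableValidationError("counts must be numeric")
        if np.any(self.counts < 0):
            s, t = np.argwhere(self.counts < 0)[0]
            raise TableValidationError(
                f"negative count at sample {self.sample_ids[s]!r}, "
                f"taxon {self.taxon_ids[t]!r}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                bad = np.argwhere(self.counts != rounded)
                s, t = bad[0]
                raise TableValidationError(
                    f"non-integer count at sample {self.sample_ids[s]!r}, "
                    f"taxon {self.taxon_ids[t]!r}"
                )
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        _check_ids(self.sample_ids, "sample")
        _check_ids(self.taxon_ids, "taxon")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def depths(self) -> np.ndarray:
        """Per-sample total read count (library size)."""
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy())

    def select_samples(self, indices) -> "CountTable":
        idx = np.asarray(indices)
        return CountTable(
            [self.sample_ids[i] for i in idx], list(self.taxon_ids), self.counts[idx]
        )

    def select_taxa(self, taxa: list[str]) -> "CountTable":
        pos = {t: j for j, t in enumerate(self.taxon_ids)}
        cols = [pos[t] for t in taxa]
        return CountTable(list(self.sample_ids), list(taxa), self.counts[:, cols])


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of real-valued abundances in [0, 1].

    Produced by :func:`coretier.preprocess.hellinger` (rows then have unit
    L2 norm) or by generators that emit relative abundances (rows sum to 1).
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise TableValidationError("values shape does not match ids")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise TableValidationError("abundance values must lie in [0, 1]")
        if np.any(self.values.sum(axis=1) == 0):
            raise TableValidationError("zero abundance rows are forbidden; filter first")
        _check_ids(self.sample_ids, "sample")
        _check_ids(self.taxon_ids, "taxon")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class SampleMetadata:
    """Per-sample host, site and geographic coordinates."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "host", "site", "latitude", "longitude")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise TableValidationError(f"metadata missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise TableValidationError("duplicate sample_id in metadata")
        lat = self.table["latitude"].to_numpy(float)
        lon = self.table["longitude"].to_numpy(float)
        if np.any(np.abs(lat) > 90):
            raise TableValidationError("latitude outside [-90, 90]")
        if np.any(np.abs(lon) > 180):
            raise TableValidationError("longitude outside [-180, 180]")
        self.table = self.table.reset_index(drop=True)
        self._by_id = self.table.set_index("sample_id")

    def for_samples(self, sample_ids: list[str]) -> pd.DataFrame:
        """Metadata rows aligned to ``sample_ids``; errors on missing samples."""
        missing = [s for s in sample_ids if s not in self._by_id.index]
        if missing:
            raise TableValidationError(f"samples without metadata: {missing[:5]}")
        return self._by_id.loc[sample_ids].reset_index()

    def sites_for(self, sample_ids: list[str]) -> pd.Series:
        return self.for_samples(sample_ids)["site"]

    def coords_for(self, sample_ids: list[str]) -> np.ndarray:
        rows = self.for_samples(sample_ids)
        return rows[["latitude", "longitude"]].to_numpy(float)


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path, format: str = "tsv", orientation: str = "samples") -> CountTable:
    """Read a count table from TSV or dense BIOM v1 JSON.

    Parameters
    ----------
    format:
        ``"tsv"`` — tab-delimited, header row and first column are ids — or
        ``"biom-dense"`` — BIOM v1 JSON with ``matrix_type: "dense"`` where
        rows are observations (taxa) and columns are samples.
    orientation:
        For TSV input, whether rows of the file are ``"samples"`` (default)
        or ``"taxa"``; the returned table always has rows = samples.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            col = bad[0]
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise TableValidationError(f"malformed numeric cell at row {row!r}, column {col!r}")
        if orientation == "taxa":
            df = df.T
        elif orientation != "samples":
            raise ValueError(f"unknown orientation {orientation!r}")
        return CountTable.from_dataframe(df)
    if format == "biom-dense":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("matrix_type") != "dense":
            raise TableValidationError("only dense BIOM matrices are supported")
        taxa = [str(r["id"]) for r in doc["rows"]]
        samples = [str(c["id"]) for c in doc["columns"]]
        data = np.asarray(doc["data"])  # observations x samples
        return CountTable(samples, taxa, data.T)
    raise ValueError(f"unknown format {format!r}")


def write_count_table(t: CountTable, path) -> None:
    t.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, dtype={"sample_id": str, "host": str, "site": str})
    return SampleMetadata(df)


def write_metadata(m: SampleMetadata, path) -> None:
    m.table.to_csv(path, index=False)
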