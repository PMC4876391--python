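"""Plot × species abundance tables and plot metadata.

The universal input of every analysis stage is a :class:`CommunityMatrix`
(plots as rows, species or morphospecies as columns, integer counts) paired
with a :class:`PlotMetadata` table mapping each plot to a transect, an
elevational band and an elevation in metres.  Both are thin, validated
wrappers around :class:`pandas.DataFrame`.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "CommunityMatrix",
    "PlotMetadata",
    "read_community_csv",
    "read_metadata_csv",
    "pool_strata",
    "split_by_transect",
]


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicate ids, missing plots...)."""


class FormatError(ValueError):
    """A file cell or column does not parse as the format requires."""


class CommunityMatrix:
    """Validated plots × species integer abundance table.

    Parameters
    ----------
    counts
        DataFrame with plot identifiers as index and species identifiers as
        columns.  Cells must be non-negative integers (integral floats are
        accepted and cast).  Absences are explicit zeros.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate plot identifiers: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species identifiers: {dups}")
        if counts.shape[0] == 0:
            raise ValidationError("community matrix has no plots")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("community matrix contains non-numeric cells")
        if values.size:
            if np.any(~np.isfinite(values.astype(float))):
                raise FormatError("community matrix contains non-finite cells")
            if np.any(values.astype(float) < 0):
                raise FormatError("community matrix contains negative counts")
            if np.any(values.astype(float) != np.floor(values.astype(float))):
                raise FormatError("community matrix contains non-integer counts")
        self._df = counts.astype(np.int64)
        self._df.index = self._df.index.astype(str)
        self._df.columns = self._df.columns.astype(str)

    # -- accessors ---------------------------------------------------------
    @property
    def counts(self) -> pd.DataFrame:
        """The underlying plots × species integer DataFrame (do not mutate)."""
        return self._df

    @property
    def plot_ids(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def species_ids(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def n_plots(self) -> int:
        return self._df.shape[0]

    @property
    def n_species(self) -> int:
        return self._df.shape[1]

    @property
    def plot_totals(self) -> pd.Series:
        return self._df.sum(axis=1)

    @property
    def species_totals(self) -> pd.Series:
        return self._df.sum(axis=0)

    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    def subset(
        self,
        plots: Sequence[str] | None = None,
        species: Sequence[str] | None = None,
    ) -> "CommunityMatrix":
        df = self._df
        if plots is not None:
            missing = [p for p in plots if p not in df.index]
            if missing:
                raise ValidationError(f"unknown plot identifiers: {missing}")
            df = df.loc[list(plots)]
        if species is not None:
            missing = [s for s in species if s not in df.columns]
            if missing:
                raise ValidationError(f"unknown species identifiers: {missing}")
            df = df[list(species)]
        out = object.__new__(CommunityMatrix)
        out._df = df.copy()
        return out

    def drop_empty_species(self) -> "CommunityMatrix":
        keep = self._df.columns[self._df.sum(axis=0) > 0]
        return self.subset(species=keep.tolist())

    def equals(self, other: "CommunityMatrix") -> bool:
        return self._df.equals(other._df)

    def to_csv(self, path, species_as_rows: bool = False) -> None:
        df = self._df.T if species_as_rows else self._df
        df.to_csv(path, index_label="id")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<CommunityMatrix {self.n_plots} plots × {self.n_species} species>"


class PlotMetadata:
    """Per-plot records: transect, elevational band, elevation and optional stratum.

    Band labels are plain strings; ordering is always derived from the mean
    elevation of the plots carrying the label, never from lexicographic sort.
    """

    REQUIRED = ("plot_id", "transect", "band", "elevation_m")
    OPTIONAL = ("stratum", "site")

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in records.columns]
        if missing:
            raise FormatError(f"metadata missing required column(s): {missing}")
        df = records.copy()
        if df["plot_id"].duplicated().any():
            dups = df.loc[df["plot_id"].duplicated(), "plot_id"].unique().tolist()
            raise ValidationError(f"plot listed more than once in metadata: {dups}")
        df["plot_id"] = df["plot_id"].astype(str)
        df["transect"] = df["transect"].astype(str)
        df["band"] = df["band"].astype(str)
        df["elevation_m"] = pd.to_numeric(df["elevation_m"], errors="raise")
        self._df = df.set_index("plot_id", drop=False)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def plot_ids(self) -> list[str]:
        return self._df.index.tolist()

    def transects(self) -> list[str]:
        return self._df["transect"].unique().tolist()

    def elevations(self) -> pd.Series:
        """Plot id → elevation (m a.s.l.)."""
        return self._df["elevation_m"]

    def band_of(self) -> pd.Series:
        """Plot id → band label."""
        return self._df["band"]

    def bands_ordered(self, transect: str | None = None) -> list[str]:
        """Band labels in increasing order of mean plot elevation."""
        df = self._df if transect is None else self._df[self._df["transect"] == transect]
        means = df.groupby("band")["elevation_m"].mean()
        return means.sort_values().index.tolist()

    def subset(self, plot_ids: Sequence[str]) -> "PlotMetadata":
        missing = [p for p in plot_ids if p not in self._df.index]
        if missing:
            raise ValidationError(f"plots without metadata record: {missing}")
        return PlotMetadata(self._df.loc[list(plot_ids)].reset_index(drop=True))

    def match(self, matrix: CommunityMatrix) -> "PlotMetadata":
        """Align metadata to a matrix's plots.

        Every plot in the matrix must have exactly one record.  Bands that end
        up with zero plots after the join are dropped with a warning.
        """
        out = self.subset(matrix.plot_ids)
        empty = set(self._df["band"]) - set(out._df["band"])
        if empty:
            warnings.warn(
                f"band(s) with no plots after join dropped: {sorted(empty)}",
                stacklevel=2,
            )
        return out

    def to_csv(self, path) -> None:
        cols = [c for c in (*self.REQUIRED, *self.OPTIONAL) if c in self._df.columns]
        self._df[cols].to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PlotMetadata {len(self._df)} plots, transects={self.transects()}>"


def read_community_csv(path, species_as_rows: bool = False) -> CommunityMatrix:
    """Read a plots × species abundance CSV.

    The first column holds plot identifiers and the header row species
    identifiers (pass ``species_as_rows=True`` for the transposed layout).
    Cells must be non-negative integers; offending cells are reported with
    their row and column labels.
    """
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    ids = header[1:]
    if len(set(ids)) != len(ids):
        dups = sorted({s for s in ids if ids.count(s) > 1})
        kind = "plot" if species_as_rows else "species"
        raise ValidationError(f"{path}: duplicate {kind} identifiers in header: {dups}")
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if species_as_rows:
        df = df.T
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no species columns found")
    parsed = {}
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(f"{path}: non-numeric count at row {row!r}, column {col!r}")
        if (numeric < 0).any():
            row = df.index[(numeric < 0).to_numpy().argmax()]
            raise FormatError(f"{path}: negative count at row {row!r}, column {col!r}")
        if (numeric != np.floor(numeric)).any():
            row = df.index[(numeric != np.floor(numeric)).to_numpy().argmax()]
            raise FormatError(f"{path}: non-integer count at row {row!r}, column {col!r}")
        parsed[col] = numeric.astype(np.int64)
    return CommunityMatrix(pd.DataFrame(parsed, index=df.index))


def read_metadata_csv(path) -> PlotMetadata:
    """Read plot metadata (columns plot_id, transect, band, elevation_m [, stratum, site])."""
    df = pd.read_csv(path, dtype={"plot_id": str, "band": str})
    return PlotMetadata(df)


def pool_strata(
    matrix: CommunityMatrix, metadata: PlotMetadata
) -> tuple[CommunityMatrix, PlotMetadata]:
    """Pool stratified samples (e.g. canopy and understorey) into one row per site.

    Rows whose metadata carries both a ``stratum`` and a ``site`` are summed
    per species within each site; rows without a stratum pass through
    unchanged under their own plot id.  Total abundance per species and per
    site is conserved.
    """
    meta = metadata.match(matrix).df
    has_stratum = "stratum" in meta.columns and meta["stratum"].notna()
    if not np.any(has_stratum):
        return matrix, metadata.match(matrix)
    if "site" not in meta.columns:
        raise ValidationError(
            "stratified plots require a 'site' metadata column to pool by"
        )
    key = meta["plot_id"].where(~has_stratum, meta["site"].astype(str))
    counts = matrix.counts.groupby(key.to_numpy()).sum()
    # keep first-seen order of pooled keys
    order = list(dict.fromkeys(key))
    counts = counts.loc[order]
    rec = meta.assign(_key=key.to_numpy()).groupby("_key", sort=False).first()
    rec = rec.loc[order]
    new_meta = pd.DataFrame(
        {
            "plot_id": order,
            "transect": rec["transect"].to_numpy(),
            "band": rec["band"].to_numpy(),
            "elevation_m": rec["elevation_m"].to_numpy(),
        }
    )
    return CommunityMatrix(counts), PlotMetadata(new_meta)


def split_by_transect(
    matrix: CommunityMatrix, metadata: PlotMetadata
) -> dict[str, tuple[CommunityMatrix, PlotMetadata]]:
    """Split a pooled dataset into per-transect matrices.

    Species with zero total abundance within a transect are dropped from that
    transect's matrix, so the species pool of each result is the set of
    species actually recorded there.
    """
    meta = metadata.match(matrix)
    out: dict[str, tuple[CommunityMatrix, PlotMetadata]] = {}
    for tr in meta.transects():
        plots = meta.df.loc[meta.df["transect"] == tr, "plot_id"].tolist()
        sub = matrix.subset(plots=plots).drop_empty_species()
        out[tr] = (sub, meta.subset(plots))
    return out
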