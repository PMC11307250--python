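"""Descriptor and retention tables: I/O, normalization, retention factors, compound sets.

Descriptor tables are compounds x named molecular descriptors, as produced by a
descriptor calculator and consumed as CSV. Retention tables are long-format
records of retention time per (compound, stationary phase, organic modifier,
time point). Both are thin wrappers over pandas DataFrames with the invariants
this pipeline relies on checked at construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Default ordinal labels for the sampling schedule of a year of column use:
#: monthly/quarterly time points plus a final post-regeneration injection "R".
DEFAULT_TIME_POINTS: tuple[str, ...] = ("0M", "1M", "2M", "3M", "6M", "9M", "12M", "R")

#: Columns a long-format retention CSV must provide.
RETENTION_REQUIRED = ("compound_id", "column_id", "modifier_id", "time_point", "t_r", "eluted")
RETENTION_OPTIONAL = ("peak_width_5pct", "k_prime")


class TableFormatError(ValueError):
    """Raised when an input table violates the declared format."""


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i, n in enumerate(names):
        if n in seen:
            raise TableFormatError(
                f"duplicate {what} {n!r} (positions {seen[n]} and {i})"
            )
        seen[n] = i


@dataclass
class DescriptorTable:
    """Compounds x molecular descriptors, pre- or post-normalization.

    Parameters
    ----------
    data
        DataFrame indexed by compound id with one numeric column per descriptor.
    normalized
        Whether columns have been scaled so that ``max |value| <= 1``.
    degenerate_columns
        Descriptor names whose column was all-zero at normalization time and
        was therefore returned unchanged.
    """

    data: pd.DataFrame
    normalized: bool = False
    degenerate_columns: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index.astype(str)), "compound id")
        _check_unique(list(self.data.columns.astype(str)), "descriptor name")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            bad = [c for c, dt in self.data.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise TableFormatError(f"non-numeric descriptor columns: {bad}")
        if self.normalized:
            finite = self.data.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                colmax = np.nanmax(np.abs(finite), axis=0)
            if np.any(colmax > 1.0 + 1e-12):
                raise TableFormatError("normalized table has |value| > 1")

    # -- convenience accessors -------------------------------------------------
    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns.astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, compound_ids: Iterable[str]) -> "DescriptorTable":
        ids = [str(c) for c in compound_ids]
        missing = [c for c in ids if c not in self.data.index]
        if missing:
            raise KeyError(f"compounds not in descriptor table: {missing[:5]}")
        return replace(self, data=self.data.loc[ids])

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "compound_id"
        out.to_csv(path)


def read_descriptors(path: str | Path) -> DescriptorTable:
    """Read a descriptor CSV: header of descriptor names, first column compound id.

    Missing values are kept as NaN and flagged by a warning, never imputed.
    Ragged rows, non-numeric cells and duplicate ids are rejected with the
    offending location in the message.
    """
    try:
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=True)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise TableFormatError(f"{path}: malformed CSV ({exc})") from exc
    df.index = df.index.astype(str)
    num = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise TableFormatError(
                f"{path}: non-numeric value {df.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        num[col] = converted
    if num.isna().any().any():
        n_missing = int(num.isna().sum().sum())
        warnings.warn(f"{path}: {n_missing} missing descriptor values (kept as NaN)")
    return DescriptorTable(data=num, normalized=False)


def normalize_by_max(table: DescriptorTable, mode: str = "abs-max") -> DescriptorTable:
    """Scale each descriptor column by its maximal value.

    ``mode="abs-max"`` (default) divides by ``max |x|``, mapping every column
    into [-1, 1] and preserving signs; ``mode="signed-max"`` divides by the
    signed maximum, which mirrors a literal reading of dividing by "the maximal
    value" but flips signs for all-negative columns. All-zero columns are
    returned unchanged and reported in ``degenerate_columns``.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    if mode not in ("abs-max", "signed-max"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    values = table.values.copy()
    degenerate: list[str] = []
    for j, name in enumerate(table.descriptor_names):
        col = values[:, j]
        denom = np.nanmax(np.abs(col)) if mode == "abs-max" else np.nanmax(col)
        if not np.isfinite(denom) or denom == 0.0:
            degenerate.append(name)
            continue
        values[:, j] = col / denom
    data = pd.DataFrame(values, index=table.data.index, columns=table.data.columns)
    return DescriptorTable(
        data=data,
        normalized=(mode == "abs-max"),
        degenerate_columns=tuple(degenerate),
    )


@dataclass
class RetentionTable:
    """Long-format retention records, one per (compound, column, modifier, time point)."""

    data: pd.DataFrame
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS

    def __post_init__(self) -> None:
        missing = [c for c in RETENTION_REQUIRED if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"retention table missing columns: {missing}")
        key = ["compound_id", "column_id", "modifier_id", "time_point"]
        dup = self.data.duplicated(subset=key)
        if dup.any():
            first = self.data.loc[dup.idxmax(), key].tolist()
            raise TableFormatError(f"duplicate retention record for {first}")
        unknown = set(self.data["time_point"]) - set(self.time_points)
        if unknown:
            raise TableFormatError(
                f"unknown time point label(s) {sorted(unknown)}; expected {self.time_points}"
            )
        eluted = self.data["eluted"].astype(bool)
        tr = pd.to_numeric(self.data["t_r"], errors="coerce")
        bad = eluted & ~(tr > 0)
        if bad.any():
            row = self.data[bad].iloc[0]
            raise TableFormatError(
                f"non-positive t_r for eluting record "
                f"{row['compound_id']}/{row['column_id']}/{row['modifier_id']}/{row['time_point']}"
            )
        if "k_prime" in self.data.columns:
            kp = pd.to_numeric(self.data["k_prime"], errors="coerce")
            if (kp.dropna() < 0).any():
                raise TableFormatError("negative k_prime in retention table")

    @property
    def conditions(self) -> list[tuple[str, str]]:
        pairs = self.data[["column_id", "modifier_id"]].drop_duplicates()
        return [tuple(r) for r in pairs.to_numpy()]

    def select(
        self,
        column_id: str | None = None,
        modifier_id: str | None = None,
        time_point: str | None = None,
        eluted_only: bool = False,
    ) -> pd.DataFrame:
        df = self.data
        if column_id is not None:
            df = df[df["column_id"] == column_id]
        if modifier_id is not None:
            df = df[df["modifier_id"] == modifier_id]
        if time_point is not None:
            df = df[df["time_point"] == time_point]
        if eluted_only:
            df = df[df["eluted"].astype(bool)]
        return df.copy()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def read_retention(
    path: str | Path, time_points: Sequence[str] = DEFAULT_TIME_POINTS
) -> RetentionTable:
    """Read a long-format retention CSV (see RETENTION_REQUIRED for columns)."""
    df = pd.read_csv(path)
    for col in ("compound_id", "column_id", "modifier_id", "time_point"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    if "eluted" in df.columns:
        df["eluted"] = df["eluted"].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
        )
    return RetentionTable(data=df, time_points=tuple(time_points))


def compute_k_prime(t_r: float, t0: float) -> float:
    """Retention factor k' = (tR - t0) / t0 for dead time t0 (minutes)."""
    if t0 <= 0:
        raise ValueError(f"dead time t0 must be positive, got {t0}")
    if t_r < t0:
        raise ValueError(f"t_r={t_r} earlier than dead time t0={t0} (non-physical)")
    return (t_r - t0) / t0


def add_k_prime(retention: RetentionTable, t0: float) -> RetentionTable:
    """Fill the k_prime column from t_r where absent, leaving provided values alone."""
    df = retention.data.copy()
    if "k_prime" not in df.columns:
        df["k_prime"] = np.nan
    needs = df["k_prime"].isna() & df["eluted"].astype(bool)
    df.loc[needs, "k_prime"] = [
        compute_k_prime(tr, t0) for tr in df.loc[needs, "t_r"].astype(float)
    ]
    return RetentionTable(data=df, time_points=retention.time_points)


@dataclass(frozen=True)
class CompoundSetTriple:
    """The three compound sets used throughout the analysis.

    ``original`` is every tested compound; ``narrowed`` those eluting on all
    stationary phases (enabling direct cross-column comparison); ``extended``
    maps each stationary phase to all compounds eluting on it.
    """

    original: frozenset[str]
    narrowed: frozenset[str]
    extended: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for col, ids in self.extended.items():
            if not self.narrowed <= ids <= self.original:
                raise ValueError(f"set invariant violated for column {col!r}")
        inter = frozenset.intersection(*self.extended.values()) if self.extended else frozenset()
        if self.narrowed != inter:
            raise ValueError("narrowed set is not the intersection of extended sets")


def build_compound_sets(
    retention: RetentionTable,
    modifier_id: str,
    baseline_time: str = "0M",
) -> CompoundSetTriple:
    """Build original/narrowed/extended sets from elution status at baseline."""
    df = retention.select(modifier_id=modifier_id, time_point=baseline_time)
    if df.empty:
        raise ValueError(f"no baseline records for modifier {modifier_id!r}")
    original = frozenset(df["compound_id"])
    extended = {
        col: frozenset(sub[sub["eluted"].astype(bool)]["compound_id"])
        for col, sub in df.groupby("column_id")
    }
    narrowed = frozenset.intersection(*extended.values())
    if not narrowed:
        warnings.warn(f"narrowed set is empty for modifier {modifier_id!r}")
    return CompoundSetTriple(original=original, narrowed=narrowed, extended=extended)
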