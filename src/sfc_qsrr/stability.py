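"""Retention-time drift and weight-stability statistics.

Two complementary views of column aging: percent shifts of retention time
against a baseline injection (binned into the five magnitude classes used for
stability heatmaps), and the standard deviation of each descriptor's network
weight across time points, compared against a stability limit derived from the
most stable reference condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ann import WeightVector
from .io_tables import RetentionTable

#: Five magnitude bins for |% shift|, lower-closed / upper-open.
BIN_EDGES = (0.0, 0.5, 1.0, 2.0, 5.0, np.inf)
BIN_LABELS = ("<0.5%", "0.5-1.0%", "1.0-2.0%", "2.0-5.0%", ">5.0%")


def bin_shifts(percent: float) -> str:
    """Map a signed percent shift to its magnitude bin (on |percent|)."""
    if not np.isfinite(percent):
        raise ValueError(f"cannot bin non-finite shift {percent!r}")
    mag = abs(percent)
    for lo, hi, label in zip(BIN_EDGES[:-1], BIN_EDGES[1:], BIN_LABELS):
        if lo <= mag < hi:
            return label
    raise AssertionError("unreachable: bins partition [0, inf)")


@dataclass
class ShiftReport:
    """Per-record percent retention-time shifts relative to a baseline injection."""

    data: pd.DataFrame  # compound_id, column_id, modifier_id, time_point, percent_shift, bin
    baseline_time: str
    skipped: tuple[tuple[str, str, str], ...] = ()  # (compound, column, modifier) w/o baseline

    def binned_counts(self) -> pd.DataFrame:
        """Count table per (column, modifier, time point) x bin."""
        ct = (
            self.data.groupby(["column_id", "modifier_id", "time_point", "bin"])
            .size()
            .unstack("bin", fill_value=0)
        )
        for label in BIN_LABELS:
            if label not in ct.columns:
                ct[label] = 0
        return ct[list(BIN_LABELS)]


def percent_shift(retention: RetentionTable, baseline_time: str = "0M") -> ShiftReport:
    """Signed percent shift 100 * (tR_t - tR_baseline) / tR_baseline per record.

    Compounds without a baseline record under a condition are skipped and
    reported in ``skipped``. Non-eluting records are ignored.
    """
    df = retention.data[retention.data["eluted"].astype(bool)].copy()
    base = df[df["time_point"] == baseline_time].set_index(
        ["compound_id", "column_id", "modifier_id"]
    )["t_r"]
    rows = []
    skipped = []
    for (cid, col, mod), sub in df.groupby(["compound_id", "column_id", "modifier_id"]):
        key = (cid, col, mod)
        if key not in base.index:
            skipped.append(key)
            continue
        tr0 = float(base.loc[key])
        for _, rec in sub.iterrows():
            shift = 100.0 * (float(rec["t_r"]) - tr0) / tr0
            rows.append((cid, col, mod, rec["time_point"], shift, bin_shifts(shift)))
    data = pd.DataFrame(
        rows,
        columns=["compound_id", "column_id", "modifier_id", "time_point", "percent_shift", "bin"],
    )
    return ShiftReport(data=data, baseline_time=baseline_time, skipped=tuple(skipped))


def fraction_exceeding(
    report: ShiftReport,
    column_id: str,
    modifier_id: str,
    time_point: str,
    cutoff: float,
) -> float:
    """Fraction of compounds with |shift| > cutoff at one condition/time point."""
    df = report.data
    sel = df[
        (df["column_id"] == column_id)
        & (df["modifier_id"] == modifier_id)
        & (df["time_point"] == time_point)
    ]
    if sel.empty:
        raise ValueError(
            f"no shifts recorded for {column_id}/{modifier_id} at {time_point}"
        )
    return float(np.mean(np.abs(sel["percent_shift"].to_numpy()) > cutoff))


@dataclass
class StabilityReport:
    """Per-descriptor weight SD across time points for one condition."""

    condition: tuple[str, str]
    sd_over_time: pd.Series  # index: descriptor names
    n_time_points: int
    limit: float | None = None

    @property
    def exceeds(self) -> pd.Series:
        if self.limit is None:
            raise ValueError("no stability limit set")
        return self.sd_over_time > self.limit

    @property
    def n_exceeding(self) -> int:
        return int(self.exceeds.sum())

    def with_limit(self, limit: float) -> "StabilityReport":
        return StabilityReport(
            condition=self.condition,
            sd_over_time=self.sd_over_time,
            n_time_points=self.n_time_points,
            limit=limit,
        )


def weight_sd(
    weight_series: dict[str, WeightVector],
    condition: tuple[str, str] = ("", ""),
    ddof: int = 0,
) -> StabilityReport:
    """Per-descriptor SD of weights across time points (population SD by default).

    ``weight_series`` maps time-point label -> WeightVector; all vectors must
    share the same descriptor names. Whether the post-regeneration point is
    part of the window is decided by what the caller includes.
    """
    if len(weight_series) < 2:
        raise ValueError("need weights at >= 2 time points")
    items = list(weight_series.items())
    names = tuple(items[0][1].descriptor_names)
    for tp, wv in items[1:]:
        if tuple(wv.descriptor_names) != names:
            raise ValueError(f"descriptor names at {tp!r} differ from the first time point")
    mat = np.vstack([wv.weights for _, wv in items])
    sd = np.std(mat, axis=0, ddof=ddof)
    return StabilityReport(
        condition=tuple(condition),
        sd_over_time=pd.Series(sd, index=list(names)),
        n_time_points=len(items),
    )


def derive_stability_limit(
    reports: dict[tuple[str, str], StabilityReport],
    reference_condition: tuple[str, str],
) -> float:
    """Stability limit = the largest per-descriptor weight SD on the reference
    (most stable) condition; weights drifting beyond it on any condition are
    flagged unstable."""
    reference_condition = tuple(reference_condition)
    if reference_condition not in reports:
        raise KeyError(f"reference condition {reference_condition} not in reports")
    limit = float(reports[reference_condition].sd_over_time.max())
    if limit == 0.0:
        import warnings

        warnings.warn("degenerate stability limit 0 (reference SDs all zero)")
    return limit


def apply_limit(
    reports: dict[tuple[str, str], StabilityReport], limit: float
) -> dict[tuple[str, str], StabilityReport]:
    return {cond: rep.with_limit(limit) for cond, rep in reports.items()}
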