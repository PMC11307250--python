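"""Evaluation of the column-regeneration procedure.

For every compound and condition with records at the first injection (0M), the
end of the year (12M) and after regeneration (R):

    %-error(R)  = 100 * (tR_0M - tR_R)  / tR_0M      (positive = retention lost)
    %-diff(12M) = 100 * (tR_0M - tR_12M) / tR_0M

Regeneration is *effective* for a compound when it brought retention strictly
closer to the first injection than it was at 12M (|%-error(R)| < |%-diff(12M)|;
a tie counts as no benefit), and *within tolerance* when |%-error(R)| <= 2%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import RetentionTable


@dataclass
class RegenerationReport:
    data: pd.DataFrame  # per (compound, column, modifier)
    summary: pd.DataFrame  # per (column, modifier): fractions and counts
    excluded: tuple[tuple[str, str, str], ...]  # missing one of the three time points


def evaluate_regeneration(
    retention: RetentionTable,
    baseline_time: str = "0M",
    worn_time: str = "12M",
    regen_time: str = "R",
    tolerance_pct: float = 2.0,
) -> RegenerationReport:
    """Per-compound %-error after regeneration and the two-way effectiveness flag.

    Compounds lacking an eluted record at any of the three time points under a
    condition are excluded and listed in ``excluded``. Width recovery is
    reported as the peak-width delta (R minus 12M) when widths are present.
    """
    df = retention.data[retention.data["eluted"].astype(bool)]
    piv = df.pivot_table(
        index=["compound_id", "column_id", "modifier_id"],
        columns="time_point",
        values="t_r",
        aggfunc="first",
    )
    have_width = "peak_width_5pct" in retention.data.columns and not (
        retention.data["peak_width_5pct"].isna().all()
    )
    if have_width:
        wpiv = df.pivot_table(
            index=["compound_id", "column_id", "modifier_id"],
            columns="time_point",
            values="peak_width_5pct",
            aggfunc="first",
        )
    needed = [baseline_time, worn_time, regen_time]
    missing_cols = [t for t in needed if t not in piv.columns]
    if missing_cols:
        raise ValueError(f"retention table has no eluted records at {missing_cols}")
    complete = piv[needed].notna().all(axis=1)
    excluded = tuple(piv.index[~complete])
    piv = piv[complete]

    tr0 = piv[baseline_time].to_numpy(dtype=float)
    tr12 = piv[worn_time].to_numpy(dtype=float)
    trr = piv[regen_time].to_numpy(dtype=float)
    pct_error_r = 100.0 * (tr0 - trr) / tr0
    diff_0_12 = 100.0 * (tr0 - tr12) / tr0
    out = pd.DataFrame(
        {
            "pct_error_R": pct_error_r,
            "diff_0_12": diff_0_12,
            "diff_0_R": pct_error_r,
            "effective": np.abs(pct_error_r) < np.abs(diff_0_12),
            "within_tolerance": np.abs(pct_error_r) <= tolerance_pct,
        },
        index=piv.index,
    ).reset_index()
    if have_width:
        wsel = wpiv.reindex(piv.index)
        if regen_time in wsel.columns and worn_time in wsel.columns:
            out["width_delta_R_minus_12M"] = (
                wsel[regen_time].to_numpy(dtype=float) - wsel[worn_time].to_numpy(dtype=float)
            )

    summary = (
        out.groupby(["column_id", "modifier_id"])
        .agg(
            n=("pct_error_R", "size"),
            fraction_within_tolerance=("within_tolerance", "mean"),
            fraction_effective=("effective", "mean"),
            median_abs_pct_error=("pct_error_R", lambda s: float(np.median(np.abs(s)))),
        )
        .reset_index()
    )
    return RegenerationReport(data=out, summary=summary, excluded=excluded)
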