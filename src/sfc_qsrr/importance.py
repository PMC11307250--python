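"""Descriptor-importance selections from trained input weights.

Key descriptors are those whose absolute input weight exceeds a threshold
(default 1.5 on the normalized training scale); signed top-k tables list the
descriptors most strongly increasing/decreasing retention. Ties are broken by
descriptor name so every report is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ann import WeightVector


@dataclass(frozen=True)
class ImportanceReport:
    condition: tuple[str, str, str] | None
    key_descriptors: tuple[tuple[str, float], ...]  # (name, weight), |w| descending
    top_positive: tuple[tuple[str, float], ...]
    top_negative: tuple[tuple[str, float], ...]
    threshold: float
    k: int

    def __post_init__(self) -> None:
        pos = {n for n, _ in self.top_positive}
        neg = {n for n, _ in self.top_negative}
        if pos & neg:
            raise ValueError(f"top_positive and top_negative overlap: {pos & neg}")

    def to_frame(self) -> pd.DataFrame:
        """One row per key descriptor: name, weight, |weight|, rank."""
        rows = [
            {"descriptor": n, "weight": w, "abs_weight": abs(w), "rank": i + 1}
            for i, (n, w) in enumerate(self.key_descriptors)
        ]
        return pd.DataFrame(rows, columns=["descriptor", "weight", "abs_weight", "rank"])


def select_key_descriptors(
    wv: WeightVector, threshold: float = 1.5
) -> ImportanceReport:
    """Descriptors with ``|w| > threshold`` (strict), ranked by |w| descending."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    order = sorted(
        zip(wv.descriptor_names, wv.weights),
        key=lambda nw: (-abs(nw[1]), nw[0]),
    )
    key = tuple((n, float(w)) for n, w in order if abs(w) > threshold)
    top_pos, top_neg = top_signed(wv, k=min(10, len(wv.descriptor_names)))
    return ImportanceReport(
        condition=wv.condition,
        key_descriptors=key,
        top_positive=top_pos,
        top_negative=top_neg,
        threshold=threshold,
        k=10,
    )


def top_signed(wv: WeightVector, k: int = 10):
    """The k most retention-increasing and k most retention-decreasing descriptors.

    Positive side is sorted by descending weight, negative side by ascending
    weight; ties go to the lexicographically smaller name.
    """
    if k > len(wv.descriptor_names):
        raise ValueError(f"k={k} exceeds number of descriptors {len(wv.descriptor_names)}")
    pairs = list(zip(wv.descriptor_names, (float(w) for w in wv.weights)))
    by_desc = sorted(pairs, key=lambda nw: (-nw[1], nw[0]))
    by_asc = sorted(pairs, key=lambda nw: (nw[1], nw[0]))
    top_pos = tuple(by_desc[:k])
    top_neg = tuple(by_asc[:k])
    overlap = {n for n, _ in top_pos} & {n for n, _ in top_neg}
    if overlap:  # k too large for a strictly signed split
        top_neg = tuple(nw for nw in by_asc if nw[0] not in {n for n, _ in top_pos})[:k]
    return top_pos, top_neg


def weight_rank(wv: WeightVector, name: str) -> int:
    """1-based rank of ``name`` by |weight| descending (ties by name)."""
    if name not in wv.descriptor_names:
        raise KeyError(f"unknown descriptor {name!r}")
    order = sorted(
        zip(wv.descriptor_names, wv.weights),
        key=lambda nw: (-abs(nw[1]), nw[0]),
    )
    return next(i + 1 for i, (n, _) in enumerate(order) if n == name)


def compare_weight_sets(wv1: WeightVector, wv2: WeightVector, ddof: int = 0):
    """Per-descriptor weight deltas between two conditions plus their spread.

    Returns ``(deltas, sd)`` where ``deltas`` is a Series (w2 - w1) sorted by
    |delta| descending and ``sd`` the standard deviation over deltas
    (population formula by default, ``ddof=1`` for the sample formula).
    """
    if tuple(wv1.descriptor_names) != tuple(wv2.descriptor_names):
        raise ValueError("weight vectors have different descriptor names")
    delta = np.asarray(wv2.weights, dtype=float) - np.asarray(wv1.weights, dtype=float)
    s = pd.Series(delta, index=list(wv1.descriptor_names))
    s = s.iloc[np.lexsort((s.index, -np.abs(s.to_numpy())))]
    return s, float(np.std(delta, ddof=ddof))


def weight_table(reports: dict[tuple, WeightVector]) -> pd.DataFrame:
    """Wide heatmap-ready table: descriptors x condition tags."""
    cols = {}
    for tag, wv in reports.items():
        label = "|".join(str(t) for t in tag) if isinstance(tag, tuple) else str(tag)
        cols[label] = pd.Series(wv.weights, index=list(wv.descriptor_names))
    return pd.DataFrame(cols)
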