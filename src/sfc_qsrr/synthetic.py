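"""Synthetic SFC column-aging studies with known ground truth.

The generator emulates the structure of a year-long retention-stability study:
~107 compounds described by 226 molecular descriptors, measured on three
-OH-bearing stationary phases (silica, hybrid BEH silica, diol) with three
organic modifiers (MeOH, MeOH + H2O, MeOH + NH3) at eight time points (monthly
and quarterly injections over 12 months plus a post-regeneration injection
"R").

Retention is generated through the same link the QSRR network assumes: the
retention factor of compound *i* under condition *c* at time *t* is

    k' = k_max * sigmoid(w(c, t) . x_i + b_c) + eps,   eps ~ N(0, noise_sd)

with ``x_i`` the max-normalized descriptor vector and ``w(c, t)`` a sparse
per-condition weight vector. Column aging is injected in weight space as
scheduled offsets on named descriptors (zero at baseline), mirroring the
interpretation of retention drift as changing stationary-phase interactions;
the stylized aging signature couples compound classes to two designated count
descriptors ("nAcid", "nBase") so that acids lose and bases gain retention.

Descriptor columns are drawn with the strong collinearity characteristic of
descriptor calculators: a "distinctive" subset carries independent variation,
and the remainder falls into correlated blocks of near-redundant columns.
Planted nonzero weights always sit on distinctive columns — importance planted
on a near-duplicate of other columns would not be attributable even in
principle, making parameter-recovery benchmarks ill-posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ann import WeightVector, _sigmoid
from .io_tables import DEFAULT_TIME_POINTS, DescriptorTable, RetentionTable

Condition = tuple[str, str]  # (stationary phase / column id, organic modifier id)

DEFAULT_CONDITIONS: tuple[Condition, ...] = tuple(
    (col, mod)
    for col in ("silica", "BEH", "diol")
    for mod in ("MeOH", "MeOH+H2O", "MeOH+NH3")
)

ACID_DESCRIPTOR = "nAcid"
BASE_DESCRIPTOR = "nBase"

#: schedule[condition][time_point][descriptor_name] -> additive weight offset
DriftSchedule = Mapping[Condition, Mapping[str, Mapping[str, float]]]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic experiment.

    Defaults emulate the deposited study's scale: 107 compounds, 226
    descriptors, nine stationary-phase/modifier combinations and eight time
    points. ``n_informative`` descriptors per condition (always including the
    class-linked "nAcid"/"nBase" counts) carry nonzero baseline weights of
    magnitude ~``effect_scale``; ``noise_sd`` is additive noise on the
    retention factor; ``elution_prob`` is the per-condition chance a compound
    elutes at all.
    """

    n_compounds: int = 107
    n_descriptors: int = 226
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    baseline_time: str = "0M"
    regeneration_time: str = "R"
    n_informative: int = 20
    effect_scale: float = 2.5
    noise_sd: float = 0.1
    drift_schedule: DriftSchedule | None = None
    class_fractions: tuple[tuple[str, float], ...] = (
        ("acidic", 0.3),
        ("basic", 0.3),
        ("neutral", 0.3),
        ("both", 0.1),
    )
    elution_prob: float | tuple[tuple[Condition, float], ...] = 0.8
    k_max: float = 20.0
    t0: float = 1.0
    # descriptor collinearity structure
    n_distinctive: int = 40
    n_null_groups: int = 30
    within_group_corr: float = 0.9
    # conditions sharing a label draw identical baseline weights
    weight_groups: tuple[tuple[Condition, str], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds <= 0 or self.n_descriptors <= 0:
            raise ValueError("n_compounds and n_descriptors must be positive")
        if not (2 <= self.n_informative <= self.n_descriptors):
            raise ValueError("need 2 <= n_informative <= n_descriptors")
        if self.n_informative > self.n_distinctive:
            raise ValueError("n_informative cannot exceed n_distinctive")
        if self.n_distinctive > self.n_descriptors:
            raise ValueError("n_distinctive cannot exceed n_descriptors")
        fr = dict(self.class_fractions)
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {sum(fr.values())}")
        if self.baseline_time not in self.time_points:
            raise ValueError(f"baseline {self.baseline_time!r} not in time_points")
        if self.regeneration_time not in self.time_points:
            raise ValueError(f"regeneration label {self.regeneration_time!r} not in time_points")
        if self.drift_schedule:
            for cond, per_tp in self.drift_schedule.items():
                if tuple(cond) not in self.conditions:
                    raise ValueError(f"drift schedule references unknown condition {cond}")
                for tp, offs in per_tp.items():
                    if tp not in self.time_points:
                        raise ValueError(f"drift schedule references unknown time label {tp!r}")
                    if tp == self.baseline_time and any(v != 0 for v in offs.values()):
                        raise ValueError("drift offsets must be zero at the baseline time point")

    @classmethod
    def scaled(
        cls,
        n_compounds: int,
        n_descriptors: int,
        n_informative: int | None = None,
        **kwargs,
    ) -> "SyntheticConfig":
        """Config with the descriptor collinearity structure scaled to size.

        Keeps the default proportions (~18 % distinctive columns, null blocks
        of ~6 near-redundant columns) for descriptor tables smaller than the
        default 226.
        """
        if n_informative is None:
            n_informative = max(2, round(n_descriptors * 0.09))
        n_distinctive = min(max(n_informative, round(n_descriptors * 0.18)), n_descriptors)
        n_null_groups = max(1, min(30, round((n_descriptors - n_distinctive) / 6)))
        return cls(
            n_compounds=n_compounds,
            n_descriptors=n_descriptors,
            n_informative=n_informative,
            n_distinctive=n_distinctive,
            n_null_groups=n_null_groups,
            **kwargs,
        )

    def elution_prob_for(self, condition: Condition) -> float:
        if isinstance(self.elution_prob, (int, float)):
            return float(self.elution_prob)
        return dict(self.elution_prob)[condition]


@dataclass
class SyntheticGroundTruth:
    """Planted truth: per-condition weight vectors, drift, classes, elution."""

    descriptor_names: tuple[str, ...]
    baseline_weights: dict[Condition, np.ndarray]
    bias: dict[Condition, float]
    drift_schedule: dict[Condition, dict[str, dict[str, float]]]
    compound_classes: dict[str, str]
    elution_mask: dict[Condition, np.ndarray]  # aligned with compound order
    compound_ids: tuple[str, ...]
    informative: dict[Condition, tuple[str, ...]]
    config: SyntheticConfig
    seed: int

    def weights_at(self, condition: Condition, time_point: str) -> np.ndarray:
        return apply_drift(self, condition, time_point)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "descriptor_names": list(self.descriptor_names),
            "compound_ids": list(self.compound_ids),
            "compound_classes": self.compound_classes,
            "baseline_weights": {
                "|".join(c): w.tolist() for c, w in self.baseline_weights.items()
            },
            "bias": {"|".join(c): b for c, b in self.bias.items()},
            "informative": {"|".join(c): list(v) for c, v in self.informative.items()},
            "elution_mask": {
                "|".join(c): m.astype(int).tolist() for c, m in self.elution_mask.items()
            },
            "drift_schedule": {
                "|".join(c): per_tp for c, per_tp in self.drift_schedule.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def apply_drift(
    truth: SyntheticGroundTruth, condition: Condition, time_point: str
) -> np.ndarray:
    """Baseline weights plus the scheduled offsets at ``time_point``."""
    condition = tuple(condition)
    if condition not in truth.baseline_weights:
        raise KeyError(f"unknown condition {condition}")
    if time_point not in truth.config.time_points:
        raise KeyError(f"unknown time point {time_point!r}")
    w = truth.baseline_weights[condition].copy()
    offsets = truth.drift_schedule.get(condition, {}).get(time_point, {})
    name_to_idx = {n: i for i, n in enumerate(truth.descriptor_names)}
    for name, off in offsets.items():
        w[name_to_idx[name]] += off
    return w


def class_drift_schedule(
    conditions: Sequence[Condition],
    time_points: Sequence[str] = DEFAULT_TIME_POINTS,
    onset: str = "2M",
    magnitude: float = 2.5,
    regen_recovery: float = 0.5,
    regeneration_time: str = "R",
) -> dict[Condition, dict[str, dict[str, float]]]:
    """Stylized aging schedule: acids lose retention, bases gain, from ``onset``.

    The weight on "nAcid" drops by ``magnitude`` and the weight on "nBase"
    rises by ``magnitude`` from the onset time point onward. At the
    post-regeneration point the offsets shrink to ``(1 - regen_recovery)`` of
    their 12M value (``regen_recovery=1`` restores the column fully).
    """
    time_points = list(time_points)
    if onset not in time_points:
        raise ValueError(f"onset {onset!r} not among time points {time_points}")
    start = time_points.index(onset)
    schedule: dict[Condition, dict[str, dict[str, float]]] = {}
    for cond in conditions:
        per_tp: dict[str, dict[str, float]] = {}
        for i, tp in enumerate(time_points):
            if i < start:
                continue
            scale = (1.0 - regen_recovery) if tp == regeneration_time else 1.0
            if scale == 0.0:
                continue
            per_tp[tp] = {
                ACID_DESCRIPTOR: -magnitude * scale,
                BASE_DESCRIPTOR: +magnitude * scale,
            }
        schedule[tuple(cond)] = per_tp
    return schedule


def _descriptor_matrix(cfg: SyntheticConfig, rng: np.random.Generator, classes: np.ndarray):
    """Raw descriptor values: distinctive columns + correlated null blocks."""
    n, p = cfg.n_compounds, cfg.n_descriptors
    names = [ACID_DESCRIPTOR, BASE_DESCRIPTOR] + [f"MD{j:03d}" for j in range(3, p + 1)]
    X = np.empty((n, p))
    X[:, 0] = np.where(
        np.isin(classes, ["acidic", "both"]), 1 + rng.poisson(1.0, n), 0
    )
    X[:, 1] = np.where(
        np.isin(classes, ["basic", "both"]), 1 + rng.poisson(1.0, n), 0
    )
    distinctive = np.concatenate(
        [[0, 1], 2 + rng.choice(p - 2, cfg.n_distinctive - 2, replace=False)]
    )
    is_distinctive = np.zeros(p, dtype=bool)
    is_distinctive[distinctive] = True

    factors = rng.normal(0.0, 1.0, (n, cfg.n_null_groups))
    group_of = rng.integers(0, cfg.n_null_groups, p)
    rho = cfg.within_group_corr
    for j in range(2, p):
        if is_distinctive[j]:
            latent = rng.normal(0.0, 1.0, n)
        else:
            latent = np.sqrt(rho) * factors[:, group_of[j]] + np.sqrt(1 - rho) * rng.normal(
                0.0, 1.0, n
            )
        kind = rng.integers(0, 4)
        if kind == 0:  # positive-mean continuous (surface areas, volumes, ...)
            X[:, j] = rng.uniform(1.0, 4.0) + latent
        elif kind == 1:  # count-like (ring/bond/atom counts)
            lam = rng.uniform(1.0, 6.0)
            X[:, j] = stats.poisson.ppf(stats.norm.cdf(latent), lam)
        elif kind == 2:  # right-skewed positive (topological indices)
            X[:, j] = np.exp(0.3 + 0.5 * latent)
        else:  # strictly negative (BCUTc-1l-like charge eigenvalues)
            X[:, j] = -np.exp(0.2 + 0.4 * latent) - 0.5
    return pd.DataFrame(X, columns=names), distinctive


def generate_study(
    config: SyntheticConfig,
) -> tuple[DescriptorTable, RetentionTable, SyntheticGroundTruth]:
    """Generate one complete study: descriptors, retention records, ground truth.

    Deterministic given ``config.seed``: two runs with the same configuration
    produce byte-identical tables.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    compound_ids = tuple(f"C{i + 1:03d}" for i in range(cfg.n_compounds))
    labels = [c for c, _ in cfg.class_fractions]
    probs = [f for _, f in cfg.class_fractions]
    classes = rng.choice(labels, size=cfg.n_compounds, p=probs)

    raw, distinctive = _descriptor_matrix(cfg, rng, classes)
    raw.index = pd.Index(compound_ids, name="compound_id")
    desc = DescriptorTable(data=raw, normalized=False)
    colmax = np.max(np.abs(raw.to_numpy()), axis=0)
    colmax[colmax == 0] = 1.0
    Xn = raw.to_numpy() / colmax

    names = tuple(raw.columns)
    name_to_idx = {n: i for i, n in enumerate(names)}

    # baseline weights per condition (shared within a weight group)
    wgroups = dict(cfg.weight_groups) if cfg.weight_groups else {
        tuple(c): "|".join(c) for c in cfg.conditions
    }
    group_w: dict[str, tuple[np.ndarray, tuple[str, ...]]] = {}
    baseline: dict[Condition, np.ndarray] = {}
    informative: dict[Condition, tuple[str, ...]] = {}
    other_distinct = np.array([j for j in distinctive if j > 1])
    for cond in cfg.conditions:
        cond = tuple(cond)
        g = wgroups[cond]
        if g not in group_w:
            idx = np.concatenate(
                [[0, 1], rng.choice(other_distinct, cfg.n_informative - 2, replace=False)]
            )
            mags = cfg.effect_scale * rng.uniform(0.8, 1.0, cfg.n_informative)
            signs = rng.choice([-1.0, 1.0], cfg.n_informative)
            signs[0] = 1.0  # acids retained at baseline
            signs[1] = 1.0  # bases retained at baseline
            w = np.zeros(cfg.n_descriptors)
            w[idx] = mags * signs
            group_w[g] = (w, tuple(names[j] for j in idx))
        baseline[cond], informative[cond] = group_w[g]

    bias = {c: float(-np.median(Xn @ baseline[c])) for c in baseline}
    elution = {
        c: rng.random(cfg.n_compounds) < cfg.elution_prob_for(c) for c in baseline
    }

    schedule = {
        tuple(c): {tp: dict(offs) for tp, offs in per.items()}
        for c, per in (cfg.drift_schedule or {}).items()
    }
    truth = SyntheticGroundTruth(
        descriptor_names=names,
        baseline_weights=baseline,
        bias=bias,
        drift_schedule=schedule,
        compound_classes=dict(zip(compound_ids, classes.tolist())),
        elution_mask=elution,
        compound_ids=compound_ids,
        informative=informative,
        config=cfg,
        seed=cfg.seed,
    )

    records = []
    for cond in cfg.conditions:
        cond = tuple(cond)
        mask = elution[cond]
        for tp in cfg.time_points:
            w = apply_drift(truth, cond, tp)
            z = Xn @ w + bias[cond]
            kp = cfg.k_max * _sigmoid(z)
            if cfg.noise_sd > 0:
                kp = kp + rng.normal(0.0, cfg.noise_sd, cfg.n_compounds)
            kp = np.maximum(kp, 0.0)
            tr = cfg.t0 * (1.0 + kp)
            width = 0.05 + 0.02 * tr
            for i, cid in enumerate(compound_ids):
                if mask[i]:
                    records.append(
                        (cid, cond[0], cond[1], tp, tr[i], width[i], kp[i], True)
                    )
                else:
                    records.append(
                        (cid, cond[0], cond[1], tp, np.nan, np.nan, np.nan, False)
                    )
    retention = RetentionTable(
        data=pd.DataFrame(
            records,
            columns=[
                "compound_id",
                "column_id",
                "modifier_id",
                "time_point",
                "t_r",
                "peak_width_5pct",
                "k_prime",
                "eluted",
            ],
        ),
        time_points=cfg.time_points,
    )
    return desc, retention, truth


def evaluate_recovery(
    wv: WeightVector,
    truth: SyntheticGroundTruth,
    condition: Condition,
    time_point: str | None = None,
    threshold: float = 1.5,
) -> dict[str, float | bool]:
    """Score a trained weight vector against the planted truth.

    Trained weights recover the planted vector only up to a positive scale
    (target normalization attenuates them), so they are first rescaled by the
    least-squares attenuation factor ``a = <w_hat, w*> / <w*, w*>`` and then
    thresholded at ``threshold`` against the planted informative set.
    """
    condition = tuple(condition)
    tp = time_point or truth.config.baseline_time
    w_true = truth.weights_at(condition, tp)
    if tuple(wv.descriptor_names) != tuple(truth.descriptor_names):
        raise ValueError("weight vector descriptors do not match the study's")
    w_hat = wv.weights
    a = float(w_hat @ w_true) / float(w_true @ w_true)
    if a <= 0:
        return {
            "precision": 0.0,
            "recall": 0.0,
            "sign_all_correct": False,
            "sign_fraction": 0.0,
            "scale": a,
        }
    rescaled = w_hat / a
    selected = np.abs(rescaled) > threshold
    informative = w_true != 0
    tp_count = int(np.sum(selected & informative))
    precision = tp_count / int(selected.sum()) if selected.any() else 0.0
    recall = tp_count / int(informative.sum())
    signs_ok = np.sign(rescaled[informative]) == np.sign(w_true[informative])
    return {
        "precision": float(precision),
        "recall": float(recall),
        "sign_all_correct": bool(np.all(signs_ok)),
        "sign_fraction": float(np.mean(signs_ok)),
        "scale": a,
    }
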