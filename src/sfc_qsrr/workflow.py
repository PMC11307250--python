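"""End-to-end orchestration: train per-condition networks, derive every report.

The pipeline mirrors the analysis order of a retention-stability study: read
(or simulate) descriptor and retention tables, normalize, fit one network per
(stationary phase, modifier, time point), extract weights, then derive
importance tables, weight-stability statistics, percent-shift reports, the
regeneration evaluation and the cross-condition PCA. Identical configuration
and seed give identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ann import AnnConfig, TrainedModel, WeightVector, extract_weights, train
from .compare import condition_distances, pca_weights
from .importance import select_key_descriptors, weight_table
from .io_tables import (
    DescriptorTable,
    RetentionTable,
    add_k_prime,
    build_compound_sets,
    normalize_by_max,
    read_descriptors,
    read_retention,
)
from .regeneration import evaluate_regeneration
from .stability import apply_limit, derive_stability_limit, percent_shift, weight_sd
from .synthetic import SyntheticConfig, generate_study

log = logging.getLogger("sfc_qsrr")

#: Converged training configuration for descriptor-importance analysis.
#: The historical default (500 cycles at rate 0.05) underconverges on
#: studies of ~100 compounds x 226 descriptors; importance and stability
#: analyses in this package use this setting unless told otherwise.
CONVERGED_ANN = AnnConfig(learning_rate=1.0, epochs=10000, init_scale=0.01)


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: exactly one of (descriptor+retention paths, synthetic config)."""

    descriptors_path: str | None = None
    retention_path: str | None = None
    synthetic: SyntheticConfig | None = None
    ann: AnnConfig = AnnConfig()
    importance_threshold: float = 1.5
    top_k: int = 10
    baseline_time: str = "0M"
    reference_condition: tuple[str, str] | None = None
    sd_limit: float | None = None
    include_regeneration_in_sd: bool = True
    t0: float = 1.0
    norm_mode: str = "abs-max"
    n_pca_components: int = 2
    skip_ann: bool = False
    out_dir: str = "sfc_qsrr_run"
    seed: int = 0

    def __post_init__(self) -> None:
        real = self.descriptors_path is not None or self.retention_path is not None
        if real == (self.synthetic is not None):
            raise ValueError("provide exactly one of real input paths or a synthetic config")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def normalized_targets(k_prime: np.ndarray) -> np.ndarray:
    """Retention factors normalized by their maximal value, as model targets."""
    kp = np.asarray(k_prime, dtype=float)
    m = kp.max()
    if m <= 0:
        raise ValueError("retention factors are all <= 0; cannot normalize")
    return kp / m


def model_seed(base_seed: int, index: int) -> int:
    """Deterministic per-model seed derived from the run seed (kept below 2^31)."""
    return (base_seed * 100003 + 7919 * index + 1) % (2**31)


def fit_condition_models(
    descriptors: DescriptorTable,
    retention: RetentionTable,
    ann_config: AnnConfig,
    base_seed: int = 0,
    conditions: list[tuple[str, str]] | None = None,
    time_points: list[str] | None = None,
) -> dict[tuple[str, str, str], TrainedModel]:
    """Train one network per (column, modifier, time point) on eluting compounds.

    ``descriptors`` must already be normalized; targets are that model's
    retention factors divided by their maximum.
    """
    if not descriptors.normalized:
        raise ValueError("normalize the descriptor table before training")
    conds = conditions or retention.conditions
    tps = time_points or list(retention.time_points)
    models: dict[tuple[str, str, str], TrainedModel] = {}
    idx = 0
    for col, mod in conds:
        for tp in tps:
            sub = retention.select(column_id=col, modifier_id=mod, time_point=tp, eluted_only=True)
            if sub.empty:
                log.warning("no eluted records for %s/%s at %s; skipped", col, mod, tp)
                continue
            if sub["k_prime"].isna().any():
                raise ValueError(
                    f"missing k_prime for {col}/{mod} at {tp}; call add_k_prime first"
                )
            X = descriptors.subset(sub["compound_id"].tolist())
            y = normalized_targets(sub["k_prime"].to_numpy(dtype=float))
            cfg = dataclasses.replace(ann_config, seed=model_seed(base_seed, idx))
            models[(col, mod, tp)] = train(X, y, cfg, condition=(col, mod, tp))
            idx += 1
    return models


def weight_matrix(models: dict[tuple[str, str, str], TrainedModel]) -> pd.DataFrame:
    """Stack extracted weight vectors into a (condition-tag x descriptor) matrix."""
    rows = {}
    for tag, model in models.items():
        rows["|".join(tag)] = extract_weights(model).as_series()
    return pd.DataFrame(rows).T


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=index)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write the artifact directory; returns its path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    log.info("run config hash %s (seed %d)", h, config.seed)

    stage = "load"
    try:
        if config.synthetic is not None:
            sc = dataclasses.replace(config.synthetic, seed=config.seed)
            desc_raw, retention, truth = generate_study(sc)
            truth.to_json(out / "ground_truth.json")
            desc_raw.to_csv(out / "descriptors.csv")
            retention.to_csv(out / "retention.csv")
        else:
            desc_raw = (
                read_descriptors(config.descriptors_path) if config.descriptors_path else None
            )
            retention = read_retention(config.retention_path)
        retention = add_k_prime(retention, config.t0)

        stage = "normalize"
        desc_norm = None
        if desc_raw is not None:
            desc_norm = normalize_by_max(desc_raw, mode=config.norm_mode)
            _write_csv(desc_norm.data, out / "descriptors_normalized.csv", h)
            if desc_norm.degenerate_columns:
                log.info("degenerate (all-zero) columns: %s", desc_norm.degenerate_columns)

        stage = "compound-sets"
        sets = {}
        for mod in sorted({m for _, m in retention.conditions}):
            triple = build_compound_sets(retention, mod, config.baseline_time)
            sets[mod] = {
                "original": sorted(triple.original),
                "narrowed": sorted(triple.narrowed),
                "extended": {c: sorted(v) for c, v in triple.extended.items()},
            }
        (out / "compound_sets.json").write_text(
            json.dumps({"config_hash": h, "sets": sets}, indent=1)
        )

        stage = "shifts"
        shifts = percent_shift(retention, config.baseline_time)
        _write_csv(shifts.data, out / "shift_report.csv", h, index=False)
        _write_csv(shifts.binned_counts(), out / "shift_binned_counts.csv", h)

        stage = "regeneration"
        tps = set(retention.data["time_point"])
        if {"12M", "R"} <= tps:
            regen = evaluate_regeneration(retention, baseline_time=config.baseline_time)
            _write_csv(regen.data, out / "regeneration_report.csv", h, index=False)
            _write_csv(regen.summary, out / "regeneration_summary.csv", h, index=False)

        models: dict[tuple[str, str, str], TrainedModel] = {}
        if not config.skip_ann:
            if desc_norm is None:
                raise ValueError("descriptor table required unless skip_ann is set")
            stage = "train"
            models = fit_condition_models(
                desc_norm, retention, config.ann, base_seed=config.seed
            )
            wdir = out / "weights"
            wdir.mkdir(exist_ok=True)
            for tag, model in models.items():
                model.save(wdir / ("_".join(tag).replace("/", "-") + ".json"))
            wm = weight_matrix(models)
            _write_csv(wm, out / "weight_matrix.csv", h)

            stage = "importance"
            reports = {}
            for tag, model in models.items():
                wv = extract_weights(model)
                rep = select_key_descriptors(wv, config.importance_threshold)
                reports[tag] = wv
                _write_csv(
                    rep.to_frame(),
                    out / f"importance_{'_'.join(tag).replace('/', '-')}.csv",
                    h,
                    index=False,
                )
            _write_csv(weight_table(reports), out / "weight_table_wide.csv", h)

            stage = "stability"
            per_cond: dict[tuple[str, str], dict[str, WeightVector]] = {}
            for (col, mod, tp), model in models.items():
                if tp == "R" and not config.include_regeneration_in_sd:
                    continue
                per_cond.setdefault((col, mod), {})[tp] = extract_weights(model)
            sd_reports = {
                cond: weight_sd(series, condition=cond)
                for cond, series in per_cond.items()
                if len(series) >= 2
            }
            if sd_reports:
                if config.sd_limit is not None:
                    limit = config.sd_limit
                elif config.reference_condition is not None:
                    limit = derive_stability_limit(sd_reports, config.reference_condition)
                else:
                    limit = None
                if limit is not None:
                    sd_reports = apply_limit(sd_reports, limit)
                sd_frame = pd.DataFrame(
                    {"|".join(c): r.sd_over_time for c, r in sd_reports.items()}
                )
                _write_csv(sd_frame, out / "weight_sd.csv", h)
                if limit is not None:
                    summary = pd.DataFrame(
                        [
                            {
                                "condition": "|".join(c),
                                "limit": limit,
                                "n_exceeding": r.n_exceeding,
                            }
                            for c, r in sd_reports.items()
                        ]
                    )
                    _write_csv(summary, out / "weight_sd_exceedance.csv", h, index=False)

            stage = "pca"
            wm_baseline = weight_matrix(
                {t: m for t, m in models.items() if t[2] == config.baseline_time}
            )
            if wm_baseline.shape[0] >= 2:
                k = min(config.n_pca_components, wm_baseline.shape[0] - 1, wm_baseline.shape[1])
                pca = pca_weights(wm_baseline, n_components=max(k, 1))
                _write_csv(pca.scores, out / "pca_scores.csv", h)
                _write_csv(pca.loadings, out / "pca_loadings.csv", h)
                dists, nn = condition_distances(pca.scores)
                _write_csv(dists, out / "pca_distances.csv", h)
                _write_csv(nn.to_frame(), out / "pca_nearest_neighbors.csv", h)

        stage = "manifest"
        manifest = {
            "config_hash": h,
            "seed": config.seed,
            "package_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config": dataclasses.asdict(config),
            "n_models": len(models),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    except Exception:
        log.error("pipeline failed in stage %r", stage)
        raise
    return out
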