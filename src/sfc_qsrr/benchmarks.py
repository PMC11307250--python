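"""Ground-truth benchmarks run on synthetic studies.

Each function regenerates studies under the package's default study
conditions, runs the full modeling path, and scores it against the planted
truth: key-descriptor recovery, detection of injected weight drift, and
clustering of conditions that share a retention mechanism. They are the
package's self-evaluation surface; the stochastic rates they return are
averaged (or counted) over independently seeded studies.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ann import AnnConfig, extract_weights, gradients, train
from .compare import condition_distances, pca_weights
from .io_tables import normalize_by_max
from .regeneration import evaluate_regeneration
from .stability import derive_stability_limit, fraction_exceeding, percent_shift, weight_sd
from .synthetic import (
    ACID_DESCRIPTOR,
    BASE_DESCRIPTOR,
    SyntheticConfig,
    class_drift_schedule,
    evaluate_recovery,
    generate_study,
)
from .workflow import CONVERGED_ANN, fit_condition_models, model_seed, normalized_targets, weight_matrix


def gradient_check(seed: int = 0, n_instances: int = 5) -> float:
    """Largest relative error between analytic and central-difference gradients."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n, p, h = 10, 4, 3
        X = rng.uniform(-1, 1, (n, p))
        y = rng.uniform(0.05, 0.95, n)
        for arch in ("direct", "hidden"):
            if arch == "direct":
                params = {"w": rng.normal(0, 1, p), "b": np.array(rng.normal())}
            else:
                params = {
                    "W1": rng.normal(0, 1, (p, h)),
                    "b1": rng.normal(0, 1, h),
                    "w2": rng.normal(0, 1, h),
                    "b2": np.array(rng.normal()),
                }
            grads = gradients(params, arch, X, y)
            eps = 1e-6
            from .ann import _forward

            def loss(pp):
                yhat, _ = _forward(pp, arch, X)
                return float(np.mean((yhat - y) ** 2))

            for key in params:
                shape = np.shape(params[key])
                for idx in np.ndindex(*shape) if shape else [()]:
                    pp = {k: np.array(v, dtype=float) for k, v in params.items()}
                    pm = {k: np.array(v, dtype=float) for k, v in params.items()}
                    if shape:
                        pp[key][idx] += eps
                        pm[key][idx] -= eps
                    else:
                        pp[key] = pp[key] + eps
                        pm[key] = pm[key] - eps
                    fd = (loss(pp) - loss(pm)) / (2 * eps)
                    ga = np.asarray(grads[key]).reshape(shape)[idx] if shape else float(grads[key])
                    denom = max(abs(fd), abs(ga), 1e-5)
                    worst = max(worst, abs(fd - ga) / denom)
    return worst


def _single_condition_config(seed: int, **overrides) -> SyntheticConfig:
    base = dict(
        conditions=(("silica", "MeOH"),),
        elution_prob=1.0,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def fit_baseline_weights(config: SyntheticConfig, ann: AnnConfig, train_seed: int):
    """Generate a study, fit the baseline model of its first condition, and
    return (weight vector, truth)."""
    desc, retention, truth = generate_study(config)
    dn = normalize_by_max(desc)
    cond = config.conditions[0]
    sub = retention.select(cond[0], cond[1], time_point=config.baseline_time, eluted_only=True)
    y = normalized_targets(sub["k_prime"].to_numpy(dtype=float))
    model = train(
        dn.subset(sub["compound_id"].tolist()),
        y,
        dataclasses.replace(ann, seed=train_seed),
        condition=(cond[0], cond[1], config.baseline_time),
    )
    return extract_weights(model), truth


def recovery_benchmark(
    n_seeds: int = 10,
    base_seed: int = 0,
    ann: AnnConfig = CONVERGED_ANN,
    threshold: float = 1.5,
) -> dict:
    """Key-descriptor recovery on default-scale studies (107 x 226, 20 planted).

    Returns mean precision/recall of the thresholded key-descriptor set
    against the planted informative descriptors, the weight-recovery Pearson
    correlation, and the number of seeds where every planted sign was
    recovered.
    """
    precs, recs, rs, sign_ok = [], [], [], 0
    for i in range(n_seeds):
        cfg = _single_condition_config(seed=base_seed + i)
        wv, truth = fit_baseline_weights(cfg, ann, model_seed(base_seed, i))
        res = evaluate_recovery(wv, truth, cfg.conditions[0], threshold=threshold)
        precs.append(res["precision"])
        recs.append(res["recall"])
        sign_ok += bool(res["sign_all_correct"])
        w_true = truth.baseline_weights[cfg.conditions[0]]
        rs.append(float(np.corrcoef(wv.weights, w_true)[0, 1]))
    return {
        "n_seeds": n_seeds,
        "precision_mean": float(np.mean(precs)),
        "recall_mean": float(np.mean(recs)),
        "pearson_r_mean": float(np.mean(rs)),
        "n_all_signs_correct": int(sign_ok),
        "precision_per_seed": precs,
        "recall_per_seed": recs,
    }


def drift_benchmark(
    n_seeds: int = 10,
    base_seed: int = 0,
    ann: AnnConfig = CONVERGED_ANN,
    magnitude: float = 2.5,
) -> dict:
    """Detection of a class-linked weight drift injected from 2M onward.

    One condition drifts (acid weight down, base weight up from month 2,
    half-reverted after regeneration), a second stays stable and serves as
    the reference for the derived SD limit. Detection = both drifting
    descriptors exceed the limit; class consistency = >= 90 % of acidic
    compounds lose and >= 90 % of basic compounds gain retention at 12M.
    """
    drifting = ("silica", "MeOH")
    reference = ("diol", "MeOH")
    detected = 0
    class_consistent = 0
    sd_drifted, limits = [], []
    for i in range(n_seeds):
        sched = class_drift_schedule([drifting], magnitude=magnitude)
        cfg = SyntheticConfig(
            conditions=(drifting, reference),
            drift_schedule=sched,
            seed=base_seed + i,
        )
        desc, retention, truth = generate_study(cfg)
        dn = normalize_by_max(desc)
        models = fit_condition_models(dn, retention, ann, base_seed=base_seed + i)
        series: dict[tuple[str, str], dict] = {}
        for (col, mod, tp), model in models.items():
            series.setdefault((col, mod), {})[tp] = extract_weights(model)
        reports = {c: weight_sd(s, condition=c) for c, s in series.items()}
        limit = derive_stability_limit(reports, reference)
        sd = reports[drifting].sd_over_time
        hit = bool(sd[ACID_DESCRIPTOR] > limit and sd[BASE_DESCRIPTOR] > limit)
        detected += hit
        sd_drifted.append(float(max(sd[ACID_DESCRIPTOR], sd[BASE_DESCRIPTOR])))
        limits.append(float(limit))

        shifts = percent_shift(retention, cfg.baseline_time)
        df = shifts.data
        at12 = df[
            (df["column_id"] == drifting[0])
            & (df["modifier_id"] == drifting[1])
            & (df["time_point"] == "12M")
        ]
        klass = at12["compound_id"].map(truth.compound_classes)
        acid = at12.loc[klass == "acidic", "percent_shift"].to_numpy()
        base = at12.loc[klass == "basic", "percent_shift"].to_numpy()
        class_consistent += bool(
            len(acid) > 0
            and len(base) > 0
            and np.mean(acid < 0) >= 0.9
            and np.mean(base > 0) >= 0.9
        )
    return {
        "n_seeds": n_seeds,
        "n_detected": int(detected),
        "n_class_consistent": int(class_consistent),
        "sd_drifted_mean": float(np.mean(sd_drifted)),
        "limit_mean": float(np.mean(limits)),
    }


def pca_clustering_benchmark(
    n_seeds: int = 10,
    base_seed: int = 0,
    ann: AnnConfig = CONVERGED_ANN,
) -> dict:
    """Mutual-nearest-neighbor recovery of two conditions sharing a mechanism.

    BEH and diol are planted with one shared weight vector, silica with its
    own; success = the two sharers are mutual nearest neighbors among the
    baseline weight vectors in 2-component PC space.
    """
    sharers = (("BEH", "MeOH"), ("diol", "MeOH"))
    odd = ("silica", "MeOH")
    mutual = 0
    for i in range(n_seeds):
        cfg = SyntheticConfig(
            conditions=(odd,) + sharers,
            weight_groups=((odd, "own"), (sharers[0], "shared"), (sharers[1], "shared")),
            seed=base_seed + i,
        )
        desc, retention, _ = generate_study(cfg)
        dn = normalize_by_max(desc)
        models = fit_condition_models(
            dn, retention, ann, base_seed=base_seed + i, time_points=[cfg.baseline_time]
        )
        wm = weight_matrix(models)
        res = pca_weights(wm, n_components=2)
        _, nn = condition_distances(res.scores)
        a = "|".join(sharers[0] + (cfg.baseline_time,))
        b = "|".join(sharers[1] + (cfg.baseline_time,))
        mutual += bool(nn[a] == b and nn[b] == a)
    return {"n_seeds": n_seeds, "n_mutual_nn": int(mutual)}


def aging_study_summary(seed: int = 0, ann: AnnConfig = CONVERGED_ANN) -> dict:
    """One full default aging study: shift fractions and regeneration summary.

    The drifting condition receives the stylized class-linked schedule; the
    reported numbers are the fraction of compounds with |shift| > 1 % at 1M
    and at 12M on the drifting condition, and the regeneration summary
    (fraction within +-2 %, fraction effective) per condition.
    """
    drifting = ("silica", "MeOH")
    reference = ("diol", "MeOH")
    cfg = SyntheticConfig(
        conditions=(drifting, reference),
        drift_schedule=class_drift_schedule([drifting]),
        seed=seed,
    )
    _, retention, _ = generate_study(cfg)
    shifts = percent_shift(retention, cfg.baseline_time)
    regen = evaluate_regeneration(retention)
    s = regen.summary.set_index(["column_id", "modifier_id"])
    return {
        "frac_gt1pct_12M_drifting": fraction_exceeding(shifts, *drifting, "12M", 1.0),
        "frac_gt1pct_12M_reference": fraction_exceeding(shifts, *reference, "12M", 1.0),
        "regen_frac_within_2pct_drifting": float(
            s.loc[drifting, "fraction_within_tolerance"]
        ),
        "regen_frac_effective_drifting": float(s.loc[drifting, "fraction_effective"]),
        "regen_frac_within_2pct_reference": float(
            s.loc[reference, "fraction_within_tolerance"]
        ),
    }
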