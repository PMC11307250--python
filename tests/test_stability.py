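import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sfc_qsrr as sq
from sfc_qsrr.ann import WeightVector
from sfc_qsrr.io_tables import RetentionTable
from sfc_qsrr.stability import (
    BIN_LABELS,
    apply_limit,
    bin_shifts,
    derive_stability_limit,
    fraction_exceeding,
    percent_shift,
    weight_sd,
)


def retention_from(rows):
    return RetentionTable(
        pd.DataFrame(
            rows,
            columns=["compound_id", "column_id", "modifier_id", "time_point", "t_r", "eluted"],
        )
    )


class TestBinShifts:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.0, "<0.5%"),
            (0.49, "<0.5%"),
            (0.5, "0.5-1.0%"),
            (0.999, "0.5-1.0%"),
            (1.0, "1.0-2.0%"),
            (2.0, "2.0-5.0%"),
            (-3.2, "2.0-5.0%"),
            (5.0, ">5.0%"),
            (-120.0, ">5.0%"),
        ],
    )
    def test_boundaries_lower_closed(self, value, label):
        assert bin_shifts(value) == label

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bin_shifts(float("nan"))

    @given(st.floats(-1e9, 1e9, allow_nan=False))
    @settings(max_examples=500, deadline=None)
    def test_partition_every_value_in_exactly_one_bin(self, x):
        label = bin_shifts(x)
        assert label in BIN_LABELS
        edges = [0.0, 0.5, 1.0, 2.0, 5.0, np.inf]
        hits = [
            lo <= abs(x) < hi for lo, hi in zip(edges[:-1], edges[1:])
        ]
        assert sum(hits) == 1 and BIN_LABELS[hits.index(True)] == label


class TestPercentShift:
    def test_signed_formula_and_bin(self):
        rows = [
            ("c1", "silica", "MeOH", "0M", 5.00, True),
            ("c1", "silica", "MeOH", "1M", 5.15, True),
        ]
        rep = percent_shift(retention_from(rows))
        row = rep.data[rep.data["time_point"] == "1M"].iloc[0]
        assert row["percent_shift"] == pytest.approx(3.0)
        assert row["bin"] == "2.0-5.0%"

    def test_baseline_is_exactly_zero(self):
        rows = [("c1", "silica", "MeOH", "0M", 5.0, True)]
        rep = percent_shift(retention_from(rows))
        assert rep.data.iloc[0]["percent_shift"] == 0.0
        assert rep.data.iloc[0]["bin"] == "<0.5%"

    def test_missing_baseline_skipped_and_reported(self):
        rows = [("c1", "silica", "MeOH", "1M", 5.0, True)]
        rep = percent_shift(retention_from(rows))
        assert rep.data.empty
        assert rep.skipped == (("c1", "silica", "MeOH"),)

    def test_rebaselining_matches_brute_force(self, small_study):
        _, retention, _ = small_study
        rep = percent_shift(retention, baseline_time="1M")
        df = retention.data[retention.data["eluted"]]
        base = df[df["time_point"] == "1M"].set_index(
            ["compound_id", "column_id", "modifier_id"]
        )["t_r"]
        for _, row in rep.data.sample(50, random_state=0).iterrows():
            tr0 = base.loc[(row["compound_id"], row["column_id"], row["modifier_id"])]
            sub = df[
                (df["compound_id"] == row["compound_id"])
                & (df["column_id"] == row["column_id"])
                & (df["time_point"] == row["time_point"])
            ]
            expected = 100.0 * (float(sub["t_r"].iloc[0]) - tr0) / tr0
            assert row["percent_shift"] == pytest.approx(expected, rel=1e-12)

    def test_drift_free_noise_free_study_all_in_lowest_bin(self):
        cfg = sq.SyntheticConfig(
            n_compounds=30,
            n_descriptors=20,
            n_informative=4,
            n_distinctive=8,
            n_null_groups=4,
            conditions=(("silica", "MeOH"),),
            noise_sd=0.0,
            elution_prob=1.0,
            seed=2,
        )
        _, retention, _ = sq.generate_study(cfg)
        rep = percent_shift(retention)
        assert (rep.data["percent_shift"] == 0).all()
        assert (rep.data["bin"] == "<0.5%").all()


class TestFractionExceeding:
    def _report(self):
        rows = [("c%d" % i, "silica", "MeOH", "0M", 5.0, True) for i in range(4)]
        rows += [
            ("c0", "silica", "MeOH", "1M", 5.0, True),   # 0%
            ("c1", "silica", "MeOH", "1M", 5.04, True),  # 0.8%
            ("c2", "silica", "MeOH", "1M", 5.2, True),   # 4%
            ("c3", "silica", "MeOH", "1M", 4.0, True),   # -20%
        ]
        return percent_shift(retention_from(rows))

    def test_counts(self):
        rep = self._report()
        assert fraction_exceeding(rep, "silica", "MeOH", "1M", 1.0) == pytest.approx(0.5)
        assert fraction_exceeding(rep, "silica", "MeOH", "1M", 0.0) == pytest.approx(0.75)
        assert fraction_exceeding(rep, "silica", "MeOH", "1M", 1000.0) == 0.0

    def test_monotone_non_increasing_in_cutoff(self):
        rep = self._report()
        cuts = [0.0, 0.5, 1.0, 2.0, 5.0, 25.0]
        fracs = [fraction_exceeding(rep, "silica", "MeOH", "1M", c) for c in cuts]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError, match="no shifts"):
            fraction_exceeding(self._report(), "BEH", "MeOH", "1M", 1.0)


def series_of(vectors):
    names = tuple(f"d{i}" for i in range(len(vectors[0])))
    return {
        tp: WeightVector(descriptor_names=names, weights=np.asarray(v, float))
        for tp, v in vectors.items()
    } if isinstance(vectors, dict) else {
        f"t{i}": WeightVector(descriptor_names=names, weights=np.asarray(v, float))
        for i, v in enumerate(vectors)
    }


class TestWeightSd:
    def test_constant_series_zero(self):
        rep = weight_sd(series_of([[1.0, -2.0], [1.0, -2.0], [1.0, -2.0]]))
        assert (rep.sd_over_time == 0).all()

    def test_two_point_closed_form(self):
        rep = weight_sd(series_of([[1.0], [-1.0]]))
        assert rep.sd_over_time.iloc[0] == pytest.approx(1.0)

    def test_single_outlier_closed_form(self):
        # one offset Delta at one of T otherwise-equal points:
        # population SD = |Delta| * sqrt(T-1) / T
        T, delta = 8, 2.5
        vecs = [[0.0]] * (T - 1) + [[delta]]
        rep = weight_sd(series_of(vecs))
        assert rep.sd_over_time.iloc[0] == pytest.approx(delta * np.sqrt(T - 1) / T)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(0, 2, (6, 10))
        rep = weight_sd(series_of(list(mat)))
        for j in range(10):
            col = mat[:, j]
            m = col.sum() / len(col)
            oracle = (sum((x - m) ** 2 for x in col) / len(col)) ** 0.5
            assert rep.sd_over_time.iloc[j] == pytest.approx(oracle, rel=1e-12)

    def test_name_mismatch_rejected(self):
        a = WeightVector(descriptor_names=("x",), weights=np.array([1.0]))
        b = WeightVector(descriptor_names=("y",), weights=np.array([1.0]))
        with pytest.raises(ValueError, match="differ"):
            weight_sd({"0M": a, "1M": b})

    def test_fewer_than_two_points_rejected(self):
        a = WeightVector(descriptor_names=("x",), weights=np.array([1.0]))
        with pytest.raises(ValueError, match=">= 2"):
            weight_sd({"0M": a})


class TestStabilityLimit:
    def _reports(self, ref_sds, other_sds):
        return {
            ("diol", "MeOH"): weight_sd(series_of(ref_sds)),
            ("silica", "MeOH"): weight_sd(series_of(other_sds)),
        }

    def test_limit_is_max_reference_sd(self):
        # reference per-descriptor SDs 0.1, 0.3, 0.66 -> limit 0.66
        ref = [[0.0, 0.0, 0.0], [0.2, 0.6, 1.32]]  # two-point SDs: 0.1, 0.3, 0.66
        other = [[0.0, 0.0, 0.0], [0.1, 2.0, 0.2]]
        reports = self._reports(ref, other)
        limit = derive_stability_limit(reports, ("diol", "MeOH"))
        assert limit == pytest.approx(0.66)
        flagged = apply_limit(reports, limit)
        assert flagged[("silica", "MeOH")].n_exceeding == 1

    def test_all_zero_reference_flagged_degenerate(self):
        reports = self._reports([[0.0], [0.0]], [[0.0], [1.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            limit = derive_stability_limit(reports, ("diol", "MeOH"))
        assert limit == 0.0

    def test_exceedance_matches_brute_force(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(0, 1, (5, 20))
        reports = {("c", "m"): weight_sd(series_of(list(mat)))}
        limit = 0.4
        flagged = apply_limit(reports, limit)[("c", "m")]
        brute = sum(float(np.std(mat[:, j])) > limit for j in range(20))
        assert flagged.n_exceeding == brute

    def test_unknown_reference_rejected(self):
        reports = self._reports([[0.0], [0.2]], [[0.0], [1.0]])
        with pytest.raises(KeyError):
            derive_stability_limit(reports, ("BEH", "MeOH"))


def test_noise_free_drift_free_weight_sd_is_zero(small_config):
    """End-to-end: zero noise + zero drift makes every stability statistic 0."""
    import dataclasses

    from sfc_qsrr.workflow import fit_condition_models

    cfg = dataclasses.replace(
        small_config, noise_sd=0.0, conditions=(("silica", "MeOH"),),
        time_points=("0M", "1M", "R"),
    )
    desc, retention, _ = sq.generate_study(cfg)
    dn = sq.normalize_by_max(desc)
    # identical data at every time point + identical seed => identical weights
    models = {}
    from sfc_qsrr.ann import AnnConfig, extract_weights, train
    from sfc_qsrr.workflow import normalized_targets

    for tp in cfg.time_points:
        sub = retention.select("silica", "MeOH", time_point=tp, eluted_only=True)
        y = normalized_targets(sub["k_prime"].to_numpy(float))
        models[tp] = extract_weights(
            train(dn.subset(sub["compound_id"]), y, AnnConfig(epochs=50, seed=3))
        )
    rep = weight_sd(models)
    # identical weights at every time point; SD is zero up to the roundoff of
    # the mean of three equal floats
    assert float(rep.sd_over_time.max()) < 1e-12
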