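"""Split protocol, noise injection, metrics and robustness sweeps."""

import numpy as np
import pytest

import morphid as m
from morphid.errors import ValidationError
from morphid.identification import NOISE_LEVELS, SIZE_STEPS

from conftest import make_table


def three_tp_table(n_subj=6, p=2, seed=0, within_sd=0.2):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 3, (n_subj, p))
    rows = np.repeat(centers, 3, axis=0) + rng.normal(0, within_sd, (3 * n_subj, p))
    return make_table(
        rows,
        subjects=[f"s{i:02d}" for i in range(n_subj) for _ in range(3)],
        timepoints=[1, 2, 3] * n_subj,
    )


class TestSplit:
    def test_fixed_mode_holds_out_the_named_timepoint(self):
        t = three_tp_table()
        plan = m.split_timepoints(t, "fixed", test_timepoint=3)
        assert all(tp == 3 for tp in plan.test_timepoint.values())
        assert all(v == [1, 2] for v in plan.train_timepoints.values())
        train, test = m.apply_split(t, plan)
        assert train.n_rows == 12 and test.n_rows == 6

    def test_global_mode_shares_one_test_point(self):
        plan = m.split_timepoints(three_tp_table(), "global_random", seed=5)
        assert len(set(plan.test_timepoint.values())) == 1

    def test_per_subject_mode_is_reproducible(self):
        t = three_tp_table()
        a = m.split_timepoints(t, "per_subject_random", seed=7)
        b = m.split_timepoints(t, "per_subject_random", seed=7)
        assert a.test_timepoint == b.test_timepoint

    def test_subject_with_single_timepoint_rejected(self):
        t = make_table([[1.0], [2.0], [3.0]], subjects=["a", "a", "b"],
                       timepoints=[1, 2, 1])
        with pytest.raises(ValidationError):
            m.split_timepoints(t, "per_subject_random")

    def test_each_timepoint_drawn_about_uniformly(self):
        """Over 10,000 subject-draws every timepoint tests ~1/3 of the time."""
        t = three_tp_table(n_subj=100, p=1)
        counts = {1: 0, 2: 0, 3: 0}
        for seed in range(100):
            plan = m.split_timepoints(t, "per_subject_random", seed=seed)
            for tp in plan.test_timepoint.values():
                counts[tp] += 1
        total = sum(counts.values())
        se = np.sqrt((1 / 3) * (2 / 3) / total)
        for tp in (1, 2, 3):
            assert abs(counts[tp] / total - 1 / 3) < 3 * se


class TestNoise:
    def test_level_zero_is_identity(self, cohort60):
        out = m.add_gaussian_noise(cohort60, 0.0, reference=cohort60, seed=1)
        np.testing.assert_array_equal(out.values, cohort60.values)

    def test_same_seed_same_level_identical(self, cohort60):
        a = m.add_gaussian_noise(cohort60, 0.2, reference=cohort60, seed=4)
        b = m.add_gaussian_noise(cohort60, 0.2, reference=cohort60, seed=4)
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_sd_tracks_level_times_reference_sd(self, schema):
        table = m.generate_cohort(m.default_config(191, seed=2, schema=schema))
        noisy = m.add_gaussian_noise(table, 0.40, reference=table, seed=0)
        s_ref = table.values.std(axis=0, ddof=1)
        emp = (noisy.values - table.values).std(axis=0, ddof=1)
        n = table.n_rows
        z = (emp / (0.40 * s_ref) - 1) / np.sqrt(1 / (2 * (n - 1)))
        assert np.abs(np.median(z)) < 1.0
        assert np.abs(z).max() < 5.0

    def test_constant_reference_feature_passes_through_with_warning(self):
        ref = make_table([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]], names=["a", "flat"])
        with pytest.warns(UserWarning, match="flat"):
            out = m.add_gaussian_noise(ref, 0.3, reference=ref, seed=0)
        np.testing.assert_array_equal(out.values[:, 1], ref.values[:, 1])
        assert not np.array_equal(out.values[:, 0], ref.values[:, 0])

    def test_negative_level_rejected(self, cohort60):
        with pytest.raises(ValidationError):
            m.add_gaussian_noise(cohort60, -0.1, reference=cohort60)


class TestMetrics:
    def test_perfect_identification(self):
        r = m.compute_metrics(["a", "b", "c", "d"], ["a", "b", "c", "d"])
        assert (r.accuracy, r.sensitivity, r.specificity, r.f1) == (1, 1, 1, 1)

    def test_hand_filled_confusion_table(self):
        """One of four subjects misattributed to another."""
        r = m.compute_metrics(["1", "2", "3", "4"], ["1", "2", "3", "3"])
        assert r.sensitivity == pytest.approx(0.75)
        assert r.specificity == pytest.approx((1 + 1 + 2 / 3 + 1) / 4)
        assert r.accuracy == pytest.approx(0.875)
        assert r.f1 == pytest.approx((1 + 1 + 2 / 3 + 0) / 4)
        assert r.confusion["3"] == {"TP": 1, "FN": 0, "FP": 1, "TN": 2}
        assert r.correct.tolist() == [True, True, True, False]

    def test_collapsed_predictor_keeps_accuracy_high(self):
        """Predicting one subject for everybody: SENS = 1/N yet ACC stays ~1.

        True negatives dominate the one-vs-rest confusion tables, which is
        why near-perfect accuracy can coexist with poor sensitivity.
        """
        N = 50
        truth = [f"s{i:02d}" for i in range(N)]
        r = m.compute_metrics(truth, ["s00"] * N)
        assert r.sensitivity == pytest.approx(1 / N)
        assert r.accuracy > 0.95
        assert r.specificity == pytest.approx(1 - (N - 1) / (N * (N - 1)))

    def test_duplicate_test_rows_rejected(self):
        with pytest.raises(ValidationError):
            m.compute_metrics(["a", "a"], ["a", "a"])

    def test_accounting_identities_on_random_predictions(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            N = int(rng.integers(3, 40))
            truth = [f"s{i}" for i in range(N)]
            pred = [truth[i] for i in rng.integers(0, N, N)]
            r = m.compute_metrics(truth, pred)
            total_tp = sum(v["TP"] for v in r.confusion.values())
            total_fp = sum(v["FP"] for v in r.confusion.values())
            assert total_tp + total_fp == N
            assert r.sensitivity == pytest.approx(total_tp / N)
            # FP mass bound links macro specificity to sensitivity
            assert r.specificity >= 1 - N * (1 - r.sensitivity) / (N - 1) - 1e-12


class TestRunIdentification:
    @pytest.mark.parametrize("engine", ["lda", "wknn"])
    def test_exact_repeat_scans_identify_perfectly(self, schema, engine):
        cfg = m.default_config(30, seed=6, schema=schema)
        cfg.scan_noise_sd[:] = 0.0
        cfg.annual_drift_fraction[:] = 0.0
        t = m.generate_cohort(cfg)
        r = m.run_identification(t, schema, "VOLUME", engine=engine, seed=2)
        assert r.sensitivity == 1.0 and r.f1 == 1.0

    def test_no_signature_cohort_identifies_at_chance(self, schema):
        n, seeds = 50, 8
        sens = []
        for seed in range(seeds):
            cfg = m.default_config(n, seed=300 + seed, schema=schema, tau_fraction=0.0)
            t = m.generate_cohort(cfg)
            r = m.run_identification(t, schema, "11LBR", engine="wknn", seed=seed)
            sens.append(r.sensitivity)
        mean = np.mean(sens)
        se = np.sqrt((1 / n) * (1 - 1 / n) / (seeds * n))
        assert abs(mean - 1 / n) < 4 * se

    def test_reports_are_bitwise_reproducible(self, schema, cohort60):
        a = m.run_identification(cohort60, schema, "AREA", engine="lda",
                                 noise_level=0.2, seed=13)
        b = m.run_identification(cohort60, schema, "AREA", engine="lda",
                                 noise_level=0.2, seed=13)
        assert a.to_dict() == b.to_dict()

    def test_default_cohort_lda_volume_identifies_nearly_everyone(self, cohort60, schema):
        r = m.run_identification(cohort60, schema, "VOLUME", engine="lda", seed=1)
        assert r.sensitivity >= 0.95


class TestSweeps:
    def test_noise_axis_is_the_nine_standard_levels(self):
        assert len(NOISE_LEVELS) == 9
        assert NOISE_LEVELS[0] == 0.0 and NOISE_LEVELS[-1] == 0.40

    def test_size_axis_is_the_nineteen_standard_sizes(self):
        assert len(SIZE_STEPS) == 19
        assert SIZE_STEPS[0] == 10 and SIZE_STEPS[-1] == 190

    def test_noise_sweep_zero_cell_equals_plain_run(self, schema, cohort60):
        sweep = m.noise_sweep(cohort60, schema, "11LBR", engine="wknn",
                              seed=17, levels=(0.0, 0.2, 0.4))
        assert len(sweep.reports) == 3
        base_seed = sweep.reports[0].seed
        direct = m.run_identification(cohort60, schema, "11LBR", engine="wknn",
                                      seed=base_seed)
        assert sweep.reports[0].to_dict() == direct.to_dict()

    def test_noise_sweep_shares_split_across_levels(self, schema, cohort60):
        sweep = m.noise_sweep(cohort60, schema, "11LBR", seed=3,
                              levels=(0.0, 0.4))
        assert sweep.reports[0].subjects == sweep.reports[1].subjects
        assert sweep.reports[0].seed == sweep.reports[1].seed

    def test_size_sweep_clips_to_cohort_and_full_size_uses_everyone(self, schema, cohort60):
        sweep = m.size_sweep(cohort60, schema, "11LBR", seed=5,
                             sizes=(10, 30, 60, 120))
        assert sweep.axis_values == [10, 30, 60]
        assert sweep.reports[-1].n_subjects == 60

    def test_sweep_dataframe_is_tidy(self, schema, cohort60):
        sweep = m.noise_sweep(cohort60, schema, "11LBR", seed=1,
                              levels=(0.0, 0.4), replicates=2)
        df = sweep.to_dataframe()
        assert len(df) == 4
        assert {"noise_level", "replicate", "engine", "dataset", "accuracy",
                "sensitivity", "specificity", "f1"} <= set(df.columns)
        assert df["replicate"].nunique() == 2

    def test_noise_degrades_sensitivity_on_a_weak_cohort(self, schema):
        """With a marginal signature, heavy test noise must not help."""
        cfg = m.default_config(40, seed=8, schema=schema,
                               tau_fraction=0.03, sigma_fraction=0.02)
        t = m.generate_cohort(cfg)
        sweep = m.noise_sweep(t, schema, "11LBR", engine="wknn", seed=2,
                              levels=(0.0, 0.2, 0.4), replicates=5)
        df = sweep.to_dataframe().groupby("noise_level")["sensitivity"].mean()
        assert df.loc[0.0] >= df.loc[0.4]
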