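"""Nested CV machinery, accuracy, bootstrap summaries, learning-rate rule."""

import numpy as np
import pytest

from gsnue import models as M
from gsnue.evaluation import (
    CVPlan,
    accuracy,
    bootstrap_gebv_mean,
    compare_train_test_means,
    learning_rate_schedule,
    run_nested_cv,
)
from gsnue.simulate import PopulationConfig, simulate_genotypes, simulate_phenotypes


class TestAccuracy:
    def test_perfect_and_inverted(self, rng):
        y = rng.normal(size=10)
        assert accuracy(y, y) == pytest.approx(1.0)
        assert accuracy(y, -y) == pytest.approx(-1.0)

    def test_three_point_hand_value(self):
        # r((1,2,3),(1,2,4)) = 9 / sqrt(84)
        assert accuracy([1, 2, 3], [1, 2, 4]) == pytest.approx(
            9 / np.sqrt(84), abs=1e-10
        )
        assert round(accuracy([1, 2, 3], [1, 2, 4]), 4) == 0.9820

    def test_affine_invariance(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert accuracy(a, b) == pytest.approx(accuracy(2 * a + 3, b), abs=1e-12)
        assert accuracy(a, b) == pytest.approx(accuracy(a, 0.5 * b - 1), abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_guard(self):
        with pytest.raises(ValueError):
            accuracy([1, 2], [1, 2])


class TestSNPHeritability:
    def test_table_style_plug_in(self):
        vc = M.VarianceComponents(sigma2_a=57.11, sigma2_e=69.81)
        assert round(M.snp_heritability(vc), 4) == 0.4500


class TestBootstrap:
    def test_constant_vector_zero_width(self):
        mean, (lo, hi) = bootstrap_gebv_mean(np.full(20, 3.0), n_boot=200, seed=0)
        assert mean == 3.0 and lo == hi == 3.0

    def test_interval_contains_point_estimate(self, rng):
        x = rng.normal(size=50)
        mean, (lo, hi) = bootstrap_gebv_mean(x, n_boot=500, seed=1)
        assert lo <= mean <= hi

    def test_clt_half_width(self, rng):
        x = rng.standard_normal(400)
        _, (lo, hi) = bootstrap_gebv_mean(x, n_boot=2000, seed=2)
        half = (hi - lo) / 2
        expected = 1.96 / np.sqrt(400)
        assert abs(half - expected) / expected <= 0.30

    def test_too_few_boots_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_gebv_mean(rng.normal(size=10), n_boot=50)


class TestLearningRateSchedule:
    def test_schedule_minimum_at_full_epoch_count(self):
        trace, minimum = learning_rate_schedule(1.0, 9900)
        assert minimum == pytest.approx(0.01, abs=1e-15)
        assert trace[0] == 1.0

    def test_strictly_decreasing_and_invariant_product(self):
        trace, _ = learning_rate_schedule(2.0, 500)
        assert np.all(np.diff(trace) < 0)
        j = np.arange(trace.size)
        np.testing.assert_allclose(trace * (100 + j), 200.0, atol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            learning_rate_schedule(0.0, 10)
        with pytest.raises(ValueError):
            learning_rate_schedule(1.0, -1)


class TestTrainTestComparison:
    def test_identical_groups(self):
        t, p, stars = compare_train_test_means([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and stars == "ns"

    def test_separated_groups(self, rng):
        a = rng.normal(size=100)
        b = a + 10 * a.std()
        _, p, stars = compare_train_test_means(a, b)
        assert p < 1e-6 and stars == "*"

    def test_welch_hand_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0, 4.0])
        t, p, _ = compare_train_test_means(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t_ref = (a.mean() - b.mean()) / np.sqrt(va / a.size + vb / b.size)
        assert t == pytest.approx(t_ref, abs=1e-10)


class TestCVPlan:
    def test_partition_property(self):
        plan = CVPlan(outer_folds=5, seed=3).materialize(97)
        counts = np.bincount(plan.assignment, minlength=5)
        assert counts.sum() == 97
        assert counts.min() >= 19  # near-equal folds

    def test_invalid_folds(self):
        with pytest.raises(ValueError):
            CVPlan(outer_folds=1).materialize(10)

    def test_check_partition_guards_small_folds(self):
        plan = CVPlan(outer_folds=5, seed=0).materialize(30)
        plan.assignment = np.zeros(30, dtype=int)  # everything in one fold
        with pytest.raises(ValueError):
            plan.check_partition(30)


class TestNestedCV:
    def test_noise_free_ceiling(self):
        # causal-only panel in strong LD: few effective dimensions, so the
        # noise-free trait is predictable almost perfectly out of sample
        cfg = PopulationConfig(
            n_genotypes=300, n_markers=1000, n_qtl=1000, h2_low_n=1.0,
            ld_block_len=50, ld_flip_prob=0.01, missing_rate=0.0, seed=17,
        )
        G = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(G, cfg)
        from gsnue.qc import apply_qc

        Gq, _ = apply_qc(G, maf_threshold=0.0, hwe_alpha=None)
        report, _ = run_nested_cv(
            Gq, pheno, models=("rrBLUP",), plan=CVPlan(seed=1),
            n_levels=("LN",), n_boot=100,
        )
        assert report.table["accuracy"].iloc[0] >= 0.95

    def test_permuted_phenotypes_average_null_accuracy(self):
        cfg = PopulationConfig(n_genotypes=100, n_markers=300, missing_rate=0.0, seed=19)
        G = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(G, cfg)
        from gsnue.data import PhenotypeTable
        from gsnue.qc import apply_qc

        Gq, _ = apply_qc(G, hwe_alpha=None)
        rng = np.random.default_rng(0)
        accs = []
        for rep in range(20):
            t = pheno.table.copy()
            for level in ("LN",):
                mask = t["n_level"] == level
                vals = t.loc[mask, "NUE"].to_numpy()
                perm = rng.permutation(vals.size)
                t.loc[mask, "NUE"] = vals[perm]
                t.loc[mask, "GY"] = t.loc[mask, "NUE"] * t.loc[mask, "Ns"]
            rep_report, _ = run_nested_cv(
                Gq, PhenotypeTable(t), models=("rrBLUP",),
                plan=CVPlan(seed=rep), n_levels=("LN",), n_boot=100,
            )
            accs.append(rep_report.table["accuracy"].iloc[0])
        assert abs(np.mean(accs)) <= 0.1

    def test_every_genotype_predicted_once(self, qc_pop):
        _, Gq, pheno, _, _ = qc_pop
        report, preds = run_nested_cv(
            Gq, pheno, models=("gBLUP", "RKHS"), plan=CVPlan(seed=2),
            n_levels=("LN",), n_boot=100,
        )
        counts = preds.groupby(["model", "genotype_id"]).size()
        assert (counts == 1).all()
        assert not preds["predicted"].isna().any()
        # report invariants hold
        assert set(report.table["model"]) == {"gBLUP", "RKHS"}
        assert ((report.table["boot_ci_low"] <= report.table["boot_gebv_mean"])
                & (report.table["boot_gebv_mean"] <= report.table["boot_ci_high"])).all()
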