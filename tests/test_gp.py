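"""RR-BLUP genomic prediction, fold plans, CV metrics, variance splits."""

import numpy as np
import pandas as pd
import pytest

from metgp.gp import (
    cross_decomposition,
    cross_share,
    gebv_predict,
    make_folds,
    marker_share,
    polygenic_partition,
    prediction_bias,
    predictive_ability,
    rrblup_fit,
    run_gp_cv,
)


def _random_panel(rng, n, p, prefix="g"):
    return pd.DataFrame(rng.choice([-1.0, 0.0, 1.0], size=(n, p)),
                        index=[f"{prefix}{i}" for i in range(n)])


class TestRRBLUP:
    def test_single_marker_matches_mixed_model_equations(self):
        """p=1 with known variances: the marker effect solves the scalar
        ridge (Henderson) system (z'R^-1 z + 1/s2_u) u = z'R^-1 (y - Xb)."""
        z = np.array([[-1.0], [0.0], [1.0]])
        y = np.array([1.0, 2.0, 4.0])
        s2u, s2e = 2.0, 1.0
        model = rrblup_fit(y, np.full(3, s2e), np.ones((3, 1)),
                           pd.DataFrame(z, index=list("abc")), sigma2_g=s2u)
        # independent oracle: solve Henderson's equations directly
        X = np.ones((3, 1))
        lhs = np.block([[X.T @ X / s2e, X.T @ z / s2e],
                        [z.T @ X / s2e, z.T @ z / s2e + 1.0 / s2u]])
        rhs = np.concatenate([X.T @ y / s2e, z.T @ y / s2e])
        sol = np.linalg.solve(lhs, rhs)
        assert model.beta[0] == pytest.approx(sol[0], abs=1e-8)
        assert model.marker_effects.iloc[0] == pytest.approx(sol[1], abs=1e-8)

    def test_vanishing_genetic_variance_shrinks_to_gls(self):
        rng = np.random.default_rng(1)
        Z = _random_panel(rng, 20, 30)
        y = rng.normal(10, 1, 20)
        model = rrblup_fit(y, np.ones(20), np.ones((20, 1)), Z, sigma2_g=1e-12)
        assert np.allclose(model.gebv, 0.0, atol=1e-9)
        assert model.beta[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_marker_space_equals_kernel_space(self):
        """Marker-effect (RR-BLUP) and genomic-kernel (GBLUP) routes agree
        to relative 1e-8 on a 50 x 200 instance."""
        rng = np.random.default_rng(3)
        Z = _random_panel(rng, 50, 200)
        y = 5 + Z.to_numpy() @ rng.normal(0, 0.1, 200) + rng.normal(0, 0.5, 50)
        R = np.full(50, 0.25)
        model = rrblup_fit(y, R, np.ones((50, 1)), Z)
        G = Z.to_numpy() @ Z.to_numpy().T / 200
        V = model.sigma2_g * G + np.diag(R)
        Vi = np.linalg.inv(V)
        ones = np.ones(50)
        beta = float(ones @ Vi @ y / (ones @ Vi @ ones))
        kernel_gebv = model.sigma2_g * G @ Vi @ (y - beta)
        scale = np.max(np.abs(kernel_gebv))
        assert np.max(np.abs(model.gebv.to_numpy() - kernel_gebv)) / scale < 1e-8

    def test_all_zero_markers_rejected(self):
        Z = pd.DataFrame(np.zeros((5, 4)))
        with pytest.raises(ValueError, match="all-zero"):
            rrblup_fit(np.ones(5), np.ones(5), np.ones((5, 1)), Z)


class TestPredict:
    def _model(self):
        rng = np.random.default_rng(7)
        Z = _random_panel(rng, 30, 40)
        y = Z.to_numpy() @ rng.normal(0, 0.2, 40) + rng.normal(0, 0.3, 30)
        return Z, rrblup_fit(y, np.ones(30), np.ones((30, 1)), Z)

    def test_training_panel_reproduces_training_gebvs(self):
        Z, model = self._model()
        again = gebv_predict(model, Z)
        assert np.allclose(again, model.gebv, atol=1e-12)

    def test_zero_code_genotype_gets_zero_gebv(self):
        Z, model = self._model()
        null = pd.DataFrame(np.zeros((1, Z.shape[1])), index=["null"],
                            columns=Z.columns)
        assert gebv_predict(model, null).iloc[0] == 0.0

    def test_duplicated_rows_identical(self):
        Z, model = self._model()
        dup = pd.concat([Z.iloc[[0]], Z.iloc[[0]]])
        out = gebv_predict(model, dup)
        assert out.iloc[0] == out.iloc[1]

    def test_marker_mismatch_rejected(self):
        Z, model = self._model()
        with pytest.raises(ValueError, match="columns"):
            gebv_predict(model, Z.iloc[:, :-1])


class TestFoldPlans:
    def test_wc_partition_sizes(self):
        plan = make_folds([f"g{i}" for i in range(10)], scheme="WC", k=5, t=1, seed=0)
        a = plan.assignments[0]
        assert sorted(a) == [f"g{i}" for i in range(10)]
        counts = pd.Series(a).value_counts()
        assert (counts == 2).all()

    def test_ac_one_cross_per_fold(self):
        cm = pd.DataFrame({"genotype": [f"g{i}" for i in range(10)],
                           "cross": np.repeat([f"c{j}" for j in range(5)], 2)})
        plan = make_folds(cm["genotype"], scheme="AC", k=5, t=1, seed=0, cross_map=cm)
        a = plan.assignments[0]
        per_cross = cm.assign(fold=cm["genotype"].map(a)).groupby("cross")["fold"].nunique()
        assert (per_cross == 1).all()
        assert len(set(a.values())) == 5

    def test_ac_never_splits_a_cross(self):
        rng = np.random.default_rng(2)
        sizes = rng.integers(2, 9, 30)
        cm = pd.DataFrame({
            "genotype": [f"c{j}.{i}" for j, s in enumerate(sizes) for i in range(s)],
            "cross": [f"c{j}" for j, s in enumerate(sizes) for _ in range(s)],
        })
        plan = make_folds(cm["genotype"], scheme="AC", k=5, t=5, seed=9, cross_map=cm)
        for a in plan.assignments:
            per_cross = cm.assign(fold=cm["genotype"].map(a)).groupby("cross")["fold"].nunique()
            assert (per_cross == 1).all()

    def test_five_by_five_means_25_fits(self):
        plan = make_folds([f"g{i}" for i in range(40)], scheme="WC", k=5, t=5, seed=1)
        assert plan.k * plan.t == 25

    def test_same_seed_reproduces_plan(self):
        genos = [f"g{i}" for i in range(23)]
        p1 = make_folds(genos, scheme="WC", k=5, t=5, seed=77)
        p2 = make_folds(genos, scheme="WC", k=5, t=5, seed=77)
        assert p1.assignments == p2.assignments

    def test_k_exceeding_crosses_rejected(self):
        cm = pd.DataFrame({"genotype": ["a", "b"], "cross": ["c1", "c1"]})
        with pytest.raises(ValueError, match="crosses"):
            make_folds(["a", "b"], scheme="AC", k=5, cross_map=cm)


class TestMetrics:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert predictive_ability(v, v) == pytest.approx(1.0)
        assert prediction_bias(v, v) == pytest.approx(1.0)

    def test_doubled_observations_slope_two(self):
        p = np.array([1.0, 2.0, 3.0, 4.0])
        assert predictive_ability(p, 2 * p) == pytest.approx(1.0)
        assert prediction_bias(2 * p, p) == pytest.approx(2.0)

    def test_five_point_pearson_hand_value(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        obs = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # hand computation of Pearson r for this pair
        assert predictive_ability(pred, obs) == pytest.approx(0.8)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = predictive_ability(np.ones(5), np.arange(5.0))
        assert np.isnan(out)


class TestCV:
    def test_perfect_signal_recovers_exactly(self):
        """Noiseless phenotypes equal to the genetic values, more training
        genotypes than markers and negligible error variance: predictive
        ability 1 in every repetition."""
        rng = np.random.default_rng(11)
        Z = _random_panel(rng, 60, 20)
        u = rng.normal(0, 1.0, 20)
        rec = pd.DataFrame({"genotype": Z.index,
                            "value": Z.to_numpy() @ u,
                            "weight": np.full(60, 1e8)})
        plan = make_folds(list(Z.index), scheme="WC", k=5, t=3, seed=0)
        res = run_gp_cv(rec, Z, plan, approach="2")
        assert np.all(res.per_repetition["rho"] > 1 - 1e-6)

    def test_permuted_phenotypes_have_no_signal(self):
        rng = np.random.default_rng(5)
        Z = _random_panel(rng, 100, 300)
        u = rng.normal(0, 0.1, 300)
        vals = Z.to_numpy() @ u + rng.normal(0, 0.3, 100)
        rec = pd.DataFrame({"genotype": Z.index,
                            "value": rng.permutation(vals),
                            "weight": np.full(100, 10.0)})
        plan = make_folds(list(Z.index), scheme="WC", k=5, t=20, seed=3)
        res = run_gp_cv(rec, Z, plan, approach="2")
        assert abs(res.per_repetition["rho"].mean()) < 0.1

    def test_records_without_markers_skipped_with_warning(self):
        rng = np.random.default_rng(6)
        Z = _random_panel(rng, 20, 30)
        rec = pd.DataFrame({"genotype": list(Z.index) + ["phantom"],
                            "value": rng.normal(size=21),
                            "weight": np.ones(21)})
        plan = make_folds(list(Z.index), scheme="WC", k=4, t=1, seed=0)
        with pytest.warns(UserWarning, match="without marker data"):
            run_gp_cv(rec, Z, plan, approach="2")


class TestCrossDecomposition:
    def test_share_arithmetic_from_reported_components(self):
        assert cross_share(4.03, 3.67, 1.66) == pytest.approx(39.2, abs=0.05)

    def test_pure_cross_structure(self):
        """Values constant within crosses: all variance goes to the cross
        component."""
        rows = []
        rng = np.random.default_rng(0)
        for c in range(12):
            val = rng.normal(0, 2)
            for k in range(5):
                rows.append({"genotype": f"c{c}.{k}", "cross": f"c{c}", "mean": val})
        df = pd.DataFrame(rows)
        res = cross_decomposition(df, df[["genotype", "cross"]], n_starts=1)
        assert res.share_pct > 95.0
        assert res.sigma2_g + res.sigma2_e < 0.05 * res.sigma2_c

    def test_single_cross_rejected(self):
        df = pd.DataFrame({"genotype": ["a", "b"], "cross": ["c", "c"],
                           "mean": [1.0, 2.0]})
        with pytest.raises(ValueError, match="single cross"):
            cross_decomposition(df, df[["genotype", "cross"]])

    def test_single_record_per_genotype_flagged_confounded(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "genotype": [f"c{j}.{i}" for j in range(8) for i in range(4)],
            "cross": [f"c{j}" for j in range(8) for _ in range(4)],
            "mean": rng.normal(size=32),
        })
        res = cross_decomposition(df, df[["genotype", "cross"]], n_starts=1)
        assert res.genotype_confounded


class TestPolygenic:
    def test_share_arithmetic_from_reported_components(self):
        assert marker_share(2.72, 0.36) == pytest.approx(88.3, abs=0.1)

    def test_zero_polygenic_covariance_reduces_to_rrblup(self):
        rng = np.random.default_rng(2)
        Z = _random_panel(rng, 50, 80)
        y = 3 + Z.to_numpy() @ rng.normal(0, 0.1, 80) + rng.normal(0, 0.4, 50)
        R = np.full(50, 0.16)
        base = rrblup_fit(y, R, np.ones((50, 1)), Z)
        part = polygenic_partition(y, R, np.ones((50, 1)), Z,
                                   relationship=np.zeros((50, 50)), n_starts=1)
        assert part.sigma2_marker == pytest.approx(base.sigma2_g, rel=1e-3)

    def test_marker_only_data_gives_boundary_polygenic(self):
        """Data simulated from marker effects alone: the polygenic
        component lands near zero in at least 80% of runs."""
        near0 = 0
        for run in range(20):
            rng = np.random.default_rng(100 + run)
            Z = _random_panel(rng, 80, 200)
            u = rng.normal(0, 0.08, 200)
            y = 3 + Z.to_numpy() @ u + rng.normal(0, 0.4, 80)
            pp = polygenic_partition(y, np.full(80, 0.16), np.ones((80, 1)), Z,
                                     n_starts=1)
            if pp.sigma2_polygenic < 0.05 * max(pp.sigma2_marker, 1e-9):
                near0 += 1
        assert near0 >= 16

    def test_non_psd_relationship_rejected(self):
        rng = np.random.default_rng(3)
        Z = _random_panel(rng, 10, 15)
        K = -np.eye(10)
        with pytest.raises(ValueError, match="positive semi-definite"):
            polygenic_partition(rng.normal(size=10), np.ones(10),
                                np.ones((10, 1)), Z, relationship=K)
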