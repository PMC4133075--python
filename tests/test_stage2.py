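"""Stage-two integration: weights, year adjustment, heritability, repeatability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metgp.reml import gls_blue, indicator_matrix
from metgp.stage1 import AdjustedMeans, adjusted_means, reml_fit
from metgp.stage2 import (
    adhoc_heritability,
    correct_year_means,
    fit_across_years,
    fit_yearwise,
    heritability,
    mean_variance_of_difference,
    repeatability,
    repeatability_from_components,
    smith_weights,
)


def _adj(table, vcov):
    return AdjustedMeans(table=table, vcov=vcov)


class TestSmithWeights:
    def _table(self, n):
        return pd.DataFrame({
            "genotype": [f"g{i}" for i in range(n)], "tester": "T",
            "mean": np.zeros(n), "se": np.ones(n),
        })

    def test_diagonal_vcov(self):
        V = np.diag([0.5, 0.25])
        t = self._table(2).assign(se=np.sqrt(np.diag(V)))
        w = smith_weights(_adj(t, V))
        assert np.allclose(w, [2.0, 4.0])

    def test_scalar_case(self):
        t = self._table(1).assign(se=2.0)
        assert smith_weights(_adj(t, np.array([[4.0]])))[0] == pytest.approx(0.25)

    def test_correlated_vcov_matches_hand_inversion(self):
        V = np.array([[1.0, 0.3, 0.1], [0.3, 0.8, 0.2], [0.1, 0.2, 1.2]])
        t = self._table(3).assign(se=np.sqrt(np.diag(V)))
        w = smith_weights(_adj(t, V))
        assert np.allclose(w, np.diag(np.linalg.inv(V)))

    def test_singular_vcov_falls_back_to_pseudo_inverse(self):
        V = np.ones((2, 2))
        t = self._table(2)
        with pytest.warns(UserWarning, match="singular"):
            w = smith_weights(_adj(t, V))
        assert np.all(np.isfinite(w))


class TestYearwise:
    def test_single_location_single_tester_pass_through(self):
        means = pd.DataFrame({
            "genotype": ["g1", "g2", "g3"], "tester": "T1", "location": "L1",
            "year": 2009, "mean": [10.0, 12.0, 9.0],
        })
        out = fit_yearwise(means, np.array([2.0, 2.0, 2.0]), n_starts=1)
        got = out.table.set_index("genotype")["mean"]
        assert np.allclose(got[["g1", "g2", "g3"]], [10.0, 12.0, 9.0], atol=1e-6)

    def test_two_location_weighted_mean(self):
        """With no genotype-by-location variance beyond the fixed residual,
        the combined mean is the closed-form inverse-variance weighted
        average of the two location values (weights 2 and 4)."""
        rng = np.random.default_rng(0)
        n = 50
        base = rng.normal(50, 2, n)
        rows, noise = [], {}
        for loc, w in (("L1", 2.0), ("L2", 4.0)):
            eps = rng.normal(0, np.sqrt(1 / w), n)
            noise[loc] = eps
            for i in range(n):
                rows.append({"genotype": f"g{i:02d}", "tester": "T",
                             "location": loc, "year": 2009,
                             "mean": base[i] + eps[i], "weight": w})
        df = pd.DataFrame(rows)
        out = fit_yearwise(df, df["weight"], n_starts=1)
        got = out.table.set_index("genotype")["mean"]
        want = (2 * (base + noise["L1"]) + 4 * (base + noise["L2"])) / 6
        order = [f"g{i:02d}" for i in range(n)]
        assert np.allclose(got[order], want, atol=1e-3)

    def test_check_present_everywhere_gets_one_mean(self, small_dataset):
        _, _, _, _, fb = small_dataset
        pooled = []
        for (yr, loc), grp in fb[fb["year"] == 2009].groupby(["year", "location"]):
            am = adjusted_means(reml_fit(grp, "M1", n_starts=1, check_hessian=False))
            t = am.table.assign(weight=smith_weights(am).to_numpy(),
                                year=yr, location=loc)
            pooled.append(t)
        pooled = pd.concat(pooled, ignore_index=True)
        out = fit_yearwise(pooled, pooled["weight"], n_starts=1)
        assert out.table["genotype"].is_unique

    def test_two_stage_equals_single_stage_gls_in_diagonal_case(self):
        """On one balanced single-location trial the two-stage genotype
        means coincide with one-step GLS means on the plots."""
        rng = np.random.default_rng(5)
        rows = []
        genos = [f"g{i}" for i in range(8)]
        for rep in (1, 2):
            for i, geno in enumerate(genos):
                rows.append({"genotype": geno, "tester": "T", "trial": "S",
                             "replicate": rep, "block": 1 + i // 4,
                             "row": 1 + i // 4, "col": i % 4 + 1,
                             "yield": rng.normal(40, 1.5)})
        fb = pd.DataFrame(rows)
        fit = reml_fit(fb, "M1", n_starts=1, check_hessian=False)
        am = adjusted_means(fit)
        s2 = fit_yearwise(am.table.assign(location="L", year=2009),
                          smith_weights(am), n_starts=1)
        direct, _ = gls_blue(fit.fit.y, fit.fit.X, fit.fit.V)
        got = s2.table.set_index("genotype")["mean"]
        want = pd.Series(direct, index=am.table["genotype"])
        assert np.allclose(got[want.index], want, atol=1e-6)


class TestAcrossYears:
    def _two_year_means(self, shift=5.0, seed=2):
        rng = np.random.default_rng(seed)
        rows = []
        for year in (2009, 2010):
            genos = [f"Y{year}G{i}" for i in range(25)] + ["CHK1"]
            for loc in ("L1", "L2"):
                for g in genos:
                    gv = 0.5 if g == "CHK1" else (hash(g) % 7 - 3) * 0.5
                    rows.append({
                        "genotype": g, "tester": f"T{year}", "location": loc,
                        "year": year,
                        "mean": 50 + (shift if year == 2010 else 0) + gv
                        + rng.normal(0, 0.3),
                        "se": 0.5,
                    })
        return pd.DataFrame(rows)

    def test_shared_check_absorbs_simulated_year_shift(self):
        df = self._two_year_means(shift=5.0)
        out = fit_across_years(df, n_starts=1).table
        g09 = out[out["genotype"].str.startswith("Y2009")]["mean"].mean()
        g10 = out[out["genotype"].str.startswith("Y2010")]["mean"].mean()
        raw09 = df[df["genotype"].str.startswith("Y2009")]["mean"].mean()
        raw10 = df[df["genotype"].str.startswith("Y2010")]["mean"].mean()
        assert abs(g10 - g09) < 0.3 * abs(raw10 - raw09)

    def test_disconnected_years_raise(self):
        df = self._two_year_means()
        df = df[df["genotype"] != "CHK1"]
        with pytest.raises(ValueError, match="common check"):
            fit_across_years(df)

    def test_duplicated_year_equals_single_year(self):
        """Feeding the same year twice returns the single-year means."""
        df = self._two_year_means(shift=0.0)
        dup = df[df["year"] == 2009].copy()
        base = fit_yearwise(
            dup.rename(columns={"se": "sd"}).assign(weight=1 / 0.25),
            np.full(len(dup), 1 / 0.25), n_starts=1,
        ).table.set_index("genotype")["mean"]
        twin = dup.assign(year=2010, tester="T2010")
        twin["genotype"] = dup["genotype"]  # identical genotype set
        both = pd.concat([dup, twin], ignore_index=True)
        out = fit_across_years(both, n_starts=1).table.set_index("genotype")["mean"]
        assert np.allclose(out[base.index], base, atol=1e-3)

    def test_year_main_effect_is_redundant_given_year_tester_cells(self):
        """Augmenting the fixed design with a year main effect leaves the
        fitted values unchanged: the year-by-tester cells already span it."""
        df = self._two_year_means().reset_index(drop=True)
        Xg = indicator_matrix(df["genotype"])
        at = df[["year", "tester"]].astype(str).agg(":".join, axis=1)
        Xat = indicator_matrix(at)[:, 1:]
        Xyear = indicator_matrix(df["year"])[:, 1:]
        V = np.diag(df["se"] ** 2) + 0.5 * Xg @ Xg.T
        b1, _ = gls_blue(df["mean"], np.hstack([Xg, Xat]), V)
        b2, _ = gls_blue(df["mean"], np.hstack([Xg, Xat, Xyear]), V)
        fitted1 = np.hstack([Xg, Xat]) @ b1
        fitted2 = np.hstack([Xg, Xat, Xyear]) @ b2
        assert np.allclose(fitted1, fitted2, atol=1e-8)


class TestYearCorrection:
    def test_subtracts_simple_year_mean(self):
        df = pd.DataFrame({"genotype": ["a", "b", "c"], "year": [1, 1, 1],
                           "mean": [10.0, 10.0, 13.0]})
        out = correct_year_means(df)
        assert np.allclose(out["mean_corrected"], [-1.0, -1.0, 2.0])

    def test_per_year_mean_exactly_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "genotype": [f"g{i}" for i in range(40)],
            "year": np.repeat([2009, 2010], 20),
            "mean": rng.normal(60, 3, 40) + np.repeat([0.0, 4.0], 20),
        })
        out = correct_year_means(df)
        per_year = out.groupby("year")["mean_corrected"].mean()
        assert np.allclose(per_year, 0.0, atol=1e-12)

    def test_alignment_after_shift(self):
        """A pure year shift disappears entirely from corrected means."""
        genos = [f"g{i}" for i in range(15)]
        gv = np.linspace(-2, 2, 15)
        df = pd.DataFrame({
            "genotype": genos * 2, "year": [2009] * 15 + [2010] * 15,
            "mean": np.concatenate([50 + gv, 55 + gv]),
        })
        out = correct_year_means(df)
        y09 = out[out["year"] == 2009].set_index("genotype")["mean_corrected"]
        y10 = out[out["year"] == 2010].set_index("genotype")["mean_corrected"]
        assert np.allclose(y09[genos], y10[genos], atol=1e-12)


class TestHeritability:
    def test_arithmetic(self):
        assert heritability(4.0, 2.0) == pytest.approx(0.8)
        assert heritability(3.0, 0.0) == pytest.approx(1.0)
        assert heritability(0.0, 2.0) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 50.0), st.floats(0.0, 50.0))
    def test_bounds_and_monotonicity(self, s2g, vd):
        h = heritability(s2g, vd)
        assert 0.0 <= h <= 1.0
        assert heritability(s2g, vd + 1.0) <= h + 1e-12

    def test_mean_variance_of_difference(self):
        C = np.array([[1.0, 0.5], [0.5, 2.0]])
        # var(g1 - g2) = 1 + 2 - 2*0.5 = 2
        assert mean_variance_of_difference(C) == pytest.approx(2.0)

    def test_estimates_on_simulated_year(self, small_dataset):
        _, _, _, truth, fb = small_dataset
        pooled = []
        for (yr, loc), grp in fb[fb["year"] == 2009].groupby(["year", "location"]):
            am = adjusted_means(reml_fit(grp, "M1", n_starts=1, check_hessian=False))
            pooled.append(am.table.assign(weight=smith_weights(am).to_numpy(),
                                          year=yr, location=loc))
        pooled = pd.concat(pooled, ignore_index=True)
        res = adhoc_heritability(pooled, pooled["weight"], n_starts=1)
        assert 0.0 <= res.h2 <= 1.0
        assert res.sigma2_g > 0.0


class TestRepeatability:
    def test_component_arithmetic(self):
        assert repeatability_from_components(4.0, 1.0, 1.0, 2.0) == pytest.approx(0.5)
        assert repeatability_from_components(0.0, 1.0, 1.0, 2.0) == 0.0

    def test_all_zero_components_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            repeatability_from_components(0.0, 0.0, 0.0, 0.0)

    def test_recovery_on_simulated_location(self):
        """Mean repeatability over 10 simulated locations sits near the
        plug-in truth 0.4 (sigma2_G=2 vs 0.5 + 0.5 + 2 noise)."""
        from conftest import small_met_config
        from metgp.simulate import (simulate_genetic_values,
                                    simulate_marker_panel, simulate_met)

        vals = []
        for seed in range(10):
            cfg = small_met_config(
                n_years=1, locations_per_year=1, genotypes_per_trial=60,
                n_crosses=35, cross_size_range=(2, 2), n_markers=60,
                shared_checks_across_years=0, v_trial=0.0, v_rep=0.5,
                v_block=0.5, v_row=0.0, v_col=0.0, v_spatial=1.0,
                v_nugget=1.0, rho_row=0.0, rho_col=0.0, tester_sd=0.0,
                location_sd=0.0, year_sd=0.0, target_plot_h2=0.5, seed=seed,
            )
            panel, cm = simulate_marker_panel(cfg)
            truth = simulate_genetic_values(panel, cfg, cm)
            fb = simulate_met(cfg, panel, truth)
            fb = fb[fb["tester"] == "T1"]
            vals.append(repeatability(fb, n_starts=1).repeatability)
        assert np.mean(vals) == pytest.approx(0.4, abs=0.1)
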