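"""Mixed models, PMM imputation, LASSO ensemble selection, Rubin pooling."""

import numpy as np
import pandas as pd
import pytest

from aortamech.simulate import (
    CohortSimParams,
    cohort_candidates,
    simulate_cohort,
)
from aortamech.stats import (
    RankDeficiencyError,
    UnimputableColumnError,
    bootstrap_backward_selection,
    design_matrix,
    ensemble_select,
    fit_random_intercept,
    impute_pmm,
    lasso_coefficients,
    lasso_per_imputation,
    pooled_growth_model,
)


@pytest.fixture(scope="module")
def cohort30():
    params = CohortSimParams(n_patients=30, missing_fraction=0.0, seed=1)
    return simulate_cohort(params)


@pytest.fixture(scope="module")
def holey():
    params = CohortSimParams(n_patients=60, missing_fraction=0.2, seed=4)
    return simulate_cohort(params)


@pytest.fixture(scope="module")
def histology_table():
    rng = np.random.default_rng(5)
    n_pat, per = 30, 4
    n = n_pat * per
    table = pd.DataFrame(
        {
            "patient": np.repeat([f"p{i}" for i in range(n_pat)], per),
            "fibrosis": rng.integers(0, 4, n).astype(float),
            "mema": rng.integers(0, 4, n).astype(float),
            "medionecrosis": rng.integers(0, 4, n).astype(float),
            "elastin_frag": rng.integers(0, 4, n).astype(float),
        }
    )
    table["E_M"] = (
        600.0 + 180.0 * table["fibrosis"]
        + np.repeat(rng.normal(0, 50, n_pat), per)
        + rng.normal(0, 120, n)
    )
    return table


class TestRandomIntercept:
    def test_direction_effect_recovery(self, cohort30):
        """Longitudinal modulus deficit recovered within 3 SEs of the truth."""
        table, _ = cohort30
        fit = fit_random_intercept(table, "E_M", ["direction", "segment"])
        row = fit.terms.loc["direction[longitudinal]"]
        assert abs(row["estimate"] - (-166.8)) < 3 * row["se"]
        assert fit.n_groups == 30
        assert fit.n_rows == len(table)

    def test_wald_ci_structure(self, cohort30):
        table, _ = cohort30
        fit = fit_random_intercept(table, "E_M", ["direction"])
        t = fit.terms
        np.testing.assert_allclose(
            t["ci_high"] - t["estimate"], 1.959963984540054 * t["se"], rtol=1e-12
        )

    def test_zero_group_variance(self):
        rng = np.random.default_rng(0)
        n = 200
        table = pd.DataFrame(
            {
                "patient": np.repeat([f"p{i}" for i in range(50)], 4),
                "x": rng.normal(size=n),
            }
        )
        # noise demeaned within patients: the between-patient variance is
        # exactly zero, so REML should sit at the boundary
        noise = rng.normal(size=n)
        noise -= pd.Series(noise).groupby(table["patient"]).transform("mean").to_numpy()
        table["y"] = 2.0 * table["x"] + noise
        fit = fit_random_intercept(table, "y", ["x"])
        assert fit.re_var <= 1e-6 * fit.resid_var + 1e-12

    def test_single_group_rejected(self):
        table = pd.DataFrame(
            {"patient": ["p0"] * 10, "x": np.arange(10.0), "y": np.arange(10.0)}
        )
        with pytest.raises(RankDeficiencyError):
            fit_random_intercept(table, "y", ["x"])

    def test_aliased_terms_named(self, cohort30):
        table, _ = cohort30
        table = table.copy()
        table["radius_twin"] = table["radius"]
        with pytest.raises(RankDeficiencyError) as err:
            fit_random_intercept(table, "growth_rate", ["radius", "radius_twin"])
        assert any("radius" in a for a in err.value.aliased)

    def test_missing_values_rejected(self):
        table = pd.DataFrame(
            {"patient": ["a", "a", "b", "b"], "x": [1.0, np.nan, 2.0, 3.0],
             "y": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(ValueError, match="impute"):
            fit_random_intercept(table, "y", ["x"])


class TestImputePMM:
    def test_complete_table_passes_through(self, cohort30):
        table, _ = cohort30
        out = impute_pmm(table, m=3, seed=0, exclude=["patient"])
        assert len(out) == 3
        for t in out:
            pd.testing.assert_frame_equal(t, table)

    def test_donor_property_and_m(self, holey):
        """Every imputed value is a value the column actually took; m tables out."""
        table, truth = holey
        out = impute_pmm(table, m=5, seed=1, exclude=["patient"])
        assert len(out) == 5
        for col in ("E_M", "toughness", "eps_rel"):
            observed = set(table[col].dropna())
            miss = table[col].isna()
            for t in out:
                assert not t[col].isna().any()
                assert set(t.loc[miss, col]) <= observed

    def test_observed_cells_untouched(self, holey):
        table, _ = holey
        out = impute_pmm(table, m=2, seed=1, exclude=["patient"])
        for col in ("E_M", "toughness"):
            obs = table[col].notna()
            for t in out:
                pd.testing.assert_series_equal(t.loc[obs, col], table.loc[obs, col])

    def test_seed_reproducibility(self, holey):
        table, _ = holey
        a = impute_pmm(table, m=2, seed=9, exclude=["patient"])
        b = impute_pmm(table, m=2, seed=9, exclude=["patient"])
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        c = impute_pmm(table, m=1, seed=10, exclude=["patient"])
        assert not a[0].equals(c[0])

    def test_all_missing_column_rejected(self, holey):
        table, _ = holey
        table = table.copy()
        table["ghost"] = np.nan
        with pytest.raises(UnimputableColumnError):
            impute_pmm(table, m=2, seed=0, exclude=["patient"])


class TestLasso:
    def test_strong_signal_recovered_with_sign(self):
        rng = np.random.default_rng(0)
        n = 200
        table = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(1, 12)})
        table["y"] = 2.0 * table["x1"] + rng.normal(0, 0.1, n)
        picks = lasso_per_imputation(
            table, "y", [f"x{i}" for i in range(1, 12)], seed=0, group=None
        )
        assert picks.get("x1") == 1

    def test_pure_noise_near_empty_selection(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            table = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(1, 11)})
            table["y"] = rng.normal(0, 1.0, n)
            picks = lasso_per_imputation(
                table, "y", [f"x{i}" for i in range(1, 11)], seed=seed, group=None
            )
            hits += len(picks) <= 1
        assert hits >= 8

    def test_constant_predictor_warned_and_dropped(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"x1": rng.normal(size=50), "flat": np.ones(50)})
        table["y"] = table["x1"]
        with pytest.warns(UserWarning, match="zero variance"):
            picks = lasso_per_imputation(table, "y", ["x1", "flat"], seed=0, group=None)
        assert "flat" not in picks

    def test_zero_penalty_matches_least_squares(self):
        """With the penalty forced to zero the fit is plain OLS."""
        rng = np.random.default_rng(2)
        n, p = 50, 8
        table = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(p)})
        table["y"] = table["x0"] - 0.5 * table["x3"] + rng.normal(0, 0.5, n)
        cands = [f"x{i}" for i in range(p)]
        coef, _ = lasso_coefficients(table, "y", cands, alpha=0.0, group=None)
        X, _ = design_matrix(table, cands)
        Xs = X.to_numpy(float)
        Xs = (Xs - Xs.mean(0)) / Xs.std(0)
        Xc = np.column_stack([np.ones(n), Xs])
        beta = np.linalg.lstsq(Xc, table["y"].to_numpy(), rcond=None)[0][1:]
        np.testing.assert_allclose([coef[c] for c in cands], beta, atol=1e-6)


class TestEnsembleSelect:
    def test_inclusion_and_sign_rules(self):
        """12/20 with 11+/1- selected; 11/20 rejected; 14/20 with 10+/4- rejected."""
        m = 20
        runs = []
        for i in range(m):
            picks = {}
            if i < 12:  # a: in 12, signs 11 pos / 1 neg
                picks["a"] = 1 if i < 11 else -1
            if i < 11:  # b: in 11
                picks["b"] = 1
            if i < 14:  # c: in 14, 10 pos / 4 neg
                picks["c"] = 1 if i < 10 else -1
            runs.append(picks)
        out = ensemble_select(runs)
        assert bool(out.loc["a", "selected"])
        assert out.loc["a", "inclusion_fraction"] == pytest.approx(0.6)
        assert out.loc["a", "sign_consistency"] == pytest.approx(11 / 12)
        assert not bool(out.loc["b", "selected"])
        assert not bool(out.loc["c", "selected"])
        assert out.loc["c", "sign_consistency"] == pytest.approx(10 / 14)

    def test_permutation_invariance(self):
        runs = [{"a": 1}, {"a": 1, "b": -1}, {"b": -1}, {}]
        fwd = ensemble_select(runs)
        rev = ensemble_select(runs[::-1])
        pd.testing.assert_frame_equal(fwd, rev)

    def test_empty_input(self):
        assert ensemble_select([]).empty


class TestPooling:
    def test_identical_tables_degenerate_pooling(self, cohort30):
        table, _ = cohort30
        single = fit_random_intercept(table, "growth_rate", ["radius", "segment"])
        pooled = pooled_growth_model([table] * 3, "growth_rate", ["radius", "segment"])
        np.testing.assert_allclose(
            pooled.terms["estimate"], single.terms["estimate"], rtol=1e-10
        )
        np.testing.assert_allclose(pooled.terms["between_var"], 0.0, atol=1e-12)
        np.testing.assert_allclose(pooled.terms["se"], single.terms["se"], rtol=1e-10)

    def test_m_equal_one(self, cohort30):
        table, _ = cohort30
        pooled = pooled_growth_model([table], "growth_rate", ["radius"])
        np.testing.assert_allclose(
            pooled.terms["se"], pooled.terms["within_se"], rtol=1e-12
        )

    def test_pooled_se_at_least_within_se(self):
        params = CohortSimParams(n_patients=60, seed=12)
        table, _ = simulate_cohort(params)
        completed = impute_pmm(table, m=8, seed=12, exclude=["patient"])
        pooled = pooled_growth_model(
            completed, "growth_rate", ["radius", "eps_rel", "segment"]
        )
        assert (pooled.terms["se"] >= pooled.terms["within_se"] - 1e-12).all()
        assert (pooled.terms["between_var"] > 0).any()

    def test_relative_strain_coefficient_recovery(self):
        """Pooled growth model recovers the 3.64 mm/y-per-unit truth within 3 SEs."""
        params = CohortSimParams(n_patients=150, seed=7)
        table, _ = simulate_cohort(params)
        completed = impute_pmm(table, m=20, seed=7, exclude=["patient"])
        pooled = pooled_growth_model(
            completed, "growth_rate", ["radius", "eps_rel", "disease_class", "segment"]
        )
        row = pooled.terms.loc["eps_rel"]
        assert abs(row["estimate"] - 3.64) < 3 * row["se"]

    def test_inconsistent_terms_rejected(self, cohort30):
        table, _ = cohort30
        other = table.drop(columns=["radius"]).assign(radius2=table["radius"])
        with pytest.raises((ValueError, KeyError)):
            pooled_growth_model([table, other], "growth_rate", ["radius"])


class TestBootstrapBackward:
    def test_strong_signal_high_frequency(self, histology_table):
        """Fibrosis-modulus association (180 kPa/grade) survives nearly every replicate."""
        freq = bootstrap_backward_selection(
            histology_table, "E_M",
            ["fibrosis", "mema", "medionecrosis", "elastin_frag"], B=100, seed=0,
        )
        assert freq.loc["fibrosis", "frequency"] >= 0.9

    def test_null_candidates_low_frequency(self):
        freqs = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n_pat, per = 30, 4
            n = n_pat * per
            table = pd.DataFrame(
                {
                    "patient": np.repeat([f"p{i}" for i in range(n_pat)], per),
                    **{f"x{i}": rng.normal(size=n) for i in range(4)},
                }
            )
            table["y"] = rng.normal(size=n)
            freq = bootstrap_backward_selection(
                table, "y", [f"x{i}" for i in range(4)], B=20, seed=seed
            )
            freqs.append(freq["frequency"].mean())
        assert np.mean(freqs) <= 0.5

    def test_single_replicate_binary(self, histology_table):
        freq = bootstrap_backward_selection(
            histology_table, "E_M", ["fibrosis", "mema"], B=1, seed=0
        )
        assert set(freq["frequency"]) <= {0.0, 1.0}

    def test_too_many_candidates_rejected(self):
        table = pd.DataFrame({"patient": ["a", "b"], "x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="ill-posed"):
            bootstrap_backward_selection(table, "y", ["x", "y", "patient"], B=2)
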