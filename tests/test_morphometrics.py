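"""Shape ratios, mass regression, species means, PCA and ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from handevol.morphometrics import (
    ELEMENTS,
    MissingElementError,
    SpecimenRecord,
    compute_ehp,
    compute_ihp,
    estimate_body_mass,
    fit_mass_regression,
    group_compare,
    pca_covariance,
    species_means,
)


def rec(taxon="Pan", sid="s1", thumb=(40, 30, 20), ray=(50, 35, 25), **kw):
    return SpecimenRecord(
        taxon, sid,
        mc1=thumb[0], pp1=thumb[1], dp1=thumb[2],
        mc4=ray[0], pp4=ray[1], ip4=ray[2], **kw,
    )


class TestIHP:
    def test_ratio_excludes_fourth_distal(self):
        assert compute_ihp(rec()) == pytest.approx(90 / 110)

    def test_equal_sums_give_unity(self):
        assert compute_ihp(rec(thumb=(30, 30, 30), ray=(40, 30, 20))) == 1.0

    def test_missing_distal_phalanx_named_in_error(self):
        r = rec()
        r.dp1 = None
        with pytest.raises(MissingElementError, match="dp1"):
            compute_ihp(r)


class TestEHP:
    @pytest.mark.parametrize("bm,length,expected", [(8, 54, 27.0), (27, 81, 27.0)])
    def test_cube_root_standardization(self, bm, length, expected):
        r = rec(thumb=(length,) * 3, ray=(length,) * 3, bm_kg=bm)
        assert compute_ehp(r)["mc1"] == pytest.approx(expected)

    def test_unit_mass_identity(self):
        r = rec(bm_kg=1.0)
        assert compute_ehp(r)["mc4"] == pytest.approx(50.0)

    def test_no_mass_no_standardization(self):
        with pytest.raises(MissingElementError):
            compute_ehp(rec())

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_consistency(self, c):
        """Scaling all lengths by c scales EHP by c, leaves IHP unchanged."""
        base = rec(bm_kg=8.0)
        scaled = rec(
            thumb=(40 * c, 30 * c, 20 * c), ray=(50 * c, 35 * c, 25 * c), bm_kg=8.0
        )
        assert compute_ihp(scaled) == pytest.approx(compute_ihp(base))
        e0, e1 = compute_ehp(base), compute_ehp(scaled)
        for k in ELEMENTS:
            assert e1[k] == pytest.approx(c * e0[k], rel=1e-9)


class TestMassRegression:
    def test_noiseless_recovery_exact(self):
        fhd = np.linspace(10, 60, 12)
        bm = 10 ** (-2.0 + 2.5 * np.log10(fhd))
        reg = fit_mass_regression(list(zip(fhd, bm)))
        assert reg.slope == pytest.approx(2.5, abs=1e-10)
        assert reg.intercept == pytest.approx(-2.0, abs=1e-10)

    def test_cube_scaling(self):
        fhd = np.array([10.0, 20.0, 40.0])
        bm = 10 ** (0.5 + 3.0 * np.log10(fhd))
        reg = fit_mass_regression(list(zip(fhd, bm)))
        assert reg.predict(24.0) == pytest.approx(8 * reg.predict(12.0), rel=1e-9)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        fhd = rng.uniform(15, 55, 50)
        ly = -2.0 + 2.5 * np.log10(fhd) + rng.normal(0, 0.05, 50)
        reg = fit_mass_regression(list(zip(fhd, 10**ly)))
        # closed-form normal equations, computed independently
        X = np.column_stack([np.ones(50), np.log10(fhd)])
        beta = np.linalg.solve(X.T @ X, X.T @ ly)
        assert reg.intercept == pytest.approx(beta[0], abs=1e-10)
        assert reg.slope == pytest.approx(beta[1], abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_mass_regression([(10, 5), (20, 15)])

    def test_estimate_inverts_regression(self):
        fhd = np.linspace(20, 50, 10)
        bm = 10 ** (-1.5 + 2.2 * np.log10(fhd))
        reg = fit_mass_regression(list(zip(fhd, bm)))
        r = rec(fhd_mm=35.0)
        out = estimate_body_mass(r, reg)
        assert out.bm_kg == pytest.approx(10 ** (-1.5 + 2.2 * np.log10(35.0)))
        assert out.mass_estimated

    def test_dual_reference_averaging(self):
        """Quadruped and biped regressions applied to one fossil, averaged."""
        fhd = np.linspace(20, 50, 10)
        reg_a = fit_mass_regression(
            list(zip(fhd, 10 ** (-1.0 + 2.0 * np.log10(fhd))))
        )
        reg_b = fit_mass_regression(
            list(zip(fhd, 10 ** (-2.0 + 2.5 * np.log10(fhd))))
        )
        r = rec(fhd_mm=30.0)
        out = estimate_body_mass(r, [reg_a, reg_b])
        expected = (reg_a.predict(30.0) + reg_b.predict(30.0)) / 2
        assert out.bm_kg == pytest.approx(expected)

    def test_no_fhd_error(self):
        with pytest.raises(MissingElementError):
            estimate_body_mass(rec(), fit_mass_regression([(1, 1), (2, 8), (4, 64)]))


class TestSpeciesMeans:
    def test_single_specimen_equals_value(self):
        m = species_means([rec(bm_kg=8.0)], "ihp")
        assert m.loc["Pan", "ihp"] == pytest.approx(90 / 110)

    def test_mean_of_two(self):
        r1 = rec(sid="a", thumb=(40, 24, 16), ray=(50, 30, 20))  # 0.8
        r2 = rec(sid="b", thumb=(45, 27, 18), ray=(50, 30, 20))  # 0.9
        m = species_means([r1, r2], "ihp")
        assert m.loc["Pan", "ihp"] == pytest.approx(0.85)

    def test_mean_of_ratios_not_ratio_of_means(self):
        # construct specimens where the two orders of operations differ
        r1 = rec(sid="a", thumb=(10, 10, 10), ray=(60, 30, 30))  # 30/120 = 0.25
        r2 = rec(sid="b", thumb=(40, 40, 40), ray=(30, 20, 10))  # 120/60 = 2.0
        mean_of_ratios = (0.25 + 2.0) / 2
        ratio_of_means = (75 + 75) / (90 + 60)  # 150/150 = 1.0
        assert mean_of_ratios != pytest.approx(ratio_of_means)
        m = species_means([r1, r2], "ihp")
        assert m.loc["Pan", "ihp"] == pytest.approx(mean_of_ratios)

    def test_incomplete_taxon_dropped_with_warning(self, caplog):
        r1 = rec(bm_kg=8.0)
        r2 = rec(taxon="Gorilla", sid="g1")
        r2.mc1 = None
        with caplog.at_level("WARNING"):
            m = species_means([r1, r2], "ehp")
        assert "Gorilla" not in m.index
        assert any("Gorilla" in msg for msg in caplog.messages)


class TestPCA:
    def test_collinear_data_rank_one(self):
        rng = np.random.default_rng(0)
        u = rng.normal(0, 1, 30)
        df = pd.DataFrame({"a": u, "b": 2 * u})
        res = pca_covariance(df)
        assert res.proportion[0] == pytest.approx(1.0)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_eigenvalues_similar(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 1, (4000, 3)))
        res = pca_covariance(df)
        assert res.eigenvalues[0] / res.eigenvalues[-1] < 1.2

    def test_fixture_matches_eigen_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (6, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        res = pca_covariance(pd.DataFrame(X))
        # independent oracle: eigenvalues of the explicitly formed
        # covariance via the general eigensolver
        cov = np.cov(X, rowvar=False, ddof=1)
        expected = np.sort(np.linalg.eigvals(cov).real)[::-1]
        np.testing.assert_allclose(res.eigenvalues, expected, atol=1e-8)

    def test_scores_reconstruct_centered_data(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 2, (15, 5))
        res = pca_covariance(pd.DataFrame(X))
        recon = res.scores.to_numpy() @ res.eigenvectors.T + res.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)
        assert res.proportion.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            res.scores.mean(axis=0), np.zeros(5), atol=1e-9
        )
        np.testing.assert_allclose(
            res.scores.var(axis=0, ddof=1), res.eigenvalues, rtol=1e-8
        )

    def test_constant_column_ok_single_row_not(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        res = pca_covariance(df)
        assert res.eigenvalues[-1] == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            pca_covariance(df.iloc[:1])


class TestGroupCompare:
    def test_identical_means_f_zero(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a"] * 3 + ["b"] * 3
        res = group_compare(vals, groups)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_sum_of_squares_oracle(self):
        a = np.array([4.1, 5.2, 6.3, 5.5])
        b = np.array([7.0, 8.1, 7.7])
        res = group_compare(np.concatenate([a, b]), ["a"] * 4 + ["b"] * 3)
        # hand SS decomposition
        grand = np.concatenate([a, b]).mean()
        ssb = 4 * (a.mean() - grand) ** 2 + 3 * (b.mean() - grand) ** 2
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_oracle = (ssb / 1) / (ssw / 5)
        assert res.f_statistic == pytest.approx(f_oracle, abs=1e-10)

    def test_bonferroni_multiplies_by_pair_count(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(m, 1, 10) for m in (0, 0.5, 3)])
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = group_compare(vals, groups)
        assert len(res.pairwise) == 3
        for _, row in res.pairwise.iterrows():
            assert row["p_bonferroni"] == pytest.approx(
                min(1.0, row["p_raw"] * 3)
            )

    def test_degenerate_groups_listed(self):
        with pytest.raises(ValueError, match="b"):
            group_compare([1.0, 2.0, 3.0], ["a", "a", "b"])
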