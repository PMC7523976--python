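"""Face-centred CCD construction, response-surface ANOVA, paired t-test."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from plaquestress import doe_engine as de


@pytest.fixture()
def factors4():
    return de.default_factors()


@pytest.fixture()
def design4(factors4):
    return de.face_centred_ccd(factors4)


def ess_pvalues(design, terms, y, factor_names):
    """Brute-force extra-sum-of-squares partial-F p-values."""
    X = de.design_matrix(design, factor_names, terms)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(((y - X @ beta) ** 2).sum())
    n, p = X.shape
    out = []
    for j in range(len(terms)):
        Xr = np.delete(X, j + 1, axis=1)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rss_r = float(((y - Xr @ br) ** 2).sum())
        F = (rss_r - rss_full) / (rss_full / (n - p))
        out.append(scipy.stats.f.sf(F, 1, n - p))
    return np.array(out)


class TestFaceCentredCcd:
    def test_four_factor_run_count(self, design4):
        assert len(design4) == 16 + 8 + 1
        assert design4.point_type.value_counts().to_dict() == {
            "factorial": 16, "axial": 8, "center": 1,
        }

    def test_two_factor_design_is_the_full_grid(self):
        d = de.face_centred_ccd([de.Factor("a", 0, 1), de.Factor("b", 0, 1)])
        assert len(d) == 9
        pts = set(zip(d.a_coded, d.b_coded))
        assert pts == set(itertools.product([-1.0, 0.0, 1.0], repeat=2))

    def test_factorial_balance_and_orthogonality(self, design4, factors4):
        fac = design4[design4.point_type == "factorial"]
        cols = [f"{f.name}_coded" for f in factors4]
        assert np.allclose(fac[cols].mean(), 0.0)
        C = fac[cols].to_numpy()
        assert np.allclose(C.T @ C, 16 * np.eye(4))

    def test_axial_points_sit_on_faces(self, design4, factors4):
        ax = design4[design4.point_type == "axial"]
        coded = ax[[f"{f.name}_coded" for f in factors4]].to_numpy()
        assert set(np.unique(coded)) <= {-1.0, 0.0, 1.0}
        assert np.all(np.abs(coded).sum(axis=1) == 1)

    def test_natural_decoding_midpoint(self, design4):
        centre = design4[design4.point_type == "center"].iloc[0]
        assert centre["LC"] == pytest.approx((0.1 + 50.0) / 2)
        assert centre["FT"] == pytest.approx((2.7 + 342.1) / 2)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            de.face_centred_ccd([de.Factor("a", 0, 1), de.Factor("a", 1, 2)])

    def test_bad_limits_rejected(self):
        with pytest.raises(ValueError):
            de.Factor("a", 1.0, 1.0)


class TestCrossWithCategorical:
    def test_campaign_size(self, design4):
        full = de.cross_with_categorical(
            design4, ("isotropic", "anisotropic"), ("geometry1", "geometry2")
        )
        assert len(full) == 100
        assert full.run.is_unique

    def test_identity_case(self, design4):
        one = de.cross_with_categorical(design4, ("anisotropic",), ("g",))
        assert len(one) == len(design4)
        np.testing.assert_array_equal(one.WT.to_numpy(), design4.WT.to_numpy())


class TestFitResponseSurface:
    def test_exact_linear_response(self, design4):
        d = design4.copy()
        d["y"] = 3.0 + 2.0 * d["WT_coded"]
        rs = de.fit_response_surface(d, "y")
        labels = [de.term_label(t) for t in rs.terms]
        assert rs.coefficients[0] == pytest.approx(3.0, abs=1e-10)
        assert rs.coefficients[1 + labels.index("WT")] == pytest.approx(2.0, abs=1e-10)
        assert rs.r_squared == pytest.approx(1.0)
        others = np.delete(rs.coefficients[1:], labels.index("WT"))
        np.testing.assert_allclose(others, 0.0, atol=1e-10)

    def test_pvalues_match_extra_sum_of_squares_oracle(self, design4, factors4):
        rng = np.random.default_rng(0)
        names = [f.name for f in factors4]
        for _ in range(3):
            d = design4.copy()
            d["y"] = rng.normal(size=len(d))
            rs = de.fit_response_surface(d, "y")
            oracle = ess_pvalues(d, rs.terms, d["y"].to_numpy(), names)
            np.testing.assert_allclose(rs.anova.p_value.to_numpy(), oracle, atol=1e-8)

    def test_pure_quadratic_detected(self, design4):
        d = design4.copy()
        rng = np.random.default_rng(1)
        d["y"] = d["WT_coded"] ** 2 + 0.01 * rng.normal(size=len(d))
        rs = de.fit_response_surface(d, "y")
        a = rs.anova.set_index("term")
        assert a.loc["WT*WT", "significant"]
        assert abs(a.loc["WT", "coefficient"]) < 0.05 * a.loc["WT*WT", "coefficient"]

    def test_rank_deficiency_reported(self, design4):
        small = design4.head(10).copy()
        small["y"] = 1.0
        with pytest.raises(de.RankDeficientDesign):
            de.fit_response_surface(small, "y")

    def test_backward_elimination_keeps_hierarchy(self, design4):
        rng = np.random.default_rng(2)
        d = design4.copy()
        d["y"] = (10 + 5 * d.WT_coded * d.FT_coded + 0.2 * rng.normal(size=len(d)))
        rs = de.fit_response_surface(d, "y", reduce=True)
        labels = [de.term_label(t) for t in rs.terms]
        assert "WT*FT" in labels
        # linear parents of a retained interaction are kept
        assert "WT" in labels and "FT" in labels

    def test_residual_normality_reported(self, design4):
        rng = np.random.default_rng(3)
        d = design4.copy()
        d["y"] = 1.0 + rng.normal(size=len(d))
        rs = de.fit_response_surface(d, "y")
        assert 0.0 <= rs.normality_p <= 1.0


class TestPairedTTest:
    def test_hand_computed_statistic(self):
        a = np.array([3.1, 4.0, 5.2, 6.1])
        b = np.array([2.0, 3.5, 4.0, 6.0])
        res = de.paired_t_test(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * scipy.stats.t.sf(abs(t), len(d) - 1)
        assert res.mean_difference == pytest.approx(d.mean())
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_constant_shift_is_degenerate(self):
        res = de.paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.mean_difference == pytest.approx(-1.0)
        assert res.degenerate and res.p_value is None

    def test_identical_vectors_degenerate(self):
        res = de.paired_t_test([1.0, 2.0], [1.0, 2.0])
        assert res.mean_difference == 0.0
        assert res.degenerate

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(size=10)
        perm = rng.permutation(10)
        r1 = de.paired_t_test(a, b)
        r2 = de.paired_t_test(a[perm], b[perm])
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.mean_difference == pytest.approx(r2.mean_difference)


class TestCubeSummary:
    def test_additive_model_corner_predictions(self, design4):
        d = design4.copy()
        d["y"] = 1.0 + 2 * d.WT_coded - 3 * d.ST_coded + 0.5 * d.LC_coded
        rs = de.fit_response_surface(d, "y")
        cubes = de.cube_summary(rs)
        assert len(cubes) == 16
        for row in cubes.itertuples():
            expect = 1.0 + 2 * row.WT - 3 * row.ST + 0.5 * row.LC
            assert row.predicted == pytest.approx(expect, abs=1e-8)

    def test_panels_split_on_ft(self, design4):
        d = design4.copy()
        d["y"] = d.FT_coded
        cubes = de.cube_summary(de.fit_response_surface(d, "y"))
        assert set(cubes.panel) == {"low FT", "high FT"}
        assert (cubes.groupby("panel").size() == 8).all()
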