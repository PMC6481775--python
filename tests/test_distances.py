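"""Genetic/geographic/phenotypic distances and heterosis~distance regression."""

import numpy as np
import pandas as pd
import pytest

from allohet import distances as dist


@pytest.fixture()
def toy_snps():
    # 10 genotypes x 10 markers with exactly 3 designed failures:
    # m01 monomorphic (MAF 0), m09 call rate 0.8, m10 call rate 0.7; the
    # seven other markers are polymorphic with complete calls.
    rng = np.random.default_rng(5)
    X = rng.integers(0, 2, size=(10, 10)).astype(float)
    X[:, 0] = 0.0  # m01 monomorphic -> MAF 0, removed
    X[0:2, 8] = np.nan  # m09 call rate 0.8, removed at 0.85
    X[0:3, 9] = np.nan  # m10 call rate 0.7, removed
    for j in range(1, 8):  # keep the rest polymorphic
        X[0, j] = 0.0
        X[1, j] = 1.0
    ids = [f"g{i}" for i in range(10)]
    markers = [f"m{j:02d}" for j in range(1, 11)]
    return pd.DataFrame(X, index=pd.Index(ids, name="genotype_id"), columns=markers)


class TestFilter:
    def test_designed_failures_are_removed(self, toy_snps):
        filtered, report = dist.filter_snps(toy_snps, maf_min=0.05, call_rate_min=0.85)
        assert report["n_markers_before"] == 10
        assert filtered.shape[1] == 7
        for gone in ("m01", "m09", "m10"):
            assert gone not in filtered.columns

    def test_call_rate_at_threshold_boundary(self):
        X = pd.DataFrame(
            {"m1": [0, 1, 0, 1, np.nan, 0, 1, 0, 1, 0], "m2": [0, 1] * 5},
            index=[f"g{i}" for i in range(10)],
        )
        filtered, _ = dist.filter_snps(X, call_rate_min=0.95)
        assert list(filtered.columns) == ["m2"]
        filtered, _ = dist.filter_snps(X, call_rate_min=0.9)
        assert list(filtered.columns) == ["m1", "m2"]

    def test_empty_result_is_not_an_error(self, toy_snps):
        filtered, report = dist.filter_snps(toy_snps, maf_min=0.51)
        assert filtered.shape[1] == 0
        assert report["n_markers_after"] == 0


class TestGeneticDistance:
    def test_identical_rows_have_zero_distance(self, toy_snps):
        m = toy_snps.copy()
        m.loc["g1"] = m.loc["g0"]
        assert dist.genetic_distance(m, ("g0", "g1")) == 0.0

    def test_single_differing_site_counts_two_alleles(self):
        m = pd.DataFrame(
            [[0.0, 1.0, 0.0], [0.0, 0.0, 0.0]],
            index=["a", "b"],
            columns=["m1", "m2", "m3"],
        )
        assert dist.genetic_distance(m, ("a", "b")) == 2.0
        assert dist.genetic_distance(m, ("a", "b"), alleles_per_site=1) == 1.0

    def test_matrix_matches_brute_force_oracle(self, rng):
        X = rng.integers(0, 2, size=(8, 50)).astype(float)
        X[rng.random(X.shape) < 0.1] = np.nan
        ids = [f"g{i}" for i in range(8)]
        m = pd.DataFrame(X, index=ids, columns=[f"s{j}" for j in range(50)])
        D = dist.genetic_distance_matrix(m)
        for i in range(8):
            for j in range(8):
                a, b = X[i], X[j]
                ok = np.isfinite(a) & np.isfinite(b)
                expected = 2 * np.sum(a[ok] != b[ok])
                assert D.iloc[i, j] == expected
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_log_transform_flags_identical_pairs(self):
        m = pd.DataFrame(
            [[0.0, 1.0], [0.0, 1.0], [1.0, 0.0]],
            index=["a", "b", "c"],
            columns=["m1", "m2"],
        )
        D = dist.genetic_distance_matrix(m, log10=True)
        assert np.isnan(D.at["a", "b"])  # identical genotypes excluded on log scale
        assert D.at["a", "c"] == pytest.approx(np.log10(4.0))


class TestTopSubset:
    def test_top_one_of_hundred(self):
        w = pd.Series(np.arange(100.0), index=[f"m{i:03d}" for i in range(100)])
        assert dist.top_snp_subset(w, 0.01) == ["m099"]

    def test_ties_broken_by_marker_id(self):
        w = pd.Series(1.0, index=[f"m{i:03d}" for i in range(100)])
        assert dist.top_snp_subset(w, 0.01) == ["m000"]

    def test_absolute_value_ranking(self):
        w = pd.Series([-5.0, 4.0, 3.0] + [0.1] * 97, index=[f"m{i:03d}" for i in range(100)])
        assert dist.top_snp_subset(w, 0.02) == ["m000", "m001"]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            dist.top_snp_subset(pd.Series([1.0]), 0.0)


class TestGeographicDistance:
    coords = pd.DataFrame(
        {
            "genotype_id": ["a", "b", "c"],
            "longitude": [0.0, 1.0, 0.0],
            "latitude": [0.0, 0.0, 0.0],
        }
    )

    def test_identical_points(self):
        assert dist.geographic_distance(self.coords, ("a", "c")) == 0.0

    def test_one_degree_along_equator(self):
        # 2*pi*R/360 with R the mean Earth radius
        d = dist.geographic_distance(self.coords, ("a", "b"))
        assert d == pytest.approx(111.195, abs=0.01)

    def test_symmetry(self):
        assert dist.geographic_distance(self.coords, ("a", "b")) == pytest.approx(
            dist.geographic_distance(self.coords, ("b", "a"))
        )

    def test_out_of_range_rejected(self):
        bad = pd.DataFrame(
            {"genotype_id": ["a", "b"], "longitude": [0.0, 200.0], "latitude": [0.0, 0.0]}
        )
        with pytest.raises(ValueError):
            dist.geographic_distance(bad, ("a", "b"))

    def test_matrix_agrees_with_pairwise(self):
        D = dist.geographic_distance_matrix(self.coords)
        assert D.at["a", "b"] == pytest.approx(
            dist.geographic_distance(self.coords, ("a", "b"))
        )
        assert np.all(np.diag(D) == 0)


class TestPhenotypicDistance:
    def _summaries(self):
        return pd.DataFrame(
            {
                "genotype_id": ["a", "b", "c"],
                "type": "accession",
                "parent1": None,
                "parent2": None,
                "mass_mg": [10.0, 100.0, 40.0],
                "age_d": [20.0, 40.0, 30.0],
                "growth_mg_per_d": [0.5, 2.5, 1.3],
                "fruit_n": [30.0, 150.0, 80.0],
            }
        )

    def test_identical_vectors_have_zero_distance(self):
        s = self._summaries()
        s.loc[1] = s.loc[0]
        s.loc[1, "genotype_id"] = "b"
        assert dist.phenotypic_distance(s, ("a", "b")) == pytest.approx(0.0)

    def test_mass_mode_absolute_difference(self):
        assert dist.phenotypic_distance(self._summaries(), ("a", "b"), mode="mass") == 90.0

    def test_triangle_inequality(self):
        s = self._summaries()
        d_ab = dist.phenotypic_distance(s, ("a", "b"))
        d_ac = dist.phenotypic_distance(s, ("a", "c"))
        d_cb = dist.phenotypic_distance(s, ("c", "b"))
        assert d_ab <= d_ac + d_cb + 1e-12


class TestRegression:
    def test_linear_response_has_null_quadratic_term(self, rng):
        d = rng.uniform(0, 10, 200)
        h = 0.3 * d + rng.normal(0, 1e-9, 200)
        res = dist.regress_heterosis_on_distance(d, h)
        assert res.quadratic == pytest.approx(0.0, abs=1e-9)
        assert res.linear_slope == pytest.approx(0.3, abs=1e-6)
        assert res.r2 == pytest.approx(1.0)

    def test_quadratic_optimum_recovered(self, rng):
        d0 = 6.0
        d = rng.uniform(0, 12, 400)
        h = -((d - d0) ** 2) + rng.normal(0, 2.0, 400)
        res = dist.regress_heterosis_on_distance(d, h)
        assert res.quadratic < 0 and res.p_quadratic < 0.01
        optimum = -res.linear / (2 * res.quadratic)
        assert optimum == pytest.approx(d0, abs=0.3)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            dist.regress_heterosis_on_distance(np.ones(20), np.arange(20.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            dist.regress_heterosis_on_distance(np.arange(5.0), np.arange(5.0))


def test_long_format_is_upper_triangle(toy_snps):
    D = dist.genetic_distance_matrix(toy_snps)
    long = dist.distance_long_format(D)
    assert len(long) == 45
    assert (long["id1"] != long["id2"]).all()
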