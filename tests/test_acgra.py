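"""Weighted grey relational analysis: coefficients, weights, ranking."""
import logging

import numpy as np
import pandas as pd
import pytest

from watergrade.acgra import (
    ComparisonMatrix,
    GreyConfig,
    WeightVector,
    ahp_weights,
    combine_weights,
    critic_weights,
    default_comparison_matrix,
    grey_coefficients,
    relational_analysis,
    select_features,
    weighted_degree,
)
from watergrade.errors import ConfigError, DegenerateColumnError, ValidationError
from watergrade.io import INDICATORS, Dataset


class TestGreyCoefficients:
    def test_hand_computed_column(self):
        # differences 0, 0.2, 0.4 -> global dmin 0, dmax 0.4, rho 0.5
        ref = np.array([0.0, 0.2, 0.4])
        sub = np.array([[0.0], [0.4], [0.8]])
        s = grey_coefficients(ref, sub)
        assert np.allclose(s[:, 0], [1.0, 0.5, 1.0 / 3.0])

    def test_literal_denominator_form(self):
        ref = np.array([0.0, 0.2, 0.4])
        sub = np.array([[0.0], [0.4], [0.8]])
        s = grey_coefficients(ref, sub, GreyConfig(denominator_form="literal"))
        # (dmin + rho*dmax) / (delta + dmax)
        assert np.allclose(s[:, 0], [0.2 / 0.4, 0.2 / 0.6, 0.2 / 0.8])

    def test_identical_series_all_ones(self):
        ref = np.array([0.1, 0.5, 0.9])
        sub = np.tile(ref[:, None], (1, 3))
        assert np.array_equal(grey_coefficients(ref, sub), np.ones((3, 3)))

    def test_coefficients_in_unit_interval_with_lower_bound(self, rng):
        ref = rng.uniform(size=50)
        sub = rng.uniform(size=(50, 6))
        sub[0, 0] = ref[0]  # force dmin = 0
        s = grey_coefficients(ref, sub)
        assert np.all(s > 0) and np.all(s <= 1)
        # with rho = 0.5 and dmin = 0 the standard form is bounded below by 1/3
        assert np.all(s >= 1.0 / 3.0 - 1e-12)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValidationError):
            grey_coefficients(np.array([0.0, 2.0]), np.array([[0.1], [0.2]]))

    def test_invalid_rho(self):
        with pytest.raises(ConfigError):
            GreyConfig(rho=0.0)


class TestAhpWeights:
    def test_all_ones_gives_equal_weights(self):
        w, cr = ahp_weights(ComparisonMatrix.equal(5))
        assert np.allclose(w.w, 0.2) and cr == 0.0

    def test_two_by_two_row_sum_weights(self):
        w, _ = ahp_weights(ComparisonMatrix([[1, 3], [1.0 / 3.0, 1]]))
        assert np.allclose(w.w, [0.75, 0.25])

    def test_consistent_matrix_matches_principal_eigenvector(self, rng):
        prio = rng.uniform(0.5, 2.0, size=5)
        Q = ComparisonMatrix.from_priorities(prio)
        w, cr = ahp_weights(Q)
        # oracle: power iteration for the principal eigenvector
        v = np.ones(5)
        for _ in range(200):
            v = Q.values @ v
            v = v / v.sum()
        assert np.allclose(w.w, v, atol=1e-9)
        assert cr == pytest.approx(0.0, abs=1e-9)

    def test_inconsistent_judgments_are_warned(self, caplog):
        Q = ComparisonMatrix([[1, 3, 1.0 / 5.0], [1.0 / 3.0, 1, 3], [5, 1.0 / 3.0, 1]])
        with caplog.at_level(logging.WARNING, logger="watergrade.acgra"):
            _, cr = ahp_weights(Q)
        assert cr > 0.1
        assert any("consistency" in r.message for r in caplog.records)

    def test_non_reciprocal_matrix_rejected(self):
        with pytest.raises(ValidationError):
            ComparisonMatrix([[1, 2], [2, 1]])
        with pytest.raises(ValidationError):
            ComparisonMatrix([[1, -3], [-1.0 / 3.0, 1]])
        with pytest.raises(ValidationError):
            ComparisonMatrix([[1, 20], [0.05, 1]])  # outside the 1-9 scale


class TestCriticWeights:
    def test_equal_sd_uncorrelated_columns_split_evenly(self):
        X = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        assert np.allclose(critic_weights(X).w, [0.5, 0.5])

    def test_sd_ratio_drives_weights_when_uncorrelated(self):
        base = np.array(
            [[1, 1, 2], [-1, 1, -2], [1, -1, -2], [-1, -1, 2]], dtype=float
        )
        # pairwise correlations are exactly 0 and sigma = (s, s, 2s)
        assert np.allclose(critic_weights(base).w, [0.25, 0.25, 0.5])

    def test_perfectly_correlated_pair_is_degenerate(self):
        x = np.array([0.0, 0.5, 1.0])
        with pytest.raises(DegenerateColumnError):
            critic_weights(np.column_stack([x, 2 * x + 1]))

    def test_constant_column_is_degenerate(self):
        with pytest.raises(DegenerateColumnError):
            critic_weights(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))


class TestCombineWeights:
    def test_identity_and_symmetry(self):
        a = WeightVector(np.array([0.6, 0.4]), "subjective")
        b = WeightVector(np.array([0.2, 0.8]), "objective")
        assert np.allclose(combine_weights(a, a).w, a.w)
        assert np.allclose(combine_weights(a, b).w, [0.4, 0.6])
        one_hot = WeightVector(np.array([1.0, 0.0]), "subjective")
        other = WeightVector(np.array([0.0, 1.0]), "objective")
        assert np.allclose(combine_weights(one_hot, other).w, [0.5, 0.5])

    def test_length_mismatch(self):
        a = WeightVector(np.array([1.0]), "subjective")
        b = WeightVector(np.array([0.5, 0.5]), "objective")
        with pytest.raises(ValidationError):
            combine_weights(a, b)


class TestWeightedDegree:
    def test_hand_computed_degrees(self):
        s = np.array([[1.0, 1.0], [0.5, 1.0], [1.0 / 3.0, 1.0]])
        omega = WeightVector(np.array([0.6, 0.4]), "combined")
        r = weighted_degree(s, omega)
        assert r[0] == pytest.approx(0.6 * (11.0 / 18.0))  # = 11/30
        assert r[1] == pytest.approx(0.4)

    def test_zero_weight_annihilates(self):
        s = np.ones((4, 2))
        omega = WeightVector(np.array([1.0, 0.0]), "combined")
        assert np.allclose(weighted_degree(s, omega), [1.0, 0.0])


class TestRelationalAnalysis:
    def test_weight_vectors_sum_to_one(self, random_dataset):
        res = relational_analysis(random_dataset(m=80))
        for wv in (res.alpha, res.beta, res.omega):
            assert abs(wv.w.sum() - 1.0) < 1e-9 and np.all(wv.w >= 0)
        assert np.all(res.degree <= res.omega.w + 1e-12)
        assert res.degree.sum() <= 1.0 + 1e-12

    def test_permutation_equivariance(self, random_dataset):
        ds = random_dataset(m=60, seed=77)
        perm = [3, 0, 6, 1, 5, 2, 4]
        names = tuple(INDICATORS[i] for i in perm)
        frame = ds.frame[[*names, "label"]]
        ds_perm = Dataset(frame, indicator_names=names)
        Q = default_comparison_matrix()
        Qp = ComparisonMatrix(Q.values[np.ix_(perm, perm)])
        a = relational_analysis(ds, Q=Q)
        b = relational_analysis(ds_perm, Q=Qp)
        for attr in ("alpha", "beta", "omega"):
            assert np.allclose(getattr(a, attr).w[perm], getattr(b, attr).w, atol=1e-12)
        assert np.allclose(a.degree[perm], b.degree, atol=1e-12)
        assert a.ranking == b.ranking

    def test_equal_weight_reduction_matches_classical_gra(self, random_dataset):
        """With omega = 1/n, n*r(j) equals the textbook relational degree."""
        ds = random_dataset(m=50, seed=3)
        cfg = GreyConfig(orientation={})
        res = relational_analysis(ds, Q=ComparisonMatrix.equal(7), cfg=cfg)

        # independent oracle: classical (Deng) GRA with explicit loops
        def deng_degrees(ref, cols, rho=0.5):
            deltas = [[abs(r - c) for r, c in zip(ref, col)] for col in cols]
            flat = [d for col in deltas for d in col]
            dmin, dmax = min(flat), max(flat)
            out = []
            for col in deltas:
                coeffs = [(dmin + rho * dmax) / (d + rho * dmax) for d in col]
                out.append(sum(coeffs) / len(coeffs))
            return out

        def norm(xs):
            lo, hi = min(xs), max(xs)
            return [(x - lo) / (hi - lo) for x in xs]

        ref = norm([float(v) for v in ds.labels])
        cols = [norm(ds.frame[name].tolist()) for name in INDICATORS]
        oracle = deng_degrees(ref, cols)
        equal = WeightVector(np.full(7, 1.0 / 7.0), "combined")
        ours = 7.0 * weighted_degree(res.coefficients, equal)
        assert np.allclose(ours, oracle, atol=1e-12)

    def test_scale_invariance_of_degrees(self, random_dataset):
        ds = random_dataset(m=40, seed=9)
        scaled = ds.frame.copy()
        scaled["codmn"] = 13.7 * scaled["codmn"] + 4.2
        a = relational_analysis(ds)
        b = relational_analysis(Dataset(scaled))
        assert np.allclose(a.degree, b.degree, atol=1e-9)
        assert np.allclose(a.coefficients, b.coefficients, atol=1e-9)

    def test_orientation_reverses_a_cost_indicator(self, banded_dataset):
        plain = relational_analysis(banded_dataset, cfg=GreyConfig(orientation={}))
        oriented = relational_analysis(banded_dataset)  # default: DO reversed
        i = INDICATORS.index("do")
        # DO falls as the class worsens, so reversal must increase its closeness
        assert oriented.coefficients[:, i].mean() > plain.coefficients[:, i].mean()


class TestSelectFeatures:
    def test_q_equals_n_returns_a_permutation(self, random_dataset):
        ds = random_dataset(m=40)
        sel = select_features(ds, q=7)
        assert sorted(sel.selected) == sorted(INDICATORS)

    def test_invalid_q(self, random_dataset):
        with pytest.raises(ConfigError):
            select_features(random_dataset(m=40), q=0)
        with pytest.raises(ConfigError):
            select_features(random_dataset(m=40), q=8)

    def test_report_table_is_rank_ordered(self, banded_dataset):
        sel = select_features(banded_dataset, q=4)
        tab = sel.result.table
        assert list(tab["rank"]) == list(range(1, 8))
        assert list(tab["indicator"][:4]) == list(sel.selected)
        assert tab["degree"].is_monotonic_decreasing
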