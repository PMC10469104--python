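"""Aggregation operators (statistical, Choquet, GOWAWA), the descriptor
matrix and PCA projection."""

import numpy as np
import pytest

from pepspace import (
    DescriptorCalculator,
    FuzzyMeasure,
    GowawaParams,
    PeptideSet,
    Peptide,
    aggregate_statistical,
    choquet_integral,
    compute_descriptor_matrix,
    gowawa,
    pca_project,
)
from _oracles import weighted_mean


class TestStatistical:
    def test_hand_arithmetic(self):
        x = [1.0, 2.0, 3.0]
        assert aggregate_statistical(x, "mean") == 2.0
        assert aggregate_statistical(x, "range") == 2.0
        assert aggregate_statistical(x, "variance") == pytest.approx(2.0 / 3.0)

    def test_length_one_profile(self):
        for op, expected in [("min", 5.0), ("max", 5.0), ("mean", 5.0),
                             ("variance", 0.0)]:
            assert aggregate_statistical([5.0], op) == expected

    def test_constant_profile_moments_zero(self):
        assert aggregate_statistical([2.0, 2.0, 2.0], "skewness") == 0.0
        assert aggregate_statistical([2.0, 2.0, 2.0], "kurtosis") == 0.0

    def test_unknown_operator_lists_set(self):
        with pytest.raises(ValueError, match="skewness"):
            aggregate_statistical([1.0], "mode")


class TestFuzzyMeasure:
    def test_additive_when_densities_sum_to_one(self):
        m = FuzzyMeasure(np.array([0.25, 0.25, 0.5]))
        assert m.lambda_ == 0.0
        assert m.measure(np.array([True, False, True])) == pytest.approx(0.75)

    def test_lambda_solves_normalization(self):
        for g in [np.full(4, 0.9 / 4), np.full(3, 0.5), np.array([0.1, 0.2, 0.05])]:
            m = FuzzyMeasure(g)
            full = m.measure(np.ones(len(g), dtype=bool))
            assert full == pytest.approx(1.0, abs=1e-9)
            assert m.measure(np.zeros(len(g), dtype=bool)) == 0.0

    def test_monotone_set_function(self, rng):
        m = FuzzyMeasure(rng.uniform(0.05, 0.4, size=6))
        for _ in range(100):
            a = rng.random(6) < 0.5
            b = a | (rng.random(6) < 0.5)
            assert m.measure(b) >= m.measure(a) - 1e-12


class TestChoquet:
    def test_additive_equals_weighted_mean_example(self):
        m = FuzzyMeasure(np.array([0.5, 0.5]))
        assert choquet_integral([0.2, 0.8], m) == pytest.approx(0.5)

    def test_additive_equals_weighted_mean_random(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 9))
            g = rng.uniform(0.01, 1.0, n)
            g /= g.sum()
            x = rng.uniform(0, 1, n)
            assert choquet_integral(x, FuzzyMeasure(g)) == pytest.approx(
                weighted_mean(x, g), abs=1e-9
            )

    def test_constant_profile_identity(self, rng):
        m = FuzzyMeasure(rng.uniform(0.05, 0.5, 5))
        assert choquet_integral([0.3] * 5, m) == pytest.approx(0.3, abs=1e-9)

    def test_bounded_by_profile_extremes(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 8))
            m = FuzzyMeasure(rng.uniform(0.01, 0.6, n))
            x = rng.uniform(0, 1, n)
            c = choquet_integral(x, m)
            assert x.min() - 1e-9 <= c <= x.max() + 1e-9

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="length"):
            choquet_integral([0.1, 0.2], FuzzyMeasure(np.array([0.5, 0.3, 0.2])))


class TestGowawa:
    def test_reduces_to_mean(self):
        p = GowawaParams(lambda_g=1.0, beta=1.0, v="uniform")
        assert gowawa([0.1, 0.5, 0.9], p) == pytest.approx(0.5)

    def test_reduces_to_max(self):
        p = GowawaParams(lambda_g=1.0, beta=1.0, v=[1.0, 0.0, 0.0])
        assert gowawa([0.1, 0.9, 0.5], p) == pytest.approx(0.9)

    def test_importance_weights_follow_position(self):
        # beta=0: pure weighted average with sigma-mapped weights
        p = GowawaParams(lambda_g=1.0, beta=0.0, w=[0.25, 0.75])
        assert gowawa([0.2, 0.8], p) == pytest.approx(0.65)

    def test_idempotent_on_constant_profile(self, rng):
        for _ in range(50):
            beta = float(rng.random())
            lam = float(rng.choice([0.5, 1.0, 2.0, 3.0]))
            p = GowawaParams(lambda_g=lam, beta=beta, v="quantifier", w="uniform")
            c = float(rng.uniform(0.05, 1.0))
            assert gowawa([c] * 6, p) == pytest.approx(c, abs=1e-9)

    def test_zero_exponent_rejected(self):
        with pytest.raises(ValueError):
            GowawaParams(lambda_g=0.0)


class TestDescriptorMatrix:
    def test_single_peptide_single_scale_mean(self):
        from pepspace.scales import KYTE_DOOLITTLE

        s = PeptideSet([Peptide("p", "AAAA")])
        m = compute_descriptor_matrix(s, scales=["kyte_doolittle"], operators=["mean"])
        assert m.values.shape == (1, 1)
        assert m.values.iloc[0, 0] == pytest.approx(KYTE_DOOLITTLE["A"])

    def test_default_shape_and_no_missing(self, small_dataset):
        peptides, _ = small_dataset
        m = compute_descriptor_matrix(peptides)
        assert m.values.shape == (len(peptides), 9 * 14)
        assert not m.values.isna().any().any()
        assert len(set(m.columns)) == len(m.columns)

    def test_row_permutation_invariance(self, small_dataset):
        peptides, _ = small_dataset
        calc = DescriptorCalculator().fit(peptides)
        fwd = calc.transform(peptides)
        rev = calc.transform(list(peptides)[::-1])
        assert np.allclose(
            fwd.values.loc[fwd.ids].to_numpy(),
            rev.values.loc[fwd.ids].to_numpy(),
        )

    def test_normalization_round_trips(self, small_dataset):
        peptides, _ = small_dataset
        m = compute_descriptor_matrix(peptides)
        norm = m.normalized()
        assert float(norm.values.min().min()) >= 0.0
        assert float(norm.values.max().max()) <= 1.0
        for col, (lo, hi) in norm.normalization.items():
            if hi > lo:
                back = norm.values[col] * (hi - lo) + lo
                assert np.allclose(back, m.values[col])


class TestPCA:
    def test_collinear_data_rank_one(self):
        import pandas as pd
        from pepspace.descriptors import DescriptorMatrix

        x = np.linspace(0, 1, 20)
        df = pd.DataFrame({"a": x, "b": 2 * x}, index=[f"p{i}" for i in range(20)])
        _, ratios = pca_project(DescriptorMatrix(df), 2)
        assert ratios[0] == pytest.approx(1.0, abs=1e-9)

    def test_ratios_non_increasing(self, descriptor_setup):
        _, _, matrix = descriptor_setup
        _, ratios = pca_project(matrix, 5)
        assert all(a >= b - 1e-12 for a, b in zip(ratios, ratios[1:]))
        assert ratios.sum() <= 1.0 + 1e-9

    def test_full_rank_projection_is_isometry(self, rng):
        import pandas as pd
        from pepspace.descriptors import DescriptorMatrix

        X = rng.normal(size=(12, 4))
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(12)],
                          columns=list("abcd"))
        scores, _ = pca_project(DescriptorMatrix(df), 4)
        Z = (X - X.mean(0)) / X.std(0)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(scores), pdist(Z), atol=1e-8)

    def test_invalid_k(self, descriptor_setup):
        _, _, matrix = descriptor_setup
        with pytest.raises(ValueError):
            pca_project(matrix, 0)
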