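"""Combined Isotopic Impact Index: normalisation, aggregation, PCA validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilrisk.cisi import (CisiConfig, assess_batch, chemical_index,
                           compute_cisi, isotopic_index, sensitivity_weights,
                           validate_pca)


class TestChemicalIndex:
    def test_endpoints_and_midpoint(self):
        assert chemical_index(10.0, 0.0, 10.0) == 1.0
        assert chemical_index(0.0, 0.0, 10.0) == 0.0
        assert chemical_index(5.0, 0.0, 10.0) == 0.5

    def test_out_of_range_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert chemical_index(12.0, 0.0, 10.0) == 1.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chemical_index(1.0, 3.0, 3.0)

    @settings(derandomize=True)
    @given(x=st.floats(0, 1), lo=st.floats(-100, 100),
           span=st.floats(0.1, 100), shift=st.floats(-50, 50))
    def test_shift_invariance(self, x, lo, span, shift):
        raw = lo + x * span
        assert chemical_index(raw + shift, lo + shift, lo + span + shift) == \
            pytest.approx(chemical_index(raw, lo, lo + span), abs=1e-9)


class TestIsotopicIndex:
    def test_reference_scores_one(self):
        assert isotopic_index(1.2, 1.2) == 1.0
        assert isotopic_index(2.5, 2.5) == 1.0

    def test_half_deviation(self):
        assert isotopic_index(0.6, 1.2) == pytest.approx(0.5)

    def test_unclamped_can_be_negative(self):
        assert isotopic_index(3.0, 1.2) < 0
        assert isotopic_index(3.0, 1.2, clamp=True) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            isotopic_index(1.0, 0.0)


class TestCisiAggregation:
    def test_low_impact_sample_worked_value(self):
        # the survey's least-impacted sample: C̄I 0.0778, II 0.1675/0.5316
        res = compute_cisi([0.0778], {"r206_207": 0.1675, "r208_207": 0.5316})
        assert round(res.cisi, 4) == 0.1865

    def test_degenerate_extremes(self):
        assert compute_cisi([0.0, 0.0], [0.0]).cisi == 0.0
        assert compute_cisi([1.0], [1.0, 1.0]).cisi == 1.0

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CisiConfig(w_chemical=0.7, w_isotopic=0.4)

    def test_high_impact_sample_back_solves(self):
        # printed II pair (0.7880, 0.8340) and CISI 0.6468 imply C̄I ≈ 0.5373
        ii_mean = (0.7880 + 0.8340) / 2
        ci_mean = (0.6468 - 0.4 * ii_mean) / 0.6
        assert abs(ci_mean - 0.5373) < 2e-4
        res = compute_cisi([ci_mean], [0.7880, 0.8340])
        assert round(res.cisi, 4) == 0.6468

    def test_monotone_in_components(self):
        base = compute_cisi([0.3, 0.4], [0.5, 0.6]).cisi
        assert compute_cisi([0.35, 0.4], [0.5, 0.6]).cisi > base
        assert compute_cisi([0.3, 0.4], [0.55, 0.6]).cisi > base

    @settings(derandomize=True)
    @given(ci=st.lists(st.floats(0, 1), min_size=1, max_size=5),
           ii=st.lists(st.floats(0, 1), min_size=1, max_size=2))
    def test_bounded_when_components_bounded(self, ci, ii):
        assert 0.0 <= compute_cisi(ci, ii).cisi <= 1.0


class TestBatch:
    @pytest.fixture
    def batch(self):
        chem = pd.DataFrame({
            "sample_id": ["A", "B", "C"],
            "pH": [7.0, 8.0, 9.0], "Pb": [10.0, 50.0, 100.0]})
        iso = pd.DataFrame({
            "sample_id": ["A", "B", "C"],
            "r206_207": [1.20, 1.15, 1.10],
            "r208_207": [2.50, 2.45, 2.40]})
        return chem, iso

    def test_ranking_and_range_from_batch(self, batch):
        cfg = CisiConfig(chemical_parameters=("pH", "Pb"))
        results = assess_batch(*batch, cfg)
        assert [r.sample_id for r in results] == ["A", "B", "C"]
        ranks = {r.sample_id: r.rank for r in results}
        by_score = sorted(results, key=lambda r: -r.cisi)
        assert ranks[by_score[0].sample_id] == 1
        # batch extremes hit the index endpoints
        assert results[0].ci["Pb"] == 0.0 and results[2].ci["Pb"] == 1.0

    def test_missing_parameter_column(self, batch):
        chem, iso = batch
        cfg = CisiConfig(chemical_parameters=("pH", "Fe"))
        with pytest.raises(KeyError, match="Fe"):
            assess_batch(chem, iso, cfg)


class TestPCA:
    def test_perfectly_correlated_features(self):
        x = np.linspace(0, 1, 20)
        df = pd.DataFrame({"a": x, "b": 2 * x + 3})
        with pytest.warns(UserWarning, match="rank"):
            evr, loadings, _ = validate_pca(df)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(40, 5)),
                          columns=list("abcde"))
        evr, loadings, scores = validate_pca(df)
        assert np.allclose(loadings.T @ loadings, np.eye(loadings.shape[1]),
                           atol=1e-9)
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identity_covariance_near_equal_shares(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(4000, 4)), columns=list("abcd"))
        evr, _, _ = validate_pca(df)
        # sampling-theory band: each share within a few percent of 1/4
        assert np.all(np.abs(evr - 0.25) < 0.04)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        _, l1, s1 = validate_pca(df)
        _, l2, s2 = validate_pca(df)
        assert np.array_equal(l1, l2) and np.array_equal(s1, s2)
        for j in range(l1.shape[1]):
            assert l1[np.argmax(np.abs(l1[:, j])), j] > 0

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            validate_pca(pd.DataFrame({"a": [1, 2], "b": [3, 4]}))


class TestSensitivityWeights:
    def test_single_sample_constant_across_grid(self):
        table = sensitivity_weights([0.4], [0.7])
        assert table["cisi_variance"].abs().max() == 0.0

    def test_pure_chemical_weight(self):
        table = sensitivity_weights([0.4, 0.8], [0.1, 0.2])
        row = table[table["w_chemical"] == 1.0].iloc[0]
        assert row["cisi_0"] == pytest.approx(0.4)
        assert row["cisi_1"] == pytest.approx(0.8)

    def test_argmax_matches_brute_force(self):
        ci = np.array([0.1, 0.9])
        ii = np.array([0.45, 0.55])
        table = sensitivity_weights(ci, ii)
        best = table.loc[table["cisi_variance"].idxmax()]
        brute = max(((w1, np.var(w1 * ci + (1 - w1) * ii))
                     for w1 in np.linspace(0, 1, 11)), key=lambda t: t[1])
        assert best["w_chemical"] == pytest.approx(brute[0])
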