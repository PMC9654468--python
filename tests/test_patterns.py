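"""Correlation-matrix PCA dietary patterns: adequacy, extraction, scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietval.patterns import (
    SingularCorrelationError,
    adequacy,
    attribute,
    congruence,
    extract,
    factor_scores,
    varimax,
)


def _two_block_data(rng, n=500, per_block=3, loading=0.8):
    """Two orthogonal latent factors loading 0.8 on disjoint variable blocks."""
    f = rng.normal(size=(n, 2))
    p = 2 * per_block
    lam = np.zeros((p, 2))
    lam[:per_block, 0] = loading
    lam[per_block:, 1] = loading
    noise = rng.normal(size=(n, p)) * np.sqrt(1 - loading**2)
    X = f @ lam.T + noise
    cols = [f"v{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), lam, f


class TestAdequacy:
    def test_identity_matrix_bartlett_is_null(self):
        adq = adequacy(np.eye(5), n=50)
        assert adq.bartlett_chi2 == pytest.approx(0.0, abs=1e-10)
        assert adq.bartlett_df == 10
        assert adq.bartlett_p == pytest.approx(1.0)

    def test_equicorrelated_kmo_closed_form(self):
        # for an equicorrelated matrix the partial correlation is
        # r / (1 + (p-2) r); with p=4, r=0.5 that is 0.25 and KMO = 0.8
        p, r = 4, 0.5
        R = np.full((p, p), r) + (1 - r) * np.eye(p)
        adq = adequacy(R, n=100)
        q = r / (1 + (p - 2) * r)
        n_off = p * (p - 1)
        expect = (n_off * r**2) / (n_off * r**2 + n_off * q**2)
        assert adq.kmo_overall == pytest.approx(expect, rel=1e-9)
        assert all(v == pytest.approx(expect, rel=1e-9) for v in adq.msa.values())

    def test_bartlett_statistic_formula(self, rng):
        X = rng.normal(size=(80, 4))
        R = np.corrcoef(X, rowvar=False)
        adq = adequacy(R, n=80)
        chi2 = -(80 - 1 - (2 * 4 + 5) / 6) * np.log(np.linalg.det(R))
        assert adq.bartlett_chi2 == pytest.approx(chi2, rel=1e-9)
        assert adq.bartlett_p == pytest.approx(stats.chi2.sf(chi2, 6), rel=1e-9)

    def test_planted_structure_has_adequate_msa(self, rng):
        data, _, _ = _two_block_data(rng)
        R = np.corrcoef(data.to_numpy(), rowvar=False)
        adq = adequacy(R, n=len(data), variables=list(data.columns))
        assert all(v > 0.5 for v in adq.msa.values())

    def test_singular_matrix_raises(self):
        R = np.ones((3, 3))
        with pytest.raises(SingularCorrelationError):
            adequacy(R, n=10)


class TestVarimax:
    def test_fixed_point_on_simple_structure(self):
        L = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.85], [0.0, 0.75]])
        rotated = varimax(L)
        # unchanged up to column sign/permutation
        best = np.abs(rotated.T @ L)
        assert np.allclose(np.sort(best.max(axis=0)), np.sort((L**2).sum(axis=0)), atol=1e-6)

    def test_rotation_preserves_communalities(self, rng):
        L = rng.normal(size=(8, 3)) * 0.5
        rotated = varimax(L)
        assert np.allclose((rotated**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-8)
        assert np.allclose((rotated**2).sum(), (L**2).sum(), atol=1e-8)


class TestExtract:
    def test_two_block_recovery(self, rng):
        data, lam, _ = _two_block_data(rng)
        model = extract(data)
        assert model.retained_k == 2
        for j in range(2):
            best = max(
                abs(congruence(lam[:, j], model.loadings.iloc[:, k].to_numpy()))
                for k in range(2)
            )
            assert best > 0.95

    def test_trace_identity(self, rng):
        data, _, _ = _two_block_data(rng, n=200)
        model = extract(data)
        assert model.eigenvalues.sum() == pytest.approx(len(model.variables), abs=1e-8)

    def test_pct_variance_of_all_components_sums_to_100(self, rng):
        data, _, _ = _two_block_data(rng, n=200)
        model = extract(data)
        # eigenvalues over p give % variance; over all p components: 100%
        assert (model.eigenvalues / len(model.variables) * 100).sum() == pytest.approx(100.0)

    def test_rotation_preserves_total_retained_variance(self, rng):
        data, _, _ = _two_block_data(rng)
        model = extract(data)
        k = model.retained_k
        assert model.pct_variance.sum() == pytest.approx(
            model.eigenvalues[:k].sum() / len(model.variables) * 100, abs=1e-6
        )

    def test_zero_variance_column_dropped(self, rng):
        data, _, _ = _two_block_data(rng, n=100)
        data["flat"] = 5.0
        model = extract(data)
        assert "flat" in model.dropped
        assert "flat" not in model.variables

    def test_msa_pruning_removes_noise_variable(self, rng):
        data, _, _ = _two_block_data(rng, n=400)
        # a pure-noise variable correlates with nothing: MSA ~ undefined/low
        data["noise1"] = rng.normal(size=len(data))
        data["noise2"] = rng.normal(size=len(data))
        model = extract(data, msa_cut=0.5)
        assert set(model.dropped) <= {"noise1", "noise2"}
        assert len(model.dropped) >= 1

    def test_factor_sign_fixed_to_dominant_variable(self, rng):
        data, _, _ = _two_block_data(rng)
        model = extract(data)
        L = model.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0


class TestFactorScores:
    def test_participant_at_variable_means_scores_zero(self, rng):
        data, _, _ = _two_block_data(rng, n=300)
        model = extract(data)
        mean_row = pd.DataFrame([model.mean_], columns=model.variables)
        s = factor_scores(model, mean_row)
        assert np.allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_scores_centered_with_bounded_variance(self, rng):
        data, _, _ = _two_block_data(rng)
        model = extract(data)
        s = model.scores.to_numpy()
        assert np.allclose(s.mean(axis=0), 0.0, atol=1e-10)
        assert np.all(s.var(axis=0, ddof=1) <= 1.0 + 1e-8)

    def test_scores_track_true_factors(self, rng):
        data, lam, f = _two_block_data(rng)
        model = extract(data)
        for j in range(2):
            best = max(
                abs(np.corrcoef(model.scores.iloc[:, k], f[:, j])[0, 1])
                for k in range(2)
            )
            assert best > 0.8

    def test_dimension_mismatch(self, rng):
        data, _, _ = _two_block_data(rng, n=100)
        model = extract(data)
        with pytest.raises(ValueError, match="lacks"):
            factor_scores(model, data[model.variables[:-1]])


class TestAttribute:
    def test_max_absolute_loading_wins(self):
        L = pd.DataFrame([[0.84, 0.30]], index=["veg"], columns=["f1", "f2"])
        assert attribute(L) == {"veg": 1}

    def test_below_threshold_unassigned(self):
        L = pd.DataFrame([[0.15, -0.2]], index=["veg"], columns=["f1", "f2"])
        assert attribute(L) == {"veg": None}

    def test_tie_breaks_to_lowest_factor_index(self):
        L = pd.DataFrame([[0.5, -0.5]], index=["veg"], columns=["f1", "f2"])
        assert attribute(L) == {"veg": 1}

    def test_negative_loading_attributed_with_sign_kept(self):
        L = pd.DataFrame([[-0.6, 0.1]], index=["soup"], columns=["f1", "f2"])
        assert attribute(L) == {"soup": 1}
        assert L.loc["soup", "f1"] < 0  # sign preserved for reporting
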