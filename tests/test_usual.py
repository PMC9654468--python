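"""Two-part shrinkage usual-intake model."""

import numpy as np
import pandas as pd
import pytest

from dietval.usual import (
    ShrinkageUnidentifiableError,
    UsualIntakeModel,
    VarianceComponents,
    boxcox_inverse,
    boxcox_transform,
    consumption_probability,
    fit_components,
    select_lambda,
    shrink_mean,
    usual_amount_from_shrunken,
)


def _comp(mu=0.0, sb=1.0, sw=1.0, lam=1.0):
    return VarianceComponents("x", lam, 0.0, mu, sb, sw, 2)


class TestShrinkMean:
    def test_half_shrinkage_single_day(self):
        assert shrink_mean(2.0, 1, _comp()) == pytest.approx(1.0)

    def test_zero_between_variance_full_pooling(self):
        c = _comp(mu=3.0, sb=0.0)
        for xbar in (-10, 0, 10):
            assert shrink_mean(xbar, 1, c) == 3.0

    def test_many_days_approach_observed_mean(self):
        assert shrink_mean(2.0, 10**6, _comp()) == pytest.approx(2.0, abs=1e-5)

    def test_no_days_falls_back_to_population_mean(self):
        assert shrink_mean(99.0, 0, _comp(mu=1.5)) == 1.5

    def test_contraction_and_monotonicity(self):
        c = _comp(mu=1.0, sb=0.7, sw=1.3)
        xs = np.linspace(-4, 6, 41)
        ts = np.array([shrink_mean(x, 2, c) for x in xs])
        assert np.all(np.abs(ts - c.mu) <= np.abs(xs - c.mu) + 1e-12)
        assert np.all(np.diff(ts) > 0)


class TestFitComponents:
    def _simulate(self, seed, n=1000, days=2, sb=0.4, sw=0.6, mu=2.0):
        rng = np.random.default_rng(seed)
        b = rng.normal(0.0, sb, n)
        return {
            str(i): np.exp(mu + b[i] + rng.normal(0.0, sw, days)) for i in range(n)
        }

    def test_lognormal_recovery_within_10pct(self):
        errs_b, errs_w = [], []
        for seed in range(5):
            comp = fit_components(self._simulate(seed), "x")
            assert comp.lam == 0.0  # log transform wins on log-normal data
            errs_b.append(abs(comp.sigma2_b - 0.16) / 0.16)
            errs_w.append(abs(comp.sigma2_w - 0.36) / 0.36)
        assert np.mean(errs_b) < 0.10
        assert np.mean(errs_w) < 0.10

    def test_shift_one_participant_changes_only_between(self):
        # identity transform so the shift is exactly on the analysis scale
        grid = (1.0,)
        rng = np.random.default_rng(3)
        vals = {str(i): 10 + rng.normal(0, 1, 2) for i in range(40)}
        base = fit_components(vals, "x", grid=grid)
        shifted = dict(vals)
        shifted["0"] = vals["0"] + 5.0
        new = fit_components(shifted, "x", grid=grid)
        assert new.sigma2_w == pytest.approx(base.sigma2_w, rel=1e-9)
        assert new.sigma2_b > base.sigma2_b

    def test_anova_decomposition_against_balanced_oracle(self):
        # balanced case: MSW/MSB have the textbook closed forms
        rng = np.random.default_rng(9)
        vals = {str(i): 5 + rng.normal(0, 1, 3) for i in range(30)}
        comp = fit_components(vals, "x", grid=(1.0,))
        arr = np.array([vals[str(i)] for i in range(30)])
        means = arr.mean(axis=1)
        msw = ((arr - means[:, None]) ** 2).sum() / (30 * 3 - 30)
        msb = 3 * ((means - arr.mean()) ** 2).sum() / 29
        assert comp.sigma2_w == pytest.approx(msw, rel=1e-9)
        assert comp.sigma2_b == pytest.approx(max(0.0, (msb - msw) / 3), rel=1e-9)

    def test_no_repeats_is_unidentifiable(self):
        vals = {str(i): np.array([float(i + 1)]) for i in range(10)}
        with pytest.raises(ShrinkageUnidentifiableError):
            fit_components(vals, "x")

    def test_zero_within_variance_errors_or_floors(self):
        vals = {str(i): np.array([float(i + 1)] * 2) for i in range(10)}
        with pytest.raises(ValueError, match="within"):
            fit_components(vals, "x", grid=(1.0,), within_floor=None)
        comp = fit_components(vals, "x", grid=(1.0,), within_floor=1e-8)
        assert comp.sigma2_w == 1e-8

    def test_lambda_grid_profile_likelihood_identity_on_normal(self):
        rng = np.random.default_rng(11)
        x = rng.normal(50, 2, 400)  # symmetric: identity should beat log
        assert select_lambda(x) == 1.0


class TestBoxCox:
    @pytest.mark.parametrize("lam", [0.0, 0.25, 1 / 3, 0.5, 1.0])
    def test_round_trip(self, lam):
        x = np.array([0.5, 1.0, 4.2, 117.0])
        assert boxcox_inverse(boxcox_transform(x, lam), lam) == pytest.approx(x)

    def test_linear_transform_has_no_bias_correction(self):
        # λ=1 maps x → x−1: linear, so back-transform round-trips exactly and
        # the curvature correction vanishes
        c = _comp(lam=1.0, sb=0.5, sw=0.5)
        x = 7.3
        t = float(boxcox_transform(np.array([x]), 1.0)[0])
        assert usual_amount_from_shrunken(t, 1, c) == pytest.approx(x)
        assert usual_amount_from_shrunken(t, 1, c, bias_correction=False) == pytest.approx(x)

    def test_log_scale_correction_is_positive(self):
        c = _comp(lam=0.0, sb=0.25, sw=0.25)
        assert usual_amount_from_shrunken(1.0, 1, c) > np.exp(1.0)

    def test_result_never_negative(self):
        c = _comp(lam=0.5, sb=0.1, sw=0.1)
        assert usual_amount_from_shrunken(-50.0, 1, c, bias_correction=False) == 0.0


class TestConsumptionProbability:
    def test_everyone_consumes_every_day(self):
        p, p_bar, m = consumption_probability(np.array([2, 2, 1]), np.array([2, 2, 1]))
        assert p_bar == 1.0
        assert np.all(p == 1.0)

    def test_symmetric_case_stays_at_half(self):
        c = np.ones(50)
        n = np.full(50, 2)
        p, p_bar, m = consumption_probability(c, n)
        assert p_bar == pytest.approx(0.5)
        assert p == pytest.approx(np.full(50, 0.5))

    def test_shrinkage_beats_raw_proportions(self):
        rng = np.random.default_rng(17)
        n_people = 500
        truth = rng.beta(2, 2, n_people)
        n = np.full(n_people, 2)
        c = rng.binomial(n, truth)
        p, _, m = consumption_probability(c, n)
        assert m >= 1.0
        mae_shrunk = np.abs(p - truth).mean()
        mae_raw = np.abs(c / n - truth).mean()
        assert mae_shrunk < mae_raw

    def test_input_validation(self):
        with pytest.raises(ValueError):
            consumption_probability(np.array([3]), np.array([2]))
        with pytest.raises(ValueError):
            consumption_probability(np.array([0]), np.array([0]))


class TestModel:
    def _frame(self, vals: dict[str, np.ndarray], variable="x"):
        rows = [
            {"participant_id": pid, "day_index": d + 1, "day_type": "week",
             "variable": variable, "value": v}
            for pid, arr in vals.items()
            for d, v in enumerate(arr)
        ]
        return pd.DataFrame(rows)

    def test_shrunken_variance_not_larger_than_raw(self):
        rng = np.random.default_rng(23)
        vals = {str(i): np.exp(rng.normal(0, 0.4) + rng.normal(0, 0.6, 2)) for i in range(300)}
        model = UsualIntakeModel()
        usual = model.fit_predict(self._frame(vals))
        raw_means = np.array([np.log(v).mean() for v in vals.values()])
        comp = model.components_["x"]
        assert comp.lam == 0.0
        assert np.var(np.log(usual["x"])) <= np.var(raw_means)

    def test_usual_tracks_truth_better_than_single_day(self):
        rng = np.random.default_rng(29)
        n = 400
        b = rng.normal(0, 0.5, n)
        vals = {str(i): np.exp(1.0 + b[i] + rng.normal(0, 0.7, 2)) for i in range(n)}
        usual = UsualIntakeModel().fit_predict(self._frame(vals))
        day1 = np.array([vals[str(i)][0] for i in range(n)])
        r_usual = np.corrcoef(usual["x"], np.exp(1.0 + b))[0, 1]
        r_day = np.corrcoef(day1, np.exp(1.0 + b))[0, 1]
        assert r_usual > r_day

    def test_episodic_zero_consumer_gets_small_positive_usual(self):
        rng = np.random.default_rng(31)
        vals = {str(i): np.exp(rng.normal(2, 0.5, 2)) for i in range(50)}
        vals["zero"] = np.zeros(2)
        model = UsualIntakeModel(episodic={"x"})
        usual = model.fit_predict(self._frame(vals)).set_index("participant_id")
        z = usual.loc["zero", "x"]
        assert 0 < z < usual.drop("zero")["x"].min() + 1e-9

    def test_unidentifiable_variable_skipped_and_recorded(self):
        frame = pd.concat(
            [
                self._frame({str(i): np.exp(np.random.default_rng(i).normal(0, 1, 2)) for i in range(5)}, "ok"),
                self._frame({str(i): np.zeros(2) for i in range(5)}, "allzero"),
            ]
        )
        model = UsualIntakeModel(episodic={"allzero"})
        usual = model.fit_predict(frame)
        assert "ok" in usual.columns and "allzero" not in usual.columns
        assert "allzero" in model.skipped_
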