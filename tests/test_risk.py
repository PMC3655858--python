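"""Risk-score function: reference limits, dichotomization, univariate
logistic weights (with closed-form and grid-search oracles) and the RSF."""

import numpy as np
import pandas as pd
import pytest

from mirpanel.errors import DataError
from mirpanel.risk import (
    RiskModel,
    build_risk_model,
    compute_rsf,
    dichotomize,
    fit_weights,
    reference_upper_limit,
)


def loglik_2x2(a, b, c, d, b0, b1):
    """Bernoulli log-likelihood of (intercept, slope) on a 2x2 table.

    a cases with s=1, b cases with s=0, c controls with s=1, d controls
    with s=0; P(case|s) = logistic(b0 + b1*s).
    """
    p1 = 1.0 / (1.0 + np.exp(-(b0 + b1)))
    p0 = 1.0 / (1.0 + np.exp(-b0))
    return (a * np.log(p1) + c * np.log(1 - p1)
            + b * np.log(p0) + d * np.log(1 - p0))


def grid_search_slope(a, b, c, d):
    """Independent MLE oracle: nested grid over (intercept, slope)."""
    lo0, hi0, lo1, hi1 = -6.0, 6.0, -8.0, 8.0
    best = (0.0, 0.0)
    for _ in range(6):
        g0 = np.linspace(lo0, hi0, 41)
        g1 = np.linspace(lo1, hi1, 41)
        ll = loglik_2x2(a, b, c, d, g0[:, None], g1[None, :])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (g0[i], g1[j])
        w0 = (hi0 - lo0) / 40
        w1 = (hi1 - lo1) / 40
        lo0, hi0 = best[0] - 2 * w0, best[0] + 2 * w0
        lo1, hi1 = best[1] - 2 * w1, best[1] + 2 * w1
    return best[1]


def s_frame(col):
    return pd.DataFrame({"m": col})


class TestReferenceUpperLimit:
    def test_parametric_formula(self):
        # log10 values with sample mean 1.0 and sample sd 0.5
        c = 0.5 * np.sqrt(7.0 / 8.0)
        lg = 1.0 + np.array([-c, -c, -c, -c, c, c, c, c])
        vals = 10.0 ** lg
        assert np.log10(vals).std(ddof=1) == pytest.approx(0.5)
        thr = reference_upper_limit(vals, method="parametric")
        assert thr == pytest.approx(10 ** 1.98, rel=1e-9)

    def test_degenerate_sd(self):
        thr = reference_upper_limit([7.5] * 10, method="parametric")
        assert thr == pytest.approx(7.5)

    def test_empirical_matches_order_statistic_oracle(self):
        vals = np.arange(1.0, 41.0)
        thr = reference_upper_limit(vals, method="empirical")
        # linear-interpolation oracle on the sorted sample
        x = np.sort(vals)
        h = 0.975 * (len(x) - 1)
        lo = int(np.floor(h))
        oracle = x[lo] + (h - lo) * (x[lo + 1] - x[lo])
        assert thr == pytest.approx(oracle, rel=1e-12)
        assert thr == pytest.approx(39.025)

    def test_too_few_or_non_positive(self):
        with pytest.raises(DataError):
            reference_upper_limit([1.0] * 7)
        with pytest.raises(DataError):
            reference_upper_limit([1.0] * 7 + [0.0])


class TestDichotomize:
    def test_strict_inequality_at_threshold(self):
        conc = pd.DataFrame({"m": [5.0, 5.0001, 4.9]})
        s = dichotomize(conc, {"m": 5.0})
        assert list(s["m"]) == [0, 1, 0]

    def test_all_below_gives_zero_matrix(self):
        conc = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        s = dichotomize(conc, {"a": 10.0, "b": 10.0})
        assert (s.to_numpy() == 0).all()

    def test_missing_threshold_errors(self):
        with pytest.raises(DataError, match="'b'"):
            dichotomize(pd.DataFrame({"b": [1.0]}), {"a": 1.0})

    def test_parametric_exceedance_calibration(self):
        # control exceedance of the in-sample parametric limit ~ 1-Phi(1.96)
        fractions = []
        rng = np.random.default_rng(2024)
        for _ in range(100):
            vals = 10 ** rng.normal(2.0, 0.4, size=500)
            thr = reference_upper_limit(vals, method="parametric")
            fractions.append(np.mean(vals > thr))
        assert abs(np.mean(fractions) - 0.025) <= 0.01


class TestFitWeights:
    def test_weight_equals_log_odds_ratio(self):
        s = s_frame([1] * 15 + [0] * 5 + [1] * 2 + [0] * 18)
        y = [1] * 20 + [0] * 20
        w, sep, conv = fit_weights(s, y)
        assert w["m"] == pytest.approx(np.log(27.0), abs=1e-6)
        assert not sep["m"] and conv["m"]

    def test_no_association_gives_zero(self):
        s = s_frame([1] * 5 + [0] * 15 + [1] * 5 + [0] * 15)
        y = [1] * 20 + [0] * 20
        w, _, _ = fit_weights(s, y)
        assert w["m"] == pytest.approx(0.0, abs=1e-8)

    def test_perfect_separation_haldane_corrected(self):
        s = s_frame([1] * 15 + [0] * 20)
        y = [1] * 15 + [0] * 20
        w, sep, _ = fit_weights(s, y)
        expected = np.log((15.5 * 20.5) / (0.5 * 0.5))
        assert w["m"] == pytest.approx(expected, rel=1e-12)
        assert sep["m"]

    def test_single_class_errors(self):
        with pytest.raises(DataError):
            fit_weights(s_frame([0, 1]), [1, 1])

    @pytest.mark.parametrize("table", [(15, 5, 2, 18), (8, 12, 3, 17),
                                       (30, 10, 12, 28), (5, 9, 4, 11)])
    def test_matches_grid_search_oracle(self, table):
        a, b, c, d = table
        s = s_frame([1] * a + [0] * b + [1] * c + [0] * d)
        y = [1] * (a + b) + [0] * (c + d)
        w, _, _ = fit_weights(s, y)
        assert abs(w["m"] - grid_search_slope(a, b, c, d)) < 1e-3

    def test_recovers_planted_odds_ratios(self):
        # exceedance indicators with known OR at n=500/500; the delta-method
        # sd of a 2x2 log-OR here is ~0.15, so |error| <= 0.3 (~2 sd) holds
        # in ~96% of draws and the mean error is ~0.15/sqrt(20)
        rng = np.random.default_rng(7)
        p_ctrl = 0.25
        for odds_ratio in (2.0, 5.0, 10.0):
            odds_case = odds_ratio * p_ctrl / (1 - p_ctrl)
            p_case = odds_case / (1 + odds_case)
            errors = []
            for _ in range(20):
                s = s_frame(
                    np.concatenate([rng.binomial(1, p_case, 500),
                                    rng.binomial(1, p_ctrl, 500)]))
                y = [1] * 500 + [0] * 500
                w, _, _ = fit_weights(s, y)
                errors.append(w["m"] - np.log(odds_ratio))
            assert np.sum(np.abs(errors) <= 0.3) >= 18
            assert abs(np.mean(errors)) <= 0.12


class TestComputeRsf:
    def _model(self, weights):
        return RiskModel(
            markers=list(weights),
            thresholds={k: 1.0 for k in weights},
            weights=dict(weights),
            contrast=("AMI", "control"),
        )

    def test_single_term(self):
        model = self._model({"a": 1.2, "b": 0.8})
        s = pd.DataFrame({"a": [1], "b": [0]})
        assert compute_rsf(s, model).rsf.iloc[0] == pytest.approx(1.2)

    def test_all_zero_indicators(self):
        model = self._model({"a": 1.2, "b": 0.8})
        s = pd.DataFrame({"a": [0, 0], "b": [0, 0]})
        assert (compute_rsf(s, model).rsf == 0).all()

    def test_hand_summed(self):
        model = self._model({"a": 3.2958, "b": 1.0986, "c": 0.6931})
        s = pd.DataFrame({"a": [1], "b": [1], "c": [1]})
        assert compute_rsf(s, model).rsf.iloc[0] == pytest.approx(5.0875,
                                                                  abs=1e-4)

    def test_column_mismatch_errors(self):
        model = self._model({"a": 1.0})
        with pytest.raises(DataError):
            compute_rsf(pd.DataFrame({"b": [1]}), model)

    def test_monotonicity_with_nonnegative_weights(self):
        model = self._model({"a": 0.5, "b": 1.5, "c": 0.0})
        base = pd.DataFrame({"a": [0], "b": [1], "c": [0]})
        bumped = pd.DataFrame({"a": [1], "b": [1], "c": [0]})
        assert compute_rsf(bumped, model).rsf.iloc[0] >= \
            compute_rsf(base, model).rsf.iloc[0]

    def test_ranking_descending(self):
        model = self._model({"a": 2.0, "b": 1.0})
        s = pd.DataFrame({"a": [1, 0, 1], "b": [1, 1, 0]})
        scores = compute_rsf(s, model)
        assert list(scores.rank) == [1, 3, 2]


class TestBuildRiskModel:
    def test_threshold_provenance_reference_only(self):
        rng = np.random.default_rng(1)
        conc = pd.DataFrame({
            "m": np.concatenate([10 ** rng.normal(2.5, 0.3, 40),
                                 10 ** rng.normal(2.0, 0.3, 40)]),
        })
        labels = np.array([1] * 40 + [0] * 40)
        model_a = build_risk_model(conc, labels, ["m"])
        # permute case rows only; thresholds must be bit-identical
        perm = np.concatenate([np.random.default_rng(9).permutation(40),
                               np.arange(40, 80)])
        model_b = build_risk_model(conc.iloc[perm].reset_index(drop=True),
                                   labels, ["m"])
        assert model_a.thresholds["m"] == model_b.thresholds["m"]

    def test_json_round_trip(self):
        rng = np.random.default_rng(3)
        conc = pd.DataFrame({
            "m": np.concatenate([10 ** rng.normal(2.6, 0.3, 40),
                                 10 ** rng.normal(2.0, 0.3, 40)]),
        })
        labels = np.array([1] * 40 + [0] * 40)
        model = build_risk_model(conc, labels, ["m"])
        restored = RiskModel.from_json(model.to_json())
        assert restored.weights == model.weights
        assert restored.thresholds == model.thresholds
        assert restored.contrast == model.contrast
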