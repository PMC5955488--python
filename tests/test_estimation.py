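"""Pooling rules, logistic fits (null effects, recovery, separation),
annualization, segment concatenation and the non-response diagnostic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import povdyn.estimation as est
from povdyn.estimation import (AgeRangeError, EstimationError, Formula,
                               SegmentFit, SeparationError,
                               concatenate_segments, fit_survival,
                               fit_transition, fits_from_json, fits_to_json,
                               nonresponse_by_state_age, pool,
                               predict_interval_probability)
from povdyn.rates import (DEFAULT_SEGMENTS, Segment, annualize,
                          annualize_survival)
from povdyn.synthetic import (GroundTruth, default_design, default_truth,
                              generate_panel, true_rateset)


def _panel_row(pid, wave, age, state, alive=1, weight=1.0, months=12.0,
               responded=1):
    return dict(person_id=pid, wave=wave, age=age, state=state, alive=alive,
                weight=weight, interval_months=months, responded=responded)


def _tiny_panel(rows):
    return pd.DataFrame(rows)


class TestPool:
    def test_missing_middle_wave_breaks_both_pairs(self):
        rows = [_panel_row(0, 0, 30, 1),
                _panel_row(0, 1, 31, np.nan, responded=0),
                _panel_row(0, 2, 32, 1),
                # second person provides one usable pair so pool() is nonempty
                _panel_row(1, 0, 40, 2), _panel_row(1, 1, 41, 2)]
        pooled = pool(_tiny_panel(rows))
        assert (pooled["person_id"] == 1).all()
        assert len(pooled) == 1

    def test_six_responded_waves_yield_five_pairs(self):
        rows = [_panel_row(0, w, 30 + w, 1) for w in range(6)]
        pooled = pool(_tiny_panel(rows))
        assert len(pooled) == 5

    def test_all_pairs_missing_raises_no_usable_pairs(self):
        rows = [_panel_row(0, 0, 30, 1),
                _panel_row(0, 1, 31, np.nan, responded=0)]
        with pytest.raises(EstimationError, match="no usable"):
            pool(_tiny_panel(rows))

    def test_death_at_next_wave_is_a_usable_pair(self):
        rows = [_panel_row(0, 0, 30, 1),
                _panel_row(0, 1, 31, np.nan, alive=0, responded=0)]
        pooled = pool(_tiny_panel(rows))
        assert len(pooled) == 1 and pooled.loc[0, "survived"] == 0

    def test_pair_count_matches_binomial_completeness_oracle(self):
        # 1,000 persons x 5 waves, independent response w.p. 0.9 at every
        # wave: a pair needs both ends responded, so E[pairs] = 4000 * 0.9^2
        rng = np.random.default_rng(7)
        rows = []
        for pid in range(1000):
            resp = rng.random(5) < 0.9
            for w in range(5):
                rows.append(_panel_row(pid, w, 30 + w,
                                       1 if resp[w] else np.nan,
                                       responded=int(resp[w])))
        pooled = pool(_tiny_panel(rows))
        expected = 4000 * 0.81
        se = np.sqrt(4000 * 0.81 * (1 - 0.81))
        assert abs(len(pooled) - expected) < 3 * se


class TestFits:
    def test_state_coefficient_null_when_survival_ignores_state(
            self, single_segment):
        seg, design = single_segment
        truth = GroundTruth.from_probabilities(0.93, 0.93, 0.3, 0.9,
                                               segments=(seg,))
        panel = generate_panel(truth, design(n_persons=8000, waves=4), seed=0)
        fit = fit_survival(pool(panel), segment=seg)
        i = fit.names.index("above")
        assert abs(fit.params[i]) < 3 * fit.bse[i]

    def test_known_truth_coefficients_recovered_within_3_se(self, truth_2x):
        # ~50k pooled rows per segment under the default noisy conditions
        panel = generate_panel(truth_2x, default_design(0.5), seed=1)
        pooled = pool(panel)
        for seg in DEFAULT_SEGMENTS:
            sc = truth_2x.coefficients[seg.name]
            for fitter, target in ((fit_survival, sc.survival),
                                   (fit_transition, sc.transition)):
                fit = fitter(pooled, segment=seg)
                z = np.abs(fit.params - target[:4]) / fit.bse
                assert z.max() < 3.0, (seg.name, fit.outcome, z)

    def test_all_survivors_raise_separation_error(self, single_segment):
        seg, design = single_segment
        truth = GroundTruth.from_probabilities(1.0, 1.0, 0.3, 0.9,
                                               segments=(seg,))
        panel = generate_panel(truth, design(n_persons=200, waves=4), seed=2)
        with pytest.raises(SeparationError):
            fit_survival(pool(panel))

    def test_frozen_states_detected_as_separation(self, single_segment):
        seg, design = single_segment
        truth = GroundTruth.from_probabilities(0.97, 0.97, 0.0, 1.0,
                                               segments=(seg,))
        panel = generate_panel(
            truth, design(n_persons=400, waves=5, initial_below=0.5), seed=3)
        with pytest.raises(SeparationError):
            fit_transition(pool(panel))

    def test_symmetric_null_transition_predicts_one_half(self, single_segment):
        seg, design = single_segment
        truth = GroundTruth.from_probabilities(0.99, 0.99, 0.5, 0.5,
                                               segments=(seg,))
        panel = generate_panel(truth, design(n_persons=6000, waves=4), seed=4)
        fit = fit_transition(pool(panel), segment=seg)
        p = predict_interval_probability(fit, 27, 1)
        se_p = 3 * np.sqrt(0.25 / fit.n_obs) * 4   # generous delta bound
        assert abs(p - 0.5) < max(0.02, se_p)

    def test_degenerate_weights_rejected(self):
        rows = [_panel_row(0, w, 30 + w, 1 + (w % 2), weight=0.0)
                for w in range(4)]
        with pytest.raises(EstimationError, match="weights"):
            fit_survival(pool(_tiny_panel(rows)))

    def test_doubling_weights_leaves_coefficients_unchanged(
            self, single_segment, truth_1x):
        seg, design = single_segment
        truth = GroundTruth.from_probabilities(0.95, 0.98, 0.3, 0.9,
                                               segments=(seg,))
        panel = generate_panel(truth,
                               design(n_persons=2000, waves=4,
                                      weight_sigma=0.5), seed=5)
        pooled = pool(panel)
        fit1 = fit_survival(pooled, segment=seg)
        pooled2 = pooled.assign(weight=2.0 * pooled["weight"])
        fit2 = fit_survival(pooled2, segment=seg)
        np.testing.assert_allclose(fit1.params, fit2.params, atol=1e-8)


class TestPredictAndAnnualize:
    def test_zero_coefficients_predict_one_half(self):
        f = _const_fit([0.0, 0.0, 0.0, 0.0])
        assert predict_interval_probability(f, 25, 1) == pytest.approx(0.5)

    def test_intercept_only_logit_round_trip(self):
        from scipy.special import logit
        f = _const_fit([float(logit(0.9)), 0.0, 0.0, 0.0])
        for age in (22, 28, 33):
            assert predict_interval_probability(f, age, 2) == \
                pytest.approx(0.9, abs=1e-12)

    def test_truth_coefficients_round_trip_to_truth_probability(
            self, truth_1x):
        from povdyn.estimation import segment_fits_from_truth
        fits = segment_fits_from_truth(truth_1x)
        for f in fits:
            a = f.age_lo + 2
            assert predict_interval_probability(f.survival, a, 1) == \
                pytest.approx(float(truth_1x.p_survive(a, 1)[0]), abs=1e-12)

    def test_prediction_refuses_extrapolation(self):
        f = _const_fit([1.0, 0.0, 0.0, 0.0])
        with pytest.raises(AgeRangeError):
            predict_interval_probability(f, 50, 1)

    def test_annualize_closed_forms(self):
        assert annualize(0.0, 24) == 0.0
        assert annualize(0.3, 12) == pytest.approx(0.3, abs=1e-15)
        # 24-month survival 0.96 compounds from two equal annual steps
        s_annual = annualize_survival(0.96, 24)
        assert s_annual == pytest.approx(np.sqrt(0.96), abs=1e-12)
        assert s_annual * s_annual == pytest.approx(0.96, abs=1e-12)
        with pytest.raises(ValueError):
            annualize(0.5, 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p=st.floats(0.0, 1.0), months=st.floats(12.0, 36.0))
    def test_annualize_shrinks_event_probability_over_longer_intervals(
            self, p, months):
        a = annualize(p, months)
        assert 0.0 <= a <= p + 1e-12
        a2 = annualize(min(1.0, p + 0.1), months)
        assert a2 >= a - 1e-12


def _const_fit(params, seg=("solo", 22, 33), months=12.0, outcome="survival"):
    params = np.asarray(params, dtype=float)
    k = params.size
    return est.FittedCoefficients(
        params, np.zeros(k), np.zeros((k, k)), Formula().names, Formula(),
        outcome, seg[0], seg[1], seg[2], months, 100)


def _const_segment_fit(p_surv, p_above_from1, p_above_from2, seg, months):
    from scipy.special import logit
    surv = _const_fit([float(logit(p_surv)), 0, 0, 0],
                      (seg.name, seg.age_lo, seg.age_hi), months)
    trans = est.FittedCoefficients(
        np.array([float(logit(p_above_from1)), 0.0,
                  float(logit(p_above_from2) - logit(p_above_from1)), 0.0]),
        np.zeros(4), np.zeros((4, 4)), Formula().names, Formula(),
        "transition", seg.name, seg.age_lo, seg.age_hi, months, 100)
    return SegmentFit(surv, trans)


class TestConcatenate:
    SEGS = (Segment("a", 22, 33, 12.0), Segment("b", 34, 50, 12.0),
            Segment("c", 51, 95, 12.0))

    def test_identical_constant_fits_have_no_seam_discontinuity(self):
        fits = [_const_segment_fit(0.95, 0.3, 0.9, s, s.interval_months)
                for s in self.SEGS]
        rs = concatenate_segments(fits)
        for col in ("s1", "s2", "t21", "t22"):
            assert rs.table[col].nunique() == 1
        assert rs.seams == (33, 50)

    def test_different_intercepts_jump_exactly_at_seams(self):
        fits = [_const_segment_fit(p, 0.3, 0.9, s, s.interval_months)
                for p, s in zip((0.93, 0.95, 0.97), self.SEGS)]
        rs = concatenate_segments(fits)
        s = rs.table["s1"]
        jumps = s.index[1:][np.abs(np.diff(s.to_numpy())) > 1e-12]
        assert list(jumps) == [34, 51]   # first age owned by the next segment

    def test_coverage_gap_lists_missing_ages(self):
        fits = [_const_segment_fit(0.95, 0.3, 0.9, self.SEGS[0], 12.0),
                _const_segment_fit(0.95, 0.3, 0.9, self.SEGS[2], 12.0)]
        with pytest.raises(EstimationError, match="34"):
            concatenate_segments(fits, ages=range(22, 96))

    def test_matrix_annualization_agrees_with_probability_root_when_exact(
            self):
        # with a 12-month interval both annualization routes are identities
        fits = [_const_segment_fit(0.95, 0.3, 0.9, s, 12.0)
                for s in self.SEGS]
        rs_p = concatenate_segments(fits, annualization="probability")
        rs_m = concatenate_segments(fits, annualization="matrix")
        pd.testing.assert_frame_equal(rs_p.table, rs_m.table, atol=1e-10)


class TestEndToEnd:
    def test_pipeline_recovers_annual_truth_closely(self, truth_2x):
        from povdyn.estimation import estimate_rateset
        panel = generate_panel(truth_2x, default_design(0.35), seed=6)
        rates, fits = estimate_rateset(panel)
        target = true_rateset(truth_2x)
        err = np.abs(rates.table.to_numpy() - target.table.to_numpy())
        # ~35k pooled rows/segment: noise-limited bound ~sqrt(3x) the 100k one
        assert err.max() < 0.025
        assert rates.seams == (33, 50)

    def test_coefficient_json_round_trip_reproduces_rates(
            self, tmp_path, truth_1x):
        from povdyn.estimation import segment_fits_from_truth
        fits = segment_fits_from_truth(truth_1x)
        path = tmp_path / "coefs.json"
        fits_to_json(fits, path)
        fits2 = fits_from_json(path)
        rs1 = concatenate_segments(fits)
        rs2 = concatenate_segments(fits2)
        pd.testing.assert_frame_equal(rs1.table, rs2.table)


class TestNonresponseDiagnostic:
    def test_zero_nonresponse_design_reports_all_zero(self, single_segment):
        seg, design = single_segment
        truth = GroundTruth.from_probabilities(0.97, 0.99, 0.3, 0.9,
                                               segments=(seg,))
        panel = generate_panel(truth, design(n_persons=500, waves=4), seed=0)
        tab = nonresponse_by_state_age(panel)
        assert (tab["p_nonresponse_below"].dropna() == 0).all()
        assert (tab["p_nonresponse_above"].dropna() == 0).all()

    def test_state_independent_nonresponse_has_null_difference(
            self, single_segment):
        seg, design = single_segment
        truth = GroundTruth.from_probabilities(0.995, 0.995, 0.3, 0.9,
                                               segments=(seg,))
        panel = generate_panel(
            truth, design(n_persons=20_000, waves=4, nonresponse=0.1), seed=1)
        tab = nonresponse_by_state_age(panel).dropna()
        n1, n2 = tab["n_below"], tab["n_above"]
        se = np.sqrt(0.1 * 0.9 * (1 / n1 + 1 / n2))
        z = tab["difference"] / se
        assert (np.abs(z) < 4).all()          # simultaneous over ~11 ages
        pooled_diff = np.average(tab["difference"],
                                 weights=(n1 * n2) / (n1 + n2))
        pooled_se = 1 / np.sqrt(((n1 * n2) / (n1 + n2) / (0.1 * 0.9)).sum())
        assert abs(pooled_diff) < 3 * pooled_se

    def test_state_dependent_nonresponse_has_positive_difference(
            self, single_segment):
        seg, design = single_segment
        truth = GroundTruth.from_probabilities(0.995, 0.995, 0.2, 0.8,
                                               segments=(seg,))
        panel = generate_panel(
            truth, design(n_persons=20_000, waves=4, nonresponse=0.1,
                          odds=2.0), seed=2)
        tab = nonresponse_by_state_age(panel).dropna()
        well = tab[(tab["n_below"] >= 200) & (tab["n_above"] >= 200)]
        assert len(well) > 0
        assert (well["difference"] > 0).all()
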