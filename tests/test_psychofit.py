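import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from numblind import psychofit as pf
from numblind import stimulus_design as sd

RATIOS = np.array(sd.RATIO_NUMERATORS) / sd.RATIO_DENOMINATOR


class TestChoiceProbability:
    def test_equal_magnitudes_give_half(self):
        for w in (0.01, 0.0743, 0.5):
            assert pf.choice_probability(12, 12, w) == pytest.approx(0.5)

    def test_lapse_asymptotes(self):
        assert pf.choice_probability(12, 1e6, 0.1) == pytest.approx(0.985)
        assert pf.choice_probability(12, 1e-6, 0.1) == pytest.approx(0.015)

    def test_monotone_in_comparison(self):
        c = np.linspace(6, 24, 200)
        p = pf.choice_probability(12.0, c, 0.0743)
        assert np.all(np.diff(p) > 0)

    @given(
        k=st.floats(0.1, 10),
        w=st.floats(0.01, 1.0),
        ratio=st.sampled_from(list(RATIOS)),
    )
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, k, w, ratio):
        """Weber noise makes choice probability depend only on c/s."""
        base = pf.choice_probability(12.0, 12.0 * ratio, w)
        scaled = pf.choice_probability(12.0 * k, 12.0 * k * ratio, w)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            pf.choice_probability(12, 16, 0.0)
        with pytest.raises(ValueError):
            pf.choice_probability(-1, 16, 0.1)

    def test_matches_sampling_oracle(self):
        """Monte-Carlo oracle: draw the two Weber-noised magnitudes and the
        3% guessing mixture directly; 10^6 draws agree within 3 SE."""
        s, c, w = 12.0, 16.0, 0.0743
        p_model = pf.choice_probability(s, c, w)
        rng = np.random.default_rng(42)
        n = 1_000_000
        s_hat = rng.normal(s, w * s, n)
        c_hat = rng.normal(c, w * c, n)
        choice = c_hat > s_hat
        guess = rng.random(n) < 0.03
        choice = np.where(guess, rng.random(n) < 0.5, choice)
        p_mc = choice.mean()
        se = math.sqrt(p_model * (1 - p_model) / n)
        assert abs(p_mc - p_model) < 3 * se


def _simulate_block(w, rng, n_trials_per_ratio=None):
    """Responses drawn from the fitted model itself at known w, using the
    skewed per-ratio allocation."""
    counts = n_trials_per_ratio or sd.TESTING_COUNTS_SKEWED
    s_list, c_list = [], []
    for num, k in counts.items():
        s_list += [12.0] * k
        c_list += [num / 12 * 12.0] * k
    s = np.array(s_list)
    c = np.array(c_list)
    y = rng.random(len(s)) < pf.choice_probability(s, c, w)
    return pd.DataFrame({"standard": s, "comparison": c, "chose_comparison": y})


class TestFitWeber:
    def test_fit_matches_grid_oracle(self):
        """The bounded optimizer's likelihood is no worse than an exhaustive
        grid over w in (1e-4, 1] at step 1e-4."""
        rng = np.random.default_rng(0)
        for w_true in (0.05, 0.15):
            df = _simulate_block(w_true, rng)
            fit = pf.fit_weber(df, participant_id="p", condition="area_only")
            s, c, y, wt = pf._records_to_arrays(df)
            s = np.append(s, 12.0)
            c = np.append(c, 11.0)
            y = np.append(y, True)
            wt = np.append(wt, 0.5)
            grid = np.arange(1e-4, 1.0 + 1e-4, 1e-4)
            # grid NLL evaluated from the model equation directly
            sigma = grid[:, None] * np.sqrt(s**2 + c**2)[None, :]
            from scipy.special import ndtr

            pm = ndtr((c - s)[None, :] / sigma) * pf.LAPSE_SCALE + pf.LAPSE_FLOOR
            nll = -np.sum(wt * np.where(y, np.log(pm), np.log1p(-pm)), axis=1)
            assert fit.neg_log_lik <= nll.min() + 1e-6
            assert abs(fit.w - grid[np.argmin(nll)]) < 5e-4

    def test_all_correct_needs_augmentation(self):
        """A flawless participant has finite positive w only because of the
        half-trial at ratio 11/12; without it the fit degenerates to the
        lower bound."""
        rows = []
        for num, k in sd.TESTING_COUNTS_SKEWED.items():
            for _ in range(k):
                rows.append(
                    pf.ChoiceRecord("p", "exp1", "area_only", 12.0, num / 12 * 12.0, num > 12)
                )
        fit = pf.fit_weber(rows)
        assert 1e-3 < fit.w < 0.1
        assert fit.n_trials_effective == pytest.approx(42.5)
        degenerate = pf.fit_weber(rows, augment=False)
        # unaugmented likelihood is flat from the lower bound up: w unidentified
        assert degenerate.w < fit.w
        s = np.full(42, 12.0)
        c = np.array([num / 12 * 12.0 for num, k in sd.TESTING_COUNTS_SKEWED.items() for _ in range(k)])
        y = c > 12
        ones = np.ones(42)
        assert pf._nll(1e-4, s, c, y, ones) == pytest.approx(
            pf._nll(degenerate.w, s, c, y, ones), abs=1e-9
        )

    def test_parameter_recovery_is_consistent(self):
        """Fits sharpen with trial count: 100x the trials brings the fitted
        w within .005 of truth."""
        rng = np.random.default_rng(1)
        w_true = 0.08
        big = {num: k * 100 for num, k in sd.TESTING_COUNTS_SKEWED.items()}
        fit = pf.fit_weber(_simulate_block(w_true, rng, big), participant_id="p", condition="x")
        assert fit.w == pytest.approx(w_true, abs=0.005)

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            pf.fit_weber([])


class TestCombination:
    def test_equal_reliability_closed_form(self):
        assert pf.combination_prediction(0.1, 0.1) == pytest.approx(0.1 / math.sqrt(2))

    def test_uninformative_cue_limit(self):
        assert pf.combination_prediction(0.05, 1e9) == pytest.approx(0.05)

    def test_table_scale_values(self):
        """Independent arithmetic: 1/w^2 reliabilities add."""
        w_a, w_n = 0.0743, 0.132
        expected = 1.0 / math.sqrt(1 / w_a**2 + 1 / w_n**2)
        assert pf.combination_prediction(w_a, w_n) == pytest.approx(expected)
        assert pf.combination_prediction(w_a, w_n) == pytest.approx(
            pf.combination_prediction(w_n, w_a)
        )

    @given(w=st.floats(0.01, 1.0))
    @settings(deadline=None, max_examples=30)
    def test_sqrt2_identity(self, w):
        assert pf.combination_prediction(w, w) * math.sqrt(2) == pytest.approx(w, rel=1e-12)

    def test_never_exceeds_better_cue(self):
        assert pf.combination_prediction(0.05, 0.2) < 0.05

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pf.combination_prediction(0.0, 0.1)


def _records_with_accuracy(n_correct, n_total):
    recs = []
    for i in range(n_total):
        correct = i < n_correct
        # comparison larger: correct means chose_comparison
        recs.append(pf.ChoiceRecord("p", "exp1", "area_only", 12.0, 13.0, correct))
    return recs


class TestAboveChance:
    def test_perfect_and_chance_performers(self):
        assert pf.above_chance_filter(_records_with_accuracy(126, 126)).keep
        res = pf.above_chance_filter(_records_with_accuracy(63, 126))
        assert not res.keep
        assert res.p_value > 0.4

    def test_threshold_matches_exact_binomial_tail(self):
        """The minimal passing correct-count equals the smallest k whose
        exact upper binomial tail (computed by direct enumeration) is
        <= .05."""
        n = 126
        tail = 0.0
        k_min = None
        pmf = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
        for k in range(n, -1, -1):
            tail += pmf[k]
            if tail > 0.05:
                k_min = k + 1
                break
        assert k_min is not None
        assert not pf.above_chance_filter(_records_with_accuracy(k_min - 1, n)).keep
        assert pf.above_chance_filter(_records_with_accuracy(k_min, n)).keep


def _fit(pid, cond, w):
    return pf.WeberFit(pid, cond, w, 0.0, 42.5, True)


class TestOutlierFilter:
    def test_three_times_median_rule(self):
        fits = [_fit("a", "x", 0.05), _fit("b", "x", 0.06), _fit("c", "x", 0.2)]
        keep = pf.outlier_filter(fits)
        assert keep.tolist() == [True, True, False]

    def test_all_equal_none_excluded(self):
        fits = [_fit(p, "x", 0.07) for p in "abc"]
        assert pf.outlier_filter(fits).all()

    def test_exactly_three_times_median_retained(self):
        fits = [_fit("a", "x", 0.05), _fit("b", "x", 0.05), _fit("c", "x", 0.15)]
        assert pf.outlier_filter(fits).all()  # strict "more than"

    def test_participant_scope_drops_all_conditions(self):
        fits = [
            _fit("a", "x", 0.05),
            _fit("a", "y", 0.05),
            _fit("b", "x", 0.05),
            _fit("b", "y", 0.05),
            _fit("c", "x", 0.5),
            _fit("c", "y", 0.05),
        ]
        keep = pf.outlier_filter(fits, scope="participant")
        assert keep.tolist() == [True, True, True, True, False, False]
        keep_obs = pf.outlier_filter(fits, scope="observation")
        assert keep_obs.tolist() == [True, True, True, True, False, True]

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError):
            pf.outlier_filter([_fit("a", "x", 0.05)], scope="block")


def _an_record(c, lum_std, lum_cmp, wf_std=0.5, wf_cmp=0.5, training=False):
    return pf.ChoiceRecord(
        "p", "exp1", "area_number", 12.0, c, True,
        is_training=training,
        white_fraction_standard=wf_std,
        white_fraction_comparison=wf_cmp,
        luminance_standard=lum_std,
        luminance_comparison=lum_cmp,
    )


class TestBrightCongruent:
    def test_selects_trials_where_larger_side_is_brighter(self):
        recs = [
            _an_record(13.0, 0.42, 0.45),  # comparison larger & brighter: in
            _an_record(13.0, 0.45, 0.42),  # comparison larger but darker: out
            _an_record(9.0, 0.45, 0.42),   # standard larger & brighter: in
            _an_record(13.0, 0.42, 0.45, training=True),  # training: out
        ]
        sel = pf.select_bright_congruent(recs)
        assert [r.comparison for r in sel] == [13.0, 9.0]

    def test_more_white_dots_is_not_brighter(self):
        """The larger side can hold more white dots yet be darker: its white
        percentage is lower and its big blue square displaces bright void.
        Selection keys on luminance, so the trial is excluded."""
        spec16 = sd.TrialSpec("area_number", 16, False, "exp1")
        pair = sd.make_stimulus_pair(spec16, seed=5)
        big, small = pair.comparison, pair.standard

        def recolor(side, n_white):
            side.dots = [
                (x, y, "white" if i < n_white else "black")
                for i, (x, y, _) in enumerate(side.dots)
            ]
            side.white_fraction = n_white / side.n_dots

        recolor(big, 7)    # 7/16 = 44% white -> more white dots than small side
        recolor(small, 6)  # 6/12 = 50% white -> higher percentage
        lum_big, lum_small = sd.mean_luminance(big), sd.mean_luminance(small)
        assert big.white_fraction < small.white_fraction
        assert lum_big < lum_small
        rec = _an_record(16.0, lum_small, lum_big, wf_std=0.5, wf_cmp=7 / 16)
        assert pf.select_bright_congruent([rec]) == []

    def test_missing_luminance_errors(self):
        rec = _an_record(13.0, float("nan"), 0.45)
        with pytest.raises(ValueError, match="mean_luminance"):
            pf.select_bright_congruent([rec])

    def test_dataframe_interface(self):
        df = pd.DataFrame(
            {
                "participant_id": ["p"] * 3,
                "condition": ["area_number", "area_number", "area_only"],
                "is_training": [False, False, False],
                "standard": [12.0, 12.0, 12.0],
                "comparison": [13.0, 13.0, 13.0],
                "chose_comparison": [True, False, True],
                "lum_std": [0.4, 0.5, 0.4],
                "lum_cmp": [0.5, 0.4, 0.5],
            }
        )
        sel = pf.select_bright_congruent(df)
        assert len(sel) == 1 and sel.iloc[0]["lum_cmp"] == 0.5
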