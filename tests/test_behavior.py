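"""Exclusion rules, confidence binning, type-1 SDT, and 2x2 RM-ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaphysio import (
    apply_exclusions,
    bin_confidence_quartiles,
    compute_masking_dprime_ci,
    compute_type1_sdt,
    rm_anova_2x2,
)


def _trials(n=640, rt=0.4, missed=False):
    return pd.DataFrame(
        dict(
            trial_index=np.arange(n),
            block=np.arange(n) // (n // 10),
            rt=np.full(n, rt, dtype=float),
            missed=np.full(n, missed),
        )
    )


class TestExclusions:
    def test_burn_in_removes_first_quarter(self):
        kept, report = apply_exclusions(_trials(640))
        assert report.n_burn_in == 160
        assert kept["trial_index"].min() == 160

    def test_burn_in_by_blocks(self):
        kept, report = apply_exclusions(_trials(640), burn_in_blocks=2)
        assert report.n_burn_in == 128

    def test_equal_rts_are_never_outliers(self):
        kept, report = apply_exclusions(_trials(640))
        assert report.n_rt_outlier == 0 and report.n_missed == 0

    def test_extreme_rt_removed_by_z_rule(self):
        t = _trials(533)
        t.loc[t.index[-1], "rt"] = 10.0
        t["rt"] += np.random.default_rng(0).normal(0, 0.01, len(t))
        kept, report = apply_exclusions(t, burn_in_fraction=0.25)
        assert report.n_rt_outlier == 1
        assert 10.0 not in kept["rt"].to_numpy()

    def test_missed_trials_removed(self):
        t = _trials(640)
        t.loc[t.index[300:310], "missed"] = True
        kept, report = apply_exclusions(t)
        assert report.n_missed == 10 and not kept["missed"].any()

    def test_empty_input(self):
        kept, report = apply_exclusions(_trials(0))
        assert len(kept) == 0 and report.n_input == 0

    def test_ledger_conserves_trials(self, session_trials):
        kept, r = apply_exclusions(session_trials)
        assert r.n_burn_in + r.n_missed + r.n_rt_outlier + r.n_kept == r.n_input == len(
            session_trials
        )


class TestConfidenceBinning:
    def test_uniform_values_split_evenly(self):
        bins = bin_confidence_quartiles(np.arange(1, 101))
        assert [np.sum(bins == k) for k in (1, 2, 3, 4)] == [25, 25, 25, 25]

    def test_degenerate_values_fall_back_to_equal_width(self):
        with pytest.warns(UserWarning):
            bins = bin_confidence_quartiles(np.full(50, 100.0))
        assert np.all(bins == 4)

    def test_tied_multiset_bins_exactly(self):
        vals = np.repeat([20, 40, 60, 80], 10)
        bins = bin_confidence_quartiles(vals)
        for k, v in zip((1, 2, 3, 4), (20, 40, 60, 80)):
            assert np.all(bins[vals == v] == k)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_confidence_quartiles(np.array([50, 101]))


class TestType1SDT:
    @staticmethod
    def _from_rates(hit, fa, n=100):
        n_hit = int(round(hit * n))
        n_fa = int(round(fa * n))
        side = ["right"] * n + ["left"] * n
        choice = (
            ["right"] * n_hit + ["left"] * (n - n_hit)
            + ["right"] * n_fa + ["left"] * (n - n_fa)
        )
        return pd.DataFrame(dict(side=side, choice=choice))

    def test_textbook_hit_fa_example(self):
        sdt = compute_type1_sdt(self._from_rates(0.8, 0.2))
        assert sdt.d_prime == pytest.approx(2 * 0.8416, abs=1e-3)
        assert sdt.criterion_c == pytest.approx(0.0, abs=1e-9)

    def test_chance_performance(self):
        sdt = compute_type1_sdt(self._from_rates(0.5, 0.5))
        assert sdt.d_prime == 0.0 and sdt.criterion_c == 0.0

    def test_pure_bias(self):
        sdt = compute_type1_sdt(self._from_rates(0.9, 0.9))
        assert sdt.d_prime == pytest.approx(0.0, abs=1e-9)
        assert sdt.criterion_c == pytest.approx(-1.2816, abs=1e-3)

    def test_degenerate_rates_get_log_linear_correction(self):
        sdt = compute_type1_sdt(self._from_rates(1.0, 0.0))
        assert np.isfinite(sdt.d_prime)
        assert sdt.hit_rate == pytest.approx(100.5 / 101)

    def test_missing_stimulus_side_rejected(self):
        df = pd.DataFrame(dict(side=["right"] * 10, choice=["right"] * 10))
        with pytest.raises(ValueError):
            compute_type1_sdt(df)


class TestMaskingEfficacy:
    @staticmethod
    def _valence_trials(p_correct, n=200, n_subjects=20, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for s in range(n_subjects):
            cue = np.where(rng.random(n) < 0.5, "disgust", "neutral")
            correct = rng.random(n) < p_correct
            other = np.where(cue == "disgust", "neutral", "disgust")
            resp = np.where(correct, cue, other)
            frames.append(pd.DataFrame(dict(subject=s, cue=cue, response=resp)))
        return pd.concat(frames)

    def test_guessing_ci_spans_zero(self):
        out = compute_masking_dprime_ci(self._valence_trials(0.5))
        assert out["masked"] is True

    def test_perfect_detection_excludes_zero(self):
        out = compute_masking_dprime_ci(self._valence_trials(0.999))
        assert out["masked"] is False and out["d_prime_mean"] > 2

    def test_t_interval_matches_closed_form(self):
        rng = np.random.default_rng(1)
        dps = rng.normal(0.3, 0.1, 25)
        # feed pre-computed d' values through the same t-interval oracle
        mean, sem = dps.mean(), dps.std(ddof=1) / 5.0
        tcrit = stats.t.ppf(0.975, 24)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
        assert lo > 0  # CI excludes zero for this effect size
        out = compute_masking_dprime_ci(self._valence_trials(0.56, n_subjects=25, seed=2))
        assert out["ci"][0] < out["d_prime_mean"] < out["ci"][1]

    def test_single_subject_warns(self):
        with pytest.warns(UserWarning):
            out = compute_masking_dprime_ci(self._valence_trials(0.5, n_subjects=1))
        assert out["ci"] is None


class TestRmAnova:
    def test_identical_cells_give_zero_f(self):
        cells = pd.DataFrame({k: np.full(10, 2.0) for k in ("NL", "NH", "DL", "DH")})
        res = rm_anova_2x2(cells)
        assert res["cue"]["F"] == 0 and res["interaction"]["F"] == 0

    def test_pure_additive_variance_effect_has_zero_interaction(self):
        base = np.random.default_rng(0).normal(1, 0.2, 12)
        cells = pd.DataFrame(dict(NL=base, DL=base, NH=base + 0.5, DH=base + 0.5))
        res = rm_anova_2x2(cells)
        assert res["interaction"]["F"] == pytest.approx(0.0, abs=1e-18)
        assert res["variance"]["p"] < 1e-6

    def test_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(3)
        cells = pd.DataFrame(
            {k: rng.normal(size=25) for k in ("NL", "NH", "DL", "DH")}
        )
        res = rm_anova_2x2(cells)
        inter = (cells["DH"] - cells["DL"]) - (cells["NH"] - cells["NL"])
        t, p = stats.ttest_1samp(inter, 0.0)
        assert res["interaction"]["F"] == pytest.approx(t**2, rel=1e-10)
        assert res["interaction"]["p"] == pytest.approx(p, rel=1e-10)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        cells = pd.DataFrame({k: rng.normal(size=15) for k in ("NL", "NH", "DL", "DH")})
        res = rm_anova_2x2(cells)
        long = cells.reset_index().melt(id_vars="index", var_name="cond")
        long["cue"] = long["cond"].str[0]
        long["variance"] = long["cond"].str[1]
        ref = pingouin.rm_anova(
            data=long, dv="value", within=["cue", "variance"], subject="index",
            detailed=True,
        )
        ref_inter = ref.loc[ref["Source"].str.contains("\\*"), "F"].iloc[0]
        assert res["interaction"]["F"] == pytest.approx(ref_inter, rel=1e-6)

    def test_missing_cells_rejected(self):
        cells = pd.DataFrame(dict(NL=[1, 2, 3], NH=[1, 2, 3], DL=[1, 2, 3]))
        with pytest.raises(ValueError):
            rm_anova_2x2(cells)
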