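"""State amounts, bouts, sleep lost and recovery normalization."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from resisleep.architecture import (RecoveryCurve, detect_bouts, mean_bout_length,
                                    percent_recovered, sleep_lost, state_minutes)
from resisleep.core import ARTIFACT, NREM, REM, WAKE, Hypnogram
from resisleep.simulate import PhenotypeParams, StudyDesign, generate_hypnogram


def hyp_from(labels, zt_start_s=0.0):
    return Hypnogram(labels=np.array(labels), epoch_s=10.0, zt_start_s=zt_start_s)


def full_day(labels_fn):
    labels = np.array([labels_fn(i) for i in range(8640)])
    return Hypnogram(labels=labels, epoch_s=10.0)


class TestStateMinutes:
    def test_all_wake_day_has_no_sleep(self):
        tc = state_minutes(full_day(lambda i: WAKE))
        assert (tc.table[NREM] == 0).all()
        assert (tc.table[REM] == 0).all()
        assert (tc.table["TOTAL_SLEEP"] == 0).all()

    def test_360_nrem_epochs_are_60_light_minutes(self):
        tc = state_minutes(full_day(lambda i: NREM if i < 360 else WAKE))
        totals = tc.totals()
        assert totals.loc[NREM, "light"] == pytest.approx(60.0)
        assert totals.loc[NREM, "dark"] == 0.0

    def test_totals_require_full_day(self):
        tc = state_minutes(hyp_from([WAKE] * 360))
        with pytest.raises(ValueError, match="24-h"):
            tc.totals()

    def test_invalid_bin_rejected(self, simple_hypnogram):
        with pytest.raises(ValueError, match="720"):
            state_minutes(simple_hypnogram, bin_min=100.0)

    @given(st.integers(0, 2**31 - 1))
    def test_conservation_sums_to_1440(self, seed):
        design = StudyDesign(days=("BASELINE",))
        hyp = generate_hypnogram(design, PhenotypeParams.resilient(),
                                 "BASELINE", seed % 50)
        totals = state_minutes(hyp).totals()
        assert totals["total_24h"].drop("TOTAL_SLEEP").sum() == pytest.approx(1440.0)

    def test_post_defeat_dark_sleep_increases_in_resilient(self):
        """The resilient-only reorganization: dark-period sleep rises and
        light-period sleep falls on post-defeat days."""
        design = StudyDesign(days=("BASELINE", "DEFEAT"))
        pheno = PhenotypeParams.resilient()
        dark_diffs, light_diffs = [], []
        for seed in range(8):
            base = state_minutes(generate_hypnogram(design, pheno, "BASELINE",
                                                    seed)).totals()
            post = state_minutes(generate_hypnogram(design, pheno, "DEFEAT",
                                                    1000 + seed)).totals()
            dark_diffs.append(post.loc["TOTAL_SLEEP", "dark"]
                              - base.loc["TOTAL_SLEEP", "dark"])
            light_diffs.append(post.loc["TOTAL_SLEEP", "light"]
                               - base.loc["TOTAL_SLEEP", "light"])
        assert np.mean(dark_diffs) > 30.0
        assert np.mean(light_diffs) < -30.0


class TestBouts:
    def test_basic_runs(self):
        bouts = detect_bouts(hyp_from([WAKE, NREM, NREM, NREM, REM, WAKE]))
        nrem = bouts[bouts["state"] == NREM]
        rem = bouts[bouts["state"] == REM]
        assert len(nrem) == 1 and nrem.iloc[0]["n_epochs"] == 3
        assert nrem.iloc[0]["duration_s"] == 30.0
        assert len(rem) == 1 and rem.iloc[0]["n_epochs"] == 1

    def test_artifact_splits_bouts(self):
        bouts = detect_bouts(hyp_from([NREM, ARTIFACT, NREM]))
        nrem = bouts[bouts["state"] == NREM]
        assert len(nrem) == 2
        assert (nrem["n_epochs"] == 1).all()

    @given(st.lists(st.sampled_from([WAKE, NREM, REM, ARTIFACT]),
                    min_size=1, max_size=200))
    def test_bout_table_reconstructs_hypnogram(self, labels):
        hyp = hyp_from(labels)
        bouts = detect_bouts(hyp)
        rebuilt = np.concatenate([
            np.repeat(row["state"], row["n_epochs"])
            for _, row in bouts.iterrows()
        ])
        np.testing.assert_array_equal(rebuilt, hyp.labels)

    def test_mean_nrem_bout_length_recovers_generator_parameter(self):
        """Parameter recovery: generated mean NREM bout length within 10%."""
        design = StudyDesign(days=("BASELINE",))
        for pheno in (PhenotypeParams.resilient(), PhenotypeParams.susceptible()):
            means = []
            for seed in range(20):
                hyp = generate_hypnogram(design, pheno, "BASELINE", seed)
                # measure on artifact-excluded labels so random artifact
                # relabeling does not shorten the underlying bout process
                clean = Hypnogram(labels=hyp.labels[hyp.labels != ARTIFACT],
                                  epoch_s=hyp.epoch_s)
                means.append(mean_bout_length(clean, NREM))
            observed = np.mean(means)
            expected = pheno.mean_nrem_bout_epochs
            assert abs(observed - expected) / expected < 0.10


class TestSleepLost:
    def test_identical_days_lose_nothing(self):
        hyp = hyp_from([NREM] * 2160)
        lost = sleep_lost(hyp, hyp, window_zt_h=(0, 6))
        assert lost[NREM] == 0.0 and lost[REM] == 0.0

    def test_subtraction_example(self):
        """Baseline 240 NREM min vs 12 min on the restriction day: 228 lost."""
        base = hyp_from([NREM] * 1440 + [WAKE] * 720)
        restr = hyp_from([NREM] * 72 + [WAKE] * 2088)
        lost = sleep_lost(restr, base, window_zt_h=(0, 6))
        assert lost[NREM] == pytest.approx(228.0)

    def test_lost_floored_at_zero(self):
        base = hyp_from([WAKE] * 2160)
        restr = hyp_from([NREM] * 2160)
        assert sleep_lost(restr, base, (0, 6))[NREM] == 0.0

    def test_misaligned_windows_rejected(self):
        short = hyp_from([NREM] * 100)
        with pytest.raises(ValueError, match="cover"):
            sleep_lost(short, short, window_zt_h=(0, 6))

    def test_phenotypes_lose_similar_nrem_under_restriction(self):
        """Enforced wakefulness removes comparable sleep from both
        phenotypes (the design matches baseline amounts)."""
        from scipy import stats as spstats
        design = StudyDesign(days=("BASELINE", "RESTRICTION_6H"))
        lost = {"RESILIENT": [], "SUSCEPTIBLE": []}
        for seed in range(10):
            for pheno in (PhenotypeParams.resilient(),
                          PhenotypeParams.susceptible()):
                base = generate_hypnogram(design, pheno, "BASELINE", seed)
                restr = generate_hypnogram(design, pheno, "RESTRICTION_6H",
                                           500 + seed)
                lost[pheno.label].append(
                    sleep_lost(restr, base, (0, 6))[NREM])
        t = spstats.ttest_ind(lost["RESILIENT"], lost["SUSCEPTIBLE"])
        assert t.pvalue > 0.05


class TestPercentRecovered:
    def test_identical_days_stay_at_zero(self):
        hyp = full_day(lambda i: NREM if i % 3 == 0 else WAKE)
        curve = percent_recovered(hyp, hyp, lost_min=120.0)
        assert (curve.table["percent_recovered"] == 0).all()

    def test_sixty_minute_excess_of_120_lost_is_fifty_percent(self):
        base = full_day(lambda i: WAKE)
        rec = full_day(lambda i: NREM if 2160 <= i < 2520 else WAKE)
        curve = percent_recovered(rec, base, lost_min=120.0,
                                  window_zt_h=(6, 24), bin_min=120.0)
        assert curve.table.iloc[0]["percent_recovered"] == pytest.approx(50.0)
        assert curve.table.iloc[-1]["percent_recovered"] == pytest.approx(50.0)

    def test_zero_lost_rejected(self):
        hyp = full_day(lambda i: WAKE)
        with pytest.raises(ValueError, match="lost"):
            percent_recovered(hyp, hyp, lost_min=0.0)

    def test_translation_invariance(self):
        """Adding the same sleep to both days leaves the curve unchanged."""
        base = full_day(lambda i: NREM if i % 5 == 0 else WAKE)
        rec = full_day(lambda i: NREM if (i % 5 == 0 or 2200 <= i < 2400) else WAKE)
        c1 = percent_recovered(rec, base, lost_min=100.0)
        # add sleep at epochs that are WAKE on *both* days
        idx = np.arange(8640)
        extra = (idx % 5 == 1) & ((idx < 2200) | (idx >= 2400))
        shift = lambda h: Hypnogram(  # noqa: E731
            labels=np.where(extra, NREM, h.labels), epoch_s=10.0)
        c2 = percent_recovered(shift(rec), shift(base), lost_min=100.0)
        np.testing.assert_allclose(c1.table["percent_recovered"],
                                   c2.table["percent_recovered"], atol=1e-9)

    def test_susceptible_recovers_more_than_resilient(self):
        """Larger homeostatic rebound in the susceptible generator pushes
        its % recovered curve above the resilient one."""
        design = StudyDesign(days=("BASELINE", "RESTRICTION_6H"))
        finals = {}
        for pheno in (PhenotypeParams.resilient(), PhenotypeParams.susceptible()):
            vals = []
            for seed in range(8):
                base = generate_hypnogram(design, pheno, "BASELINE", seed)
                restr = generate_hypnogram(design, pheno, "RESTRICTION_6H",
                                           900 + seed)
                lost = sleep_lost(restr, base, (0, 6))[NREM]
                curve = percent_recovered(restr, base, lost, (6, 24))
                vals.append(curve.table.iloc[-1]["percent_recovered"])
            finals[pheno.label] = np.mean(vals)
        assert finals["SUSCEPTIBLE"] > finals["RESILIENT"]
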