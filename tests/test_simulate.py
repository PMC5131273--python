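"""Synthetic trial, test and cohort generation."""
import numpy as np
import pytest

import tinnipy as tp
from tinnipy.records import GAP, NO_GAP
from tinnipy.scoring import score_test


def test_noise_free_peak_equals_median(quiet_cfg, rng):
    """With zero noise, zero sigma and no suppression the transient peak is the median."""
    cfg = quiet_cfg
    for idx in (1, 5, 20):
        trial = tp.simulate_trial(cfg, "no_gap", idx, rng)
        assert trial.startle_window.max() == pytest.approx(cfg.startle_amp_median)
        assert np.all(trial.baseline_window == 0.0)


def test_habituation_decays_peak(rng):
    cfg = tp.SimConfig(
        baseline_noise_sd=0.0, startle_amp_sigma=0.0, habituation_decay=0.95
    )
    t1 = tp.simulate_trial(cfg, "no_gap", 1, rng)
    t10 = tp.simulate_trial(cfg, "no_gap", 10, rng)
    assert t10.startle_window.max() == pytest.approx(
        t1.startle_window.max() * 0.95**9
    )


def test_full_gap_suppression_zeroes_the_transient(rng):
    cfg = tp.SimConfig(
        baseline_noise_sd=0.0, startle_amp_sigma=0.0, gap_suppression=1.0
    )
    trial = tp.simulate_trial(cfg, "gap", 1, rng)
    assert np.all(trial.startle_window == 0.0)
    assert np.array_equal(
        trial.startle_window[: trial.baseline_window.size], trial.baseline_window
    )


def test_unknown_condition_rejected(rng):
    with pytest.raises(ValueError):
        tp.simulate_trial(tp.SimConfig(), "gapp", 1, rng)


def test_lognormal_amplitude_median(rng):
    """Monte-Carlo check of the stated lognormal peak-amplitude median."""
    cfg = tp.SimConfig(
        baseline_noise_sd=0.0, startle_amp_sigma=0.5, habituation_decay=1.0
    )
    peaks = [
        tp.simulate_trial(cfg, "no_gap", 1, rng).startle_window.max()
        for _ in range(2000)
    ]
    assert np.median(peaks) == pytest.approx(cfg.startle_amp_median, rel=0.05)


def test_condition_balance_and_random_order(rng):
    cfg = tp.SimConfig()
    rec = tp.simulate_test(cfg, "GPIAS", 8.0, rng)
    conds = [t.condition for t in rec.trials]
    assert len(rec.trials) == 50
    assert conds.count(GAP) == 25 and conds.count(NO_GAP) == 25
    rec2 = tp.simulate_test(cfg, "GPIAS", 8.0, rng)
    assert [t.condition for t in rec2.trials] != conds  # order re-randomised


def test_ppi_test_uses_prepulse_conditions(rng):
    rec = tp.simulate_test(tp.SimConfig(), "PPI", 14.0, rng)
    assert {t.condition for t in rec.trials} == {"prepulse", "no_prepulse"}


def test_seed_reproducibility():
    cfg = tp.SimConfig()
    a = tp.simulate_test(cfg, "GPIAS", 8.0, np.random.default_rng(9))
    b = tp.simulate_test(cfg, "GPIAS", 8.0, np.random.default_rng(9))
    for ta, tb in zip(a.trials, b.trials):
        assert ta.condition == tb.condition
        assert np.array_equal(ta.baseline_window, tb.baseline_window)
        assert np.array_equal(ta.startle_window, tb.startle_window)


def test_tinnitus_effect_abolishes_gap_suppression(rng):
    """tinnitus_effect=0 at the tinnitus frequency: both conditions identically distributed."""
    cfg = tp.SimConfig(tinnitus_effect=0.0, baseline_noise_sd=0.0, startle_amp_sigma=0.0)
    truth = tp.AnimalTruth(tinnitus="8", onset_week=2)
    rec = tp.simulate_test(cfg, "GPIAS", 8.0, rng, truth=truth, week=5)
    peaks = {c: [] for c in (GAP, NO_GAP)}
    for t in rec.trials:
        peaks[t.condition].append(t.startle_window.max() / 0.99 ** (t.trial_index - 1))
    assert np.allclose(sorted(peaks[GAP]), sorted(peaks[NO_GAP]))
    # at the other frequency suppression is intact
    rec2 = tp.simulate_test(cfg, "GPIAS", 14.0, rng, truth=truth, week=5)
    for t in rec2.trials:
        if t.condition == GAP:
            assert t.startle_window.max() < 0.6 * cfg.startle_amp_median


def test_tinnitus_inactive_before_onset(rng):
    cfg = tp.SimConfig(tinnitus_effect=0.0, baseline_noise_sd=0.0, startle_amp_sigma=0.0)
    truth = tp.AnimalTruth(tinnitus="8", onset_week=6)
    rec = tp.simulate_test(cfg, "GPIAS", 8.0, rng, truth=truth, week=3)
    gaps = [t.startle_window.max() for t in rec.trials if t.condition == GAP]
    assert max(gaps) < 0.6 * cfg.startle_amp_median


def test_restore_recovers_suppression(rng):
    cfg = tp.SimConfig(tinnitus_effect=0.0, startle_amp_sigma=0.1)
    truth = tp.AnimalTruth(tinnitus="8", onset_week=2)
    rec = tp.simulate_test(cfg, "GPIAS", 8.0, rng, truth=truth, week=8, restore=1.0)
    res = score_test(rec)
    assert res.passed
    assert res.percent_suppression == pytest.approx(50.0, abs=5)


def test_mean_suppression_monotone_in_tinnitus_effect():
    """Sweep: stronger tinnitus (smaller effect factor) means less suppression."""
    means = []
    truth = tp.AnimalTruth(tinnitus="8", onset_week=1)
    for effect in (0.0, 0.3, 0.6, 1.0):
        rng = np.random.default_rng(77)
        cfg = tp.SimConfig(tinnitus_effect=effect)
        vals = [
            score_test(
                tp.simulate_test(cfg, "GPIAS", 8.0, rng, truth=truth, week=4)
            ).percent_suppression
            for _ in range(40)
        ]
        means.append(np.mean(vals))
    assert means == sorted(means)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        tp.SimConfig(gap_suppression=1.5)
    with pytest.raises(ValueError):
        tp.SimConfig(n_trials=49)
    with pytest.raises(ValueError):
        tp.SimConfig(isi_range_s=(30.0, 15.0))
    with pytest.raises(ValueError):
        tp.CohortSpec(n_animals=0)
    with pytest.raises(ValueError):
        tp.CohortSpec(prevalence=1.2)


def test_cohort_structure(small_cohort):
    assert len(small_cohort.timelines) == 10
    for tl in small_cohort.timelines:
        phases = [s.phase for s in tl.sessions]
        # baseline sessions strictly precede post-trauma sessions
        first_post = phases.index("post_trauma") if "post_trauma" in phases else len(phases)
        assert all(p == "baseline" for p in phases[:first_post])
        weeks = [s.week for s in tl.sessions]
        assert weeks == sorted(weeks)
    treated = [tl for tl in small_cohort.timelines if tl.arm is not None]
    assert treated, "some animals should be confirmed and treated"
    for tl in treated:
        assert tl.sessions[-1].phase == "day15"
        assert len(tl.sessions[-1].recordings) == 2
    arms = {tl.arm for tl in treated}
    if len(treated) >= 2:
        assert arms == {"LI-rTMS", "sham"}


def test_cohort_tissue_tables(small_cohort):
    treated_ids = {tl.animal_id for tl in small_cohort.timelines if tl.arm}
    assert set(small_cohort.neurons["animal_id"].unique()) == treated_ids
    per_animal = small_cohort.neurons.groupby("animal_id").size()
    assert per_animal.between(77, 95).all()
    aud = small_cohort.audiograms
    loss = (
        aud.pivot_table(
            index=["animal_id", "ear", "frequency_khz"],
            columns="phase",
            values="threshold_db_spl",
        )
        .eval("post - pre")
        .reset_index(name="loss")
    )
    left_high = loss[(loss["ear"] == "left") & (loss["frequency_khz"] > 10)]
    left_low = loss[(loss["ear"] == "left") & (loss["frequency_khz"] <= 10)]
    assert left_high["loss"].mean() > 15
    assert abs(left_low["loss"].mean()) < 5
    bdnf = small_cohort.bdnf
    ic = bdnf[bdnf["region"] == "inferior_colliculus"]
    right = ic[ic["side"] == "right"]["concentration_pg_ml"].mean()
    left = ic[ic["side"] == "left"]["concentration_pg_ml"].mean()
    assert right > left


def test_hearing_loss_affects_high_frequency_tests(rng):
    cfg = tp.SimConfig(startle_amp_sigma=0.1)
    truth = tp.AnimalTruth(hearing_loss=True)
    rec14 = tp.simulate_test(cfg, "PPI", 14.0, rng, truth=truth, week=2)
    assert not score_test(rec14).passed
    rec8 = tp.simulate_test(cfg, "PPI", 8.0, rng, truth=truth, week=2)
    assert score_test(rec8).passed
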