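"""Synthetic behavioural sessions, cohorts, neuron populations, audiograms and BDNF samples.

The generator emulates the statistical structure of the guinea-pig tinnitus
study so that every downstream stage (scoring, longitudinal classification,
rank tests, mixed ANOVA) can be exercised without any recorded data:

* Startle trials: the baseline window is zero-mean Gaussian transducer noise;
  the startle window adds a half-sine force transient whose peak amplitude is
  lognormal (median ``startle_amp_median``) with geometric per-trial
  habituation. A gap (or prepulse) multiplies the amplitude by
  ``1 - suppression``.
* Tinnitus acts multiplicatively on gap suppression only (the "fill-in"
  model): at the tinnitus frequency, from the onset week, the effective gap
  suppression is ``gap_suppression * tinnitus_effect`` (0 = abolished).
  Treatment restores it toward baseline by the arm's efficacy.
* Hearing loss (simulated, optional) abolishes gap and prepulse detection at
  the 14 kHz background — the frequency region of the simulated threshold
  loss — producing the GPIAS-fail + PPI-fail confound.
* Each cohort animal is run through the study protocol: baseline GPIAS (two
  passing sessions required) and PPI (one pass), acoustic trauma, weekly
  GPIAS at both frequencies; a GPIAS failure triggers a same-week PPI test
  and, if PPI passes, a confirmation GPIAS; two GPIAS failures with a PPI
  pass in one week establish the deficit, after which treatment is assigned
  and a day-15 session is recorded.
* Neuron populations are lognormal spontaneous rates with the >=10 kHz
  stratum elevated by a hyperactivity factor; left-ear audiograms acquire a
  post-trauma threshold loss above 10 kHz; BDNF concentrations carry a
  right-vs-left inferior-colliculus offset.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import scoring
from .records import (
    ARM_RTMS,
    ARM_SHAM,
    CONDITIONS,
    FREQUENCIES,
    GAP,
    GPIAS,
    PHASE_BASELINE,
    PHASE_DAY15,
    PHASE_POST_TRAUMA,
    PPI,
    PREPULSE,
    TEST_CONDITIONS,
    AnimalTimeline,
    AnimalTruth,
    Session,
    TestRecording,
    TrialRecord,
)


@dataclass(frozen=True)
class SimConfig:
    """Signal-level parameters of one simulated test.

    Amplitudes are in arbitrary force-transducer units; what matters
    downstream is the ratio statistic, which is scale invariant.
    """

    startle_amp_median: float = 50.0
    startle_amp_sigma: float = 0.5
    baseline_noise_sd: float = 1.0
    habituation_decay: float = 0.99
    gap_suppression: float = 0.5
    prepulse_suppression: float = 0.5
    tinnitus_effect: float = 0.1
    hearing_loss_factor: float = 0.0
    n_trials: int = 50
    sample_rate: float = 1000.0
    baseline_window_ms: float = 200.0
    startle_window_ms: float = 200.0
    transient_ms: float = 100.0
    isi_range_s: tuple[float, float] = (15.0, 30.0)

    def __post_init__(self) -> None:
        for name in (
            "gap_suppression",
            "prepulse_suppression",
            "tinnitus_effect",
            "hearing_loss_factor",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.habituation_decay <= 1.0:
            raise ValueError("habituation_decay must be in (0, 1]")
        if self.n_trials <= 0 or self.n_trials % 2:
            raise ValueError("n_trials must be even and positive")
        if self.isi_range_s[0] > self.isi_range_s[1]:
            raise ValueError("isi_range_s must be (low, high) with low <= high")
        if self.startle_amp_median < 0 or self.startle_amp_sigma < 0:
            raise ValueError("amplitude parameters must be non-negative")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be non-negative")
        if min(self.sample_rate, self.baseline_window_ms, self.startle_window_ms) <= 0:
            raise ValueError("sample rate and window lengths must be positive")


def _n_samples(cfg: SimConfig) -> tuple[int, int, int]:
    n_base = int(round(cfg.sample_rate * cfg.baseline_window_ms / 1000.0))
    n_start = int(round(cfg.sample_rate * cfg.startle_window_ms / 1000.0))
    n_tr = min(int(round(cfg.sample_rate * cfg.transient_ms / 1000.0)), n_start)
    return max(n_base, 1), max(n_start, 1), max(n_tr, 1)


def _transient_shape(n: int) -> np.ndarray:
    # half sine, normalised so the peak sample equals the drawn amplitude
    s = np.sin(np.pi * np.arange(1, n + 1) / (n + 1))
    return s / s.max()


def _suppression_for(cfg: SimConfig, condition: str) -> float:
    if condition == GAP:
        return cfg.gap_suppression
    if condition == PREPULSE:
        return cfg.prepulse_suppression
    return 0.0


def simulate_trial(
    cfg: SimConfig, condition: str, trial_index: int, rng: np.random.Generator
) -> TrialRecord:
    """Simulate a single startle trial.

    The startle transient's peak amplitude is lognormal with median
    ``startle_amp_median * habituation_decay**(trial_index - 1)``, reduced by
    the condition's suppression fraction.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if trial_index < 1:
        raise ValueError("trial_index is 1-based")
    n_base, n_start, n_tr = _n_samples(cfg)
    amp = (
        cfg.startle_amp_median
        * cfg.habituation_decay ** (trial_index - 1)
        * math.exp(cfg.startle_amp_sigma * rng.standard_normal())
    )
    amp *= 1.0 - _suppression_for(cfg, condition)
    baseline = rng.normal(0.0, cfg.baseline_noise_sd, n_base)
    startle = rng.normal(0.0, cfg.baseline_noise_sd, n_start)
    startle[:n_tr] += amp * _transient_shape(n_tr)
    return TrialRecord(condition, baseline, startle, trial_index)


def _effective_config(
    cfg: SimConfig,
    test_type: str,
    frequency_khz: float,
    truth: AnimalTruth | None,
    week: int | None,
    restore: float,
) -> SimConfig:
    gap_s = cfg.gap_suppression
    pre_s = cfg.prepulse_suppression
    if truth is not None:
        tinnitus_on = truth.affects(frequency_khz) and (
            week is None or truth.onset_week is None or week >= truth.onset_week
        )
        if tinnitus_on:
            factor = cfg.tinnitus_effect + restore * (1.0 - cfg.tinnitus_effect)
            gap_s *= factor
        # hearing loss is trauma-induced: only post-trauma weeks, 14 kHz region
        if truth.hearing_loss and frequency_khz > 10.0 and (week is None or week >= 1):
            gap_s *= cfg.hearing_loss_factor
            pre_s *= cfg.hearing_loss_factor
    return replace(cfg, gap_suppression=gap_s, prepulse_suppression=pre_s)


def simulate_test(
    cfg: SimConfig,
    test_type: str,
    background_frequency: float,
    rng: np.random.Generator,
    *,
    truth: AnimalTruth | None = None,
    week: int | None = None,
    restore: float = 0.0,
) -> TestRecording:
    """Simulate one 50-trial test: half of the trials per condition in random order.

    ``restore`` is the treatment efficacy in [0, 1]: the fraction by which
    abolished gap suppression is restored toward baseline (relevant for
    day-15 sessions of treated animals).
    """
    if test_type not in TEST_CONDITIONS:
        raise ValueError(f"unknown test type {test_type!r}")
    eff = _effective_config(cfg, test_type, background_frequency, truth, week, restore)
    inh, uninh = TEST_CONDITIONS[test_type]
    n = eff.n_trials
    half = n // 2
    inh_mask = rng.permutation(n) < half  # exactly half the trials per condition

    n_base, n_start, n_tr = _n_samples(eff)
    shape = _transient_shape(n_tr)
    amps = (
        eff.startle_amp_median
        * eff.habituation_decay ** np.arange(n)
        * np.exp(eff.startle_amp_sigma * rng.standard_normal(n))
    )
    amps = np.where(inh_mask, amps * (1.0 - _suppression_for(eff, inh)), amps)
    baselines = rng.normal(0.0, eff.baseline_noise_sd, (n, n_base))
    startles = rng.normal(0.0, eff.baseline_noise_sd, (n, n_start))
    startles[:, :n_tr] += amps[:, None] * shape
    isis = rng.uniform(eff.isi_range_s[0], eff.isi_range_s[1], n)

    trials = [
        TrialRecord(
            inh if inh_mask[i] else uninh, baselines[i], startles[i], i + 1
        )
        for i in range(n)
    ]
    return TestRecording(test_type, float(background_frequency), trials, isis)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level structure: prevalence, onsets, treatment, neural and tissue effects.

    Defaults mirror the study conditions: 18 animals entering the protocol,
    two-thirds developing the deficit between weeks 2 and 9 (mean ~5.2), a
    5:5:2 split of deficits at 8 kHz, 14 kHz and both, a 12-week observation
    window, and treatment that fully restores gap suppression in the LI-rTMS
    arm but not in the sham arm.
    """

    n_animals: int = 18
    prevalence: float = 2.0 / 3.0
    freq_probs: tuple[float, float, float] = (5 / 12, 5 / 12, 2 / 12)  # 8, 14, both
    onset_mean_weeks: float = 5.2
    onset_sd_weeks: float = 1.7
    onset_range_weeks: tuple[int, int] = (2, 9)
    max_weeks: int = 12
    treatment_efficacy: float = 1.0
    hearing_loss_prob: float = 0.0
    n_baseline_gpias_sessions: int = 2
    alpha: float = scoring.DEFAULT_ALPHA
    n_exclude: int = scoring.DEFAULT_N_EXCLUDE
    # neuron populations
    neurons_per_animal: tuple[int, int] = (77, 95)
    rate_median_hz: float = 5.0
    rate_sigma: float = 0.8
    hyperactivity_factor: float = 2.0
    treatment_rate_factor: float = 0.9
    cf_cutoff_khz: float = 10.0
    tonotopy_f_min_khz: float = 1.0
    tonotopy_octaves_per_mm: float = 1.0
    tonotopy_depth_range_um: tuple[float, float] = (0.0, 5000.0)
    # audiograms
    audiogram_freqs_khz: tuple[float, ...] = (4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 20.0, 24.0)
    base_threshold_db: float = 35.0
    threshold_noise_sd_db: float = 3.0
    trauma_loss_db: float = 25.0
    trauma_loss_sd_db: float = 5.0
    # BDNF
    bdnf_ic_pg_ml: float = 500.0
    bdnf_right_ic_offset_pg_ml: float = 150.0
    bdnf_ac_pg_ml: float = 600.0
    bdnf_noise_sd_pg_ml: float = 75.0
    bdnf_total_protein_ug_ml: float = 100.0
    bdnf_total_protein_sd: float = 10.0
    bdnf_dilution_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        for name in ("prevalence", "treatment_efficacy", "hearing_loss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.freq_probs) - 1.0) > 1e-9:
            raise ValueError("freq_probs must sum to 1")
        if self.max_weeks < 1:
            raise ValueError("max_weeks must be >= 1")


@dataclass
class Cohort:
    """Output bundle of ``simulate_cohort``."""

    timelines: list[AnimalTimeline]
    neurons: pd.DataFrame
    audiograms: pd.DataFrame
    bdnf: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "animal_id": tl.animal_id,
                "arm": tl.arm,
                "true_tinnitus": tl.truth.tinnitus,
                "true_onset_week": tl.truth.onset_week,
                "hearing_loss": tl.truth.hearing_loss,
            }
            for tl in self.timelines
        ]
        return pd.DataFrame(rows)


def _draw_truth(spec: CohortSpec, rng: np.random.Generator) -> AnimalTruth:
    if rng.random() < spec.prevalence:
        label = ("8", "14", "both")[rng.choice(3, p=np.asarray(spec.freq_probs))]
        lo, hi = spec.onset_range_weeks
        onset = int(np.clip(round(rng.normal(spec.onset_mean_weeks, spec.onset_sd_weeks)), lo, hi))
    else:
        label, onset = "none", None
    return AnimalTruth(
        tinnitus=label,
        onset_week=onset,
        hearing_loss=bool(rng.random() < spec.hearing_loss_prob),
    )


def _passes(cfg: SimConfig, spec: CohortSpec, rec: TestRecording) -> bool:
    return scoring.score_test(rec, alpha=spec.alpha, n_exclude=spec.n_exclude).passed


def _simulate_behaviour(
    cfg: SimConfig,
    spec: CohortSpec,
    animal_id: str,
    truth: AnimalTruth,
    rng: np.random.Generator,
) -> tuple[AnimalTimeline, int | None]:
    """Baseline and weekly post-trauma protocol for one animal.

    Returns the timeline (without day-15 session) and the week in which the
    deficit was established, if any.
    """
    tl = AnimalTimeline(animal_id=animal_id, truth=truth)
    sid = 0

    def new_session(phase: str, week: int) -> Session:
        nonlocal sid
        sid += 1
        s = Session(session_id=f"S{sid:03d}", phase=phase, week=week)
        tl.sessions.append(s)
        return s

    # baseline: repeat GPIAS sessions until two with both frequencies passed
    passed_sessions = 0
    for _ in range(3 * spec.n_baseline_gpias_sessions):
        s = new_session(PHASE_BASELINE, 0)
        ok = True
        for f in FREQUENCIES:
            rec = simulate_test(cfg, GPIAS, f, rng, truth=truth, week=0)
            s.recordings.append(rec)
            ok &= _passes(cfg, spec, rec)
        passed_sessions += ok
        if passed_sessions >= spec.n_baseline_gpias_sessions:
            break
    # baseline PPI: one passing session required
    for _ in range(3):
        s = new_session(PHASE_BASELINE, 0)
        ok = True
        for f in FREQUENCIES:
            rec = simulate_test(cfg, PPI, f, rng, truth=truth, week=0)
            s.recordings.append(rec)
            ok &= _passes(cfg, spec, rec)
        if ok:
            break

    # weekly post-trauma testing with the adaptive confirmation protocol
    for week in range(1, spec.max_weeks + 1):
        order = FREQUENCIES if week % 2 else FREQUENCIES[::-1]
        s = new_session(PHASE_POST_TRAUMA, week)
        failed: list[float] = []
        for f in order:
            rec = simulate_test(cfg, GPIAS, f, rng, truth=truth, week=week)
            s.recordings.append(rec)
            if not _passes(cfg, spec, rec):
                failed.append(f)
        if not failed:
            continue
        ppi_session = new_session(PHASE_POST_TRAUMA, week)
        heard: list[float] = []
        for f in failed:
            rec = simulate_test(cfg, PPI, f, rng, truth=truth, week=week)
            ppi_session.recordings.append(rec)
            if _passes(cfg, spec, rec):
                heard.append(f)
        if not heard:
            continue
        confirm_session = new_session(PHASE_POST_TRAUMA, week)
        confirmed: list[float] = []
        for f in heard:
            rec = simulate_test(cfg, GPIAS, f, rng, truth=truth, week=week)
            confirm_session.recordings.append(rec)
            if not _passes(cfg, spec, rec):
                confirmed.append(f)
        if confirmed:
            return tl, week
    return tl, None


def _simulate_neurons(
    spec: CohortSpec, arm: str, rng: np.random.Generator
) -> pd.DataFrame:
    from .neural import TonotopicMap, depth_to_nominal_cf

    tmap = TonotopicMap(
        f_min_khz=spec.tonotopy_f_min_khz,
        octaves_per_mm=spec.tonotopy_octaves_per_mm,
        depth_range_um=spec.tonotopy_depth_range_um,
    )
    n = int(rng.integers(spec.neurons_per_animal[0], spec.neurons_per_animal[1] + 1))
    depths = rng.uniform(*spec.tonotopy_depth_range_um, n)
    cfs = depth_to_nominal_cf(depths, tmap)
    medians = np.where(
        cfs >= spec.cf_cutoff_khz,
        spec.rate_median_hz * spec.hyperactivity_factor,
        spec.rate_median_hz,
    )
    if arm == ARM_RTMS:
        medians = medians * spec.treatment_rate_factor
    rates = medians * np.exp(spec.rate_sigma * rng.standard_normal(n))
    return pd.DataFrame(
        {
            "depth_um": depths,
            "nominal_cf_khz": cfs,
            "spont_rate_hz": rates,
        }
    )


def _simulate_audiograms(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    freqs = np.asarray(spec.audiogram_freqs_khz, dtype=float)
    rows = []
    for ear in ("left", "right"):
        pre = spec.base_threshold_db + rng.normal(0, spec.threshold_noise_sd_db, freqs.size)
        shift = np.zeros(freqs.size)
        if ear == "left":
            loss = np.clip(rng.normal(spec.trauma_loss_db, spec.trauma_loss_sd_db), 0, None)
            shift = np.where(freqs > 10.0, loss, 0.0)
        post = pre + shift + rng.normal(0, spec.threshold_noise_sd_db, freqs.size)
        for phase, th in (("pre", pre), ("post", post)):
            for f, t in zip(freqs, th):
                rows.append(
                    {
                        "ear": ear,
                        "frequency_khz": float(f),
                        "threshold_db_spl": float(t),
                        "phase": phase,
                    }
                )
    return pd.DataFrame(rows)


def _simulate_bdnf(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for region, base in (
        ("inferior_colliculus", spec.bdnf_ic_pg_ml),
        ("auditory_cortex", spec.bdnf_ac_pg_ml),
    ):
        for side in ("left", "right"):
            mean = base
            if region == "inferior_colliculus" and side == "right":
                mean += spec.bdnf_right_ic_offset_pg_ml
            conc = max(0.0, rng.normal(mean, spec.bdnf_noise_sd_pg_ml))
            tp = max(1.0, rng.normal(spec.bdnf_total_protein_ug_ml, spec.bdnf_total_protein_sd))
            rows.append(
                {
                    "region": region,
                    "side": side,
                    "concentration_pg_ml": conc,
                    "total_protein_ug_ml": tp,
                    "dilution_factor": spec.bdnf_dilution_factor,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    cfg: SimConfig, spec: CohortSpec, rng: np.random.Generator
) -> Cohort:
    """Simulate a full cohort through the study protocol.

    Animals confirmed with the deficit are alternately assigned to the
    LI-rTMS and sham arms (in order of confirmation week) and receive a
    day-15 session; only those animals contribute neuron populations,
    post-trauma audiograms and BDNF samples, mirroring the study flow in
    which animals without behavioural evidence of tinnitus did not proceed.
    """
    streams = rng.spawn(spec.n_animals + 1)
    tissue_rng = streams[-1]

    timelines: list[AnimalTimeline] = []
    confirm_weeks: dict[str, int] = {}
    day15_rngs: dict[str, np.random.Generator] = {}
    for i in range(spec.n_animals):
        animal_id = f"A{i + 1:03d}"
        a_rng, d_rng = streams[i].spawn(2)
        truth = _draw_truth(spec, a_rng)
        tl, confirmed_week = _simulate_behaviour(cfg, spec, animal_id, truth, a_rng)
        timelines.append(tl)
        if confirmed_week is not None:
            confirm_weeks[animal_id] = confirmed_week
            day15_rngs[animal_id] = d_rng

    # alternating arm assignment in order of confirmation
    confirmed = sorted(confirm_weeks, key=lambda a: (confirm_weeks[a], a))
    arms = {a: (ARM_RTMS if i % 2 == 0 else ARM_SHAM) for i, a in enumerate(confirmed)}

    neurons, audiograms, bdnf = [], [], []
    for tl in timelines:
        if tl.animal_id not in arms:
            continue
        tl.arm = arms[tl.animal_id]
        week = confirm_weeks[tl.animal_id]
        restore = spec.treatment_efficacy if tl.arm == ARM_RTMS else 0.0
        d_rng = day15_rngs[tl.animal_id]
        s = Session(
            session_id=f"S{len(tl.sessions) + 1:03d}",
            phase=PHASE_DAY15,
            week=week + 3,
        )
        for f in FREQUENCIES:
            s.recordings.append(
                simulate_test(
                    cfg, GPIAS, f, d_rng, truth=tl.truth, week=week + 3, restore=restore
                )
            )
        tl.sessions.append(s)

        nf = _simulate_neurons(spec, tl.arm, tissue_rng)
        nf.insert(0, "animal_id", tl.animal_id)
        nf.insert(1, "arm", tl.arm)
        neurons.append(nf)
        af = _simulate_audiograms(spec, tissue_rng)
        af.insert(0, "animal_id", tl.animal_id)
        af.insert(1, "arm", tl.arm)
        audiograms.append(af)
        bf = _simulate_bdnf(spec, tissue_rng)
        bf.insert(0, "animal_id", tl.animal_id)
        bf.insert(1, "arm", tl.arm)
        bdnf.append(bf)

    empty_n = pd.DataFrame(
        columns=["animal_id", "arm", "depth_um", "nominal_cf_khz", "spont_rate_hz"]
    )
    empty_a = pd.DataFrame(
        columns=["animal_id", "arm", "ear", "frequency_khz", "threshold_db_spl", "phase"]
    )
    empty_b = pd.DataFrame(
        columns=[
            "animal_id",
            "arm",
            "region",
            "side",
            "concentration_pg_ml",
            "total_protein_ug_ml",
            "dilution_factor",
        ]
    )
    return Cohort(
        timelines=timelines,
        neurons=pd.concat(neurons, ignore_index=True) if neurons else empty_n,
        audiograms=pd.concat(audiograms, ignore_index=True) if audiograms else empty_a,
        bdnf=pd.concat(bdnf, ignore_index=True) if bdnf else empty_b,
    )
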