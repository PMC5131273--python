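"""Startle-reflex scoring for GPIAS and PPI tests.

A test is 50 trials at one background (or prepulse) frequency, half with the
inhibitory pre-stimulus (a silent gap in the background noise, or a weak
prepulse) and half without. The trial statistic is the ratio between the RMS
of the force produced during the startle-response window and the RMS of the
pre-stimulus baseline window. A test "passes" when the ratio distributions
of the two conditions differ significantly (t-test, p < alpha) in the
inhibitory direction — i.e. the animal demonstrably detected the gap or
prepulse. The mean startle suppression is additionally expressed as a
percentage of the uninhibited response.

The first trials of every test are excluded before scoring to avoid
habituation bias (default: the first 4 of 50, by overall trial order).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special as sc

from .records import TEST_CONDITIONS, TestRecording, TrialRecord

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_N_EXCLUDE = 4


class FlaggedTrialError(ValueError):
    """A trial whose baseline window has zero RMS; its ratio is undefined."""


def compute_rms(window) -> float:
    """Root mean square of a force-sample window.

    Raises ValueError on an empty window.
    """
    w = np.asarray(window, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("cannot compute RMS of an empty window")
    return float(np.sqrt(np.dot(w, w) / w.size))


def compute_startle_ratio(trial: TrialRecord) -> float:
    """Per-trial startle ratio: RMS(startle window) / RMS(baseline window).

    A zero-RMS baseline makes the ratio undefined; such trials are flagged
    (FlaggedTrialError) so callers drop them explicitly instead of
    propagating an infinity.
    """
    rms_baseline = compute_rms(trial.baseline_window)
    if rms_baseline == 0.0:
        raise FlaggedTrialError(
            f"trial {trial.trial_index}: zero baseline RMS, ratio undefined"
        )
    return compute_rms(trial.startle_window) / rms_baseline


@dataclass
class RatioSet:
    """Per-trial startle ratios of one condition within a test."""

    condition: str
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.size and np.any(self.ratios < 0):
            raise ValueError("startle ratios are non-negative by construction")


@dataclass
class TestResult:
    """Outcome of one GPIAS or PPI test."""

    test_type: str
    background_frequency: float
    ratio_sets: dict[str, RatioSet]
    n_used: int
    t_statistic: float
    p_value: float
    passed: bool
    percent_suppression: float


def _t_test(a: np.ndarray, b: np.ndarray, variant: str) -> tuple[float, float]:
    """Two-sample t from the definitional formulas; two-tailed p.

    variant "student": pooled (equal-variance) t on n1+n2-2 df;
    variant "welch": Welch t with Satterthwaite df.
    """
    n1, n2 = a.size, b.size
    m1, m2 = a.mean(), b.mean()
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1)
    # Zero variance everywhere would give 0/0 in the t formula; identical-mean
    # degenerate samples are reported as no evidence of a difference.
    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            return 0.0, 1.0
        return float("inf") if m1 > m2 else float("-inf"), 0.0
    if variant == "student":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    else:  # welch
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = (m1 - m2) / se
    p = 2.0 * float(sc.stdtr(df, -abs(t)))
    return float(t), p


def score_ratios(
    inhibited: np.ndarray,
    uninhibited: np.ndarray,
    *,
    alpha: float = DEFAULT_ALPHA,
    t_variant: str = "student",
    suppression_formula: str = "ratio_of_means",
) -> tuple[float, float, bool, float]:
    """Compare the two conditions' ratio sets.

    Returns (t, two-tailed p, passed, percent suppression). `passed` requires
    both p < alpha and suppression in the inhibitory direction (mean of the
    inhibited condition below the uninhibited mean), so that paradoxical
    startle facilitation never counts as gap/prepulse detection.

    suppression_formula:
      - "ratio_of_means" (default): 100 * (1 - mean(inh) / mean(uninh))
      - "mean_of_ratios": trials paired by within-condition order,
        100 * mean(1 - inh_k / uninh_k)
    """
    if t_variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {t_variant!r}")
    inhibited = np.asarray(inhibited, dtype=float)
    uninhibited = np.asarray(uninhibited, dtype=float)
    if inhibited.size < 2 or uninhibited.size < 2:
        raise ValueError("need at least 2 trials per condition after exclusion")

    t, p = _t_test(inhibited, uninhibited, t_variant)
    mean_inh = float(np.mean(inhibited))
    mean_uninh = float(np.mean(uninhibited))

    if suppression_formula == "ratio_of_means":
        if mean_uninh <= 0:
            pct = float("nan")
        else:
            pct = 100.0 * (1.0 - mean_inh / mean_uninh)
    elif suppression_formula == "mean_of_ratios":
        k = min(inhibited.size, uninhibited.size)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = float(100.0 * np.mean(1.0 - inhibited[:k] / uninhibited[:k]))
    else:
        raise ValueError(f"unknown suppression formula {suppression_formula!r}")

    passed = bool(p < alpha and mean_inh < mean_uninh)
    return t, p, passed, pct


def score_test(
    rec: TestRecording,
    *,
    alpha: float = DEFAULT_ALPHA,
    n_exclude: int = DEFAULT_N_EXCLUDE,
    t_variant: str = "student",
    suppression_formula: str = "ratio_of_means",
) -> TestResult:
    """Score one test recording: exclusion, per-trial ratios, t-test, suppression.

    The first `n_exclude` trials of the test (by trial_index over the whole
    test, regardless of condition) are excluded. Trials with a zero-RMS
    baseline are dropped with a logged warning. Each condition must retain
    at least 2 trials.
    """
    inh_label, uninh_label = TEST_CONDITIONS[rec.test_type]
    ratios: dict[str, list[float]] = {inh_label: [], uninh_label: []}
    n_used = 0
    for trial in rec.trials:
        if trial.trial_index <= n_exclude:
            continue
        try:
            r = compute_startle_ratio(trial)
        except FlaggedTrialError as err:
            log.warning("dropping flagged trial: %s", err)
            continue
        ratios[trial.condition].append(r)
        n_used += 1

    inh = np.asarray(ratios[inh_label], dtype=float)
    uninh = np.asarray(ratios[uninh_label], dtype=float)
    t, p, passed, pct = score_ratios(
        inh,
        uninh,
        alpha=alpha,
        t_variant=t_variant,
        suppression_formula=suppression_formula,
    )
    return TestResult(
        test_type=rec.test_type,
        background_frequency=rec.background_frequency,
        ratio_sets={
            inh_label: RatioSet(inh_label, inh),
            uninh_label: RatioSet(uninh_label, uninh),
        },
        n_used=n_used,
        t_statistic=t,
        p_value=p,
        passed=passed,
        percent_suppression=pct,
    )
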