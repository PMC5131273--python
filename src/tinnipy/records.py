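"""Shared record types: trials, test recordings, timelines, neurons, audiograms, tissue samples."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GPIAS = "GPIAS"
PPI = "PPI"
TEST_TYPES = (GPIAS, PPI)

GAP = "gap"
NO_GAP = "no_gap"
PREPULSE = "prepulse"
NO_PREPULSE = "no_prepulse"
CONDITIONS = frozenset({GAP, NO_GAP, PREPULSE, NO_PREPULSE})

#: (inhibited, uninhibited) condition labels per test type
TEST_CONDITIONS = {GPIAS: (GAP, NO_GAP), PPI: (PREPULSE, NO_PREPULSE)}

#: narrowband background / prepulse centre frequencies, kHz
FREQUENCIES = (8.0, 14.0)

PHASE_BASELINE = "baseline"
PHASE_POST_TRAUMA = "post_trauma"
PHASE_DAY15 = "day15"

ARM_RTMS = "LI-rTMS"
ARM_SHAM = "sham"


@dataclass
class TrialRecord:
    """One startle trial: a pre-stimulus baseline window and a startle-response window.

    Both windows are force-transducer sample vectors on a common sample rate;
    the trial statistic downstream is RMS(startle) / RMS(baseline).
    """

    condition: str
    baseline_window: np.ndarray
    startle_window: np.ndarray
    trial_index: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        self.baseline_window = np.asarray(self.baseline_window, dtype=float)
        self.startle_window = np.asarray(self.startle_window, dtype=float)
        if self.baseline_window.size == 0 or self.startle_window.size == 0:
            raise ValueError("trial windows must be non-empty")
        if self.trial_index < 1:
            raise ValueError("trial_index is 1-based")


@dataclass
class TestRecording:
    """One GPIAS or PPI test: an ordered sequence of trials at one background frequency."""

    test_type: str
    background_frequency: float
    trials: list[TrialRecord]
    isis_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.test_type not in TEST_CONDITIONS:
            raise ValueError(f"unknown test type {self.test_type!r}")
        allowed = set(TEST_CONDITIONS[self.test_type])
        for t in self.trials:
            if t.condition not in allowed:
                raise ValueError(
                    f"condition {t.condition!r} inconsistent with test type {self.test_type}"
                )


@dataclass(frozen=True)
class AnimalTruth:
    """Simulator ground truth for one animal.

    tinnitus: "none", "8", "14" or "both" (background frequency at which the
    gap-detection deficit is expressed); onset_week: first post-trauma week
    the deficit is present; hearing_loss: peripheral loss severe enough to
    abolish gap and prepulse detection at the 14 kHz background.
    """

    tinnitus: str = "none"
    onset_week: int | None = None
    hearing_loss: bool = False

    def __post_init__(self) -> None:
        if self.tinnitus not in ("none", "8", "14", "both"):
            raise ValueError(f"bad tinnitus label {self.tinnitus!r}")
        if self.tinnitus != "none" and self.onset_week is None:
            raise ValueError("tinnitus-positive truth needs an onset week")

    def affects(self, frequency_khz: float) -> bool:
        if self.tinnitus == "none":
            return False
        if self.tinnitus == "both":
            return True
        return float(self.tinnitus) == float(frequency_khz)


@dataclass
class Session:
    """One testing visit: a phase label, a week stamp and its test recordings."""

    session_id: str
    phase: str
    week: int
    recordings: list[TestRecording] = field(default_factory=list)


@dataclass
class AnimalTimeline:
    """Ordered sessions of one animal across baseline, post-trauma and day-15 phases."""

    animal_id: str
    truth: AnimalTruth
    arm: str | None = None
    sessions: list[Session] = field(default_factory=list)


@dataclass(frozen=True)
class NeuronRecord:
    """One CNIC unit: electrode depth, nominal CF from the tonotopic map, spontaneous rate."""

    depth_um: float
    nominal_cf_khz: float
    spont_rate_hz: float

    def __post_init__(self) -> None:
        if self.depth_um < 0:
            raise ValueError("depth must be >= 0")
        if self.spont_rate_hz < 0:
            raise ValueError("spontaneous rate must be >= 0")


@dataclass(frozen=True)
class CapAudiogram:
    """CAP audiogram of one ear: thresholds (dB SPL) on a strictly increasing kHz grid."""

    ear: str
    frequencies_khz: tuple[float, ...]
    thresholds_db_spl: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.ear not in ("left", "right"):
            raise ValueError("ear must be 'left' or 'right'")
        if len(self.frequencies_khz) != len(self.thresholds_db_spl):
            raise ValueError("frequency and threshold lists differ in length")
        f = np.asarray(self.frequencies_khz, dtype=float)
        if f.size and np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass(frozen=True)
class BdnfSample:
    """One tissue sample: ELISA concentration plus the diluted-aliquot total protein."""

    region: str
    side: str
    concentration_pg_ml: float
    total_protein_ug_ml: float
    dilution_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.region not in ("auditory_cortex", "inferior_colliculus"):
            raise ValueError(f"bad region {self.region!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"bad side {self.side!r}")
        if self.concentration_pg_ml < 0:
            raise ValueError("concentration must be >= 0")
        if self.total_protein_ug_ml <= 0:
            raise ValueError("total protein must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")
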