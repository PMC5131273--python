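"""Longitudinal tinnitus classification from scored GPIAS/PPI tests.

The decision rules operate on a per-animal table of scored tests (one row
per test) carrying ``phase``, ``week``, ``session_id``, ``test_type``,
``frequency_khz``, ``passed`` and ``percent_suppression``:

* Baseline eligibility: at least two baseline sessions in which the GPIAS
  tests at both background frequencies passed, plus at least one passed
  baseline PPI test, are required before trauma.
* Tinnitus call: the first post-trauma week containing, at some frequency f,
  a failed GPIAS, a passed PPI, and a second failed GPIAS at f establishes
  the deficit; the animal is called tinnitus-positive with that onset week
  and frequency ("both" when both frequencies qualify in the same week).
* If a GPIAS failure coincides with a PPI failure (hearing-loss confound)
  and no later week qualifies, the animal is `undetermined`; with no
  qualifying week and no confound within the observation window it is
  `no_tinnitus`.

Within a week, tests are ordered by session id; the first GPIAS at a
frequency is the initial test, subsequent ones the confirmation retest (the
"two days later" retest of the protocol — calendar days are not modelled).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import GPIAS, PHASE_BASELINE, PHASE_DAY15, PHASE_POST_TRAUMA, PPI

STATUS_TINNITUS = "tinnitus"
STATUS_NO_TINNITUS = "no_tinnitus"
STATUS_UNDETERMINED = "undetermined"

RESULT_COLUMNS = [
    "phase",
    "week",
    "session_id",
    "test_type",
    "frequency_khz",
    "passed",
    "percent_suppression",
]


@dataclass(frozen=True)
class TinnitusCall:
    animal_id: str
    status: str
    onset_week: int | None = None
    tinnitus_frequency: str | None = None  # "8", "14" or "both"

    def __post_init__(self) -> None:
        if self.status == STATUS_TINNITUS and (
            self.onset_week is None or self.tinnitus_frequency is None
        ):
            raise ValueError("tinnitus call requires onset week and frequency")


@dataclass(frozen=True)
class PhaseOutcome:
    """Percent suppression of one animal in one phase (BT, AT or D15)."""

    animal_id: str
    phase: str  # BT | AT | D15
    tinnitus_freq_suppression: float
    other_freq_suppression: float | None = None


def _check_columns(results: pd.DataFrame) -> None:
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")


def check_baseline_eligibility(results: pd.DataFrame) -> bool:
    """True iff the baseline rows satisfy the pre-trauma entry rule."""
    _check_columns(results)
    base = results[results["phase"] == PHASE_BASELINE]
    gpias = base[base["test_type"] == GPIAS]
    n_passed_sessions = 0
    for _, session in gpias.groupby("session_id"):
        if len(session) and session["passed"].all():
            n_passed_sessions += 1
    ppi_passed = bool(base[(base["test_type"] == PPI)]["passed"].any())
    return n_passed_sessions >= 2 and ppi_passed


def _validate_weeks(post: pd.DataFrame) -> None:
    by_session = post.groupby("session_id")["week"].agg(["min", "max"])
    if (by_session["min"] != by_session["max"]).any():
        raise ValueError("a session spans multiple week stamps")
    ordered = by_session.sort_index()["min"].to_numpy()
    if np.any(np.diff(ordered) < 0):
        raise ValueError("week stamps decrease with session order")
    dup = post.duplicated(subset=["session_id", "test_type", "frequency_khz"])
    if dup.any():
        rows = post.index[dup].tolist()
        raise ValueError(f"duplicate test rows within a session at rows {rows}")


def assign_tinnitus_frequency(confirmed_frequencies) -> str:
    """Map the set of confirmed failing frequencies to "8", "14" or "both"."""
    freqs = sorted({float(f) for f in confirmed_frequencies})
    if not freqs:
        raise ValueError("no confirmed failing frequency")
    if len(freqs) > 1:
        return "both"
    return str(int(freqs[0]))


def classify_timeline(
    results: pd.DataFrame, animal_id: str = "", max_weeks: int = 12
) -> TinnitusCall:
    """Apply the weekly decision rule to one animal's scored post-trauma tests."""
    _check_columns(results)
    post = results[results["phase"] == PHASE_POST_TRAUMA]
    _validate_weeks(post)
    confound_seen = False
    for week in sorted(post["week"].unique()):
        if week > max_weeks:
            break
        wk = post[post["week"] == week].sort_values("session_id", kind="stable")
        gpias = wk[wk["test_type"] == GPIAS]
        ppi = wk[wk["test_type"] == PPI]
        confirmed: list[float] = []
        for f, tests in gpias.groupby("frequency_khz"):
            seq = tests["passed"].to_numpy()
            if seq[0]:
                continue  # initial GPIAS passed at this frequency
            ppi_f = ppi[ppi["frequency_khz"] == f]
            if len(ppi_f) == 0:
                continue  # failure never followed up; cannot qualify
            if not ppi_f["passed"].any():
                confound_seen = True
                continue
            if len(seq) >= 2 and not seq[1]:
                confirmed.append(float(f))
        if confirmed:
            return TinnitusCall(
                animal_id=animal_id,
                status=STATUS_TINNITUS,
                onset_week=int(week),
                tinnitus_frequency=assign_tinnitus_frequency(confirmed),
            )
    status = STATUS_UNDETERMINED if confound_seen else STATUS_NO_TINNITUS
    return TinnitusCall(animal_id=animal_id, status=status)


def _mean_suppression(df: pd.DataFrame, freqs: list[float]) -> float:
    sel = df[df["frequency_khz"].isin(freqs)]
    if len(sel) == 0:
        raise ValueError("no GPIAS tests at the requested frequencies")
    return float(sel["percent_suppression"].mean())


def treatment_outcome(results: pd.DataFrame, call: TinnitusCall) -> list[PhaseOutcome]:
    """Per-phase percent suppression (BT, AT, D15) for a tinnitus-positive animal.

    BT is the mean over the qualifying (fully passed) baseline GPIAS
    sessions; AT is the mean over the onset week's GPIAS tests at the
    tinnitus frequency (initial and confirmation); D15 comes from the day-15
    session. For animals with the deficit at both frequencies the mean over
    both frequencies is reported and no non-tinnitus-frequency value exists.
    """
    if call.status != STATUS_TINNITUS:
        raise ValueError("phase outcomes are defined only for tinnitus-positive calls")
    _check_columns(results)
    gpias = results[results["test_type"] == GPIAS]
    if call.tinnitus_frequency == "both":
        tin_freqs, other_freqs = [8.0, 14.0], None
    else:
        f = float(call.tinnitus_frequency)
        tin_freqs = [f]
        other_freqs = [14.0 if f == 8.0 else 8.0]

    base = gpias[gpias["phase"] == PHASE_BASELINE]
    qualifying = [
        s for _, s in base.groupby("session_id") if len(s) and s["passed"].all()
    ]
    if not qualifying:
        raise ValueError("no qualifying baseline GPIAS sessions")
    base_q = pd.concat(qualifying)

    onset = gpias[(gpias["phase"] == PHASE_POST_TRAUMA) & (gpias["week"] == call.onset_week)]
    day15 = gpias[gpias["phase"] == PHASE_DAY15]
    if len(day15) == 0:
        raise ValueError("missing day-15 session")

    out = []
    for phase, df in (("BT", base_q), ("AT", onset), ("D15", day15)):
        out.append(
            PhaseOutcome(
                animal_id=call.animal_id,
                phase=phase,
                tinnitus_freq_suppression=_mean_suppression(df, tin_freqs),
                other_freq_suppression=(
                    None if other_freqs is None else _mean_suppression(df, other_freqs)
                ),
            )
        )
    return out
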