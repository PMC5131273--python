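"""Longitudinal tinnitus decision rules."""
import pandas as pd
import pytest

from tinnipy.phenotype import (
    STATUS_NO_TINNITUS,
    STATUS_TINNITUS,
    STATUS_UNDETERMINED,
    TinnitusCall,
    assign_tinnitus_frequency,
    check_baseline_eligibility,
    classify_timeline,
    treatment_outcome,
)


def _baseline_rows(builder, gpias_sessions=2, gpias_pass=True, ppi_pass=True):
    rows = []
    sid = 0
    for _ in range(gpias_sessions):
        sid += 1
        for f in (8.0, 14.0):
            rows.append(
                dict(
                    phase="baseline",
                    week=0,
                    session_id=f"S{sid:03d}",
                    frequency_khz=f,
                    passed=gpias_pass,
                    percent_suppression=50.0,
                )
            )
    sid += 1
    for f in (8.0, 14.0):
        rows.append(
            dict(
                phase="baseline",
                week=0,
                session_id=f"S{sid:03d}",
                test_type="PPI",
                frequency_khz=f,
                passed=ppi_pass,
                percent_suppression=40.0,
            )
        )
    return builder(rows)


@pytest.mark.parametrize(
    "gpias_sessions,gpias_pass,ppi_pass,eligible",
    [
        (2, True, True, True),
        (1, True, True, False),
        (2, False, True, False),
        (2, True, False, False),
    ],
)
def test_baseline_eligibility_rule(
    result_table_builder, gpias_sessions, gpias_pass, ppi_pass, eligible
):
    df = _baseline_rows(
        result_table_builder,
        gpias_sessions=gpias_sessions,
        gpias_pass=gpias_pass,
        ppi_pass=ppi_pass,
    )
    assert check_baseline_eligibility(df) is eligible


def _week(builder_rows, week, sid0, freq_passed, ppi=None, confirm=None):
    """One post-trauma week: initial GPIAS at both freqs, then optional PPI and
    confirmation sessions."""
    rows = []
    sid = sid0
    for f, p in freq_passed.items():
        rows.append(dict(week=week, session_id=f"S{sid:03d}", frequency_khz=f, passed=p))
    sid += 1
    if ppi is not None:
        for f, p in ppi.items():
            rows.append(
                dict(
                    week=week,
                    session_id=f"S{sid:03d}",
                    test_type="PPI",
                    frequency_khz=f,
                    passed=p,
                )
            )
        sid += 1
    if confirm is not None:
        for f, p in confirm.items():
            rows.append(
                dict(week=week, session_id=f"S{sid:03d}", frequency_khz=f, passed=p)
            )
        sid += 1
    builder_rows.extend(rows)
    return sid


def test_confirmed_failure_is_tinnitus(result_table_builder):
    rows = []
    sid = _week(rows, 1, 1, {8.0: True, 14.0: True})
    sid = _week(rows, 5, sid, {8.0: True, 14.0: False}, ppi={14.0: True}, confirm={14.0: False})
    call = classify_timeline(result_table_builder(rows), animal_id="A")
    assert call.status == STATUS_TINNITUS
    assert call.onset_week == 5
    assert call.tinnitus_frequency == "14"


def test_all_passes_is_no_tinnitus(result_table_builder):
    rows = []
    sid = 1
    for week in range(1, 13):
        sid = _week(rows, week, sid, {8.0: True, 14.0: True})
    call = classify_timeline(result_table_builder(rows))
    assert call.status == STATUS_NO_TINNITUS
    assert call.onset_week is None


def test_ppi_failure_confound_is_undetermined(result_table_builder):
    rows = []
    sid = _week(rows, 3, 1, {8.0: False, 14.0: True}, ppi={8.0: False})
    for week in range(4, 13):
        sid = _week(rows, week, sid, {8.0: True, 14.0: True})
    call = classify_timeline(result_table_builder(rows))
    assert call.status == STATUS_UNDETERMINED


def test_unconfirmed_failure_continues_to_no_tinnitus(result_table_builder):
    """GPIAS fail, PPI pass, but the retest passes: not tinnitus that week."""
    rows = []
    sid = _week(rows, 2, 1, {8.0: False, 14.0: True}, ppi={8.0: True}, confirm={8.0: True})
    for week in range(3, 13):
        sid = _week(rows, week, sid, {8.0: True, 14.0: True})
    call = classify_timeline(result_table_builder(rows))
    assert call.status == STATUS_NO_TINNITUS


def test_failures_after_window_ignored(result_table_builder):
    rows = []
    sid = 1
    for week in range(1, 13):
        sid = _week(rows, week, sid, {8.0: True, 14.0: True})
    sid = _week(rows, 13, sid, {8.0: False, 14.0: False}, ppi={8.0: True, 14.0: True},
                confirm={8.0: False, 14.0: False})
    call = classify_timeline(result_table_builder(rows), max_weeks=12)
    assert call.status == STATUS_NO_TINNITUS


def test_both_frequency_deficit(result_table_builder):
    rows = []
    _week(
        rows,
        4,
        1,
        {8.0: False, 14.0: False},
        ppi={8.0: True, 14.0: True},
        confirm={8.0: False, 14.0: False},
    )
    call = classify_timeline(result_table_builder(rows))
    assert call.status == STATUS_TINNITUS
    assert call.tinnitus_frequency == "both"


def test_duplicate_rows_rejected(result_table_builder):
    rows = [
        dict(week=1, session_id="S001", frequency_khz=8.0, passed=True),
        dict(week=1, session_id="S001", frequency_khz=8.0, passed=False),
    ]
    with pytest.raises(ValueError):
        classify_timeline(result_table_builder(rows))


def test_week_decreasing_with_session_order_rejected(result_table_builder):
    rows = [
        dict(week=5, session_id="S001", frequency_khz=8.0, passed=True),
        dict(week=2, session_id="S002", frequency_khz=8.0, passed=True),
    ]
    with pytest.raises(ValueError):
        classify_timeline(result_table_builder(rows))


@pytest.mark.parametrize(
    "freqs,expected",
    [([8.0], "8"), ([14.0], "14"), ([8.0, 14.0], "both"), ([14.0, 8.0], "both")],
)
def test_frequency_assignment(freqs, expected):
    assert assign_tinnitus_frequency(freqs) == expected


def test_frequency_assignment_empty_rejected():
    with pytest.raises(ValueError):
        assign_tinnitus_frequency([])


def _outcome_fixture(builder, both=False):
    rows = []
    # two passed baseline sessions, suppression 60/50 at 8, 40/50 at 14
    rows.append(dict(phase="baseline", week=0, session_id="S001", frequency_khz=8.0,
                     percent_suppression=60.0))
    rows.append(dict(phase="baseline", week=0, session_id="S001", frequency_khz=14.0,
                     percent_suppression=40.0))
    rows.append(dict(phase="baseline", week=0, session_id="S002", frequency_khz=8.0,
                     percent_suppression=50.0))
    rows.append(dict(phase="baseline", week=0, session_id="S002", frequency_khz=14.0,
                     percent_suppression=50.0))
    # onset week 5: initial + confirmation at 8 (and 14 when both)
    rows.append(dict(week=5, session_id="S010", frequency_khz=8.0, passed=False,
                     percent_suppression=10.0))
    rows.append(dict(week=5, session_id="S010", frequency_khz=14.0,
                     passed=not both, percent_suppression=20.0 if both else 45.0))
    rows.append(dict(week=5, session_id="S012", frequency_khz=8.0, passed=False,
                     percent_suppression=6.0))
    if both:
        rows.append(dict(week=5, session_id="S012", frequency_khz=14.0, passed=False,
                         percent_suppression=12.0))
    # day 15
    rows.append(dict(phase="day15", week=8, session_id="S020", frequency_khz=8.0,
                     percent_suppression=40.0))
    rows.append(dict(phase="day15", week=8, session_id="S020", frequency_khz=14.0,
                     percent_suppression=60.0))
    return builder(rows)


def test_treatment_outcome_single_frequency(result_table_builder):
    df = _outcome_fixture(result_table_builder)
    call = TinnitusCall("A", STATUS_TINNITUS, onset_week=5, tinnitus_frequency="8")
    out = {o.phase: o for o in treatment_outcome(df, call)}
    assert out["BT"].tinnitus_freq_suppression == pytest.approx(55.0)
    assert out["BT"].other_freq_suppression == pytest.approx(45.0)
    assert out["AT"].tinnitus_freq_suppression == pytest.approx(8.0)
    assert out["AT"].other_freq_suppression == pytest.approx(45.0)
    assert out["D15"].tinnitus_freq_suppression == pytest.approx(40.0)
    assert out["D15"].other_freq_suppression == pytest.approx(60.0)


def test_treatment_outcome_both_frequencies_averages(result_table_builder):
    df = _outcome_fixture(result_table_builder, both=True)
    call = TinnitusCall("A", STATUS_TINNITUS, onset_week=5, tinnitus_frequency="both")
    out = {o.phase: o for o in treatment_outcome(df, call)}
    assert out["D15"].tinnitus_freq_suppression == pytest.approx(50.0)  # mean of 40, 60
    assert out["D15"].other_freq_suppression is None
    assert out["AT"].tinnitus_freq_suppression == pytest.approx((10 + 20 + 6 + 12) / 4)


def test_outcome_requires_day15(result_table_builder):
    df = _outcome_fixture(result_table_builder)
    df = df[df["phase"] != "day15"]
    call = TinnitusCall("A", STATUS_TINNITUS, onset_week=5, tinnitus_frequency="8")
    with pytest.raises(ValueError):
        treatment_outcome(df, call)


def test_no_tinnitus_call_without_ppi_pass(small_cohort_results):
    """Invariant on simulated cohorts: every tinnitus call has a passed PPI
    at the tinnitus frequency in the onset week."""
    from tinnipy import pipeline

    calls = pipeline.classify_results(small_cohort_results)
    for _, row in calls[calls["status"] == STATUS_TINNITUS].iterrows():
        grp = small_cohort_results[
            small_cohort_results["animal_id"] == row["animal_id"]
        ]
        week = grp[(grp["week"] == int(row["onset_week"])) & (grp["phase"] == "post_trauma")]
        ppi = week[(week["test_type"] == "PPI") & week["passed"]]
        assert len(ppi) >= 1


def test_classification_deterministic(small_cohort_results):
    from tinnipy import pipeline

    a = pipeline.classify_results(small_cohort_results)
    b = pipeline.classify_results(small_cohort_results.sample(frac=1.0, random_state=0))
    pd.testing.assert_frame_equal(a, b)
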