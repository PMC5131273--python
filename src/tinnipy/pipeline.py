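"""End-to-end orchestration: simulate -> score -> classify -> neural -> stats.

Each stage is a pure function from tables to tables so stages can be rerun
independently; `run_pipeline` wires them together, writes every output table
plus a machine-readable manifest, and is byte-reproducible for a fixed
configuration.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, neural, phenotype, scoring, stats
from .io import RunConfig, write_table
from .records import ARM_RTMS, ARM_SHAM
from .simulate import Cohort, simulate_cohort


def trials_frame(cohort: Cohort) -> pd.DataFrame:
    """Trial-level table with precomputed per-window RMS values."""
    rows = []
    for tl in cohort.timelines:
        for session in tl.sessions:
            for rec in session.recordings:
                for trial in rec.trials:
                    rows.append(
                        {
                            "animal_id": tl.animal_id,
                            "session_id": session.session_id,
                            "test_type": rec.test_type,
                            "frequency_khz": rec.background_frequency,
                            "condition": trial.condition,
                            "trial_index": trial.trial_index,
                            "rms_baseline": scoring.compute_rms(trial.baseline_window),
                            "rms_startle": scoring.compute_rms(trial.startle_window),
                        }
                    )
    return pd.DataFrame(rows)


def timeline_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for tl in cohort.timelines:
        for session in tl.sessions:
            rows.append(
                {
                    "animal_id": tl.animal_id,
                    "arm": tl.arm if tl.arm is not None else "",
                    "phase": session.phase,
                    "week": session.week,
                    "session_id": session.session_id,
                }
            )
    return pd.DataFrame(rows)


def score_trials(
    trials: pd.DataFrame,
    timeline: pd.DataFrame,
    *,
    alpha: float = 0.05,
    n_exclude: int = 4,
    t_variant: str = "student",
    suppression_formula: str = "ratio_of_means",
) -> pd.DataFrame:
    """Score every test in a trial table; one row per (animal, session, test, frequency)."""
    meta = timeline.set_index(["animal_id", "session_id"])
    rows = []
    for (animal, session, ttype, freq), grp in trials.groupby(
        ["animal_id", "session_id", "test_type", "frequency_khz"], sort=True
    ):
        grp = grp.sort_values("trial_index")
        keep = grp["trial_index"] > n_exclude
        flagged = grp["rms_baseline"] == 0
        use = grp[keep & ~flagged]
        inh_label, _ = scoring.TEST_CONDITIONS[ttype]
        ratios = use["rms_startle"] / use["rms_baseline"]
        inh = ratios[use["condition"] == inh_label].to_numpy()
        uninh = ratios[use["condition"] != inh_label].to_numpy()
        t, p, passed, pct = scoring.score_ratios(
            inh,
            uninh,
            alpha=alpha,
            t_variant=t_variant,
            suppression_formula=suppression_formula,
        )
        phase, week = meta.loc[(animal, session), ["phase", "week"]]
        rows.append(
            {
                "animal_id": animal,
                "session_id": session,
                "phase": phase,
                "week": int(week),
                "test_type": ttype,
                "frequency_khz": float(freq),
                "n_used": int(len(use)),
                "t": t,
                "p": p,
                "passed": passed,
                "percent_suppression": pct,
            }
        )
    return pd.DataFrame(rows).sort_values(["animal_id", "session_id"], ignore_index=True)


def score_cohort(cohort: Cohort, **kwargs) -> pd.DataFrame:
    """Score an in-memory cohort directly from its raw trial windows."""
    alpha = kwargs.get("alpha", 0.05)
    n_exclude = kwargs.get("n_exclude", 4)
    t_variant = kwargs.get("t_variant", "student")
    formula = kwargs.get("suppression_formula", "ratio_of_means")
    rows = []
    for tl in cohort.timelines:
        for session in tl.sessions:
            for rec in session.recordings:
                res = scoring.score_test(
                    rec,
                    alpha=alpha,
                    n_exclude=n_exclude,
                    t_variant=t_variant,
                    suppression_formula=formula,
                )
                rows.append(
                    {
                        "animal_id": tl.animal_id,
                        "session_id": session.session_id,
                        "phase": session.phase,
                        "week": session.week,
                        "test_type": res.test_type,
                        "frequency_khz": res.background_frequency,
                        "n_used": res.n_used,
                        "t": res.t_statistic,
                        "p": res.p_value,
                        "passed": res.passed,
                        "percent_suppression": res.percent_suppression,
                    }
                )
    return pd.DataFrame(rows)


def classify_results(results: pd.DataFrame, max_weeks: int = 12) -> pd.DataFrame:
    """Per-animal tinnitus calls from a scored results table."""
    rows = []
    for animal, grp in results.groupby("animal_id", sort=True):
        call = phenotype.classify_timeline(grp, animal_id=animal, max_weeks=max_weeks)
        rows.append(
            {
                "animal_id": animal,
                "status": call.status,
                "onset_week": call.onset_week if call.onset_week is not None else "",
                "tinnitus_frequency": call.tinnitus_frequency or "",
            }
        )
    return pd.DataFrame(rows)


def phase_outcomes(results: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """BT/AT/D15 percent-suppression outcomes for tinnitus-positive animals with a day-15 session."""
    rows = []
    for _, call_row in calls.iterrows():
        if call_row["status"] != phenotype.STATUS_TINNITUS:
            continue
        grp = results[results["animal_id"] == call_row["animal_id"]]
        if not (grp["phase"] == "day15").any():
            continue
        call = phenotype.TinnitusCall(
            animal_id=call_row["animal_id"],
            status=call_row["status"],
            onset_week=int(call_row["onset_week"]),
            tinnitus_frequency=str(call_row["tinnitus_frequency"]),
        )
        for outcome in phenotype.treatment_outcome(grp, call):
            rows.append(
                {
                    "animal_id": outcome.animal_id,
                    "phase": outcome.phase,
                    "tinnitus_freq_suppression_pct": outcome.tinnitus_freq_suppression,
                    "other_freq_suppression_pct": (
                        outcome.other_freq_suppression
                        if outcome.other_freq_suppression is not None
                        else ""
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id",
            "phase",
            "tinnitus_freq_suppression_pct",
            "other_freq_suppression_pct",
        ],
    )


def gpias_phase_analysis(
    outcomes: pd.DataFrame, arms: pd.DataFrame
) -> tuple[stats.AnovaTable, pd.DataFrame]:
    """Mixed ANOVA (arm x BT/AT/D15) on tinnitus-frequency suppression plus
    the four Sidak post-hoc contrasts: AT vs BT per arm, D15 vs BT per arm."""
    arm_map = arms.set_index("animal_id")["arm"]
    data = outcomes.assign(arm=outcomes["animal_id"].map(arm_map))
    data = data[data["arm"].isin([ARM_RTMS, ARM_SHAM])]
    table = stats.mixed_anova(
        data,
        subject="animal_id",
        between="arm",
        within="phase",
        response="tinnitus_freq_suppression_pct",
    )
    contrasts = [
        ((ARM_RTMS, "AT"), (ARM_RTMS, "BT")),
        ((ARM_SHAM, "AT"), (ARM_SHAM, "BT")),
        ((ARM_RTMS, "D15"), (ARM_RTMS, "BT")),
        ((ARM_SHAM, "D15"), (ARM_SHAM, "BT")),
    ]
    posthoc = stats.posthoc_pairwise(
        data,
        contrasts,
        subject="animal_id",
        between="arm",
        within="phase",
        response="tinnitus_freq_suppression_pct",
    )
    return table, posthoc


def neural_analysis(
    neurons: pd.DataFrame,
    *,
    cutoff_khz: float = 10.0,
    dunn_correction: str = "bonferroni",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified rate summary plus the study's rank tests.

    Returns (summary table, tests table). Tests: overall sham-vs-LI-rTMS
    Mann-Whitney, and Kruskal-Wallis over the four arm x CF-stratum groups
    with Dunn's pairwise comparisons.
    """
    summary = neural.stratified_summary(neurons, cutoff_khz)
    tests = []
    sham = neurons[neurons["arm"] == ARM_SHAM]["spont_rate_hz"].to_numpy()
    rtms = neurons[neurons["arm"] == ARM_RTMS]["spont_rate_hz"].to_numpy()
    if sham.size and rtms.size:
        mw = neural.mann_whitney_u(sham, rtms)
        tests.append(
            {
                "test": "mann_whitney_sham_vs_rtms",
                "comparison": "overall rates",
                "statistic": mw.statistic,
                "p": mw.p_value,
                "method": mw.method,
            }
        )
    low, high = neural.stratify_by_cf(neurons, cutoff_khz)
    groups = {}
    for arm in (ARM_SHAM, ARM_RTMS):
        for name, df in ((f"{arm}_low", low), (f"{arm}_high", high)):
            rates = df[df["arm"] == arm]["spont_rate_hz"].to_numpy()
            if rates.size:
                groups[name] = rates
    if len(groups) >= 2:
        kw = neural.kruskal_wallis_dunn(groups, correction=dunn_correction)
        tests.append(
            {
                "test": "kruskal_wallis",
                "comparison": "arm x CF stratum",
                "statistic": kw.statistic,
                "p": kw.p_value,
                "method": kw.method,
            }
        )
        for pw in kw.pairwise:
            tests.append(
                {
                    "test": "dunn",
                    "comparison": f"{pw.pair[0]} vs {pw.pair[1]}",
                    "statistic": pw.z,
                    "p": pw.p_adjusted,
                    "method": dunn_correction,
                }
            )
    return summary, pd.DataFrame(tests)


def threshold_loss_table(audiograms: pd.DataFrame) -> pd.DataFrame:
    """Per (animal, ear, frequency) post-minus-pre CAP threshold shift."""
    wide = audiograms.pivot_table(
        index=["animal_id", "arm", "ear", "frequency_khz"],
        columns="phase",
        values="threshold_db_spl",
        aggfunc="first",
    ).reset_index()
    if "pre" not in wide.columns or "post" not in wide.columns:
        raise ValueError("audiogram table needs both 'pre' and 'post' phases")
    wide["loss_db"] = wide["post"] - wide["pre"]
    return wide[["animal_id", "arm", "ear", "frequency_khz", "loss_db"]]


def cap_analysis(audiograms: pd.DataFrame, ear: str = "left") -> stats.AnovaTable:
    """Mixed ANOVA of CAP threshold loss: arm (between) x frequency (within)."""
    loss = threshold_loss_table(audiograms)
    loss = loss[loss["ear"] == ear]
    return stats.mixed_anova(
        loss,
        subject="animal_id",
        between="arm",
        within="frequency_khz",
        response="loss_db",
    )


def bdnf_analysis(bdnf: pd.DataFrame) -> dict[str, stats.AnovaTable]:
    """Per-region mixed ANOVA of BDNF %-of-total-protein: arm (between) x side (within)."""
    df = bdnf.copy()
    df["percent_total_protein"] = (
        100.0
        * (df["concentration_pg_ml"] * 1e-6)
        / (df["total_protein_ug_ml"] * df["dilution_factor"])
    )
    out = {}
    for region, grp in df.groupby("region"):
        out[region] = stats.mixed_anova(
            grp,
            subject="animal_id",
            between="arm",
            within="side",
            response="percent_total_protein",
        )
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Full reproducible run; returns the manifest dictionary.

    Writes: trials.csv, timeline.csv, truth.csv, neurons.csv, audiograms.csv,
    bdnf.csv, results.tsv, calls.tsv, phase_outcomes.tsv, neural_summary.tsv,
    neural_tests.tsv, anova_*.tsv, posthoc_gpias.tsv, manifest.json,
    summary.txt.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.require_seed()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    cohort = simulate_cohort(config.sim, config.cohort, rng)
    trials = trials_frame(cohort)
    timeline = timeline_frame(cohort)
    truth = cohort.truth_frame().fillna("")
    write_table(trials, out / "trials.csv")
    write_table(timeline, out / "timeline.csv")
    write_table(truth, out / "truth.csv")
    write_table(cohort.neurons, out / "neurons.csv")
    write_table(cohort.audiograms, out / "audiograms.csv")
    write_table(cohort.bdnf, out / "bdnf.csv")

    results = score_trials(
        trials,
        timeline,
        alpha=config.alpha,
        n_exclude=config.n_exclude,
        t_variant=config.t_variant,
        suppression_formula=config.suppression_formula,
    )
    write_table(results, out / "results.tsv", sep="\t")

    calls = classify_results(results, max_weeks=config.max_weeks)
    write_table(calls, out / "calls.tsv", sep="\t")
    outcomes = phase_outcomes(results, calls)
    write_table(outcomes, out / "phase_outcomes.tsv", sep="\t")

    summary_lines = [f"tinnipy {__version__} run (seed={seed})"]
    n_tin = int((calls["status"] == phenotype.STATUS_TINNITUS).sum())
    summary_lines.append(
        f"animals: {len(calls)}; tinnitus calls: {n_tin}; "
        f"undetermined: {int((calls['status'] == phenotype.STATUS_UNDETERMINED).sum())}"
    )

    if len(cohort.neurons):
        summary, tests = neural_analysis(
            cohort.neurons,
            cutoff_khz=config.cf_cutoff_khz,
            dunn_correction=config.dunn_correction,
        )
        write_table(summary, out / "neural_summary.tsv", sep="\t")
        write_table(tests, out / "neural_tests.tsv", sep="\t")
        summary_lines.append(f"neurons analysed: {len(cohort.neurons)}")

    arms = truth[["animal_id", "arm"]]
    analyses_done = []
    try:
        table, posthoc = gpias_phase_analysis(outcomes, arms)
        write_table(table.to_frame(), out / "anova_gpias.tsv", sep="\t")
        write_table(posthoc, out / "posthoc_gpias.tsv", sep="\t")
        inter = table["interaction"]
        summary_lines.append(
            f"GPIAS phase ANOVA interaction: F({inter.df:g}, "
            f"{table['residual'].df:g}) = {inter.f:.3f}, p = {inter.p:.4g}"
        )
        analyses_done.append("gpias")
    except (ValueError, KeyError) as err:
        summary_lines.append(f"GPIAS phase ANOVA skipped: {err}")
    try:
        cap_table = cap_analysis(cohort.audiograms)
        write_table(cap_table.to_frame(), out / "anova_cap_left.tsv", sep="\t")
        analyses_done.append("cap")
    except ValueError as err:
        summary_lines.append(f"CAP ANOVA skipped: {err}")
    try:
        for region, tbl in bdnf_analysis(cohort.bdnf).items():
            write_table(tbl.to_frame(), out / f"anova_bdnf_{region}.tsv", sep="\t")
        analyses_done.append("bdnf")
    except ValueError as err:
        summary_lines.append(f"BDNF ANOVA skipped: {err}")

    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n", encoding="utf-8")

    outputs = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": seed,
        "config_sha256": config.digest(),
        "tinnipy_version": __version__,
        "analyses": analyses_done,
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
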