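"""Calibration and recovery experiments run on the synthetic-data generator.

These are the package's own quality checks: type-I-error calibration of the
per-test t-test, ground-truth recovery of the longitudinal classifier, the
end-to-end treatment-pattern experiment, and detection-rate studies for the
neural rank tests. Both the test suite and the reporting script call them.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import pipeline
from .neural import kruskal_wallis_dunn
from .phenotype import STATUS_TINNITUS
from .records import ARM_RTMS, ARM_SHAM, GPIAS
from .scoring import score_test
from .simulate import CohortSpec, SimConfig, simulate_cohort, simulate_test


def null_significance_rate(
    n_tests: int = 2000, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Fraction of tests significant at alpha when gap and no-gap trials are
    identically distributed (gap_suppression = 0): the t-test's type-I error."""
    cfg = SimConfig(gap_suppression=0.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    hits = 0
    for _ in range(n_tests):
        res = score_test(simulate_test(cfg, GPIAS, 8.0, rng))
        hits += res.p_value < alpha
    return {"rate": hits / n_tests, "n": n_tests}


def classifier_recovery(
    n_animals: int = 200,
    seed: int = 0,
    cfg: SimConfig | None = None,
    spec: CohortSpec | None = None,
) -> dict:
    """Sensitivity, specificity and onset-week error of the tinnitus
    classifier against the generator's ground truth."""
    cfg = cfg or SimConfig()
    spec = replace(spec or CohortSpec(), n_animals=n_animals)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    cohort = simulate_cohort(cfg, spec, rng)
    results = pipeline.score_cohort(cohort)
    calls = pipeline.classify_results(results, max_weeks=spec.max_weeks)
    truth = cohort.truth_frame()
    merged = calls.merge(truth, on="animal_id")
    true_pos = merged["true_tinnitus"] != "none"
    called_pos = merged["status"] == STATUS_TINNITUS
    sensitivity = float((called_pos & true_pos).sum() / true_pos.sum())
    specificity = float((~called_pos & ~true_pos).sum() / (~true_pos).sum())
    recovered = merged[called_pos & true_pos]
    onset_err = (
        pd.to_numeric(recovered["onset_week"]) - recovered["true_onset_week"]
    ).abs()
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "median_onset_error_weeks": float(onset_err.median()),
        "n_true_positive": int(true_pos.sum()),
        "n_true_negative": int((~true_pos).sum()),
        "n": n_animals,
    }


def phase_pattern_run(seed: int, run_index: int = 0, cfg: SimConfig | None = None,
                      spec: CohortSpec | None = None) -> dict:
    """One end-to-end run: cohort -> scoring -> classification -> phase ANOVA.

    Returns the interaction F/p and the Sidak post-hoc verdicts for the four
    planned contrasts (AT vs BT per arm, D15 vs BT per arm).
    """
    cfg = cfg or SimConfig()
    spec = spec or CohortSpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303, run_index]))
    cohort = simulate_cohort(cfg, spec, rng)
    results = pipeline.score_cohort(cohort)
    calls = pipeline.classify_results(results, max_weeks=spec.max_weeks)
    outcomes = pipeline.phase_outcomes(results, calls)
    arms = cohort.truth_frame()[["animal_id", "arm"]]
    table, posthoc = pipeline.gpias_phase_analysis(outcomes, arms)
    ph = posthoc.set_index(["cell_1", "cell_2"])

    def verdict(arm, phase):
        row = ph.loc[(f"{arm}:{phase}", f"{arm}:BT")]
        return {"diff": float(row["mean_diff"]), "p": float(row["p_sidak"])}

    return {
        "interaction_f": float(table["interaction"].f),
        "interaction_p": float(table["interaction"].p),
        "at_rtms": verdict(ARM_RTMS, "AT"),
        "at_sham": verdict(ARM_SHAM, "AT"),
        "d15_rtms": verdict(ARM_RTMS, "D15"),
        "d15_sham": verdict(ARM_SHAM, "D15"),
        "n_treated": int(outcomes["animal_id"].nunique()),
    }


def phase_pattern_matches(run: dict, alpha: float = 0.05) -> bool:
    """The published qualitative pattern: interaction significant; suppression
    drops after trauma in both arms; recovers at day 15 under LI-rTMS only."""
    return (
        run["interaction_p"] < alpha
        and run["at_rtms"]["p"] < alpha and run["at_rtms"]["diff"] < 0
        and run["at_sham"]["p"] < alpha and run["at_sham"]["diff"] < 0
        and run["d15_rtms"]["p"] >= alpha
        and run["d15_sham"]["p"] < alpha and run["d15_sham"]["diff"] < 0
    )


def phase_pattern_recovery(n_runs: int = 100, seed: int = 0) -> dict:
    """Fraction of seeded end-to-end runs reproducing the treatment pattern."""
    hits = 0
    for i in range(n_runs):
        hits += phase_pattern_matches(phase_pattern_run(seed, run_index=i))
    return {"rate": hits / n_runs, "n": n_runs}


def _neuron_groups(
    spec: CohortSpec, factor: float, n_per_group: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    groups = {}
    for arm in (ARM_SHAM, ARM_RTMS):
        arm_factor = spec.treatment_rate_factor if arm == ARM_RTMS else 1.0
        for stratum, med in (("low", 1.0), ("high", factor)):
            groups[f"{arm}_{stratum}"] = (
                spec.rate_median_hz
                * med
                * arm_factor
                * np.exp(spec.rate_sigma * rng.standard_normal(n_per_group))
            )
    return groups


def neural_detection_rate(
    factor: float,
    n_seeds: int = 20,
    n_per_group: int = 250,
    seed: int = 0,
    p_threshold: float = 0.001,
) -> dict:
    """Rate at which the four-group Kruskal-Wallis/Dunn analysis detects the
    >=10 kHz hyperactivity (both within-arm Dunn comparisons significant)."""
    spec = CohortSpec()
    hits = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 404, i]))
        groups = _neuron_groups(spec, factor, n_per_group, rng)
        res = kruskal_wallis_dunn(groups)
        pw = {frozenset(c.pair): c.p_adjusted for c in res.pairwise}
        detected = (
            res.p_value < p_threshold
            and pw[frozenset(("sham_low", "sham_high"))] < p_threshold
            and pw[frozenset(("LI-rTMS_low", "LI-rTMS_high"))] < p_threshold
        )
        hits += detected
    return {"rate": hits / n_seeds, "n": n_seeds, "n_per_group": n_per_group}


def neural_null_rate(
    n_seeds: int = 1000, n_per_group: int = 250, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Omnibus Kruskal-Wallis rejection rate when all four groups share one
    rate distribution (hyperactivity factor 1, no treatment effect)."""
    spec = replace(CohortSpec(), treatment_rate_factor=1.0)
    hits = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 505, i]))
        groups = _neuron_groups(spec, 1.0, n_per_group, rng)
        res = kruskal_wallis_dunn(groups)
        hits += res.p_value < alpha
    return {"rate": hits / n_seeds, "n": n_seeds}
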