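"""Spontaneous-rate analysis: tonotopic nominal CF, stratification, exact rank tests.

Spontaneous firing rates in the central nucleus of the inferior colliculus
(CNIC) are right-skewed and not normally distributed, so group comparisons
use rank statistics. Characteristic frequencies (CF) estimated audio-visually
are unreliable in the region of peripheral threshold loss, so each unit is
assigned a *nominal* CF from its electrode depth via an exponential
tonotopic map (constant octaves per millimetre), and units are stratified at
10 kHz — the boundary between the intact and hearing-loss frequency regions.

The Mann-Whitney U test uses exact enumeration of the permutation
distribution for small samples (both n <= ``exact_limit``) and the
tie-corrected, continuity-corrected normal approximation otherwise. The
Kruskal-Wallis H test carries the tie correction, with Dunn's z post-hoc
comparisons on mean ranks and a configurable multiplicity correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_EXACT_LIMIT = 7


@dataclass(frozen=True)
class TonotopicMap:
    """Exponential depth→frequency map: f(d) = f_min * 2**(octaves_per_mm * d / 1000)."""

    f_min_khz: float = 1.0
    octaves_per_mm: float = 1.0
    depth_range_um: tuple[float, float] = (0.0, 5000.0)

    def __post_init__(self) -> None:
        if self.f_min_khz <= 0 or self.octaves_per_mm <= 0:
            raise ValueError("f_min and octaves_per_mm must be positive")
        if self.depth_range_um[0] > self.depth_range_um[1]:
            raise ValueError("invalid depth range")


def depth_to_nominal_cf(depth_um, tmap: TonotopicMap = TonotopicMap()):
    """Nominal CF (kHz) from electrode depth (µm); strictly increasing in depth."""
    d = np.asarray(depth_um, dtype=float)
    lo, hi = tmap.depth_range_um
    if np.any(d < lo) or np.any(d > hi):
        raise ValueError(f"depth outside valid range [{lo}, {hi}] um")
    cf = tmap.f_min_khz * 2.0 ** (tmap.octaves_per_mm * d / 1000.0)
    return float(cf) if np.isscalar(depth_um) else cf


def stratify_by_cf(
    neurons: pd.DataFrame, cutoff_khz: float = 10.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a neuron table into (CF < cutoff, CF >= cutoff); the boundary goes high."""
    if "nominal_cf_khz" not in neurons.columns:
        raise ValueError("neuron table needs a nominal_cf_khz column")
    high = neurons["nominal_cf_khz"] >= cutoff_khz
    return neurons[~high], neurons[high]


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # U (Mann-Whitney) or H (Kruskal-Wallis)
    p_value: float
    method: str  # "exact" | "normal_approximation" | "chi_square"
    pairwise: tuple[PairwiseComparison, ...] | None = None


def _tie_term(values: np.ndarray) -> float:
    """sum of t**3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _exact_mw_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-tailed exact p by enumeration of all assignments of the pooled
    values to a group of size n1 (mid-ranks, so ties are handled naturally)."""
    ranks = sps.rankdata(pooled)
    n = pooled.size
    mu = n1 * (n - n1) / 2.0
    dev = abs(u_obs - mu)
    offset = n1 * (n1 + 1) / 2.0
    hits = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / comb(n, n1)


def mann_whitney_u(
    a, b, *, exact_limit: int = DEFAULT_EXACT_LIMIT
) -> RankTestResult:
    """Two-tailed Mann-Whitney U test.

    The reported statistic is U of the first sample (rank-sum definition
    with mid-ranks). Exact enumeration is used whenever both group sizes are
    <= ``exact_limit``; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if n1 <= exact_limit and n2 <= exact_limit:
        p = _exact_mw_p(pooled, n1, u1)
        return RankTestResult(statistic=float(u1), p_value=p, method="exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie = _tie_term(pooled)
    var = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie / (12.0 * n * (n - 1))
    if var <= 0:  # all values tied
        return RankTestResult(statistic=float(u1), p_value=1.0, method="normal_approximation")
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    return RankTestResult(statistic=float(u1), p_value=p, method="normal_approximation")


def kruskal_wallis_dunn(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    *,
    correction: str = "bonferroni",
) -> RankTestResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise z comparisons.

    ``groups`` maps group label to rate sample (lists get numeric labels).
    The omnibus p comes from the chi-square distribution on k-1 df; Dunn's z
    uses mean ranks with the pooled tie-corrected variance, adjusted over
    all k(k-1)/2 pairs with the requested correction (none | bonferroni |
    sidak).
    """
    if correction not in ("none", "bonferroni", "sidak"):
        raise ValueError(f"unknown correction {correction!r}")
    if not isinstance(groups, dict):
        groups = {str(i): g for i, g in enumerate(groups)}
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("all groups must be non-empty")

    pooled = np.concatenate(samples)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [s.size for s in samples]
    mean_ranks = {}
    start = 0
    h = 0.0
    for lab, sz in zip(labels, sizes):
        rbar = ranks[start : start + sz].mean()
        mean_ranks[lab] = rbar
        h += sz * (rbar - (n + 1) / 2.0) ** 2
        start += sz
    h *= 12.0 / (n * (n + 1))
    tie = _tie_term(pooled)
    denom = 1.0 - tie / (n**3 - n) if n > 1 else 1.0
    if denom <= 0:  # every pooled value identical
        h_corr, p = 0.0, 1.0
    else:
        h_corr = h / denom
        p = float(sps.chi2.sf(h_corr, len(samples) - 1))

    m = len(labels) * (len(labels) - 1) // 2
    var_unit = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1)) if n > 1 else 0.0
    pairwise = []
    for (la, na), (lb, nb) in combinations(zip(labels, sizes), 2):
        se = np.sqrt(var_unit * (1.0 / na + 1.0 / nb)) if var_unit > 0 else 0.0
        z = (mean_ranks[la] - mean_ranks[lb]) / se if se > 0 else 0.0
        p_raw = float(2.0 * sps.norm.sf(abs(z))) if se > 0 else 1.0
        if correction == "bonferroni":
            p_adj = min(1.0, p_raw * m)
        elif correction == "sidak":
            p_adj = 1.0 - (1.0 - p_raw) ** m
        else:
            p_adj = p_raw
        pairwise.append(PairwiseComparison((la, lb), float(z), p_raw, float(p_adj)))

    return RankTestResult(
        statistic=float(h_corr),
        p_value=p,
        method="chi_square",
        pairwise=tuple(pairwise),
    )


def stratified_summary(
    neurons: pd.DataFrame, cutoff_khz: float = 10.0
) -> pd.DataFrame:
    """Per (arm, CF stratum) summary of spontaneous rates: n, mean, median."""
    low, high = stratify_by_cf(neurons, cutoff_khz)
    rows = []
    for stratum, df in ((f"<{cutoff_khz:g}", low), (f">={cutoff_khz:g}", high)):
        for arm, sub in df.groupby("arm"):
            rows.append(
                {
                    "arm": arm,
                    "cf_stratum_khz": stratum,
                    "n": len(sub),
                    "mean_rate_hz": sub["spont_rate_hz"].mean(),
                    "median_rate_hz": sub["spont_rate_hz"].median(),
                }
            )
    return pd.DataFrame(rows)
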