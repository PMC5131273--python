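"""Group-level statistics: split-plot (two-way mixed) ANOVA, Sidak post-hocs,
CAP threshold loss, and BDNF percent-of-total-protein arithmetic.

The split-plot design has one between-subjects factor (e.g. treatment arm)
and one within-subjects factor (e.g. time BT/AT/D15, ear side, or stimulus
frequency), each subject measured once at every within level. The classical
decomposition splits the between-subjects sum of squares into the group
effect and subjects-within-groups (the whole-plot error), and the
within-subjects sum of squares into the within-factor main effect, the
group x within interaction, and the residual (subplot error):

    F_group       = MS_group / MS_subjects(group)
    F_within      = MS_within / MS_residual
    F_interaction = MS_interaction / MS_residual

No sphericity correction is applied by default; a Greenhouse-Geisser
adjustment of the within-factor dfs is available for designs with three or
more within levels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import BdnfSample, CapAudiogram


@dataclass(frozen=True)
class AnovaRow:
    source: str
    ss: float
    df: float
    ms: float
    f: float | None
    p: float | None


@dataclass
class AnovaTable:
    rows: list[AnovaRow]

    def __getitem__(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "ss": r.ss,
                    "df": r.df,
                    "ms": r.ms,
                    "F": r.f,
                    "p": r.p,
                }
                for r in self.rows
            ]
        )


def _f_p(ss: float, df: float, ms_err: float, df_err: float) -> tuple[float, float]:
    ms = ss / df if df > 0 else 0.0
    if ms_err == 0.0:
        if ms == 0.0:
            return 0.0, 1.0  # degenerate 0/0: no variation anywhere
        return float("inf"), 0.0
    f = ms / ms_err
    return f, float(sps.f.sf(f, df, df_err))


def _layout(
    data: pd.DataFrame, subject: str, between: str, within: str, response: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Validate completeness and return (subject x within response matrix, subject->group)."""
    for col in (subject, between, within, response):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    if not np.all(np.isfinite(data[response].to_numpy(dtype=float))):
        raise ValueError("responses must be finite")
    groups = data.groupby(subject)[between].nunique()
    if (groups > 1).any():
        bad = groups[groups > 1].index.tolist()
        raise ValueError(f"subjects with multiple between levels: {bad}")
    counts = data.groupby([subject, within]).size()
    if (counts != 1).any():
        raise ValueError("design incomplete or has duplicate (subject, within) cells")
    wide = data.pivot_table(index=subject, columns=within, values=response, aggfunc="first")
    if wide.isna().any().any():
        raise ValueError("incomplete design: missing within-level measurements")
    subj_group = data.groupby(subject)[between].first()
    if wide.shape[1] < 2 or subj_group.nunique() < 2:
        raise ValueError("need >= 2 levels per factor")
    if (subj_group.value_counts() < 2).any():
        raise ValueError("need >= 2 subjects per between level")
    return wide, subj_group


def _gg_epsilon(wide: pd.DataFrame, subj_group: pd.Series) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    b = wide.shape[1]
    mats = []
    for g in subj_group.unique():
        y = wide.loc[subj_group[subj_group == g].index].to_numpy()
        mats.append(np.cov(y, rowvar=False) * (y.shape[0] - 1))
    s = np.sum(mats, axis=0) / (wide.shape[0] - subj_group.nunique())
    # double-centre
    s = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    lam = np.linalg.eigvalsh(s)
    lam = np.clip(lam, 0, None)
    denom = (b - 1) * np.sum(lam**2)
    if denom == 0:
        return 1.0
    return float(min(1.0, np.sum(lam) ** 2 / denom))


def mixed_anova(
    data: pd.DataFrame,
    *,
    subject: str = "subject",
    between: str = "between",
    within: str = "within",
    response: str = "y",
    gg_correction: bool = False,
) -> AnovaTable:
    """Classical split-plot decomposition of a complete mixed design.

    Unequal numbers of subjects per between-group are allowed; every subject
    must have exactly one observation at every within level.
    """
    wide, subj_group = _layout(data, subject, between, within, response)
    y = wide.to_numpy(dtype=float)
    s_total, b = y.shape
    grand = y.mean()
    group_labels = subj_group.loc[wide.index]

    ss_total = float(np.sum((y - grand) ** 2))
    subj_means = y.mean(axis=1)
    ss_between_subj = float(b * np.sum((subj_means - grand) ** 2))

    ss_group = 0.0
    ss_inter = 0.0
    within_means = y.mean(axis=0)
    for g in group_labels.unique():
        mask = (group_labels == g).to_numpy()
        yg = y[mask]
        ss_group += b * yg.shape[0] * (yg.mean() - grand) ** 2
        cell = yg.mean(axis=0)
        ss_inter += yg.shape[0] * np.sum((cell - yg.mean() - within_means + grand) ** 2)
    ss_subj_w = max(ss_between_subj - ss_group, 0.0)
    ss_within = float(s_total * np.sum((within_means - grand) ** 2))
    ss_err = max(ss_total - ss_group - ss_subj_w - ss_within - ss_inter, 0.0)

    a = group_labels.nunique()
    df_group = a - 1
    df_subj = s_total - a
    df_within = b - 1
    df_inter = (a - 1) * (b - 1)
    df_err = (s_total - a) * (b - 1)

    ms_subj = ss_subj_w / df_subj if df_subj else 0.0
    ms_err = ss_err / df_err if df_err else 0.0

    f_group, p_group = _f_p(ss_group, df_group, ms_subj, df_subj)
    eps = _gg_epsilon(wide, subj_group) if (gg_correction and b >= 3) else 1.0
    f_within, _ = _f_p(ss_within, df_within, ms_err, df_err)
    f_inter, _ = _f_p(ss_inter, df_inter, ms_err, df_err)
    if ms_err == 0.0:
        p_within = 1.0 if ss_within == 0 else 0.0
        p_inter = 1.0 if ss_inter == 0 else 0.0
    else:
        p_within = float(sps.f.sf(f_within, eps * df_within, eps * df_err))
        p_inter = float(sps.f.sf(f_inter, eps * df_inter, eps * df_err))

    rows = [
        AnovaRow("between", ss_group, df_group, ss_group / df_group, f_group, p_group),
        AnovaRow("subjects_within_groups", ss_subj_w, df_subj, ms_subj, None, None),
        AnovaRow("within", ss_within, df_within, ss_within / df_within, f_within, p_within),
        AnovaRow("interaction", ss_inter, df_inter,
                 ss_inter / df_inter if df_inter else 0.0, f_inter, p_inter),
        AnovaRow("residual", ss_err, df_err, ms_err, None, None),
    ]
    return AnovaTable(rows)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak-adjusted p for one of m comparisons: 1 - (1 - p)**m, clipped to [0, 1]."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    # -expm1(m*log1p(-p)) == 1-(1-p)**m without underflow at tiny p
    if p == 1.0:
        return 1.0
    return float(min(1.0, -np.expm1(m * np.log1p(-p))))


def posthoc_pairwise(
    data: pd.DataFrame,
    contrasts: list[tuple[tuple[str, str], tuple[str, str]]],
    *,
    subject: str = "subject",
    between: str = "between",
    within: str = "within",
    response: str = "y",
) -> pd.DataFrame:
    """Sidak-corrected pairwise cell contrasts using the ANOVA error terms.

    Each contrast is a pair of design cells ((between level, within level),
    (between level, within level)). Within-subject contrasts (same between
    level) use the residual MS; contrasts across between levels use the
    Winer pooled error term ``(MS_subj + (b-1) MS_res) / b`` with
    Satterthwaite degrees of freedom. The Sidak family size is the number
    of contrasts requested.
    """
    table = mixed_anova(
        data, subject=subject, between=between, within=within, response=response
    )
    wide, subj_group = _layout(data, subject, between, within, response)
    b = wide.shape[1]
    ms_res, df_res = table["residual"].ms, table["residual"].df
    ms_subj, df_subj = table["subjects_within_groups"].ms, table["subjects_within_groups"].df

    def cell(between_level, within_level):
        if within_level not in wide.columns:
            raise KeyError(f"unknown within level {within_level!r}")
        idx = subj_group[subj_group == between_level].index
        if len(idx) == 0:
            raise KeyError(f"unknown between level {between_level!r}")
        return wide.loc[idx, within_level]

    m = len(contrasts)
    rows = []
    for (g1, w1), (g2, w2) in contrasts:
        c1, c2 = cell(g1, w1), cell(g2, w2)
        n1, n2 = len(c1), len(c2)
        diff = float(c1.mean() - c2.mean())
        if g1 == g2:
            se = np.sqrt(ms_res * (1.0 / n1 + 1.0 / n2))
            df = df_res
        else:
            pooled = (ms_subj + (b - 1) * ms_res) / b
            se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
            num = (ms_subj + (b - 1) * ms_res) ** 2
            den = ms_subj**2 / df_subj + ((b - 1) * ms_res) ** 2 / df_res
            df = num / den if den > 0 else df_res
        if se == 0.0:
            t, p_raw = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
        else:
            t = diff / se
            p_raw = float(2.0 * sps.t.sf(abs(t), df))
        rows.append(
            {
                "cell_1": f"{g1}:{w1}",
                "cell_2": f"{g2}:{w2}",
                "mean_diff": diff,
                "t": float(t),
                "df": float(df),
                "p_raw": p_raw,
                "p_sidak": sidak_adjust(p_raw, m),
            }
        )
    return pd.DataFrame(rows)


def threshold_loss(pre: CapAudiogram, post: CapAudiogram) -> np.ndarray:
    """Per-frequency CAP threshold loss in dB (post - pre; positive = loss)."""
    if pre.ear != post.ear:
        raise ValueError("pre and post audiograms are from different ears")
    if pre.frequencies_khz != post.frequencies_khz:
        raise ValueError("pre and post audiograms use different frequency grids")
    return np.asarray(post.thresholds_db_spl, float) - np.asarray(pre.thresholds_db_spl, float)


def bdnf_percent_total(sample: BdnfSample) -> float:
    """BDNF as a percentage of total protein, both per mL of undiluted lysate.

    The ELISA concentration (pg/mL) is measured on the undiluted
    supernatant; the total protein (µg/mL) is measured on the diluted
    aliquot, so it is scaled back by the dilution factor. pg are converted
    to µg (1e-6) before forming the percentage.
    """
    total_undiluted_ug_ml = sample.total_protein_ug_ml * sample.dilution_factor
    return 100.0 * (sample.concentration_pg_ml * 1e-6) / total_undiluted_ug_ml
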