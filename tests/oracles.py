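"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's code paths: U statistics come from
pairwise comparisons rather than rank sums, ranks are assigned by an explicit
sort-and-average loop, and ANOVA sums of squares come from sequential
least-squares projections.
"""
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


def mw_oracle(a, b):
    """Exact two-tailed Mann-Whitney by subset enumeration; U from pairwise counts."""
    pooled = np.concatenate([a, b])
    n = pooled.size
    n1 = len(a)

    def u_of(idx):
        sel = np.zeros(n, bool)
        sel[list(idx)] = True
        x, y = pooled[sel], pooled[~sel]
        gt = (x[:, None] > y[None, :]).sum()
        eq = (x[:, None] == y[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_of(range(n1))
    mu = n1 * (n - n1) / 2.0
    hits = sum(
        1
        for idx in combinations(range(n), n1)
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-12
    )
    return u_obs, hits / comb(n, n1)


def ranks_by_hand(pooled):
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kw_dunn_oracle(groups):
    """H and Dunn z from the definitional rank formulas."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = ranks_by_hand(pooled)
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    rsums = [r.sum() for r in split]
    h = 12.0 / (n * (n + 1)) * sum(rs**2 / sz for rs, sz in zip(rsums, sizes)) - 3 * (
        n + 1
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie = float(np.sum(counts**3 - counts))
    h /= 1.0 - tie / (n**3 - n)
    zs = {}
    for (i, j) in combinations(range(len(groups)), 2):
        num = rsums[i] / sizes[i] - rsums[j] / sizes[j]
        den = np.sqrt(
            (n * (n + 1) / 12.0 - tie / (12.0 * (n - 1)))
            * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        zs[(str(i), str(j))] = num / den
    return h, zs


def make_design(rng, a=2, b=3, n=(4, 5), group_means=None, within_effects=None,
                noise=1.0):
    """Random complete split-plot data frame."""
    if isinstance(n, int):
        n = [n] * a
    rows = []
    sid = 0
    for g in range(a):
        for _ in range(n[g]):
            sid += 1
            subj_effect = rng.normal(0, 1)
            for w in range(b):
                y = subj_effect + rng.normal(0, noise)
                if group_means is not None:
                    y += group_means[g]
                if within_effects is not None:
                    y += within_effects[g][w]
                rows.append(
                    {"subject": f"s{sid}", "between": f"g{g}", "within": f"w{w}", "y": y}
                )
    return pd.DataFrame(rows)


def anova_oracle(data):
    """Sequential sums of squares via least-squares projections (numpy lstsq):
    intercept -> +group -> +subject -> +within -> +interaction."""
    d = data.copy()
    subj = pd.get_dummies(d["subject"]).to_numpy(float)
    grp = pd.get_dummies(d["between"]).to_numpy(float)
    wit = pd.get_dummies(d["within"]).to_numpy(float)
    inter = np.einsum("ij,ik->ijk", grp, wit).reshape(len(d), -1)
    y = d["y"].to_numpy(float)

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r)

    one = np.ones((len(d), 1))
    r0 = rss(one)
    r1 = rss(np.hstack([one, grp]))
    r2 = rss(np.hstack([one, subj]))  # subjects nest groups
    r3 = rss(np.hstack([one, subj, wit]))
    r4 = rss(np.hstack([one, subj, wit, inter]))
    return {
        "between": r0 - r1,
        "subjects_within_groups": r1 - r2,
        "within": r2 - r3,
        "interaction": r3 - r4,
        "residual": r4,
    }
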