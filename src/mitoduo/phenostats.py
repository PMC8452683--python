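"""Mitotype and sex effects on enzyme activities.

Percent reduction of group means with a percentile-bootstrap CI,
Kruskal-Wallis across the four sex x mitotype cells, pairwise Wilcoxon
rank-sum post hocs with Holm adjustment, and marginal factor contrasts
(mitotype pooled over sex, sex pooled over mitotype).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ENDPOINTS = ("ETS", "COX", "CS")
REQUIRED_COLUMNS = {"individual", "sex", "mitotype"}


def validate_table(table: pd.DataFrame, endpoint: str) -> None:
    if not REQUIRED_COLUMNS <= set(table.columns):
        raise ValueError(f"phenotype table needs columns {sorted(REQUIRED_COLUMNS)}")
    if endpoint not in table.columns:
        raise ValueError(f"endpoint {endpoint!r} not in table")
    if (table[endpoint] <= 0).any():
        raise ValueError("activities must be > 0")
    if set(table["sex"]) - {"female", "male"} or set(table["mitotype"]) - {"F", "M"}:
        raise ValueError("sex must be female/male and mitotype F/M")


@dataclass
class PercentReduction:
    percent: float          # 100 * (mean(ref) - mean(other)) / mean(ref)
    ci_low: float
    ci_high: float
    reps: int
    level: float


def percent_reduction(reference, other, bootstrap_reps: int = 2000,
                      seed: int | None = None, ci: float = 0.95) -> PercentReduction:
    """Percent change of group means relative to ``reference``.

    Positive values mean ``other`` is reduced relative to the reference
    group (e.g. M-carriers vs F-carriers). CI by percentile bootstrap over
    both groups (default 2,000 replicates).
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(other, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 values per group")
    ma = a.mean()
    if ma <= 0:
        raise ValueError("reference mean must be > 0")
    point = 100.0 * (ma - b.mean()) / ma
    rng = np.random.default_rng(seed)
    reps = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        ra = rng.choice(a, len(a)).mean()
        rb = rng.choice(b, len(b)).mean()
        reps[r] = 100.0 * (ra - rb) / ra
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(reps, [alpha, 1 - alpha])
    return PercentReduction(float(point), float(lo), float(hi), bootstrap_reps, ci)


@dataclass
class EffectReport:
    endpoint: str
    kw_statistic: float
    kw_p: float
    posthoc: pd.DataFrame              # group1, group2, p_raw, p_holm
    marginal: dict[str, tuple[float, float]]  # factor -> (statistic, p)
    skipped: list[str] = field(default_factory=list)


def factorial_tests(table: pd.DataFrame, endpoint: str,
                    alpha: float = 0.05) -> EffectReport:
    """Nonparametric factorial suite for one enzyme endpoint.

    Kruskal-Wallis across the sex x mitotype cells, pairwise two-sided
    Wilcoxon rank-sum post hocs with Holm adjustment, and Wilcoxon
    rank-sum marginal contrasts for mitotype (pooled over sex) and sex
    (pooled over mitotype). Cells with fewer than two observations are
    flagged and excluded from pairwise contrasts.
    """
    validate_table(table, endpoint)
    cells = {}
    skipped = []
    for (sex, mito), grp in table.groupby(["sex", "mitotype"]):
        name = f"{sex}/{mito}"
        vals = grp[endpoint].to_numpy(dtype=float)
        if len(vals) < 2:
            skipped.append(name)
        else:
            cells[name] = vals
    if len(cells) < 2:
        raise ValueError("need at least two sex x mitotype cells with >= 2 observations")
    kw_stat, kw_p = stats.kruskal(*cells.values())

    names = sorted(cells)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    raw = []
    for a, b in pairs:
        raw.append(stats.mannwhitneyu(cells[a], cells[b],
                                      alternative="two-sided").pvalue)
    holm = multipletests(raw, alpha=alpha, method="holm")[1] if raw else []
    posthoc = pd.DataFrame({"group1": [p[0] for p in pairs],
                            "group2": [p[1] for p in pairs],
                            "p_raw": raw, "p_holm": holm})

    marginal = {}
    for factor, (lv1, lv2) in (("mitotype", ("F", "M")), ("sex", ("female", "male"))):
        g1 = table.loc[table[factor] == lv1, endpoint].to_numpy(dtype=float)
        g2 = table.loc[table[factor] == lv2, endpoint].to_numpy(dtype=float)
        if len(g1) < 2 or len(g2) < 2:
            skipped.append(f"marginal:{factor}")
            continue
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided")
        marginal[factor] = (float(res.statistic), float(res.pvalue))
    return EffectReport(endpoint, float(kw_stat), float(kw_p), posthoc,
                        marginal, skipped)


def effect_summary(table: pd.DataFrame, seed: int | None = None,
                   bootstrap_reps: int = 2000) -> pd.DataFrame:
    """Headline percent reductions on a phenotype table.

    ETS and COX: M-carriers relative to F-carriers (mitotype effect,
    sexes pooled); CS: females relative to males (sex effect, mitotypes
    pooled).
    """
    rows = []
    for endpoint, factor, ref_level, other_level in (
            ("ETS", "mitotype", "F", "M"),
            ("COX", "mitotype", "F", "M"),
            ("CS", "sex", "male", "female")):
        validate_table(table, endpoint)
        ref = table.loc[table[factor] == ref_level, endpoint]
        oth = table.loc[table[factor] == other_level, endpoint]
        pr = percent_reduction(ref, oth, bootstrap_reps=bootstrap_reps, seed=seed)
        rows.append((endpoint, factor, ref_level, other_level,
                     pr.percent, pr.ci_low, pr.ci_high))
    return pd.DataFrame(rows, columns=["endpoint", "factor", "reference", "other",
                                       "percent_reduction", "ci_low", "ci_high"])
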