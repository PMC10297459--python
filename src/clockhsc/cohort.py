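"""Fibrosis scoring, stratification and nonparametric group comparison.

The clinical question is whether a serum biomarker (e.g. AOC3/VAP-1)
tracks fibrosis severity.  Patients are stratified either by transient
elastography (LSM, kPa: <8 no significant fibrosis, 8-15 fibrosis, >15
cirrhosis) or by the blood-based FIB-4 index (<1.3; 1.3-3.2; >3.2), and
biomarker distributions are compared with Kruskal-Wallis followed by
Dunn's pairwise mean-rank tests.  Values exactly on a band boundary join
the middle band so the three bands partition the line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LSM_BANDS = (8.0, 15.0)
FIB4_BANDS = (1.3, 3.2)
GROUP_LABELS = ("low", "mid", "high")


def fib4(age, ast, alt, platelets, allow_zero_ast: bool = False):
    """FIB-4 index: (age [y] x AST [U/L]) / (platelets [10^9/L] x sqrt(ALT [U/L])).

    Scalar or array inputs.  All inputs must be positive; AST of zero is
    permitted (score 0) only with ``allow_zero_ast``.
    """
    age = np.asarray(age, dtype=float)
    ast = np.asarray(ast, dtype=float)
    alt = np.asarray(alt, dtype=float)
    platelets = np.asarray(platelets, dtype=float)
    if (age <= 0).any() or (alt <= 0).any() or (platelets <= 0).any():
        raise ValueError("age, ALT and platelets must be positive")
    if allow_zero_ast:
        if (ast < 0).any():
            raise ValueError("AST must be non-negative")
    elif (ast <= 0).any():
        raise ValueError("AST must be positive (pass allow_zero_ast to permit 0)")
    score = (age * ast) / (platelets * np.sqrt(alt))
    return float(score) if score.ndim == 0 else score


def add_fib4(records: pd.DataFrame, allow_zero_ast: bool = False) -> pd.DataFrame:
    """Return a copy of the cohort table with a ``fib4`` column."""
    out = records.copy()
    out["fib4"] = fib4(
        records["age"],
        records["ast"],
        records["alt"],
        records["platelets"],
        allow_zero_ast=allow_zero_ast,
    )
    return out


def stratify(records: pd.DataFrame, by: str = "lsm") -> pd.Series:
    """Three-band severity labels ('low', 'mid', 'high') per patient.

    ``by='lsm'`` uses the lsm_kpa column with bands <8 / 8-15 / >15 kPa;
    ``by='fib4'`` uses (or computes) FIB-4 with bands <1.3 / 1.3-3.2 /
    >3.2.  Boundary values fall in the middle band.  Missing values yield
    NA labels and are counted in the log.
    """
    if by == "lsm":
        if "lsm_kpa" not in records.columns:
            raise ValueError("cohort table lacks lsm_kpa")
        values = records["lsm_kpa"].astype(float)
        lo, hi = LSM_BANDS
    elif by == "fib4":
        values = (
            records["fib4"].astype(float)
            if "fib4" in records.columns
            else add_fib4(records)["fib4"]
        )
        lo, hi = FIB4_BANDS
    else:
        raise ValueError("stratify by must be 'lsm' or 'fib4'")
    missing = int(values.isna().sum())
    if missing:
        logger.warning("%d records with missing %s excluded from stratification", missing, by)
    labels = pd.Series(pd.NA, index=records.index, dtype="string")
    labels[values < lo] = "low"
    labels[(values >= lo) & (values <= hi)] = "mid"
    labels[values > hi] = "high"
    return labels


def _round_half_up(x: float, decimals: int = 1) -> float:
    return float(
        Decimal(repr(float(x))).quantize(Decimal(f"1e-{decimals}"), ROUND_HALF_UP)
    )


def cohort_summary(labels: pd.Series) -> pd.DataFrame:
    """Count and percentage per label, half-up rounded to one decimal.

    Includes a final 'total' row.  Labels with zero members can be shown
    by passing a Categorical with the full category list.
    """
    labels = labels.dropna()
    if len(labels) == 0:
        raise ValueError("no labelled records to summarise")
    counts = labels.value_counts(sort=False)
    total = int(counts.sum())
    rows = [
        {
            "label": str(label),
            "count": int(count),
            "percent": _round_half_up(100.0 * count / total),
        }
        for label, count in counts.items()
    ]
    rows.append({"label": "total", "count": total, "percent": 100.0})
    return pd.DataFrame(rows)


@dataclass
class StratifiedComparison:
    """Kruskal-Wallis omnibus plus Dunn pairwise results for one grouping."""

    grouping: str
    group_stats: pd.DataFrame  # label, n, median, q1, q3
    h_statistic: float
    p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj


def _dunn_pairwise(
    values: np.ndarray,
    labels: np.ndarray,
    groups: list,
    adjust: str,
) -> pd.DataFrame:
    """Dunn's mean-rank z tests with tie correction."""
    n_total = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    variance_unit = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    records = []
    for g1, g2 in combinations(groups, 2):
        se = math.sqrt(max(variance_unit, 0.0) * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        diff = mean_rank[g1] - mean_rank[g2]
        z = diff / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        records.append({"group_a": g1, "group_b": g2, "z": z, "p_raw": p_raw})
    pairwise = pd.DataFrame(records)
    method = {"bonferroni": "bonferroni", "holm": "holm"}[adjust]
    pairwise["p_adj"] = multipletests(pairwise["p_raw"], method=method)[1]
    return pairwise


def compare_groups(
    values,
    groups,
    grouping: str = "group",
    adjust: str = "bonferroni",
) -> StratifiedComparison:
    """Kruskal-Wallis test across groups with Dunn post-hoc comparisons.

    Requires >=2 groups each with >=2 values.  All-identical values give
    H = 0, p = 1.  ``adjust`` selects Bonferroni (default, GraphPad-style)
    or Holm correction of the C(k,2) pairwise p-values.
    """
    if adjust not in ("bonferroni", "holm"):
        raise ValueError("adjust must be 'bonferroni' or 'holm'")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValueError("values and groups must have equal length")
    mask = ~np.isnan(values)
    values, labels = values[mask], labels[mask]
    group_ids = list(pd.unique(labels))
    if len(group_ids) < 2:
        raise ValueError("need at least two groups")
    samples = [values[labels == g] for g in group_ids]
    for g, sample in zip(group_ids, samples):
        if len(sample) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    if np.all(values == values[0]):
        h_stat, p = 0.0, 1.0
    else:
        h_stat, p = stats.kruskal(*samples)

    group_stats = pd.DataFrame(
        {
            "label": [str(g) for g in group_ids],
            "n": [len(s) for s in samples],
            "median": [float(np.median(s)) for s in samples],
            "q1": [float(np.percentile(s, 25)) for s in samples],
            "q3": [float(np.percentile(s, 75)) for s in samples],
        }
    )
    pairwise = _dunn_pairwise(values, labels, group_ids, adjust)
    return StratifiedComparison(
        grouping=grouping,
        group_stats=group_stats,
        h_statistic=float(h_stat),
        p=float(p),
        pairwise=pairwise,
    )
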