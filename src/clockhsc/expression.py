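"""Expression contrasts, direction-pattern clustering and primed-gene lists.

The experiment has six conditions: quiescent (Q) and activated HSCs
collected 24 h (T0) or 36 h (T12) after synchronisation, each for wild-type
(WT) and dominant-negative CLOCK-mutant (Mut) cells.  Values are log2
intensities; contrasts report log2 fold-change with positive sign meaning
higher in the first-named condition, a two-sample t-test p-value on log2
replicates, and Benjamini–Hochberg FDR across genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONDITIONS = ("WT-Q", "Mut-Q", "WT-A-T0", "Mut-A-T0", "WT-A-T12", "Mut-A-T12")

#: 3x3 taxonomy of (Mut-Q vs WT-Q direction) x (activation direction,
#: required concordant across both genotypes and both timepoints).
#: Numbered so that (up, up) = 4 and (down, down) = 6, the two patterns
#: with a described biological reading (primed-profibrotic, lost-quiescence).
#: Cell 9 (flat, flat) carries no consistent change and is reported
#: unassigned.
CLUSTER_TAXONOMY: dict[tuple[str, str], int] = {
    ("up", "down"): 1,
    ("up", "flat"): 2,
    ("flat", "up"): 3,
    ("up", "up"): 4,
    ("flat", "down"): 5,
    ("down", "down"): 6,
    ("down", "up"): 7,
    ("down", "flat"): 8,
    ("flat", "flat"): 9,
}
UNASSIGNED_CELL = 9


@dataclass
class ExpressionMatrix:
    """Genes x (condition, replicate) log2 expression values.

    Column labels follow ``<condition>_<replicate>``, e.g. ``WT-Q_1``.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.index.isna().any():
            raise ValueError("missing gene ids in expression matrix")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        for col in self.values.columns:
            cond = self._condition_of(col)
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition in column {col!r}")
        for cond in self.conditions():
            if not self.replicate_columns(cond):
                raise ValueError(f"condition {cond} has no replicates")

    @staticmethod
    def _condition_of(column: str) -> str:
        return column.rsplit("_", 1)[0]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def conditions(self) -> list[str]:
        seen = []
        for col in self.values.columns:
            cond = self._condition_of(col)
            if cond not in seen:
                seen.append(cond)
        return seen

    def replicate_columns(self, condition: str) -> list[str]:
        return [
            c for c in self.values.columns if self._condition_of(c) == condition
        ]

    def replicates(self, condition: str) -> pd.DataFrame:
        cols = self.replicate_columns(condition)
        if not cols:
            raise ValueError(f"unknown condition label: {condition!r}")
        return self.values[cols]


def _ttest_with_zero_variance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sample t-test p per gene; degenerate zero-variance genes get
    p = 1 when the group means agree and p = 0 when they differ."""
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, axis=1).pvalue
    pooled_var = a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)
    degenerate = pooled_var == 0
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
    return p


def contrast(matrix: ExpressionMatrix, cond_a: str, cond_b: str) -> pd.DataFrame:
    """Pairwise contrast ``cond_a`` vs ``cond_b``.

    Returns a frame indexed by gene_id with columns comparison, log2fc,
    fold_change (= 2**|log2fc|, direction carried by the log2fc sign),
    p and fdr.  With a single replicate on either side p and fdr are NaN.
    """
    a = matrix.replicates(cond_a).to_numpy(dtype=float)
    b = matrix.replicates(cond_b).to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    if a.shape[1] >= 2 and b.shape[1] >= 2:
        p = _ttest_with_zero_variance(a, b)
        fdr = benjamini_hochberg(p)
    else:
        logger.warning(
            "contrast %s vs %s has a single replicate; p/fdr unavailable",
            cond_a,
            cond_b,
        )
        p = np.full(len(log2fc), np.nan)
        fdr = np.full(len(log2fc), np.nan)
    return pd.DataFrame(
        {
            "comparison": f"{cond_a}_vs_{cond_b}",
            "log2fc": log2fc,
            "fold_change": 2.0 ** np.abs(log2fc),
            "p": p,
            "fdr": fdr,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def standard_contrasts(matrix: ExpressionMatrix) -> dict[str, pd.DataFrame]:
    """The five contrasts the clustering and regulome stages consume."""
    return {
        "mut_vs_wt_q": contrast(matrix, "Mut-Q", "WT-Q"),
        "mut_vs_wt_a_t0": contrast(matrix, "Mut-A-T0", "WT-A-T0"),
        "mut_vs_wt_a_t12": contrast(matrix, "Mut-A-T12", "WT-A-T12"),
        "wt_act_t0": contrast(matrix, "WT-A-T0", "WT-Q"),
        "wt_act_t12": contrast(matrix, "WT-A-T12", "WT-Q"),
        "mut_act_t0": contrast(matrix, "Mut-A-T0", "Mut-Q"),
        "mut_act_t12": contrast(matrix, "Mut-A-T12", "Mut-Q"),
    }


def _direction(frame: pd.DataFrame, fold: float, p: float) -> pd.Series:
    """Per-gene direction call: 'up', 'down' or 'flat' (strict thresholds)."""
    significant = (frame["fold_change"] > fold) & (frame["p"] < p)
    direction = pd.Series("flat", index=frame.index)
    direction[significant & (frame["log2fc"] > 0)] = "up"
    direction[significant & (frame["log2fc"] < 0)] = "down"
    return direction


def assign_pattern_cluster(
    contrasts: dict[str, pd.DataFrame],
    fold: float = 1.5,
    p: float = 0.1,
) -> pd.DataFrame:
    """Assign genes to the nine direction-pattern clusters.

    A gene's pattern is (i) its Mut-Q vs WT-Q direction and (ii) its
    activation direction, which must be concordant across both genotypes
    and both collection timepoints to count as up or down (anything else
    is flat).  Genes in the all-flat cell are unassigned.
    """
    required = ["mut_vs_wt_q", "wt_act_t0", "wt_act_t12", "mut_act_t0", "mut_act_t12"]
    missing = [k for k in required if k not in contrasts]
    if missing:
        raise ValueError(f"missing contrasts for clustering: {missing}")
    mut_dir = _direction(contrasts["mut_vs_wt_q"], fold, p)
    act_dirs = pd.DataFrame(
        {k: _direction(contrasts[k], fold, p) for k in required[1:]}
    )
    act_dir = pd.Series("flat", index=mut_dir.index)
    act_dir[(act_dirs == "up").all(axis=1)] = "up"
    act_dir[(act_dirs == "down").all(axis=1)] = "down"

    logger.info("cluster taxonomy (mutant-vs-WT, activation) -> cluster:")
    for pattern, number in sorted(CLUSTER_TAXONOMY.items(), key=lambda kv: kv[1]):
        note = " (unassigned)" if number == UNASSIGNED_CELL else ""
        logger.info("  cluster %d = %s%s", number, pattern, note)

    cluster = pd.Series(
        [CLUSTER_TAXONOMY[(m, a)] for m, a in zip(mut_dir, act_dir)],
        index=mut_dir.index,
        dtype="Int64",
    )
    cluster[cluster == UNASSIGNED_CELL] = pd.NA
    return pd.DataFrame(
        {
            "cluster": cluster,
            "mutant_direction": mut_dir,
            "activation_direction": act_dir,
        },
        index=pd.Index(mut_dir.index, name="gene_id"),
    )


def select_primed_genes(
    mut_vs_wt_q: pd.DataFrame,
    fold: float = 1.5,
    p: float = 0.1,
) -> tuple[list[str], list[str]]:
    """Genes over ``fold``-fold up/down in mutant vs WT quiescent cells.

    Both thresholds are strict, matching 'over 1.5 fold' and 'p < 0.1'.
    Returns (up list, down list), each sorted by gene id.
    """
    passing = (mut_vs_wt_q["fold_change"] > fold) & (mut_vs_wt_q["p"] < p)
    up = sorted(mut_vs_wt_q.index[passing & (mut_vs_wt_q["log2fc"] > 0)])
    down = sorted(mut_vs_wt_q.index[passing & (mut_vs_wt_q["log2fc"] < 0)])
    return up, down
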