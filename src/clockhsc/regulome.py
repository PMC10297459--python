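"""CLOCK regulome inference: differential peaks -> motif -> nearest gene -> expression.

A gene is called *repressed* by WT CLOCK when a motif-bearing peak that is
more accessible in quiescent cells lies nearest to it and the gene is
up-regulated in the CLOCK-mutant in the matching cell state (the mutant
binds but cannot transactivate, so de-repression in the mutant implies WT
repression); *activated* is the mirror image.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OPEN_IN_Q = "open-in-qHSC"
OPEN_IN_A = "open-in-aHSC"


def tss_positions(genes: pd.DataFrame) -> pd.Series:
    """TSS per gene: start on the + strand, end-1 on the - strand."""
    return pd.Series(
        np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1),
        index=genes.index,
    )


def differential_peaks(
    peaks: pd.DataFrame,
    fold: float = 2.0,
    pseudocount: float = 0.5,
) -> tuple[set[str], set[str]]:
    """Split peaks by accessibility bias, strict >fold in either direction.

    The pseudocount is added to both concentrations before the ratio to
    guard zeros; with pseudocount 0, non-positive concentrations are an
    error.
    """
    conc_q = peaks["conc_q"].to_numpy(dtype=float)
    conc_a = peaks["conc_a"].to_numpy(dtype=float)
    if pseudocount == 0 and ((conc_q <= 0).any() or (conc_a <= 0).any()):
        raise ValueError("non-positive concentrations require a pseudocount")
    if ((conc_q + pseudocount) <= 0).any() or ((conc_a + pseudocount) <= 0).any():
        raise ValueError("concentrations must be positive after pseudocount")
    ratio = (conc_q + pseudocount) / (conc_a + pseudocount)
    q_open = set(peaks["peak_id"][ratio > fold])
    a_open = set(peaks["peak_id"][ratio < 1.0 / fold])
    return q_open, a_open


def _distance_to_interval(tss: np.ndarray, start: int, end: int) -> np.ndarray:
    """Separation between TSS points and a 0-based half-open interval."""
    d = np.zeros(tss.shape, dtype=np.int64)
    left = tss < start
    right = tss >= end
    d[left] = start - tss[left]
    d[right] = tss[right] - (end - 1)
    return d


def nearest_gene(
    peak: Mapping,
    genes: pd.DataFrame,
    _tss: pd.Series | None = None,
) -> tuple[str | None, int | None]:
    """Nearest gene to a peak by TSS-to-interval distance.

    Distance is 0 when the TSS falls inside the peak.  Ties break to the
    lexicographically smaller gene id; a chromosome with no genes yields
    (None, None).
    """
    on_chrom = genes["chrom"].to_numpy() == peak["chrom"]
    if not on_chrom.any():
        return None, None
    sub = genes.loc[on_chrom]
    tss = (tss_positions(genes) if _tss is None else _tss).loc[sub.index]
    dist = _distance_to_interval(
        tss.to_numpy(dtype=np.int64), int(peak["start"]), int(peak["end"])
    )
    best = dist.min()
    candidates = sub["gene_id"].to_numpy()[dist == best]
    return str(min(candidates)), int(best)


def nearest_genes(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Vectorised nearest-gene assignment for a whole peak table."""
    tss = tss_positions(genes)
    records = []
    for _, peak in peaks.iterrows():
        gene_id, dist = nearest_gene(peak, genes, _tss=tss)
        records.append((peak["peak_id"], gene_id, dist))
    return pd.DataFrame(records, columns=["peak_id", "gene_id", "distance_bp"])


def _check_ids(name_a: str, ids_a: set, name_b: str, ids_b: set) -> None:
    orphans = sorted(ids_a - ids_b)
    if orphans:
        shown = ", ".join(map(str, orphans[:10]))
        raise ValueError(
            f"{len(orphans)} {name_a} ids missing from {name_b}: {shown}"
        )


def infer_regulome(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    motif_peaks: Iterable[str],
    contrast_q: pd.DataFrame,
    contrast_a: pd.DataFrame,
    acc_fold: float = 2.0,
    expr_fold: float = 1.5,
    p_max: float | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Integrate accessibility, motif and mutant-expression evidence.

    Pipeline: select peaks >acc_fold biased toward one state, keep those
    carrying the motif, map each to its nearest gene, then test the gene's
    mutant-vs-WT expression in the matching state (``contrast_q`` for
    qHSC-open peaks, ``contrast_a`` for aHSC-open).  Genes up over
    ``expr_fold`` in the mutant are called repressed, down over
    ``expr_fold`` activated; others are dropped.  One call per gene, backed
    by the closest supporting peak.  ``p_max`` optionally adds a p-value
    gate on the expression contrast (off by default).
    """
    motif_set = set(motif_peaks)
    peak_ids = set(peaks["peak_id"])
    _check_ids("motif-flag", motif_set, "peak table", peak_ids)

    q_open, a_open = differential_peaks(peaks, fold=acc_fold, pseudocount=pseudocount)
    selected = peaks[
        peaks["peak_id"].isin((q_open | a_open) & motif_set)
    ]
    assignments = nearest_genes(selected, genes)
    assigned = assignments.dropna(subset=["gene_id"])

    contrast_by_state = {OPEN_IN_Q: contrast_q, OPEN_IN_A: contrast_a}
    for state, frame in contrast_by_state.items():
        _check_ids(
            f"nearest-gene ({state})",
            set(assigned["gene_id"]),
            "expression contrast",
            set(frame.index),
        )

    records = []
    for _, row in assigned.iterrows():
        state = OPEN_IN_Q if row["peak_id"] in q_open else OPEN_IN_A
        expr = contrast_by_state[state].loc[row["gene_id"]]
        if p_max is not None and not (expr["p"] < p_max):
            continue
        fold = 2.0 ** expr["log2fc"]
        if fold > expr_fold:
            mode = "repressed"
        elif 1.0 / fold > expr_fold:
            mode = "activated"
        else:
            continue
        records.append(
            {
                "gene_id": row["gene_id"],
                "mode": mode,
                "peak_id": row["peak_id"],
                "peak_state": state,
                "expression_fold": fold,
                "log2fc": expr["log2fc"],
                "distance_bp": row["distance_bp"],
            }
        )
    calls = pd.DataFrame(
        records,
        columns=[
            "gene_id",
            "mode",
            "peak_id",
            "peak_state",
            "expression_fold",
            "log2fc",
            "distance_bp",
        ],
    )
    if calls.empty:
        return calls
    # one call per gene: smallest TSS distance, then smallest peak id
    calls = calls.sort_values(["gene_id", "distance_bp", "peak_id"], kind="mergesort")
    calls = calls.drop_duplicates("gene_id", keep="first").reset_index(drop=True)
    return calls.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
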