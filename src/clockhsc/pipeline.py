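"""End-to-end regulome run wiring the module stages together."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from clockhsc import motif as motif_mod
from clockhsc.expression import ExpressionMatrix, standard_contrasts
from clockhsc.motif import PWM, default_threshold, ebox_pwm
from clockhsc.regulome import infer_regulome


@dataclass
class PipelineConfig:
    """Thresholds shared across pipeline stages.

    acc_fold / expr_fold are the accessibility and expression fold-change
    filters (strict >); de_fold / de_p gate the direction calls used for
    pattern clustering and primed-gene selection; motif_threshold_frac sets
    the PWM score cutoff as a fraction of the maximum attainable score.
    """

    acc_fold: float = 2.0
    expr_fold: float = 1.5
    expr_p_max: float | None = None
    de_fold: float = 1.5
    de_p: float = 0.1
    motif_threshold_frac: float = 0.8
    pseudocount: float = 0.5
    state_timepoint: str = "T0"  # aHSC contrast used for aHSC-open peaks


def run_regulome(
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    sequences: dict[str, str],
    expression: pd.DataFrame | ExpressionMatrix,
    pwm: PWM | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Full inference: contrasts + motif flags + peak/gene integration.

    Returns the regulome call table (one row per called gene with its
    supporting peak, state, expression fold and TSS distance).
    """
    config = config or PipelineConfig()
    pwm = pwm or ebox_pwm()
    if not isinstance(expression, ExpressionMatrix):
        expression = ExpressionMatrix(expression)
    if config.state_timepoint not in ("T0", "T12"):
        raise ValueError("state_timepoint must be 'T0' or 'T12'")

    contrasts = standard_contrasts(expression)
    threshold = default_threshold(pwm, config.motif_threshold_frac)
    motif_peaks = {
        peak_id
        for peak_id, seq in sequences.items()
        if motif_mod.peak_has_motif(seq, pwm, threshold)
    }
    a_key = "mut_vs_wt_a_t0" if config.state_timepoint == "T0" else "mut_vs_wt_a_t12"
    return infer_regulome(
        peaks=peaks,
        genes=genes,
        motif_peaks=motif_peaks,
        contrast_q=contrasts["mut_vs_wt_q"],
        contrast_a=contrasts[a_key],
        acc_fold=config.acc_fold,
        expr_fold=config.expr_fold,
        p_max=config.expr_p_max,
        pseudocount=config.pseudocount,
    )
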