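"""Position-weight-matrix scanning and motif enrichment for peak sequences.

The CLOCK:BMAL1 heterodimer binds the palindromic E-box CACGTG; the default
matrix is a sharp 6-mer PWM centred on that consensus.  Scores are log2
odds against the background base composition; both strands are scanned and
minus-strand hits are reported at the plus-strand coordinate of their
window start.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
# complement of column order A,C,G,T is T,G,C,A i.e. reversed columns
EBOX = "CACGTG"


class MotifHit(NamedTuple):
    """A scored PWM match: 0-based window start on the forward strand."""

    offset: int
    strand: str
    score: float


@dataclass
class PWM:
    """Probability matrix over A,C,G,T with background and pseudocount.

    ``matrix`` has shape (width, 4); rows sum to 1.  The pseudocount is
    added to every probability before forming log-odds, guarding log(0)
    for degenerate columns.
    """

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01
    name: str = "motif"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """Per-position log2-odds weights, pseudocount-regularised."""
        weights = self.matrix + self.pseudocount
        weights = weights / weights.sum(axis=1, keepdims=True)
        return np.log2(weights / self.background)

    def max_score(self) -> float:
        """Best attainable log-odds score (consensus on every position)."""
        return float(self.log_odds().max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background.copy(),
            pseudocount=self.pseudocount,
            name=self.name + "_rc",
        )

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        pseudocount: float = 0.01,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        name: str | None = None,
    ) -> "PWM":
        consensus = consensus.upper()
        if not re.fullmatch(f"[{ALPHABET}]+", consensus):
            raise ValueError("consensus must be over A,C,G,T")
        matrix = np.zeros((len(consensus), 4))
        for i, base in enumerate(consensus):
            matrix[i, _BASE_INDEX[base]] = 1.0
        return cls(
            matrix=matrix,
            background=np.asarray(background, float),
            pseudocount=pseudocount,
            name=name or consensus,
        )


def ebox_pwm(pseudocount: float = 0.01) -> PWM:
    """Default CACGTG E-box matrix with uniform background."""
    return PWM.from_consensus(EBOX, pseudocount=pseudocount, name="EBOX")


def default_threshold(pwm: PWM, frac: float = 0.8) -> float:
    """Score threshold as a fraction of the maximum attainable score."""
    return frac * pwm.max_score()


def _encode(sequence: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and N (or anything else) to 4."""
    seq = sequence.upper()
    if not re.fullmatch("[ACGTN]*", seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains letters outside ACGTN: {bad}")
    table = np.full(256, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(encoded: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window start; windows touching N score -inf."""
    w = log_odds.shape[0]
    n = encoded.size
    if n < w:
        return np.empty(0)
    # extend the weight table with a -inf column for N
    lo = np.column_stack([log_odds, np.full(w, -np.inf)])
    scores = np.zeros(n - w + 1)
    for j in range(w):
        scores += lo[j, encoded[j : j + n - w + 1]]
    return scores


def scan(sequence: str, pwm: PWM, threshold: float | None = None) -> list[MotifHit]:
    """All PWM matches on both strands with score >= threshold.

    Hits are returned in ascending offset ('+' before '-' at equal offset);
    a minus-strand hit's offset is the forward-strand position of its
    window start.  A sequence shorter than the motif yields no hits.
    """
    if threshold is None:
        threshold = default_threshold(pwm)
    encoded = _encode(sequence)
    lo = pwm.log_odds()
    hits: list[MotifHit] = []
    fwd = _window_scores(encoded, lo)
    rev = _window_scores(encoded, lo[::-1, ::-1])
    for offset in range(fwd.size):
        if fwd[offset] >= threshold:
            hits.append(MotifHit(offset, "+", float(fwd[offset])))
        if rev[offset] >= threshold:
            hits.append(MotifHit(offset, "-", float(rev[offset])))
    return hits


def peak_has_motif(sequence: str, pwm: PWM, threshold: float | None = None) -> bool:
    """True iff the sequence carries at least one match."""
    return len(scan(sequence, pwm, threshold)) > 0


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided Fisher's exact test for over-representation.

    Table rows are (foreground, background), columns (with motif, without):
    [[a, b], [c, d]].  Returns (odds ratio, p).  The odds ratio uses the
    Haldane–Anscombe 0.5 correction when any cell is zero.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table cells must be non-negative")
    n_total = a + b + c + d
    # hypergeometric upper tail: P(X >= a) with K = a+c motif-positives
    # drawn into a foreground of size a+b
    p = float(stats.hypergeom.sf(a - 1, n_total, a + c, a + b))
    p = min(p, 1.0)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), p


def motif_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    pwm: PWM,
    threshold: float | None = None,
) -> tuple[float, float]:
    """Fisher enrichment of motif-bearing sequences in foreground vs background."""
    fg = list(foreground)
    bg = list(background)
    if not fg or not bg:
        raise ValueError("foreground and background sets must be non-empty")
    fg_hit = sum(peak_has_motif(s, pwm, threshold) for s in fg)
    bg_hit = sum(peak_has_motif(s, pwm, threshold) for s in bg)
    return fisher_exact_greater(fg_hit, len(fg) - fg_hit, bg_hit, len(bg) - bg_hit)


def write_meme(pwm: PWM, path) -> None:
    """Write a MEME minimal-format motif file."""
    bg = " ".join(
        f"{base} {freq:.5f}" for base, freq in zip(ALPHABET, pwm.background)
    )
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        bg,
        "",
        f"MOTIF {pwm.name}",
        f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20 E= 0",
    ]
    for row in pwm.matrix:
        lines.append(" " + " ".join(f"{p:.6f}" for p in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_meme(path, pseudocount: float = 0.01) -> PWM:
    """Read the first motif from a MEME minimal-format file."""
    text = Path(path).read_text()
    background = np.full(4, 0.25)
    bg_match = re.search(
        r"Background letter frequencies.*?\n\s*A\s+([\d.eE+-]+)\s+C\s+([\d.eE+-]+)"
        r"\s+G\s+([\d.eE+-]+)\s+T\s+([\d.eE+-]+)",
        text,
        re.S,
    )
    if bg_match:
        background = np.array([float(g) for g in bg_match.groups()])
    motif_match = re.search(r"MOTIF\s+(\S+)", text)
    if motif_match is None:
        raise ValueError("no MOTIF block found")
    name = motif_match.group(1)
    lpm = re.search(r"letter-probability matrix:[^\n]*w=\s*(\d+)[^\n]*\n", text)
    if lpm is None:
        raise ValueError("no letter-probability matrix found")
    width = int(lpm.group(1))
    rows = []
    for line in text[lpm.end():].splitlines():
        fields = line.split()
        if len(fields) == 4:
            rows.append([float(f) for f in fields])
        elif rows:
            break
        if len(rows) == width:
            break
    if len(rows) != width:
        raise ValueError(f"expected {width} matrix rows, found {len(rows)}")
    matrix = np.array(rows)
    matrix = matrix / matrix.sum(axis=1, keepdims=True)  # tolerate rounding
    return PWM(matrix=matrix, background=background, pseudocount=pseudocount, name=name)


def scan_peaks(
    sequences: dict[str, str],
    pwm: PWM,
    threshold: float | None = None,
):
    """Scan a peak-id -> sequence mapping; returns a tidy hits table."""
    import pandas as pd

    if threshold is None:
        threshold = default_threshold(pwm)
    records = []
    for peak_id in sequences:
        for hit in scan(sequences[peak_id], pwm, threshold):
            records.append((peak_id, hit.offset, hit.strand, hit.score))
    return pd.DataFrame(records, columns=["peak_id", "offset", "strand", "score"])
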