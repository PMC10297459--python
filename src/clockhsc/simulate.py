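"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume:

* a small annotated genome with non-overlapping genes;
* accessibility peaks in which planted regulome genes receive a nearest
  peak carrying an embedded CACGTG E-box and a >2-fold quiescent/activated
  concentration ratio, plus decoy peaks engineered to fail exactly one
  downstream filter (no motif, no accessibility fold, or no expression
  fold) and motif-scrubbed background peaks;
* a six-condition log2 expression matrix with lognormal (Gaussian-in-log2)
  replicate noise and planted mutant-vs-WT and activation effects;
* a damped-cosine bioluminescence trace with baseline drift;
* a three-group patient cohort with monotone biomarker shifts;
* a GMT collection with one term planted on the repressed genes.

Coordinates are 0-based half-open throughout; the TSS of a minus-strand
gene is end-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from clockhsc import io
from clockhsc.motif import EBOX

GENOME_STREAM = 1
PEAK_STREAM = 2
EXPRESSION_STREAM = 3
TRACE_STREAM = 4
COHORT_STREAM = 5
GENESET_STREAM = 6
TRUTH_STREAM = 7

MIN_GENE_LENGTH = 500
MAX_GENE_LENGTH = 5_000
MIN_GENE_GAP = 200
PEAK_HALF_WIDTH = 125
MOTIF_EDGE_MARGIN = 5

DIAGNOSES = ("NAFLD", "ArLD", "other")
DIAGNOSIS_PROBS = (0.68, 0.12, 0.20)


class CapacityError(ValueError):
    """Requested gene count cannot be packed into the chromosomes."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    Effect-size defaults clear the pipeline's thresholds in the noise-free
    limit: accessibility_fold 2.5 > 2 and expression_fold 1.8 > 1.5.
    """

    seed: int = 0
    n_genes: int = 200
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_peaks: int = 300
    n_planted_repressed: int = 30
    n_planted_activated: int = 30
    n_decoys_per_class: int = 10
    accessibility_fold: float = 2.5
    expression_fold: float = 1.8
    expression_noise_sd: float = 0.2
    n_replicates: int = 3
    trace_amplitude: float = 100.0
    trace_period_h: float = 23.5
    trace_damping_rate: float = 0.01
    trace_phase_rad: float = 0.0
    trace_baseline: float = 20.0
    trace_slope: float = -0.05
    trace_noise_sd: float = 10.0
    trace_duration_h: float = 168.0
    trace_interval_h: float = 1.0 / 6.0
    cohort_sizes: tuple[int, int, int] = (50, 50, 50)
    cohort_group_shifts: tuple[float, float, float] = (0.0, 2.0, 15.0)
    cohort_biomarker_baseline: float = 10.0
    cohort_biomarker_sd: float = 4.0
    n_gene_sets: int = 20
    planted_term_size: int = 20

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_chroms": self.n_chroms,
            "chrom_length": self.chrom_length,
            "n_peaks": self.n_peaks,
            "n_planted_repressed": self.n_planted_repressed,
            "n_planted_activated": self.n_planted_activated,
            "n_replicates": self.n_replicates,
            "n_gene_sets": self.n_gene_sets,
            "planted_term_size": self.planted_term_size,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.n_decoys_per_class < 0:
            raise ValueError("n_decoys_per_class must be >= 0")
        n_special = (
            self.n_planted_repressed
            + self.n_planted_activated
            + 3 * self.n_decoys_per_class
        )
        if n_special > self.n_genes:
            raise ValueError(
                "planted + decoy genes exceed n_genes "
                f"({n_special} > {self.n_genes})"
            )
        if self.accessibility_fold <= 2.0:
            raise ValueError("accessibility_fold must exceed the 2-fold filter")
        if self.expression_fold <= 1.5:
            raise ValueError("expression_fold must exceed the 1.5-fold filter")
        if self.expression_noise_sd < 0 or self.trace_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.trace_period_h <= 0:
            raise ValueError("trace period must be positive")
        if self.trace_damping_rate < 0:
            raise ValueError("trace damping rate must be >= 0")
        if self.trace_interval_h <= 0:
            raise ValueError("trace sampling interval must be positive")
        if self.trace_duration_h < 3 * self.trace_period_h:
            raise ValueError("trace duration must cover at least 3 periods")
        if len(self.cohort_sizes) != 3 or len(self.cohort_group_shifts) != 3:
            raise ValueError("cohort_sizes and cohort_group_shifts need 3 entries")
        if any(s <= 0 for s in self.cohort_sizes):
            raise ValueError("all cohort group sizes must be > 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted structure the pipeline is expected to recover."""

    repressed_genes: set[str] = field(default_factory=set)
    activated_genes: set[str] = field(default_factory=set)
    motif_peak_ids: set[str] = field(default_factory=set)
    enriched_term: str = ""
    true_period_h: float = 0.0
    # decoy genes, each engineered to fail exactly one regulome filter
    decoy_no_motif_genes: set[str] = field(default_factory=set)
    decoy_no_accessibility_genes: set[str] = field(default_factory=set)
    decoy_no_expression_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.repressed_genes & self.activated_genes:
            raise ValueError("repressed and activated gene sets must be disjoint")

    @property
    def planted_genes(self) -> set[str]:
        return self.repressed_genes | self.activated_genes

    @property
    def decoy_genes(self) -> set[str]:
        return (
            self.decoy_no_motif_genes
            | self.decoy_no_accessibility_genes
            | self.decoy_no_expression_genes
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: sorted(v) if isinstance(v, set) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        sets = {
            k: set(v)
            for k, v in d.items()
            if k.endswith("_genes") or k == "motif_peak_ids"
        }
        return cls(
            enriched_term=d.get("enriched_term", ""),
            true_period_h=float(d.get("true_period_h", 0.0)),
            **sets,
        )


def generate_genome(config: SimulationConfig) -> pd.DataFrame:
    """Non-overlapping genes packed onto n_chroms chromosomes.

    Genes get uniform lengths in [500, 5000] bp separated by gaps of at
    least 200 bp; raises :class:`CapacityError` when they cannot fit.
    """
    rng = config.rng(GENOME_STREAM)
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    worst = per_chrom.max() * (MAX_GENE_LENGTH + MIN_GENE_GAP)
    if worst > config.chrom_length:
        raise CapacityError(
            f"cannot pack {per_chrom.max()} genes of up to {MAX_GENE_LENGTH} bp "
            f"(+{MIN_GENE_GAP} bp gaps) into a {config.chrom_length} bp chromosome"
        )
    records = []
    gene_no = 0
    for c in range(config.n_chroms):
        k = int(per_chrom[c])
        lengths = rng.integers(MIN_GENE_LENGTH, MAX_GENE_LENGTH + 1, size=k)
        slack = config.chrom_length - int(lengths.sum()) - k * MIN_GENE_GAP
        # spread the remaining slack over the k+1 inter-gene gaps
        extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        pos = 0
        for i in range(k):
            pos += MIN_GENE_GAP + int(extra[i])
            start = pos
            end = start + int(lengths[i])
            pos = end
            gene_no += 1
            records.append(
                {
                    "gene_id": f"g{gene_no:04d}",
                    "symbol": f"Sym{gene_no:04d}",
                    "chrom": f"chr{c + 1}",
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "start": start,
                    "end": end,
                }
            )
    return pd.DataFrame(records)


def plant_ground_truth(config: SimulationConfig, genes: pd.DataFrame) -> GroundTruth:
    """Pick disjoint planted and decoy gene sets."""
    rng = config.rng(TRUTH_STREAM)
    ids = genes["gene_id"].to_numpy()
    n_needed = (
        config.n_planted_repressed
        + config.n_planted_activated
        + 3 * config.n_decoys_per_class
    )
    chosen = rng.choice(ids, size=n_needed, replace=False)
    cursor = 0

    def take(n: int) -> set[str]:
        nonlocal cursor
        block = set(map(str, chosen[cursor : cursor + n]))
        cursor += n
        return block

    return GroundTruth(
        repressed_genes=take(config.n_planted_repressed),
        activated_genes=take(config.n_planted_activated),
        decoy_no_motif_genes=take(config.n_decoys_per_class),
        decoy_no_accessibility_genes=take(config.n_decoys_per_class),
        decoy_no_expression_genes=take(config.n_decoys_per_class),
        true_period_h=config.trace_period_h,
    )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _scrub_motif(seq: str, rng: np.random.Generator) -> str:
    """Remove every CACGTG occurrence (palindromic: one pattern covers
    both strands) by point mutation, re-checking after each edit."""
    seq = list(seq)
    while True:
        text = "".join(seq)
        pos = text.find(EBOX)
        if pos < 0:
            return text
        offset = int(rng.integers(0, len(EBOX)))
        current = seq[pos + offset]
        seq[pos + offset] = rng.choice([b for b in "ACGT" if b != current])


def _embed_motif(seq: str, rng: np.random.Generator) -> str:
    """Plant one CACGTG at a random offset >= 5 bp from either edge."""
    w = len(EBOX)
    lo = MOTIF_EDGE_MARGIN
    hi = len(seq) - w - MOTIF_EDGE_MARGIN
    if hi < lo:
        raise ValueError("peak too short to embed the motif away from edges")
    offset = int(rng.integers(lo, hi + 1))
    return seq[:offset] + EBOX + seq[offset + w :]


def generate_peaks(
    config: SimulationConfig,
    genes: pd.DataFrame,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Peak table plus sequences; fills ``truth.motif_peak_ids``.

    Planted regulome genes (and the no-expression decoys) get a
    motif-bearing peak centred on their TSS with conc_q/conc_a equal to
    ``accessibility_fold``; no-motif decoys get the fold without the
    motif; no-accessibility decoys get the motif with balanced
    concentrations; background peaks have neither and are motif-scrubbed.
    """
    rng = config.rng(PEAK_STREAM)
    from clockhsc.regulome import tss_positions

    tss = tss_positions(genes)
    by_id = genes.set_index("gene_id")
    tss_by_id = pd.Series(tss.to_numpy(), index=genes["gene_id"].to_numpy())

    records: list[dict] = []
    sequences: dict[str, str] = {}
    truth.motif_peak_ids.clear()

    def add_peak(chrom, start, end, conc_q, conc_a, seq, with_motif):
        peak_id = f"p{len(records) + 1:04d}"
        records.append(
            {
                "peak_id": peak_id,
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "conc_q": float(conc_q),
                "conc_a": float(conc_a),
            }
        )
        sequences[peak_id] = seq
        if with_motif:
            truth.motif_peak_ids.add(peak_id)

    def targeted_peak(gene_id: str, with_motif: bool, with_fold: bool):
        gene = by_id.loc[gene_id]
        centre = int(tss_by_id[gene_id])
        start = max(0, centre - PEAK_HALF_WIDTH)
        end = start + 2 * PEAK_HALF_WIDTH
        base = rng.uniform(10.0, 50.0)
        if with_fold:
            conc_q, conc_a = config.accessibility_fold * base, base
        else:
            conc_q = conc_a = base
        seq = _scrub_motif(_random_sequence(rng, end - start), rng)
        if with_motif:
            seq = _embed_motif(seq, rng)
        add_peak(gene["chrom"], start, end, conc_q, conc_a, seq, with_motif)

    for gene_id in sorted(truth.planted_genes):
        targeted_peak(gene_id, with_motif=True, with_fold=True)
    for gene_id in sorted(truth.decoy_no_motif_genes):
        targeted_peak(gene_id, with_motif=False, with_fold=True)
    for gene_id in sorted(truth.decoy_no_accessibility_genes):
        targeted_peak(gene_id, with_motif=True, with_fold=False)
    for gene_id in sorted(truth.decoy_no_expression_genes):
        targeted_peak(gene_id, with_motif=True, with_fold=True)

    n_background = config.n_peaks - len(records)
    if n_background < 0:
        raise ValueError(
            f"n_peaks={config.n_peaks} too small for "
            f"{len(records)} planted/decoy peaks"
        )
    chroms = sorted(genes["chrom"].unique())
    for _ in range(n_background):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, config.chrom_length - 2 * PEAK_HALF_WIDTH))
        end = start + 2 * PEAK_HALF_WIDTH
        base = rng.uniform(10.0, 50.0)
        ratio = rng.uniform(0.8, 1.25)
        seq = _scrub_motif(_random_sequence(rng, end - start), rng)
        add_peak(chrom, start, end, ratio * base, base, seq, with_motif=False)

    return pd.DataFrame(records), sequences


def generate_expression(
    config: SimulationConfig,
    genes: pd.DataFrame,
    truth: GroundTruth,
) -> pd.DataFrame:
    """Six-condition log2 matrix with planted effects and replicate noise.

    Repressed genes: +log2(expression_fold) in Mut-Q and on activation in
    both genotypes (so they are activation-concordant, landing in pattern
    cluster 4 in the noise-free limit); activated genes mirrored (cluster
    6).  No-motif / no-accessibility decoy genes carry the same expression
    signature (half up, half down); no-expression decoys and background
    genes are flat.
    """
    from clockhsc.expression import CONDITIONS

    rng = config.rng(EXPRESSION_STREAM)
    gene_ids = genes["gene_id"].to_numpy()
    n = len(gene_ids)
    baseline = rng.uniform(6.0, 12.0, size=n)
    d = np.log2(config.expression_fold)

    # per-gene signed effect: +1 repressed-like, -1 activated-like, 0 flat
    sign = pd.Series(0.0, index=gene_ids)
    sign[sorted(truth.repressed_genes)] = 1.0
    sign[sorted(truth.activated_genes)] = -1.0
    for decoys in (truth.decoy_no_motif_genes, truth.decoy_no_accessibility_genes):
        ordered = sorted(decoys)
        half = len(ordered) // 2
        sign[ordered[:half]] = 1.0
        sign[ordered[half:]] = -1.0
    s = sign.to_numpy()

    # condition means: activation adds |effect| steps so both genotypes
    # respond concordantly while Mut-vs-WT keeps the planted direction
    means = {
        "WT-Q": baseline,
        "Mut-Q": baseline + s * d,
        "WT-A-T0": baseline + s * d,
        "WT-A-T12": baseline + s * d,
        "Mut-A-T0": baseline + 2 * s * d,
        "Mut-A-T12": baseline + 2 * s * d,
    }
    columns = {}
    for cond in CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            noise = (
                rng.normal(0.0, config.expression_noise_sd, size=n)
                if config.expression_noise_sd > 0
                else np.zeros(n)
            )
            columns[f"{cond}_{rep}"] = means[cond] + noise
    return pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))


def generate_trace(config: SimulationConfig) -> pd.DataFrame:
    """Damped-cosine reporter trace with linear baseline drift and noise.

    value(t) = A exp(-lambda t) cos(2 pi t / T + phi) + (a + b t) + N(0, sigma),
    sampled uniformly every ``trace_interval_h`` over ``trace_duration_h``
    (inclusive endpoints).
    """
    rng = config.rng(TRACE_STREAM)
    n = int(round(config.trace_duration_h / config.trace_interval_h)) + 1
    t = np.arange(n) * config.trace_interval_h
    value = (
        config.trace_amplitude
        * np.exp(-config.trace_damping_rate * t)
        * np.cos(2 * np.pi * t / config.trace_period_h + config.trace_phase_rad)
        + config.trace_baseline
        + config.trace_slope * t
    )
    if config.trace_noise_sd > 0:
        value = value + rng.normal(0.0, config.trace_noise_sd, size=n)
    return pd.DataFrame({"time_h": t, "value": value})


def generate_cohort(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Three-severity-group cohort with monotone biomarker shifts.

    LSM values are drawn within each group's elastography stratum
    (<8 / 8-15 / >15 kPa); the biomarker is baseline + group shift +
    Gaussian noise; age, AST, ALT and platelets come from plausible
    clinical ranges so FIB-4 is computable.
    """
    rng = config.rng(COHORT_STREAM)
    lsm_ranges = [(2.0, 7.9), (8.0, 15.0), (15.1, 40.0)]
    severity = ("non-fibrotic", "fibrotic", "cirrhotic")
    rows = []
    patient = 0
    for g, (size, shift) in enumerate(
        zip(config.cohort_sizes, config.cohort_group_shifts)
    ):
        for _ in range(size):
            patient += 1
            rows.append(
                {
                    "patient_id": f"pt{patient:04d}",
                    "age": int(rng.integers(25, 81)),
                    "ast": float(np.round(rng.uniform(15.0, 120.0), 1)),
                    "alt": float(np.round(rng.uniform(10.0, 150.0), 1)),
                    "platelets": float(np.round(rng.uniform(100.0, 400.0), 0)),
                    "lsm_kpa": float(np.round(rng.uniform(*lsm_ranges[g]), 1)),
                    "biomarker": float(
                        config.cohort_biomarker_baseline
                        + shift
                        + rng.normal(0.0, config.cohort_biomarker_sd)
                    ),
                    "diagnosis": str(rng.choice(DIAGNOSES, p=DIAGNOSIS_PROBS)),
                    "severity": severity[g],
                }
            )
    return pd.DataFrame(rows)


def generate_gene_sets(
    config: SimulationConfig,
    genes: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT collection with one term planted on the repressed genes.

    The planted term draws 90% of its members from
    ``truth.repressed_genes`` (filled with random genes), the rest are
    random draws from the genome; fills ``truth.enriched_term``.
    """
    rng = config.rng(GENESET_STREAM)
    ids = genes["gene_id"].to_numpy()
    repressed = np.array(sorted(truth.repressed_genes))
    size = min(config.planted_term_size, max(2, len(repressed)))
    n_from_truth = min(len(repressed), int(np.ceil(0.9 * size)))
    members = set(
        map(str, rng.choice(repressed, size=n_from_truth, replace=False))
    )
    others = ids[~np.isin(ids, list(members))]
    fill = rng.choice(others, size=size - len(members), replace=False)
    members |= set(map(str, fill))

    sets: dict[str, tuple[str, frozenset[str]]] = {
        "TERM0000": ("planted repressed-gene programme", frozenset(members))
    }
    truth.enriched_term = "TERM0000"
    for i in range(1, config.n_gene_sets):
        k = int(rng.integers(5, 51))
        random_members = rng.choice(ids, size=min(k, len(ids)), replace=False)
        sets[f"TERM{i:04d}"] = (
            f"random term {i}",
            frozenset(map(str, random_members)),
        )
    return sets


@dataclass
class SimulationResult:
    """Everything one seed generates, plus the ground truth."""

    config: SimulationConfig
    genes: pd.DataFrame
    peaks: pd.DataFrame
    sequences: dict[str, str]
    expression: pd.DataFrame
    trace: pd.DataFrame
    cohort: pd.DataFrame
    gene_sets: dict[str, tuple[str, frozenset[str]]]
    truth: GroundTruth


def simulate_all(
    config: SimulationConfig,
    outdir: str | Path | None = None,
) -> SimulationResult:
    """Run every generator; optionally write all files to ``outdir``."""
    genes = generate_genome(config)
    truth = plant_ground_truth(config, genes)
    peaks, sequences = generate_peaks(config, genes, truth)
    expression = generate_expression(config, genes, truth)
    trace = generate_trace(config)
    cohort = generate_cohort(config, truth)
    gene_sets = generate_gene_sets(config, genes, truth)
    result = SimulationResult(
        config=config,
        genes=genes,
        peaks=peaks,
        sequences=sequences,
        expression=expression,
        trace=trace,
        cohort=cohort,
        gene_sets=gene_sets,
        truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_genes(genes, outdir / "genes.tsv")
        io.write_peaks(peaks, outdir / "peaks.tsv")
        io.write_fasta(sequences, outdir / "peaks.fasta")
        io.write_expression(expression, outdir / "expression.csv")
        io.write_trace(trace, outdir / "trace.csv")
        io.write_cohort(cohort, outdir / "cohort.csv")
        io.write_gmt(gene_sets, outdir / "sets.gmt")
        io.write_truth(truth.to_dict(), outdir / "truth.json")
    return result
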