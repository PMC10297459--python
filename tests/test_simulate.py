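"""Synthetic-data generators: determinism, planted structure, file round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clockhsc import io
from clockhsc.motif import EBOX
from clockhsc.simulate import (
    CapacityError,
    GroundTruth,
    SimulationConfig,
    generate_cohort,
    generate_expression,
    generate_gene_sets,
    generate_genome,
    generate_peaks,
    generate_trace,
    plant_ground_truth,
    simulate_all,
)


class TestConfigValidation:
    def test_planted_genes_must_fit(self):
        with pytest.raises(ValueError, match="exceed n_genes"):
            SimulationConfig(n_genes=10, n_planted_repressed=8, n_planted_activated=8)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"accessibility_fold": 2.0},
            {"expression_fold": 1.5},
            {"n_genes": 0},
            {"trace_period_h": -1.0},
            {"trace_duration_h": 48.0},
            {"cohort_sizes": (0, 5, 5)},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_disjoint_truth_sets_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            GroundTruth(repressed_genes={"g1"}, activated_genes={"g1"})


class TestGenome:
    def test_fixed_seed_is_deterministic(self):
        a = generate_genome(SimulationConfig(seed=1))
        b = generate_genome(SimulationConfig(seed=1))
        pd.testing.assert_frame_equal(a, b)

    def test_genes_within_bounds_and_non_overlapping(self):
        cfg = SimulationConfig(
            seed=3,
            n_genes=40,
            n_chroms=2,
            n_planted_repressed=5,
            n_planted_activated=5,
            n_decoys_per_class=2,
        )
        genes = generate_genome(cfg)
        assert len(genes) == 40
        assert (genes["start"] >= 0).all()
        assert (genes["end"] <= cfg.chrom_length).all()
        assert (genes["start"] < genes["end"]).all()
        for _, sub in genes.groupby("chrom"):
            ordered = sub.sort_values("start")
            assert (ordered["start"].to_numpy()[1:] >= ordered["end"].to_numpy()[:-1]).all()

    def test_capacity_error_when_unpackable(self):
        with pytest.raises(CapacityError):
            generate_genome(SimulationConfig(n_genes=100, n_chroms=1, chrom_length=10_000))


class TestPeaks:
    def test_planted_peaks_carry_motif_and_fold(self, noise_free_sim):
        res = noise_free_sim
        peaks = res.peaks.set_index("peak_id")
        planted_ids = {
            pid for pid in res.truth.motif_peak_ids
        }
        assert planted_ids, "some peaks must carry the planted motif"
        for pid in planted_ids:
            assert EBOX in res.sequences[pid]

    def test_planted_accessibility_ratio_clears_filter(self, noise_free_sim):
        res = noise_free_sim
        cfg = res.config
        # locate one planted gene's peak: ratio is exactly accessibility_fold
        peaks = res.peaks
        ratio = peaks["conc_q"] / peaks["conc_a"]
        exact = np.isclose(ratio, cfg.accessibility_fold)
        assert exact.sum() >= cfg.n_planted_repressed + cfg.n_planted_activated
        assert (ratio[exact] > 2.0).all()

    def test_background_peaks_fail_the_fold_filter(self, noise_free_sim):
        res = noise_free_sim
        cfg = res.config
        n_targeted = (
            cfg.n_planted_repressed
            + cfg.n_planted_activated
            + 3 * cfg.n_decoys_per_class
        )
        background = res.peaks.iloc[n_targeted:]
        ratio = background["conc_q"] / background["conc_a"]
        assert ((ratio <= 2.0) & (ratio >= 0.5)).all()

    def test_fasta_and_peak_table_share_id_sets(self, noise_free_sim):
        res = noise_free_sim
        assert set(res.sequences) == set(res.peaks["peak_id"])

    def test_concentrations_strictly_positive(self, default_sim):
        assert (default_sim.peaks[["conc_q", "conc_a"]] > 0).all().all()

    def test_decoy_and_background_sequences_lack_motif(self, noise_free_sim):
        res = noise_free_sim
        for pid, seq in res.sequences.items():
            if pid not in res.truth.motif_peak_ids:
                assert EBOX not in seq


class TestExpression:
    def test_noise_free_planted_ratio_is_exact(self, noise_free_sim):
        res = noise_free_sim
        expr = res.expression
        mut = expr[[c for c in expr.columns if c.startswith("Mut-Q_")]].mean(axis=1)
        wt = expr[[c for c in expr.columns if c.startswith("WT-Q_")]].mean(axis=1)
        fold = 2.0 ** (mut - wt)
        for g in res.truth.repressed_genes:
            assert fold[g] == pytest.approx(res.config.expression_fold)
        for g in res.truth.activated_genes:
            assert fold[g] == pytest.approx(1.0 / res.config.expression_fold)

    def test_non_planted_gene_log2fc_zero_without_noise(self, noise_free_sim):
        res = noise_free_sim
        expr = res.expression
        background = (
            set(expr.index)
            - res.truth.planted_genes
            - res.truth.decoy_genes
        )
        mut = expr[[c for c in expr.columns if c.startswith("Mut-Q_")]].mean(axis=1)
        wt = expr[[c for c in expr.columns if c.startswith("WT-Q_")]].mean(axis=1)
        assert np.allclose((mut - wt)[sorted(background)], 0.0)

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(seed=7)
        genes = generate_genome(cfg)
        truth = plant_ground_truth(cfg, genes)
        a = generate_expression(cfg, genes, truth)
        b = generate_expression(cfg, genes, truth)
        pd.testing.assert_frame_equal(a, b)


class TestTrace:
    def test_sample_count_inclusive_endpoints(self):
        cfg = SimulationConfig(trace_duration_h=168.0, trace_interval_h=1.0 / 6.0)
        trace = generate_trace(cfg)
        assert len(trace) == 1009  # 168 * 6 + 1

    def test_damped_envelope_decreases_without_noise(self):
        cfg = SimulationConfig(
            trace_noise_sd=0.0, trace_baseline=0.0, trace_slope=0.0
        )
        trace = generate_trace(cfg)
        t, v = trace["time_h"].to_numpy(), trace["value"].to_numpy()
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(v)
        heights = v[peaks]
        assert (np.diff(heights) < 0).all()

    def test_pure_cosine_matches_analytic_values(self):
        cfg = SimulationConfig(
            trace_noise_sd=0.0,
            trace_damping_rate=0.0,
            trace_baseline=0.0,
            trace_slope=0.0,
            trace_amplitude=2.0,
            trace_period_h=24.0,
        )
        trace = generate_trace(cfg)
        expected = 2.0 * np.cos(2 * np.pi * trace["time_h"] / 24.0)
        assert np.allclose(trace["value"], expected)


class TestCohort:
    def test_mean_biomarker_increases_with_planted_shifts(self):
        cfg = SimulationConfig(seed=5, cohort_group_shifts=(0.0, 5.0, 20.0))
        cohort = generate_cohort(cfg)
        means = cohort.groupby("severity", sort=False)["biomarker"].mean()
        assert means["non-fibrotic"] < means["fibrotic"] < means["cirrhotic"]

    def test_null_shifts_give_nominal_type_one_error(self):
        from clockhsc.cohort import compare_groups

        rejections = 0
        n_sims = 200
        for seed in range(n_sims):
            cfg = SimulationConfig(
                seed=seed,
                cohort_group_shifts=(0.0, 0.0, 0.0),
                cohort_sizes=(20, 20, 20),
            )
            cohort = generate_cohort(cfg)
            result = compare_groups(cohort["biomarker"], cohort["severity"])
            rejections += result.p < 0.05
        assert 0.01 <= rejections / n_sims <= 0.09

    def test_lsm_values_respect_group_strata(self, default_sim):
        cohort = default_sim.cohort
        by = cohort.groupby("severity")["lsm_kpa"]
        assert by.max()["non-fibrotic"] < 8.0
        assert 8.0 <= by.min()["fibrotic"] and by.max()["fibrotic"] <= 15.0
        assert by.min()["cirrhotic"] > 15.0


class TestGeneSets:
    def test_planted_term_overlaps_repressed_genes(self, default_sim):
        res = default_sim
        _, members = res.gene_sets[res.truth.enriched_term]
        overlap = len(members & res.truth.repressed_genes)
        assert overlap >= 0.8 * len(members)

    def test_gmt_round_trip_is_lossless(self, tmp_path, default_sim):
        path = tmp_path / "sets.gmt"
        io.write_gmt(default_sim.gene_sets, path)
        assert io.read_gmt(path) == default_sim.gene_sets

    def test_random_term_overlap_near_hypergeometric_mean(self):
        # average overlap of random terms with a fixed query across seeds
        overlaps, expected = [], []
        for seed in range(10):
            cfg = SimulationConfig(seed=seed)
            genes = generate_genome(cfg)
            truth = plant_ground_truth(cfg, genes)
            sets = generate_gene_sets(cfg, genes, truth)
            query = truth.repressed_genes
            big_n = cfg.n_genes
            for term, (_, members) in sets.items():
                if term == truth.enriched_term:
                    continue
                overlaps.append(len(members & query))
                expected.append(len(members) * len(query) / big_n)
        assert np.mean(overlaps) == pytest.approx(np.mean(expected), rel=0.15)


class TestFullBundle:
    def test_outputs_parse_with_own_readers(self, tmp_path):
        cfg = SimulationConfig(seed=2)
        res = simulate_all(cfg, outdir=tmp_path)
        assert len(io.read_genes(tmp_path / "genes.tsv")) == cfg.n_genes
        assert len(io.read_peaks(tmp_path / "peaks.tsv")) == cfg.n_peaks
        assert set(io.read_fasta(tmp_path / "peaks.fasta")) == set(res.sequences)
        expr = io.read_expression(tmp_path / "expression.csv")
        assert expr.shape == res.expression.shape
        assert len(io.read_trace(tmp_path / "trace.csv")) == len(res.trace)
        assert len(io.read_cohort(tmp_path / "cohort.csv")) == sum(cfg.cohort_sizes)
        assert io.read_gmt(tmp_path / "sets.gmt") == res.gene_sets
        truth = io.read_truth(tmp_path / "truth.json")
        assert set(truth["repressed_genes"]) == res.truth.repressed_genes

    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        simulate_all(SimulationConfig(seed=9), outdir=dir_a)
        simulate_all(SimulationConfig(seed=9), outdir=dir_b)
        for name in sorted(p.name for p in dir_a.iterdir()):
            assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes()
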