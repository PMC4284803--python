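"""Synthetic-data generator: determinism, construction guarantees,
distributional properties of the planted signals."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from p53lnc.chromatin import MarkTrack, promoter_mark_evidence
from p53lnc.coding import read_fasta
from p53lnc.genome import Biotype, GenomicInterval, parse_annotation
from p53lnc.peaks import read_narrowpeak
from p53lnc.signature import roc_auc
from p53lnc.simulate import (
    P53RE_CONSENSUS,
    SimulationConfig,
    TruthTable,
    simulate_all,
    simulate_cohort_arrays,
    simulate_expression_tables,
    simulate_genome_annotation,
    simulate_marks,
    validate_outputs,
)

SMALL = dict(
    seed=3,
    n_chromosomes=2,
    chromosome_length=900_000,
    n_genes=60,
    n_planted_targets=10,
    n_decoy_peaks=16,
)


class TestDeterminismAndConstruction:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        manifest = simulate_all(SimulationConfig(**SMALL), a)
        simulate_all(SimulationConfig(**SMALL), b)
        for name in list(manifest.values()) + ["truth_genes.tsv"]:
            assert filecmp.cmp(a / name, b / name, shallow=False), name

    def test_emitted_files_consistent_with_truth(self, small_sim_dir):
        validate_outputs(small_sim_dir)

    def test_requested_biotype_counts_are_exact(self, small_sim_dir, small_sim_config):
        with open(small_sim_dir / "annotation.gtf") as fh:
            transcripts = parse_annotation(fh)
        counts = pd.Series([t.biotype for t in transcripts]).value_counts()
        total = small_sim_config.n_genes
        for biotype, frac in small_sim_config.biotype_mix.items():
            assert abs(counts.get(biotype, 0) - frac * total) < 1
        assert len(transcripts) == total

    def test_gene_tss_within_chromosome_bounds(self, small_sim_dir, small_sim_config):
        truth = pd.read_csv(small_sim_dir / "truth_genes.tsv", sep="\t")
        assert (truth["tss"] >= 0).all()
        assert (truth["tss"] < small_sim_config.chromosome_length).all()

    def test_each_planted_site_covered_by_exactly_one_treated_peak(self, small_sim_dir):
        truth = pd.read_csv(small_sim_dir / "truth_genes.tsv", sep="\t")
        peaks = read_narrowpeak(small_sim_dir / "peaks_treated.narrowPeak")
        for row in truth[truth["is_direct_target"]].itertuples(index=False):
            covering = [
                p
                for p in peaks
                if p.interval.chrom == row.chrom
                and p.interval.start <= row.planted_site_pos
                and p.interval.end >= row.planted_site_pos + len(P53RE_CONSENSUS)
            ]
            assert len(covering) == 1

    def test_planted_site_sequence_present_in_fasta(self, small_sim_dir):
        genome = read_fasta(small_sim_dir / "genome.fa")
        truth = pd.read_csv(small_sim_dir / "truth_genes.tsv", sep="\t")
        for row in truth[truth["is_direct_target"]].itertuples(index=False):
            seq = genome[row.chrom][row.planted_site_pos : row.planted_site_pos + 20]
            assert seq == P53RE_CONSENSUS

    def test_untreated_peaks_are_subset_of_treated(self, small_sim_dir):
        treated = {
            (p.interval.chrom, p.interval.start)
            for p in read_narrowpeak(small_sim_dir / "peaks_treated.narrowPeak")
        }
        untreated = {
            (p.interval.chrom, p.interval.start)
            for p in read_narrowpeak(small_sim_dir / "peaks_untreated.narrowPeak")
        }
        assert untreated <= treated and untreated

    def test_coverage_mass_matches_model_within_one_percent(
        self, small_sim_dir, small_sim_config
    ):
        from p53lnc.peaks import read_bedgraph

        cfg = small_sim_config
        track = read_bedgraph(small_sim_dir / "coverage.bedGraph")
        peaks = read_narrowpeak(small_sim_dir / "peaks_treated.narrowPeak")
        w, b = cfg.coverage_window, cfg.coverage_bin
        centres = np.arange(-w, w, b) + b / 2
        bump_mass = b * (
            cfg.coverage_bump_height * np.exp(-0.5 * (centres / cfg.coverage_bump_sd) ** 2)
        ).sum()
        noise_mass = b * len(centres) * cfg.coverage_noise / 2
        expected = len(peaks) * (bump_mass + noise_mass)
        assert track.total_mass() == pytest.approx(expected, rel=0.01)


class TestExpressionTables:
    def fake_truth(self, n_null, n_planted=0):
        genes = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(n_null + n_planted)],
                "is_direct_target": [False] * n_null + [True] * n_planted,
                "direction": [""] * n_null + ["up"] * n_planted,
            }
        )
        transcripts = pd.DataFrame(
            {
                "transcript_id": [f"T{i}" for i in range(n_null + n_planted)],
                "gene_id": genes["gene_id"],
                "label": "genuine",
                "marked": True,
            }
        )
        return TruthTable(genes, transcripts, pd.DataFrame())

    def test_null_pvalues_uniform(self):
        truth = self.fake_truth(5_000)
        tables = simulate_expression_tables(truth, SimulationConfig(seed=2))
        ks = stats.kstest(tables[0]["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_significance_rate_matches_beta_tail(self):
        cfg = SimulationConfig(seed=4)
        truth = self.fake_truth(0, 2_000)
        tables = simulate_expression_tables(truth, cfg)
        sig = (
            (tables[0]["p_value"] < cfg.de_alpha) | (tables[1]["p_value"] < cfg.de_alpha)
        ).mean()
        p_one = cfg.de_alpha ** cfg.de_planted_beta_a  # Beta(a,1) tail below alpha
        expected = 1 - (1 - p_one) ** 2
        assert sig == pytest.approx(expected, abs=0.01)

    def test_same_seed_identical_tables(self):
        truth = self.fake_truth(100, 20)
        cfg = SimulationConfig(seed=5)
        t1 = simulate_expression_tables(truth, cfg)
        t2 = simulate_expression_tables(truth, cfg)
        assert t1[0].equals(t2[0]) and t1[1].equals(t2[1])

    def test_noiseless_mode_is_exactly_recoverable(self):
        cfg = SimulationConfig(seed=6, noiseless=True)
        truth = self.fake_truth(500, 50)
        tables = simulate_expression_tables(truth, cfg)
        planted = truth.genes["is_direct_target"].to_numpy()
        for tab in tables:
            assert (tab.loc[planted, "p_value"] < cfg.de_alpha).all()
            assert (tab.loc[~planted, "p_value"] >= cfg.de_alpha).all()


class TestMarks:
    @pytest.mark.parametrize("fraction,expect_all,expect_none", [(1.0, True, False), (0.0, False, True)])
    def test_mark_fraction_extremes(self, fraction, expect_all, expect_none):
        cfg = SimulationConfig(**{**SMALL, "mark_fraction": fraction})
        genome, transcripts, truth = simulate_genome_annotation(cfg)
        beds = simulate_marks(truth, transcripts, cfg)
        tracks = [
            MarkTrack(
                m,
                [GenomicInterval(r.chrom, r.start, r.end) for r in df.itertuples(index=False)],
            )
            for m, df in beds.items()
        ]
        genuine = set(truth.transcripts.query("label == 'genuine'")["transcript_id"])
        for t in transcripts:
            active = promoter_mark_evidence(t, tracks).active
            if t.transcript_id in genuine:
                if expect_all:
                    assert active, t.transcript_id
                if expect_none:
                    assert not active

    def test_artefact_transcripts_never_promoter_active(self, small_sim_dir):
        with open(small_sim_dir / "annotation.gtf") as fh:
            transcripts = {t.transcript_id: t for t in parse_annotation(fh)}
        truth = pd.read_csv(small_sim_dir / "truth_transcripts.tsv", sep="\t")
        tracks = [
            MarkTrack.from_bed(m, small_sim_dir / f"mark_{m}.bed")
            for m in ("H3K4me3", "H3K4me1", "H3K27ac")
        ]
        artefacts = truth[truth["label"] == "artefact"]["transcript_id"]
        assert len(artefacts) > 0
        for tid in artefacts:
            assert not promoter_mark_evidence(transcripts[tid], tracks).active


class TestCohort:
    def test_null_marker_auc_near_half(self):
        cfg = SimulationConfig(seed=7, n_patients=500, marker_deltas=(0.0,))
        tumour, normal, _ = simulate_cohort_arrays(cfg)
        scores = np.r_[tumour[:, 0], normal[:, 0]]
        labels = np.r_[np.ones(500), np.zeros(500)]
        assert abs(roc_auc(scores, labels).auc - 0.5) < 0.03

    def test_paired_difference_free_of_patient_effect(self):
        base = dict(seed=8, n_patients=2_000, marker_deltas=(0.0,), cohort_sigma=1.0)
        lo = simulate_cohort_arrays(SimulationConfig(**base, patient_sd=0.0))
        hi = simulate_cohort_arrays(SimulationConfig(**base, patient_sd=5.0))
        var_lo = np.var(lo[0][:, 0] - lo[1][:, 0])
        var_hi = np.var(hi[0][:, 0] - hi[1][:, 0])
        # tumour − normal cancels u_i: variance 2σ² in both cases
        assert var_lo == pytest.approx(2.0, rel=0.1)
        assert var_hi == pytest.approx(2.0, rel=0.1)

    def test_raw_ct_encoding(self):
        from p53lnc.simulate import simulate_cohort

        cfg = SimulationConfig(seed=9, n_patients=5)
        table, truth = simulate_cohort(cfg)
        assert (table["reference_ct"] == cfg.reference_ct).all()
        assert set(table["tissue"]) == {"tumour", "normal"}
        assert len(table) == 5 * 2 * len(cfg.marker_deltas)


def test_config_validation():
    with pytest.raises(ValueError, match="mix"):
        SimulationConfig(seed=1, biotype_mix={Biotype.MRNA: 0.5})
    with pytest.raises(ValueError, match="do not fit"):
        simulate_genome_annotation(SimulationConfig(seed=1, n_genes=10_000))
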