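import pytest

from p53lnc.simulate import SimulationConfig, simulate_all


SMALL_SIM = dict(
    seed=11,
    n_chromosomes=2,
    chromosome_length=900_000,
    n_genes=60,
    n_planted_targets=10,
    n_decoy_peaks=20,
)


@pytest.fixture(scope="session")
def small_sim_dir(tmp_path_factory):
    """One small synthetic input bundle shared across tests."""
    outdir = tmp_path_factory.mktemp("sim")
    simulate_all(SimulationConfig(**SMALL_SIM), outdir)
    return outdir


@pytest.fixture(scope="session")
def small_sim_config():
    return SimulationConfig(**SMALL_SIM)


def pipeline_config_for(sim_dir, out_dir, seed=7):
    from p53lnc.pipeline import PipelineConfig

    return PipelineConfig(
        annotation=str(sim_dir / "annotation.gtf"),
        genome_fasta=str(sim_dir / "genome.fa"),
        peaks=str(sim_dir / "peaks_treated.narrowPeak"),
        output_dir=str(out_dir),
        de_tables=[str(sim_dir / "de_rep1.tsv"), str(sim_dir / "de_rep2.tsv")],
        mark_beds={
            m: str(sim_dir / f"mark_{m}.bed")
            for m in ("H3K4me3", "H3K4me1", "H3K27ac")
        },
        coverage=str(sim_dir / "coverage.bedGraph"),
        cohort_ct=str(sim_dir / "cohort_ct.tsv"),
        seed=seed,
    )
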