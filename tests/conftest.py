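import numpy as np
import pytest

from supscan import SimulationConfig
from supscan.pipeline import PipelineConfig, run, standard_scenario
from supscan.synthdata import UniqueSpec, generate_reference


@pytest.fixture(scope="session")
def standard_run(tmp_path_factory):
    """One full run of the frozen 13-strain study conditions (seed 0)."""
    out = tmp_path_factory.mktemp("standard")
    report = run(standard_scenario(seed=0, outdir=out))
    return report, out


def small_pipeline_config(seed: int, outdir, n_strains: int = 3) -> PipelineConfig:
    """A reduced scenario for fast pipeline-level tests: 10-kb genome,
    4 genes + 1 tRNA, 3 strains (missense SNV / 3-bp deletion / intergenic
    SNV), 120X so single sequencing errors cannot break the 99% rule."""
    sim = SimulationConfig(
        genome_length=10_000,
        gene_count=4,
        trna_count=1,
        n_strains=n_strains,
        mean_depth=120.0,
        error_rate=1e-4,
        seed=seed,
    )
    unique = {
        "strain01": UniqueSpec("SNV", "missense"),
        "strain02": UniqueSpec("DEL", del_length=3),
        "strain03": UniqueSpec("SNV", "intergenic"),
    }
    shared = ("missense", "anticodon", "intergenic", "synonymous")
    return PipelineConfig(
        sim=sim, shared_spec=shared, unique_spec=unique, min_depth=40, outdir=outdir
    )


@pytest.fixture()
def tiny_reference():
    """A ~4-kb annotated toy genome for aligner/annotator unit tests."""
    cfg = SimulationConfig(
        genome_length=4_000, gene_count=3, trna_count=1, n_strains=2, seed=7
    )
    return generate_reference(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
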