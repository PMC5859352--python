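import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    from epiconcord.simulate import SimulationConfig

    return SimulationConfig(
        seed=7,
        n_genes=120,
        n_chromosomes=2,
        chrom_length=200_000,
        snp_count=30,
        n_pwms=4,
        trimodal_means=(1.0, 3.5, 6.0),
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    from epiconcord.simulate import simulate_study

    return simulate_study(small_config)


@pytest.fixture(scope="session")
def e2e_result(tmp_path_factory):
    """Full-size synthetic study run end-to-end once per session.

    2,000 genes, 3 cell types, 6 control + 6 SLE samples per assay and
    cell type — the planted-truth recovery checks all read from this run.
    """
    from epiconcord.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("e2e") / "run"
    cfg = PipelineConfig(outdir=str(out), seed=1)
    return run_pipeline(cfg)


def make_reads(rng, n, chrom="chr1", lo=0, hi=100_000, length=36):
    """Random clean read table in the package's interval format."""
    starts = rng.integers(lo, hi - length, size=n)
    return pd.DataFrame({
        "chrom": chrom,
        "start": starts,
        "end": starts + length,
        "name": [f"r{i}" for i in range(n)],
        "mapq": np.full(n, 60, dtype=np.int32),
        "strand": rng.choice(["+", "-"], size=n),
        "flag": np.zeros(n, dtype=np.int64),
        "cigar": [f"{length}M"] * n,
        "cigar_clean": np.ones(n, dtype=bool),
    })
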