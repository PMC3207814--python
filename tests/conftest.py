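import numpy as np
import pytest

from tagdex.simulate import SimConfig


@pytest.fixture
def tiny_config():
    """Small, fast configuration with every orthology class populated."""
    return SimConfig(
        n_genes=40,
        transcript_len_range=(400, 1500),
        n_de_genes=8,
        library_size_focal=5000,
        library_size_ref=5000,
        seed=7,
    )


@pytest.fixture
def clean_config():
    """No divergence, no artifacts, no errors, full single-contig coverage."""
    return SimConfig(
        n_genes=30,
        transcript_len_range=(400, 1200),
        div_focal_refA=0.0,
        div_focal_refB=0.0,
        frac_one_to_one=0.8,
        frac_refB_only=0.2,
        frac_paralog=0.0,
        contig_coverage=1.0,
        contig_fragmentation_rate=0.0,
        library_size_focal=4000,
        library_size_ref=4000,
        frac_artifact=0.0,
        error_rate=0.0,
        n_de_genes=6,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def recommended_result():
    """One full-size end-to-end run (about a minute), shared by the
    parameter-recovery and sensitivity tests."""
    from tagdex.pipeline import run_pipeline

    cfg = SimConfig(
        n_genes=200,
        n_de_genes=40,
        library_size_focal=500_000,
        library_size_ref=500_000,
        div_focal_refA=0.10,
        div_focal_refB=0.03,
        contig_coverage=0.8,
        frac_artifact=0.3,
        seed=1,
    )
    return run_pipeline(cfg)
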