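import pytest

from spongeworks.pipeline import PipelineConfig, run_pipeline
from spongeworks.simulate import SimConfig, generate_all


@pytest.fixture(scope="session")
def sim42():
    """The default-condition fixture: 500/150/200 features, seed 42."""
    return generate_all(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down fixture for structural (non-recovery) tests."""
    return generate_all(SimConfig(n_mrna=60, n_lncrna=30, n_mirna=20, seed=11))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One small end-to-end pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("pipe") / "run"
    config = PipelineConfig(
        out_dir=str(out),
        seed=13,
        sim=SimConfig(n_mrna=120, n_lncrna=60, n_mirna=60, seed=13),
    )
    manifest = run_pipeline(config)
    return config, manifest, out
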