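import pytest

from utiliseq.core_model import PipelineConfig
from utiliseq import synthetic_data as synth


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_truth():
    """A compact synthetic study reused by read-only tests."""
    return synth.make_genome(1, 30_000, 40, seed=7)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full pipeline run on a small synthetic study."""
    from utiliseq import pipeline

    out = tmp_path_factory.mktemp("run")
    manifest = pipeline.run_all(
        out, PipelineConfig(), seed=11,
        sim_kwargs={"n_genes": 60, "contig_len_bp": 40_000},
    )
    return out, manifest
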