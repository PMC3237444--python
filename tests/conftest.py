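import pytest

from srnamir import synthetic
from srnamir.config import RunConfig
from srnamir.pipeline import run_pipeline

SMALL_SYNTH = dict(
    n_conserved=3,
    n_new=2,
    genome_length=20_000,
    library_size=8_000,
    depth_range=(100, 300),
)


@pytest.fixture(scope="session")
def small_truth():
    """Small synthetic study: toy genome + truth manifest."""
    params = synthetic.SyntheticParams(**SMALL_SYNTH)
    genome, manifest = synthetic.build_toy_genome(params, seed=42)
    return params, genome, manifest


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Full pipeline result on the small synthetic study."""
    cfg = RunConfig(seed=42, synthetic=dict(SMALL_SYNTH))
    outdir = tmp_path_factory.mktemp("smallrun")
    return cfg, run_pipeline(cfg, outdir)
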