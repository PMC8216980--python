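import pytest

from limnotte import io_cli
from limnotte import synthetic_data as synth


@pytest.fixture(scope="session")
def study_scale_result():
    """One full pipeline run at the study's scale (5/7/8/10 lakes)."""
    cfg = io_cli.PipelineConfig(seed=20190722, output_dir="scratch/_unused")
    return io_cli.run_pipeline(cfg, write=False)


@pytest.fixture(scope="session")
def small_surveys():
    """A small deterministic survey set (one lake per class)."""
    cfg = synth.GeneratorConfig(seed=7)
    cfg.n_lakes_per_class = {c: 1 for c in cfg.n_lakes_per_class}
    return synth.generate_survey(cfg)
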