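import logging
import warnings

import pytest

from cernet.pipeline import PipelineConfig, run_pipeline
from cernet.synthetic import SimulationConfig, generate_bundle

logging.disable(logging.CRITICAL)


@pytest.fixture(scope="session")
def bundle():
    """One fully generated synthetic study (default study conditions)."""
    return generate_bundle(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the default synthetic config."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(outdir=str(out), seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_pipeline(cfg)
    return cfg, report
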