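"""Shared fixtures: a small synthetic dataset and one tiny end-to-end run."""

import numpy as np
import pytest

from seedgrader import classify, pipeline, synth


@pytest.fixture(scope="session")
def tiny_synth_config():
    return synth.SynthConfig(counts=(12, 12, 12), size=96, seed=42)


@pytest.fixture(scope="session")
def tiny_images(tiny_synth_config):
    images, manifest = synth.generate_dataset(tiny_synth_config)
    return images, manifest


@pytest.fixture(scope="session")
def tiny_pipeline_config(tiny_synth_config):
    return pipeline.PipelineConfig(
        synth=tiny_synth_config,
        dict_size_color=8,
        dict_size_surf=8,
        svm=classify.SvmConfig(C_grid=(1.0, 10.0), gamma_scale_grid=(0.5, 2.0), cv=3),
        baselines=("lab",),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_pipeline_config):
    """One complete (small) pipeline run shared across tests."""
    return pipeline.run_pipeline(tiny_pipeline_config)
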