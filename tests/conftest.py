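"""Shared fixtures: synthetic records and (expensive) pipeline runs."""

import pytest

from fecg import PipelineConfig, run_pipeline, synth_aecg


@pytest.fixture(scope="session")
def default_synth():
    """The default 60 s seeded abdominal mixture."""
    return synth_aecg(seed=0)


@pytest.fixture(scope="session")
def default_pipeline(default_synth):
    """Proposed-method pipeline result on the default mixture."""
    return run_pipeline(default_synth.record)


@pytest.fixture(scope="session")
def periodic_maternal():
    """Strictly periodic, noiseless, maternal-only record (steady state)."""
    return synth_aecg(seed=0, fetal_amp_ratio=0.0, noise_sd=0.0,
                      wander_amp=0.0, morph_drift=0.0, rr_jitter=0.0)


@pytest.fixture(scope="session")
def drift_synth():
    """Mixture with 3x the default maternal morphology drift."""
    return synth_aecg(seed=0, morph_drift=0.15)


@pytest.fixture(scope="session")
def drift_pipelines(drift_synth):
    """Proposed vs Cerutti pipeline results on the high-drift mixture."""
    proposed = run_pipeline(drift_synth.record)
    baseline = run_pipeline(drift_synth.record, PipelineConfig(method="cerutti"))
    return proposed, baseline
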