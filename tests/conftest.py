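"""Shared fixtures: phantoms and one cached full pipeline run."""

from __future__ import annotations

import warnings

import pytest

from renasl.phantom import PhantomSpec, default_seed_points, make_phantom
from renasl.pipeline import run_acquisition


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless, jitter-free phantom: the exact-arithmetic reference case."""
    spec = PhantomSpec(seed=0, noise_sd=0.0, jitter_max_translation=0.0, jitter_max_rotation=0.0)
    series, truth = make_phantom(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def default_phantom():
    """The canonical default phantom: 8 pairs, 2% noise, jitter, seed 42."""
    spec = PhantomSpec(seed=42)
    series, truth = make_phantom(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def default_pipeline_run(default_phantom):
    """One full pipeline run on the default phantom, shared across tests."""
    spec, series, truth = default_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary, artifacts = run_acquisition(series, default_seed_points(spec))
    return spec, series, truth, summary, artifacts
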