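"""Shared fixtures.

Sampling runs are session-scoped and cached: several test modules reuse
the same symmetric (λ=40, ΔG₀=0) surrogate dataset rather than
re-sampling it.
"""

import warnings

import pytest

from evbscreen import (
    EVBParameters,
    SurrogateModel,
    default_schedule,
    fep_accumulate,
    run_evb_protocol,
)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def params0():
    """Uncalibrated parameters: α = 0, H₁₂ = 0, 300 K."""
    return EVBParameters()


@pytest.fixture(scope="session")
def sym40_model():
    """Symmetric linear-response model: λ = 40, ΔG₀ = 0 kcal/mol."""
    return SurrogateModel.from_targets(lam=40.0, dG0=0.0)


@pytest.fixture(scope="session")
def sym40_frames(sym40_model, schedule, params0):
    """Full 27-window protocol at 2×10⁴ Metropolis steps per window."""
    return run_evb_protocol(sym40_model, schedule, params0,
                            n_steps_per_window=20000, seed=101)


@pytest.fixture(scope="session")
def sym40_dgm(sym40_frames, schedule, params0):
    return fep_accumulate(sym40_frames, schedule, params0)


@pytest.fixture(autouse=True)
def _no_notice_noise():
    """Library notices are expected in several tests; keep output clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
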