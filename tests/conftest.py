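"""Shared fixtures: study-calibrated parameters, reduced designs, cohorts.

Expensive simulate-and-fit fixtures are session-scoped so several test
modules can share one fitted model.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from riclpm.estimation import FitOptions, fit
from riclpm.model import build_model
from riclpm.simulate import default_parameters, exclusion_filter, simulate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_params():
    """Four-construct generating parameters calibrated to the study profile."""
    return default_parameters()


@pytest.fixture(scope="session")
def reduced_params(study_params):
    """Two-construct, four-wave reduced design used for desk-scale experiments."""
    return study_params.subset(("relsat", "dep"))


@pytest.fixture(scope="session")
def tied_reduced_params(reduced_params):
    """Reduced design with time-invariant transitions (the constrained scheme
    is the generating truth); residual covariances keep the within process
    stationary."""
    B0 = reduced_params.B[0]
    C = reduced_params.Sw1
    T = reduced_params.n_waves
    B = np.repeat(B0[None], T - 1, axis=0)
    Theta = np.repeat((C - B0 @ C @ B0.T)[None], T - 1, axis=0)
    return replace(reduced_params, B=B, Theta=Theta).validate()


@pytest.fixture(scope="session")
def reduced_cohort(reduced_params):
    """One filtered cohort (n=5000 before exclusions) from the reduced design."""
    cohort = simulate_cohort(reduced_params, 5000, seed=20240601, items=False)
    filtered, _ = exclusion_filter(cohort)
    return filtered


@pytest.fixture(scope="session")
def reduced_scheme_fits(reduced_params, reduced_cohort):
    """The three constraint schemes fitted to the same reduced cohort."""
    out = {}
    for scheme in ("constrained", "first_free", "free"):
        spec = build_model(reduced_params.model_config(scheme=scheme))
        out[scheme] = fit(
            spec, reduced_cohort.panel, options=FitOptions(compute_se=(scheme == "free"))
        )
    return out
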