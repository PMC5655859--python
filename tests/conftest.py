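"""Shared fixtures: small synthetic references, molecules, null models.

The expensive cohort run used by the acceptance tests is session-scoped
so its cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from omsv.map_align import ScoringParams, fit_null
from omsv.molecule_sim import ErrorModel, simulate_run
from omsv.reference_maps import poisson_reference


@pytest.fixture(scope="session")
def small_ref():
    """1 Mb single-channel Poisson reference, 6 kb mean spacing."""
    return poisson_reference(1_000_000, 6000, 1, seed=5)


@pytest.fixture(scope="session")
def scoring():
    return ScoringParams()


@pytest.fixture(scope="session")
def scoring_noiseless():
    return ScoringParams(resolution_limit=0.0)


@pytest.fixture(scope="session")
def small_null(small_ref, scoring):
    return fit_null(small_ref, scoring, n_draws=1400, seed=2)


@pytest.fixture(scope="session")
def noiseless_molecules(small_ref):
    mols, summary = simulate_run(small_ref, ErrorModel.noiseless(), 20.0,
                                 seed=9)
    return mols, summary


@pytest.fixture(scope="session")
def noisy_molecules(small_ref):
    mols, summary = simulate_run(small_ref, ErrorModel(), 40.0, seed=10)
    return mols, summary


@pytest.fixture(scope="session")
def cohort_outputs():
    """Full cohort pipeline run (all 11 samples), computed once.

    Several acceptance checks read from this single run: concordance,
    breakpoint resolution, inversion recovery, haplotype behavior.
    """
    from omsv.config import PipelineConfig
    from omsv.pipeline import run_cohort

    cfg = PipelineConfig(seed=1)
    outputs, report, scenarios = run_cohort(seed=1, config=cfg)
    return outputs, report, scenarios
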