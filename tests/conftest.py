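"""Shared fixtures: model solves and synthetic datasets are expensive, so
session-scoped fixtures compute them once and tests share them."""

import numpy as np
import pytest

from cyanoecon import (ModelParameters, light_response, simulate_proteomics,
                       SyntheticSpec)

LIGHT_GRID = [27.5, 55.0, 110.0, 220.0, 440.0, 660.0, 880.0, 1100.0]


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def fitted_sweep(default_params):
    """Light response at the packaged (fitted) parameter set."""
    return light_response(default_params, LIGHT_GRID)


@pytest.fixture(scope="session")
def no_damage_sweep(default_params):
    """Light response with photodamage switched off (kd = 0)."""
    return light_response(default_params.with_theta(kd=0.0), LIGHT_GRID)


@pytest.fixture(scope="session")
def small_instance_params() -> ModelParameters:
    """A reduced model instance whose optimal proteome partition is
    interior and representable on a coarse allocation grid (slow
    transport and metabolism force sizeable T and M fractions)."""
    return ModelParameters(kcat_T=0.5, kcat_M=0.5, kcat_R=2.0, kdiff=1e-8)


@pytest.fixture(scope="session")
def constrained_deficits(default_params, fitted_sweep):
    """Max relative growth deficit per class when its proteome fraction is
    pinned at the peak-growth value, over a reduced light grid."""
    from cyanoecon import ConstraintSpec

    grid = [27.5, 110.0, 440.0, 1100.0]
    mu_un = {st.env.I: st.mu for st in fitted_sweep if st.env.I in grid}
    peak = max(fitted_sweep, key=lambda s: s.mu)
    deficits = {}
    for z in ("R", "P", "M"):
        cs = ConstraintSpec(z, peak.mass_fractions[z])
        states = light_response(default_params, grid, constraint=cs)
        deficits[z] = max(1.0 - st.mu / mu_un[st.env.I] for st in states)
    return deficits


@pytest.fixture(scope="session")
def synth_dataset():
    """Full-size synthetic proteomics matrix with ground truth (seed 1)."""
    return simulate_proteomics(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def archetype_dataset():
    """Equal-weight 7-archetype dataset for clustering recovery tests."""
    spec = SyntheticSpec(seed=42, n_proteins=700, dependent_fraction=1.0,
                         archetype_weights=(1,) * 7, missing_rate=0.0,
                         n_contaminants=0, n_reverse=0, n_low_evidence=0)
    return simulate_proteomics(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
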