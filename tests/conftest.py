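"""Shared fixtures: small, fast synthetic spectra with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from plasmanmr import synthspec as ss


@pytest.fixture
def acq_clean() -> ss.AcquisitionConfig:
    """Noise-free, moderately fine grid over the full plasma window."""
    return ss.AcquisitionConfig(n_points=16384, ppm_range=(-0.5, 10.8),
                                noise_sd=0.0, seed=0)


@pytest.fixture
def acq_noisy() -> ss.AcquisitionConfig:
    return ss.AcquisitionConfig(n_points=16384, ppm_range=(-0.5, 10.8),
                                noise_sd=1.0, seed=0)


@pytest.fixture
def singlet() -> ss.MetaboliteSpec:
    """One isolated 1.5 Hz singlet at 2.5 ppm, 1 mM."""
    return ss.MetaboliteSpec(
        name="probe", multiplet=[(2.5, 1.0, 1.5)],
        concentration_by_group={"A": 1.0},
    )


@pytest.fixture
def macromolecule() -> ss.MacromoleculeSpec:
    return ss.MacromoleculeSpec(
        name="hump", humps=[(2.5, 50.0, 200.0)], diffusion=0.0,
    )


@pytest.fixture
def standard() -> ss.InternalStandardSpec:
    return ss.default_standard("MA")


def render_single(met: ss.MetaboliteSpec, acq: ss.AcquisitionConfig,
                  obs: ss.ObservationModel, conc: float = 1.0):
    """Render one metabolite alone (no standard, no macromolecules)."""
    comp = ss.ComponentSet(metabolites=[met])
    return ss.render_spectrum(comp, None, acq, obs,
                              concentrations={met.name: conc})


@pytest.fixture
def two_group_cohort():
    """9+9 replicate cohort with 2-fold changes on 5 metabolites, 10% CV."""
    components = ss.default_plasma_components(replicate_cv=0.10)
    design = ss.CohortDesign(groups={"PA": {}, "PPGL": {}},
                             n_replicates={"PA": 9, "PPGL": 9})
    return components, design
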