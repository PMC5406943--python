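"""Shared fixtures: calibrated anchors, cohorts, and one full-scale pipeline
run (B = 500 bootstrap replicates x 10,000 MRI pairs) reused across tests."""

import pytest

from indirectpower import (
    BivariateSpec,
    bootstrap_regression,
    derive_anchors,
    generate_pseudo_population,
    propagate,
    sample_bivariate,
)
from indirectpower.anchors import BIOMARKERS, MRI_DENSITY, RHO_GRID

SEED = 0
BIOMARKER_NAMES = tuple(BIOMARKERS)


@pytest.fixture(scope="session")
def anchor_sets():
    return {b: derive_anchors(b) for b in BIOMARKER_NAMES}


@pytest.fixture(scope="session")
def pseudo_pops(anchor_sets):
    return {b: generate_pseudo_population(a, SEED) for b, a in anchor_sets.items()}


@pytest.fixture(scope="session")
def ensembles(pseudo_pops):
    return {b: bootstrap_regression(p, B=500, seed=SEED) for b, p in pseudo_pops.items()}


@pytest.fixture(scope="session")
def mri_samples():
    out = {}
    for rho in RHO_GRID:
        spec = BivariateSpec(
            mu_pre=MRI_DENSITY["pre_mean"],
            mu_post=MRI_DENSITY["post_mean"],
            sd_pre=MRI_DENSITY["pre_sd"],
            sd_post=MRI_DENSITY["post_sd"],
            rho=rho,
        )
        out[rho] = sample_bivariate(spec, 10_000, seed=SEED, stream=f"mri:{rho}")
    return out


@pytest.fixture(scope="session")
def full_propagation(anchor_sets, ensembles, mri_samples):
    """All nine (biomarker, rho) propagation results at published scale."""
    out = {}
    for b in BIOMARKER_NAMES:
        for rho in RHO_GRID:
            out[(b, rho)] = propagate(
                ensembles[b], mri_samples[rho], anchor_sets[b], rho_dosi=rho, seed=SEED
            )
    return out
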