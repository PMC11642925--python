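"""Shared fixtures: frame schedules, reference curves, and one fitted posterior.

The expensive session fixtures (reference library, simulated dataset, MCMC
fit) are built once and shared; their sizes are chosen so the whole suite
runs in minutes while still exercising realistic study conditions.
"""

from dataclasses import replace

import numpy as np
import pytest

from simbaref.design import MCMCOptions, Priors, SimbaSpec, build_design
from simbaref.io import TAC
from simbaref.kinetics import FengOneTCParams, FengParams, OneTissueIRF
from simbaref.model import SimbaModel, sample_posterior
from simbaref.nls import fit_dataset_nls
from simbaref.simulate import (
    default_frame_schedule,
    default_truth_parameters,
    make_reference_library,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def frames():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def ref_params():
    """A canonical Feng-1TC reference parameter set used across tests."""
    return FengOneTCParams(
        FengParams(100.0, 1.0, 0.5, 4.0, 0.5, 0.05, 0.5), OneTissueIRF(1.0, 0.1)
    )


@pytest.fixture(scope="session")
def ref_tac(ref_params, frames):
    from simbaref.kinetics import feng1tc_predict

    return TAC("s1", "m1", "cerebellum", frames, feng1tc_predict(ref_params, frames))


@pytest.fixture(scope="session")
def library():
    """50 noisy reference TACs with refits (shared across the suite)."""
    return make_reference_library(n=50, seed=7, fit_n_starts=5)


@pytest.fixture(scope="session")
def three_region_design():
    base = default_truth_parameters()
    regions = [r for r in base.regions if r.name in ("DBS", "FC", "OC")]
    return replace(base, n_per_group=10, regions=regions, seed=11)


@pytest.fixture(scope="session")
def small_dataset(three_region_design, library):
    """10+10 subjects x pre/post x 3 regions with ground truth and reference fits."""
    return simulate_dataset(three_region_design, library)


@pytest.fixture(scope="session")
def nls_estimates(small_dataset):
    table, _, ref_fits = small_dataset
    return fit_dataset_nls(table, ref_fits, seed=0)


@pytest.fixture(scope="session")
def model_spec():
    return SimbaSpec(
        covariates={"logBPND": ["group", "post", "group:post"]},
        priors=Priors(
            intercept_mu={
                "logR1": float(np.log(0.95)),
                "logk2prime": float(np.log(0.09)),
                "logBPND": float(np.log(0.8)),
            }
        ),
        mcmc=MCMCOptions(chains=2, warmup=600, samples=600, seed=4),
    )


@pytest.fixture(scope="session")
def lme_null_statistics(library):
    """500 null-simulation replicates of the LME diff-in-diff on true logBPND.

    Shared by the calibration tests: z statistics and p-values under a design
    with no treatment effect (group difference retained), n=10 per group.
    """
    from simbaref.evaluation import lme_contrast

    base = replace(
        default_truth_parameters(), n_per_group=10, treatment_effect_logBPND=0.0
    )
    zs, ps = [], []
    for rep in range(500):
        design = replace(base, seed=20_000 + rep)
        _, truth, _ = simulate_dataset(design, library)
        res = lme_contrast(truth.rename(columns={"true_logBPND": "logBPND"}))
        if res["converged"]:
            zs.append(res["z"])
            ps.append(res["pvalue"])
    return np.asarray(zs), np.asarray(ps)


@pytest.fixture(scope="session")
def fitted_posterior(small_dataset, nls_estimates, model_spec):
    """One MCMC fit of the hierarchical model, shared by the posterior tests."""
    table, _, ref_fits = small_dataset
    design = build_design(table, ref_fits, model_spec)
    model = SimbaModel(design)
    return sample_posterior(model, warm_start_estimates=nls_estimates)
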