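"""Shared fixtures: the two synthetic study ensembles and their mixture fits.

The five-state ensemble mirrors the lifted (GO-BSA) bilayer experiment, the
two-state ensemble the unlifted GO-supported one. Both are expensive enough
(a minute or two for the free-N physical fit) that they are built once per
session and shared across the state-inference and acceptance tests.
"""

import numpy as np
import pytest

import sifa
from sifa import states as st

STUDY_SEED = 1


@pytest.fixture(scope="session")
def cfg5():
    return sifa.RunConfig(seed=STUDY_SEED, scenario="five_state")


@pytest.fixture(scope="session")
def cfg2():
    return sifa.RunConfig(seed=STUDY_SEED, scenario="two_state", n_max=4)


@pytest.fixture(scope="session")
def ensemble5(cfg5):
    return sifa.simulate_traces(
        cfg5.state_model(), cfg5.quench_model(), cfg5.noise_model(),
        n_traces=cfg5.n_traces, duration=cfg5.duration_s, seed=cfg5.seed,
    )


@pytest.fixture(scope="session")
def ensemble2(cfg2):
    return sifa.simulate_traces(
        cfg2.state_model(), cfg2.quench_model(), cfg2.noise_model(),
        n_traces=cfg2.n_traces, duration=cfg2.duration_s, seed=cfg2.seed,
    )


@pytest.fixture(scope="session")
def fit5(ensemble5, cfg5):
    traces, _ = ensemble5
    pdf = st.build_intensity_pdf(traces)
    return st.fit_mixture(
        pdf, n_range=range(1, 8), seed=cfg5.seed, n_init=2,
        method="physical", quench=cfg5.quench_model(), noise=cfg5.noise_model(),
    )


@pytest.fixture(scope="session")
def fit2(ensemble2, cfg2):
    traces, _ = ensemble2
    pdf = st.build_intensity_pdf(traces)
    return st.fit_mixture(
        pdf, n_range=range(1, 5), seed=cfg2.seed, n_init=2,
        background=(cfg2.background_mean, cfg2.background_sd),
        method="physical", quench=cfg2.quench_model(), noise=cfg2.noise_model(),
    )
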