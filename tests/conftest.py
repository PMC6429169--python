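import warnings

import numpy as np
import pytest

import neurosem as ns

# statsmodels emits benign overflow/convergence chatter on near-separated
# logistic fits; keep test output readable
warnings.filterwarnings("ignore", message=".*overflow encountered.*")
warnings.filterwarnings("ignore", message=".*divide by zero encountered.*")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spec():
    """Two groups, five regions, three SNPs."""
    grouping = {"r1": "GA", "r2": "GA", "r3": "GA", "r4": "GB", "r5": "GB"}
    return ns.build_spec(grouping, snp_ids=["s1", "s2", "s3"],
                         region_order=["r1", "r2", "r3", "r4", "r5"])


@pytest.fixture
def small_config():
    """Fast small-scale study condition for unit tests."""
    return ns.SimulationConfig(n_individuals=300, n_snps=6,
                               group_sizes=(4, 3, 3), n_nonzero_a=4)


def random_valid_params(spec, rng):
    """Random SEMParams respecting the sparsity pattern and anchors."""
    B = np.zeros((spec.q, spec.m))
    B[spec.loading_pattern()] = rng.uniform(0.3, 1.8, size=spec.q)
    B[spec.anchor_index, np.arange(spec.m)] = 1.0
    A = rng.normal(scale=0.5, size=(spec.m, spec.p))
    root = rng.normal(size=(spec.p, spec.p + 2))
    sigma_gg = root @ root.T / (spec.p + 2) if spec.p else np.zeros((0, 0))
    return ns.SEMParams(
        A=A, B=B,
        psi=rng.uniform(0.2, 2.0, size=spec.m),
        theta=rng.uniform(0.2, 2.0, size=spec.m),
        sigma_gg=sigma_gg,
    )


@pytest.fixture(scope="session")
def default_study():
    """Twenty replicates of the base study condition, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ns.run_simulation_study(ns.SimulationConfig(), n_replicates=20, seed=7)
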