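"""Shared fixtures: the synthetic trial replica and derived objects.

Session-scoped because the replica, its encoding and the optimized
allocation are deterministic and reused across many tests.
"""

import numpy as np
import pytest

import dsalloc as da


@pytest.fixture(scope="session")
def replica_table():
    return da.generate_trial_replica(da.ReplicaParams(seed=0))


@pytest.fixture(scope="session")
def replica_X(replica_table):
    return da.encode_covariates(replica_table)


@pytest.fixture(scope="session")
def spec_3x54():
    return da.DesignSpec(arm_sizes=(54, 54, 54))


@pytest.fixture(scope="session")
def stratified_spec(replica_table, spec_3x54):
    sizes = replica_table.data["visit_group"].value_counts().to_dict()
    counts = da.even_stratum_arm_counts(sizes, spec_3x54)
    return da.DesignSpec(arm_sizes=(54, 54, 54), stratum_arm_counts=counts)


@pytest.fixture(scope="session")
def optimized(replica_X, spec_3x54):
    """Exchange-optimized allocation of the replica (50 restarts)."""
    return da.exchange_optimize(replica_X, spec_3x54, n_restarts=50, seed=1)


def random_full_rank_instance(rng, N, p, t):
    """Random full-rank X (intercept + p standard-normal columns) and an
    as-even-as-possible t-arm allocation of N subjects."""
    X = np.column_stack([np.ones(N), rng.standard_normal((N, p))])
    base, extra = divmod(N, t)
    sizes = tuple(base + (1 if k < extra else 0) for k in range(t))
    spec = da.DesignSpec(arm_sizes=sizes)
    alloc = da.initial_allocation(spec, rng)
    return X, spec, alloc
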