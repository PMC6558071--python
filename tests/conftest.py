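"""Shared fixtures: small synthetic datasets and the session-scoped power
study used by the acceptance tests (computed once, consumed by several
tests)."""

from __future__ import annotations

import numpy as np
import pytest

from covqtl.data import LongitudinalDataset, MarkerPartition
from covqtl.growth import LogisticParams, TimeGrid, logistic
from covqtl.simulate import (
    ScenarioSpec,
    compute_cell_thresholds,
    run_power_study,
    simulate_dataset,
)

WEEKS = TimeGrid(np.arange(1.0, 10.0))


@pytest.fixture(scope="session")
def weeks() -> TimeGrid:
    return WEEKS


def make_dataset(
    n: int = 60,
    grid: TimeGrid = WEEKS,
    curves=(LogisticParams(55, 12, 0.7), LogisticParams(45, 12, 0.6)),
    mu_z=(4.5, 5.6),
    cov=(6.0, 0.6, 0.4, 1.0),
    seed: int = 0,
    balanced: bool = True,
):
    """Small two-genotype dataset drawn from the generative model; returns
    (dataset, genotype vector, partition)."""
    from covqtl.covariance import CovParams, build_joint_cov

    rng = np.random.default_rng(seed)
    g = np.repeat([0, 1], n // 2) if balanced else rng.integers(0, 2, n)
    T = len(grid)
    mu = np.vstack(
        [
            np.append(logistic(grid.times, curves[0]), mu_z[0]),
            np.append(logistic(grid.times, curves[1]), mu_z[1]),
        ]
    )
    S = build_joint_cov(CovParams(*cov), T)
    Y = mu[g] + rng.standard_normal((n, T + 1)) @ S.cholesky.T
    data = LongitudinalDataset(y=Y[:, :T], z=Y[:, T], grid=grid)
    return data, g, MarkerPartition.from_genotypes(g)


@pytest.fixture()
def small_dataset():
    return make_dataset(n=40, seed=3)


# ---------------------------------------------------------------------------
# session-scoped power study (shared across the acceptance tests)
# ---------------------------------------------------------------------------

POWER_REPS = 200
POWER_SEED = 20260929
# (scenario, n, h2) cells: the four Table-2 target cells plus the scenario-1
# sample-size series used by the ordering checks
POWER_CELLS = [
    (1, 100, 0.05),
    (1, 500, 0.10),
    (4, 500, 0.10),
    (3, 500, 0.05),
    (1, 200, 0.05),
    (1, 500, 0.05),
]


@pytest.fixture(scope="session")
def power_results() -> dict:
    """Power of the joint model and the traditional pair for each simulation
    cell, 200 replicates per cell with shared per-cell thresholds."""
    out = {}
    for k, n, h2 in POWER_CELLS:
        spec = ScenarioSpec.for_scenario(k, n, h2)
        res = run_power_study(
            spec, n_replicates=POWER_REPS, seed=POWER_SEED + 1000 * k + n
        )
        out[(k, n, h2)] = {r.method: r for r in res}
    return out
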