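"""Shared fixtures: small geometries, expanded problems, and helpers."""

import numpy as np
import pytest

from bafsogl import optics, parcels


@pytest.fixture(scope="session")
def probe():
    return optics.build_probe(9, 8, 20.0, 25.0, (760.0, 850.0))


@pytest.fixture(scope="session")
def small_model():
    """Pruned sensitivity model on a small 2-D slab under the standard probe."""
    p = optics.build_probe(9, 8, 20.0, 25.0, (760.0, 850.0))
    grid = optics.slab_grid(9, 3, 10.0, 15.0, 40.0, 2.5)
    model = optics.build_sensitivity_model(p, grid)
    model, _ = optics.prune_voxels(model, 50.0)
    return model


@pytest.fixture(scope="session")
def small_parcellation(small_model):
    return parcels.rectangular_parcellation(small_model.grid, 3, overlap=1)


@pytest.fixture(scope="session")
def small_structure(small_model, small_parcellation):
    _, structure = parcels.expand_overlapping_groups(small_model, small_parcellation)
    return structure


def make_single_group_problem(n_voxels, n_obs=12, rho=0.0, c=1.0, seed=0,
                              adjacency=None, beta_scale=1.0):
    """A one-group expanded problem with a well-conditioned design.

    Returns (y, X, structure, beta_star).  The design is overdetermined so the
    objective has a unique minimizer; beta_star is the generating coefficient
    vector (length 2*n_voxels, HbO block then HbR block).
    """
    rng = np.random.default_rng(seed)
    P = 2 * n_voxels
    X = rng.standard_normal((n_obs, P)) / np.sqrt(n_obs)
    beta_star = beta_scale * rng.standard_normal(P)
    y = X @ beta_star + 0.1 * rng.standard_normal(n_obs)

    if adjacency is None:
        adjacency = np.array([(i, i + 1) for i in range(n_voxels - 1)])
    # one group over a dummy 1-D grid
    grid = optics.VoxelGrid(
        coordinates=np.column_stack(
            [np.arange(n_voxels) * 10.0, np.zeros(n_voxels), np.full(n_voxels, 15.0)]
        ),
        spacing=10.0,
    )
    parc = parcels.Parcellation(
        groups=(np.arange(n_voxels),),
        labels=("g1",),
        adjacency=(np.asarray(adjacency).reshape(-1, 2),),
    )
    wrapped = optics.SensitivityModel(
        jacobian=X,
        probe=optics.build_probe(1, 1, wavelengths=tuple(700.0 + i for i in range(n_obs))),
        grid=grid,
    )
    X_tilde, structure = parcels.expand_overlapping_groups(wrapped, parc, rho=rho, c=c)
    assert np.allclose(X_tilde, X)  # single full group: expansion is identity
    return y, X, structure, beta_star
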