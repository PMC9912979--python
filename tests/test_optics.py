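"""Probe geometry, diffusion sensitivity, Jacobian assembly, whitening."""

import numpy as np
import pytest

from bafsogl import optics
from bafsogl.optics import (
    ChannelData,
    GeometryError,
    OpticalProperties,
    SensitivityModel,
    VoxelGrid,
    assemble_jacobian,
    build_probe,
    prune_voxels,
    roi_sensitivity_table,
    sensitivity_profile,
    slab_grid,
    whiten,
)
from bafsogl.parcels import Parcellation


@pytest.mark.parametrize(
    "n_src,n_det,wavelengths,n_pairs,n_channels",
    [
        (9, 8, (760.0, 850.0), 16, 32),   # the standard forehead montage
        (1, 1, (760.0,), 1, 1),
        (3, 2, (760.0,), 4, 4),           # each detector keeps its two flanking sources
    ],
)
def test_nearest_pair_probe_counts(n_src, n_det, wavelengths, n_pairs, n_channels):
    probe = build_probe(n_src, n_det, 20.0, 25.0, wavelengths)
    assert probe.n_pairs == n_pairs
    assert probe.n_channels == n_channels
    # brute-force check of the nearest rule: every kept pair is minimal for its detector
    for s, d in probe.pairs:
        dists = np.linalg.norm(probe.sources - probe.detectors[d], axis=1)
        assert probe.pair_distance(s, d) <= dists.min() + 1e-9


def test_probe_invalid_geometry():
    with pytest.raises(GeometryError):
        build_probe(3, 2, -1.0, 25.0)
    with pytest.raises(GeometryError):
        build_probe(0, 2)


@pytest.fixture(scope="module")
def optics_props():
    return OpticalProperties.default()


def test_sensitivity_midline_exceeds_lateral(optics_props):
    probe = build_probe(1, 1, 20.0, 25.0, (760.0,))
    mid = (probe.sources[0] + probe.detectors[0]) / 2.0
    grid = VoxelGrid(
        coordinates=np.array([mid + [0, 0, 10.0], mid + [50.0, 0, 10.0]]),
        spacing=10.0,
    )
    prof = sensitivity_profile(probe, grid, optics_props)[760.0]
    assert prof[0, 0] > prof[0, 1] > 0


def test_sensitivity_mirror_symmetry(optics_props):
    probe = build_probe(1, 1, 20.0, 25.0, (760.0,))
    mid = (probe.sources[0] + probe.detectors[0]) / 2.0
    axis = probe.detectors[0] - probe.sources[0]
    axis /= np.linalg.norm(axis)
    grid = VoxelGrid(
        coordinates=np.array([mid + 7.0 * axis + [0, 0, 12.0],
                              mid - 7.0 * axis + [0, 0, 12.0]]),
        spacing=10.0,
    )
    prof = sensitivity_profile(probe, grid, optics_props)[760.0]
    assert prof[0, 0] == pytest.approx(prof[0, 1], rel=1e-10)


def test_sensitivity_matches_hand_greens_product(optics_props):
    """Independent scalar evaluation of the semi-infinite Green's function."""
    wl = 760.0
    mua, musp = optics_props.mua[wl], optics_props.musp[wl]
    probe = build_probe(1, 1, 20.0, 25.0, (wl,))
    voxels = np.array([[12.0, 5.0, 9.0], [3.0, 18.0, 22.0]])
    grid = VoxelGrid(coordinates=voxels, spacing=10.0)
    prof = sensitivity_profile(probe, grid, optics_props)[wl]

    D = 1.0 / (3.0 * (mua + musp))
    mueff = np.sqrt(3.0 * mua * (mua + musp))
    z0 = 1.0 / (mua + musp)
    zb = 2.0 * D

    def g(opt, pt):
        r1 = np.linalg.norm(pt - (opt + [0, 0, z0]))
        r2 = np.linalg.norm(pt - (opt - [0, 0, z0 + 2 * zb]))
        return (np.exp(-mueff * r1) / r1 - np.exp(-mueff * r2) / r2) / (4 * np.pi * D)

    s, d = probe.sources[0], probe.detectors[0]
    for v in range(2):
        expected = g(s, voxels[v]) * g(d, voxels[v]) / g(s, d)
        assert prof[0, v] == pytest.approx(expected, rel=1e-12)
    assert np.all(prof >= 0)


def test_sensitivity_rejects_surface_voxels(optics_props):
    probe = build_probe(1, 1, 20.0, 25.0, (760.0,))
    grid = VoxelGrid(coordinates=np.array([[5.0, 5.0, 0.0]]), spacing=10.0)
    with pytest.raises(GeometryError):
        sensitivity_profile(probe, grid, optics_props)


def test_assemble_jacobian_scales_by_extinction():
    probe = build_probe(1, 1, 20.0, 25.0, (760.0,))
    grid = VoxelGrid(coordinates=np.array([[10.0, 12.5, 15.0]]), spacing=10.0)
    props = OpticalProperties(
        mua={760.0: 0.02}, musp={760.0: 1.0}, extinction={760.0: (1.5, 0.5)}
    )
    model = assemble_jacobian({760.0: np.array([[2.0]])}, props, probe, grid)
    assert model.jacobian == pytest.approx(np.array([[3.0, 1.0]]))

    # equal extinction coefficients -> identical chromophore blocks
    props_eq = OpticalProperties(
        mua={760.0: 0.02}, musp={760.0: 1.0}, extinction={760.0: (0.7, 0.7)}
    )
    m2 = assemble_jacobian({760.0: np.array([[2.0]])}, props_eq, probe, grid)
    assert m2.jacobian[0, 0] == m2.jacobian[0, 1]

    # zero profile -> zero row
    m3 = assemble_jacobian({760.0: np.array([[0.0]])}, props, probe, grid)
    assert np.all(m3.jacobian == 0)


def test_jacobian_finite_nonnegative(small_model):
    assert np.all(np.isfinite(small_model.jacobian))
    assert np.all(small_model.jacobian >= 0)


def test_prune_voxels_distance_rule():
    probe = build_probe(1, 1, 20.0, 25.0, (760.0,))
    mid = (probe.sources[0] + probe.detectors[0]) / 2.0
    coords = np.array([mid + [10.0, 0, 5.0], mid + [40.0, 0, 5.0], mid + [55.0, 0, 5.0]])
    grid = VoxelGrid(coordinates=coords, spacing=10.0)
    model = optics.build_sensitivity_model(probe, grid)

    pruned, kept = prune_voxels(model, 50.0)
    # distances are ~10.3/40.1/55.1 mm -> two voxels survive
    assert list(kept) == [0, 1]
    assert pruned.jacobian.shape == (1, 4)

    same, kept_all = prune_voxels(model, np.inf)
    assert list(kept_all) == [0, 1, 2]
    assert np.array_equal(same.jacobian, model.jacobian)

    with pytest.raises(GeometryError):
        prune_voxels(model, 1.0)


def test_roi_sensitivity_table_scaling(small_model):
    V = small_model.n_voxels
    # hand-built two-ROI split: table = row sums ratio, max exactly 1
    parc = Parcellation(
        groups=(np.arange(V // 2), np.arange(V // 2, V)),
        labels=("left", "right"),
        adjacency=(np.empty((0, 2), int), np.empty((0, 2), int)),
    )
    table = roi_sensitivity_table(small_model, parc)
    sums = [small_model.jacobian[:, np.concatenate([g, V + g])].sum() for g in parc.groups]
    assert table.max() == pytest.approx(1.0)
    assert table["left"] / table["right"] == pytest.approx(sums[0] / sums[1])

    single = Parcellation(
        groups=(np.arange(V),), labels=("all",),
        adjacency=(np.empty((0, 2), int),),
    )
    assert roi_sensitivity_table(small_model, single)["all"] == pytest.approx(1.0)


def test_whiten_identity_and_scaled(small_model):
    N = small_model.n_channels
    y = np.arange(N, dtype=float)

    Xs, ys, W = whiten(small_model, ChannelData(y=y, cov=np.eye(N)))
    assert np.allclose(Xs, small_model.jacobian)
    assert np.allclose(ys, y)

    Xs, ys, W = whiten(small_model, ChannelData(y=y, cov=4.0 * np.eye(N)))
    assert np.allclose(Xs, small_model.jacobian / 2.0)
    assert np.allclose(ys, y / 2.0)


def test_whiten_random_spd_properties(small_model):
    rng = np.random.default_rng(3)
    N = small_model.n_channels
    A = rng.standard_normal((N, N))
    C = A @ A.T + N * np.eye(N)
    y = rng.standard_normal(N)
    Xs, ys, W = whiten(small_model, ChannelData(y=y, cov=C))
    assert np.linalg.norm(W.T @ W - np.linalg.inv(C)) < 1e-8

    # whitened least-squares term equals the C-weighted one, for any beta
    for _ in range(3):
        beta = rng.standard_normal(small_model.n_coefficients)
        r = y - small_model.jacobian @ beta
        assert np.linalg.norm(ys - Xs @ beta) ** 2 == pytest.approx(
            r @ np.linalg.solve(C, r), rel=1e-8
        )


def test_whiten_rejects_indefinite(small_model):
    N = small_model.n_channels
    C = -np.eye(N)
    with pytest.raises(optics.DecompositionError, match="eigenvalue"):
        whiten(small_model, ChannelData(y=np.zeros(N), cov=C))
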