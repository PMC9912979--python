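"""Overlap expansion, contraction, difference matrices and prior covariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bafsogl import optics, parcels
from bafsogl.parcels import (
    InvalidAdjacencyError,
    Parcellation,
    build_group_covariance,
    build_structure_matrix,
    contract_duplicates,
    expand_overlapping_groups,
    grid_adjacency,
    rectangular_parcellation,
)


def _line_model(V, n_obs=6, seed=0):
    rng = np.random.default_rng(seed)
    grid = optics.VoxelGrid(
        coordinates=np.column_stack([np.arange(V) * 10.0, np.zeros(V), np.full(V, 15.0)]),
        spacing=10.0,
    )
    probe = optics.build_probe(1, 1, wavelengths=tuple(700.0 + i for i in range(n_obs)))
    X = rng.standard_normal((n_obs, 2 * V))
    return optics.SensitivityModel(jacobian=X, probe=probe, grid=grid)


class TestExpansion:
    def test_disjoint_groups_are_column_permutation(self):
        model = _line_model(4)
        parc = Parcellation(
            groups=(np.array([0, 1]), np.array([2, 3])),
            labels=("a", "b"),
            adjacency=(np.array([[0, 1]]), np.array([[0, 1]])),
        )
        Xt, structure = expand_overlapping_groups(model, parc)
        assert Xt.shape[1] == 8 == model.n_coefficients
        # every original column appears exactly once
        matches = {
            j: [k for k in range(8) if np.array_equal(Xt[:, k], model.jacobian[:, j])]
            for j in range(8)
        }
        assert all(len(v) == 1 for v in matches.values())

    def test_overlap_duplicates_columns(self):
        model = _line_model(2)
        parc = Parcellation(
            groups=(np.array([0, 1]), np.array([1])),
            labels=("a", "b"),
            adjacency=(np.array([[0, 1]]), np.empty((0, 2), int)),
        )
        Xt, structure = expand_overlapping_groups(model, parc)
        # expanded dimension = sum of group sizes x 2 chromophores
        assert structure.n_expanded == 2 * (2 + 1)
        # voxel 1's HbO column appears twice (once per group)
        hbo1 = model.jacobian[:, 1]
        count = sum(np.array_equal(Xt[:, k], hbo1) for k in range(Xt.shape[1]))
        assert count == 2
        # enumerate (group, voxel, chromophore) triples
        triples = set(zip(structure.col_group, structure.col_voxel, structure.col_chrom))
        assert triples == {(0, 0, 0), (0, 1, 0), (0, 0, 1), (0, 1, 1),
                           (1, 1, 0), (1, 1, 1)}

    def test_expansion_rejects_missing_voxel(self):
        model = _line_model(2)
        parc = Parcellation(
            groups=(np.array([0, 5]),), labels=("a",),
            adjacency=(np.empty((0, 2), int),),
        )
        with pytest.raises(IndexError, match="voxel 5"):
            expand_overlapping_groups(model, parc)

    def test_fit_identity_under_duplication(self):
        """X~ @ b~ always equals X @ contract(b~): duplication preserves the fit."""
        model = _line_model(5, seed=2)
        parc = rectangular_parcellation(model.grid, 2, overlap=1)
        Xt, structure = expand_overlapping_groups(model, parc)
        rng = np.random.default_rng(7)
        for _ in range(5):
            bt = rng.standard_normal(structure.n_expanded)
            assert np.allclose(Xt @ bt, model.jacobian @ contract_duplicates(bt, structure))


class TestContraction:
    def test_sum_convention(self):
        model = _line_model(2)
        parc = Parcellation(
            groups=(np.array([0, 1]), np.array([1])), labels=("a", "b"),
            adjacency=(np.empty((0, 2), int), np.empty((0, 2), int)),
        )
        _, structure = expand_overlapping_groups(model, parc)
        # group a columns: [hbo0, hbo1, hbr0, hbr1]; group b: [hbo1, hbr1]
        bt = np.array([0.1, 0.3, 0.4, 0.7, 0.2, 0.05])
        b = contract_duplicates(bt, structure)
        assert b == pytest.approx([0.1, 0.5, 0.4, 0.75])

    def test_no_overlap_roundtrip_and_zero(self):
        model = _line_model(4, seed=1)
        parc = Parcellation(
            groups=(np.array([0, 1]), np.array([2, 3])), labels=("a", "b"),
            adjacency=(np.empty((0, 2), int), np.empty((0, 2), int)),
        )
        _, structure = expand_overlapping_groups(model, parc)
        rng = np.random.default_rng(0)
        bt = rng.standard_normal(structure.n_expanded)
        b = contract_duplicates(bt, structure)
        assert sorted(np.round(b, 12)) == sorted(np.round(bt, 12))
        assert np.all(contract_duplicates(np.zeros_like(bt), structure) == 0)


class TestStructureMatrix:
    def test_worked_example_five_pairs(self):
        """4 elements, 5 connected pairs: the voxel-level block is 5 x 4."""
        pairs = np.array([[0, 1], [0, 2], [1, 2], [1, 3], [2, 3]])
        D = build_structure_matrix(4, pairs)
        assert D.shape == (10, 8)
        d_vox = D[:5, :4]
        assert np.array_equal(d_vox, D[5:, 4:])      # identical diagonal blocks
        assert np.all(D[:5, 4:] == 0) and np.all(D[5:, :4] == 0)
        for row, (i, j) in zip(d_vox, pairs):
            assert row[i] == 1 and row[j] == -1 and np.abs(row).sum() == 2

    def test_single_voxel_no_pairs(self):
        D = build_structure_matrix(1, np.empty((0, 2), int))
        assert D.shape == (0, 2)

    def test_constant_blocks_annihilated(self):
        pairs = np.array([[0, 1], [1, 2]])
        D = build_structure_matrix(3, pairs)
        beta = np.concatenate([np.full(3, 1.7), np.full(3, -0.4)])
        assert np.allclose(D @ beta, 0)

    def test_self_pair_rejected(self):
        with pytest.raises(InvalidAdjacencyError):
            build_structure_matrix(3, np.array([[1, 1]]))


class TestGroupCovariance:
    def test_identity_case(self):
        assert np.array_equal(build_group_covariance(3, rho=0.0, c=1.0), np.eye(6))

    def test_hand_single_voxel(self):
        S = build_group_covariance(1, rho=-0.75, c=2.0 / 7.0)
        expected = np.array([[1.0, -0.75 * 2 / 7], [-0.75 * 2 / 7, (2 / 7) ** 2]])
        assert S == pytest.approx(expected)
        assert S[0, 1] == pytest.approx(-0.2142857142857143)
        assert S[1, 1] == pytest.approx(0.08163265306122448)

    @given(
        rho=st.floats(-0.99, 0.99),
        c=st.floats(0.05, 5.0),
        nv=st.integers(1, 4),
    )
    @settings(max_examples=50, deadline=None)
    def test_positive_definite_for_valid_params(self, rho, c, nv):
        S = build_group_covariance(nv, rho=rho, c=c)
        np.linalg.cholesky(S)  # raises if not SPD

    def test_invalid_rho_rejected(self):
        with pytest.raises(optics.ConfigurationError):
            build_group_covariance(2, rho=1.0)


class TestAdjacencyAndParcellation:
    def test_grid_adjacency_is_lattice_connectivity(self):
        grid = optics.slab_grid(3, 2, 10.0, 15.0)
        pairs = grid_adjacency(grid, np.arange(6))
        # 3x2 lattice: 2*3 vertical + 2*2... : (3-1)*2 + 3*(2-1) = 7 edges
        assert pairs.shape == (7, 2)
        coords = grid.coordinates
        for i, j in pairs:
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(10.0)

    def test_rectangular_parcellation_overlap(self):
        grid = optics.slab_grid(9, 2, 10.0, 15.0)
        parc = rectangular_parcellation(grid, 3, overlap=1)
        assert parc.n_groups == 3
        sets = [set(g.tolist()) for g in parc.groups]
        assert sets[0] & sets[1] and sets[1] & sets[2]       # margins shared
        assert not (sets[0] & sets[2])                        # non-adjacent disjoint
        assert set().union(*sets) == set(range(18))           # full cover

    def test_remap_after_pruning(self):
        grid = optics.slab_grid(4, 1, 10.0, 15.0)
        parc = Parcellation(
            groups=(np.array([0, 1, 2, 3]),), labels=("g",),
            adjacency=(np.array([[0, 1], [1, 2], [2, 3]]),),
        )
        kept = np.array([0, 1, 3])   # voxel 2 pruned
        new = parc.remap(kept)
        assert list(new.groups[0]) == [0, 1, 2]
        assert new.adjacency[0].tolist() == [[0, 1]]  # pairs touching voxel 2 dropped


def test_fused_penalty_invariant_to_constant_hbo_shift(small_structure):
    """Adding a constant to a group's HbO coefficients never changes ||D b||_1."""
    rng = np.random.default_rng(5)
    for g in range(small_structure.n_groups):
        D = small_structure.D[g]
        m = small_structure.m[g]
        b = rng.standard_normal(m)
        shifted = b.copy()
        shifted[: m // 2] += 3.21
        assert np.abs(D @ b).sum() == pytest.approx(np.abs(D @ shifted).sum())
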