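"""Voxel parcellations, overlap expansion, and the per-group penalty geometry.

Atlas parcellations can assign border voxels to more than one region.  An
overlapping group lasso is equivalent to a regular group lasso after
duplicating the covariates shared between groups: each (group, voxel,
chromophore) triple becomes its own column of the expanded design, the groups
are disjoint in expanded space, and the original coefficient is recovered as
the sum of its duplicated copies (latent-decomposition convention).

Each group g carries two structure objects:

* ``D_g`` -- a difference matrix with one row per connected voxel pair,
  assigning +1/-1 to the paired columns, block-diagonal over the HbO and HbR
  halves (the two chromophores are never cross-coupled, their changes are not
  expected to be equal);
* ``Sigma_g`` -- an SPD prior covariance coupling the HbO and HbR coefficients
  of the same voxel with correlation ``rho`` (anticorrelated during
  activation) and HbR/HbO scale ratio ``c`` (HbR changes are smaller).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .optics import ConfigurationError, SensitivityModel, VoxelGrid

__all__ = [
    "InvalidAdjacencyError",
    "Parcellation",
    "GroupStructure",
    "grid_adjacency",
    "rectangular_parcellation",
    "build_structure_matrix",
    "build_group_covariance",
    "expand_overlapping_groups",
    "contract_duplicates",
]

DEFAULT_RHO = -0.75   # prior HbO-HbR correlation at a voxel
DEFAULT_C = 2.0 / 7.0  # prior HbR/HbO scale ratio (|-2| / 7 simulated amplitudes)


class InvalidAdjacencyError(ValueError):
    """Adjacency list references an invalid voxel pair."""


@dataclass(frozen=True)
class Parcellation:
    """Possibly-overlapping voxel groups with per-group voxel adjacency.

    ``groups[g]`` holds (global) voxel indices; ``adjacency[g]`` holds (q_g, 2)
    pairs of *local* indices into ``groups[g]``.
    """

    groups: tuple            # of int arrays (voxel indices)
    labels: tuple            # of str
    adjacency: tuple         # of (q, 2) int arrays, local indices

    def __post_init__(self):
        if len(self.groups) < 1:
            raise ConfigurationError("parcellation needs at least one group")
        if not (len(self.groups) == len(self.labels) == len(self.adjacency)):
            raise ConfigurationError("groups, labels and adjacency lengths differ")
        groups = tuple(np.asarray(g, dtype=int) for g in self.groups)
        adj = tuple(np.asarray(a, dtype=int).reshape(-1, 2) for a in self.adjacency)
        for label, g, a in zip(self.labels, groups, adj):
            if g.size == 0:
                raise ConfigurationError(f"group {label!r} is empty")
            if a.size and (a.min() < 0 or a.max() >= g.size):
                raise InvalidAdjacencyError(
                    f"group {label!r}: adjacency references voxels outside the group"
                )
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def remap(self, kept: np.ndarray) -> "Parcellation":
        """Re-index onto a pruned grid given surviving original voxel indices.

        Voxels absent from ``kept`` are dropped from their groups together with
        any adjacency pair touching them.  Groups may not end up empty.
        """
        pos = {int(v): i for i, v in enumerate(np.asarray(kept, dtype=int))}
        new_groups, new_adj = [], []
        for g, a in zip(self.groups, self.adjacency):
            keep_local = np.array([i for i, v in enumerate(g) if int(v) in pos], dtype=int)
            local_map = {int(old): new for new, old in enumerate(keep_local)}
            new_groups.append(np.array([pos[int(g[i])] for i in keep_local], dtype=int))
            pairs = [
                (local_map[int(i)], local_map[int(j)])
                for i, j in a
                if int(i) in local_map and int(j) in local_map
            ]
            new_adj.append(np.array(pairs, dtype=int).reshape(-1, 2))
        return Parcellation(tuple(new_groups), self.labels, tuple(new_adj))

    def to_json(self) -> str:
        return json.dumps(
            {
                "groups": {l: g.tolist() for l, g in zip(self.labels, self.groups)},
                "adjacency": {l: a.tolist() for l, a in zip(self.labels, self.adjacency)},
            }
        )

    @classmethod
    def from_json(cls, text: str, grid: VoxelGrid | None = None) -> "Parcellation":
        d = json.loads(text)
        labels = tuple(d["groups"].keys())
        groups = tuple(np.asarray(d["groups"][l], dtype=int) for l in labels)
        if "adjacency" in d and d["adjacency"]:
            adjacency = tuple(
                np.asarray(d["adjacency"][l], dtype=int).reshape(-1, 2) for l in labels
            )
        elif grid is not None:
            adjacency = tuple(grid_adjacency(grid, g) for g in groups)
        else:
            adjacency = tuple(np.empty((0, 2), dtype=int) for _ in labels)
        return cls(groups, labels, adjacency)


def grid_adjacency(grid: VoxelGrid, voxels: np.ndarray) -> np.ndarray:
    """Connected voxel pairs within a group: grid distance equal to the spacing.

    This is 6-connectivity on a 3-D lattice (4-connectivity on a 2-D slab).
    Returns (q, 2) local indices into ``voxels``.
    """
    voxels = np.asarray(voxels, dtype=int)
    coords = grid.coordinates[voxels]
    pairs = []
    for i in range(len(voxels)):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        for j in np.nonzero(np.abs(d - grid.spacing) < 1e-6 * grid.spacing)[0]:
            pairs.append((i, i + 1 + j))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def rectangular_parcellation(
    grid: VoxelGrid,
    n_groups: int,
    overlap: int = 1,
    labels=None,
) -> Parcellation:
    """Synthetic parcellation: rectangular patches sharing a border margin.

    The grid's unique x-coordinate columns are split into ``n_groups``
    near-equal bands; adjacent bands share ``overlap`` voxel columns,
    emulating the border-sharing of atlas parcellations.
    """
    if n_groups < 1:
        raise ConfigurationError("need at least one group")
    xs = np.unique(grid.coordinates[:, 0])
    if n_groups > xs.size:
        raise ConfigurationError("more groups than voxel columns")
    edges = np.linspace(0, xs.size, n_groups + 1).round().astype(int)
    groups, adjacency = [], []
    for g in range(n_groups):
        lo = max(edges[g] - (overlap if g > 0 else 0), 0)
        hi = min(edges[g + 1] + (overlap if g < n_groups - 1 else 0), xs.size)
        band = xs[lo:hi]
        voxels = np.nonzero(np.isin(grid.coordinates[:, 0], band))[0]
        groups.append(voxels)
        adjacency.append(grid_adjacency(grid, voxels))
    if labels is None:
        labels = tuple(f"ROI-{g + 1}" for g in range(n_groups))
    return Parcellation(tuple(groups), tuple(labels), tuple(adjacency))


# ---------------------------------------------------------------------------
# penalty geometry
# ---------------------------------------------------------------------------

def build_structure_matrix(n_voxels: int, pairs: np.ndarray) -> np.ndarray:
    """Spatial difference matrix D_g for one group.

    The voxel-level block has one row per connected pair with +1 and -1 in the
    paired columns; D_g = blockdiag(D_vox, D_vox) so HbO and HbR differences
    are penalized separately.  Shape (2q, 2V_g); with no pairs the fused term
    vanishes (0 rows).
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    q = pairs.shape[0]
    if q and (pairs.min() < 0 or pairs.max() >= n_voxels):
        raise InvalidAdjacencyError("adjacency pair outside the group")
    if np.any(pairs[:, 0] == pairs[:, 1]):
        raise InvalidAdjacencyError("self-pair (v, v) in adjacency")
    d_vox = np.zeros((q, n_voxels))
    d_vox[np.arange(q), pairs[:, 0]] = 1.0
    d_vox[np.arange(q), pairs[:, 1]] = -1.0
    D = np.zeros((2 * q, 2 * n_voxels))
    D[:q, :n_voxels] = d_vox
    D[q:, n_voxels:] = d_vox
    return D


def build_group_covariance(
    n_voxels: int, rho: float = DEFAULT_RHO, c: float = DEFAULT_C
) -> np.ndarray:
    """Hemodynamic prior covariance Sigma_g for one group.

    Coefficient ordering within the group is [HbO voxels | HbR voxels].  Each
    voxel's 2x2 HbO/HbR block is [[1, rho*c], [rho*c, c^2]]; distinct voxels
    are a priori uncorrelated.  SPD for |rho| < 1 and c > 0.
    """
    if not abs(rho) < 1:
        raise ConfigurationError(f"|rho| must be < 1 for positive definiteness, got {rho}")
    if c <= 0:
        raise ConfigurationError("scale ratio c must be positive")
    eye = np.eye(n_voxels)
    return np.block([[eye, rho * c * eye], [rho * c * eye, c * c * eye]])


@dataclass(frozen=True)
class GroupStructure:
    """Expanded (duplicated-covariate) representation of overlapping groups."""

    parcellation: Parcellation
    n_voxels: int                 # V of the (pruned) model
    col_group: np.ndarray         # (P~,) group index of each expanded column
    col_voxel: np.ndarray         # (P~,) original voxel index
    col_chrom: np.ndarray         # (P~,) 0 = HbO, 1 = HbR
    slices: tuple                 # per-group slice into expanded columns
    D: tuple                      # per-group (2q_g, m_g) difference matrices
    sigma: tuple                  # per-group (m_g, m_g) prior covariances
    sigma_inv: tuple = field(repr=False, default=())

    @property
    def n_groups(self) -> int:
        return len(self.slices)

    @property
    def n_expanded(self) -> int:
        return self.col_group.size

    @property
    def n_original(self) -> int:
        return 2 * self.n_voxels

    @property
    def m(self) -> np.ndarray:
        """Per-group expanded sizes m_g (= 2 * voxels in group)."""
        return np.array([s.stop - s.start for s in self.slices])

    @property
    def q(self) -> np.ndarray:
        """Per-group difference counts (rows of D_g, already chromophore-doubled)."""
        return np.array([D.shape[0] for D in self.D])

    def group_coefficients(self, beta_expanded: np.ndarray, g: int) -> np.ndarray:
        return np.asarray(beta_expanded)[..., self.slices[g]]


def expand_overlapping_groups(
    model: SensitivityModel,
    parcellation: Parcellation,
    rho: float = DEFAULT_RHO,
    c: float = DEFAULT_C,
):
    """Duplicate shared covariates: (expanded design X~, GroupStructure).

    The expanded design has one column per (group, voxel, chromophore) triple,
    equal to the original Jacobian column for that (voxel, chromophore); a
    voxel in k groups contributes k duplicated columns per chromophore.  Group
    columns are contiguous, ordered [HbO voxels | HbR voxels] within a group.
    """
    V = model.n_voxels
    X = model.jacobian
    col_group, col_voxel, col_chrom, slices, D_list, S_list = [], [], [], [], [], []
    blocks = []
    start = 0
    for g, (voxels, pairs) in enumerate(zip(parcellation.groups, parcellation.adjacency)):
        voxels = np.asarray(voxels, dtype=int)
        if voxels.size and voxels.max() >= V:
            bad = voxels[voxels >= V][0]
            raise IndexError(
                f"group {parcellation.labels[g]!r} references voxel {bad}, "
                f"but the model has only {V} voxels (pruned?)"
            )
        nv = voxels.size
        blocks.append(np.hstack([X[:, voxels], X[:, V + voxels]]))
        col_group.extend([g] * (2 * nv))
        col_voxel.extend(list(voxels) * 2)
        col_chrom.extend([0] * nv + [1] * nv)
        slices.append(slice(start, start + 2 * nv))
        start += 2 * nv
        D_list.append(build_structure_matrix(nv, pairs))
        S_list.append(build_group_covariance(nv, rho=rho, c=c))

    X_tilde = np.hstack(blocks)
    structure = GroupStructure(
        parcellation=parcellation,
        n_voxels=V,
        col_group=np.asarray(col_group, dtype=int),
        col_voxel=np.asarray(col_voxel, dtype=int),
        col_chrom=np.asarray(col_chrom, dtype=int),
        slices=tuple(slices),
        D=tuple(D_list),
        sigma=tuple(S_list),
        sigma_inv=tuple(np.linalg.inv(S) for S in S_list),
    )
    return X_tilde, structure


def contract_duplicates(beta_expanded: np.ndarray, structure: GroupStructure) -> np.ndarray:
    """Map an expanded estimate back to voxel space (length P = 2V).

    Each original coefficient is the *sum* of its duplicated copies, matching
    the latent decomposition under which the duplicated regular group lasso is
    equivalent to the overlapping one.  Supports batched input (..., P~).
    """
    beta_expanded = np.asarray(beta_expanded, dtype=float)
    if beta_expanded.shape[-1] != structure.n_expanded:
        raise ConfigurationError(
            f"expanded estimate has {beta_expanded.shape[-1]} entries, "
            f"expected {structure.n_expanded}"
        )
    target = structure.col_chrom * structure.n_voxels + structure.col_voxel
    out = np.zeros(beta_expanded.shape[:-1] + (structure.n_original,))
    np.add.at(out, (..., target), beta_expanded)
    return out
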