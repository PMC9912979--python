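"""Optical forward model: probe geometry, sensitivity profiles, Jacobian, whitening.

fNIRS measures optical-density changes between scalp source-detector pairs at two
or more near-infrared wavelengths.  Under the modified Beer-Lambert law the
channel-space measurement is linear in the voxel-space oxy- (HbO) and
deoxy-hemoglobin (HbR) concentration changes::

    y = X (beta + xi) + nu

where ``X`` is the N x P sensitivity (Jacobian) matrix, ``beta`` stacks the HbO
changes of all voxels first and the HbR changes second (P = 2V), ``xi`` is
image-space physiological noise and ``nu`` is channel noise with covariance
``C_nu``.  The forward model here uses the closed-form continuous-wave diffusion
Green's function of a semi-infinite homogeneous medium (the Rytov "banana"
product) rather than a Monte-Carlo or FEM photon-transport solve: it is
deterministic, desk-scale, and preserves the depth and lateral structure an
inverse solver has to cope with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "GeometryError",
    "ConfigurationError",
    "DecompositionError",
    "ProbeLayout",
    "VoxelGrid",
    "OpticalProperties",
    "SensitivityModel",
    "ChannelData",
    "build_probe",
    "slab_grid",
    "sensitivity_profile",
    "assemble_jacobian",
    "build_sensitivity_model",
    "prune_voxels",
    "roi_sensitivity_table",
    "whiten",
]

#: pair-distance tolerance (mm) for the nearest source-detector rule
NEAREST_PAIR_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid probe or grid geometry."""


class ConfigurationError(ValueError):
    """Inconsistent or missing configuration values."""


class DecompositionError(ValueError):
    """A required matrix factorization failed."""


@dataclass(frozen=True)
class ProbeLayout:
    """Optode positions (mm), measured source-detector pairs and wavelengths.

    A *channel* is one source-detector pair at one wavelength; channels are
    ordered wavelength-major (all pairs at ``wavelengths[0]`` first).
    """

    sources: np.ndarray        # (S, 3) mm
    detectors: np.ndarray      # (D, 3) mm
    pairs: tuple               # ((source_idx, detector_idx), ...)
    wavelengths: tuple         # nm

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise GeometryError("duplicate source-detector pairs")
        for s, d in self.pairs:
            if self.pair_distance(s, d) <= 0:
                raise GeometryError(f"pair ({s}, {d}) has non-positive distance")

    def pair_distance(self, s: int, d: int) -> float:
        return float(np.linalg.norm(self.sources[s] - self.detectors[d]))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_channels(self) -> int:
        return len(self.pairs) * len(self.wavelengths)

    def pair_midpoints(self) -> np.ndarray:
        """(n_pairs, 3) midpoints of the measured pairs."""
        return np.array(
            [(self.sources[s] + self.detectors[d]) / 2.0 for s, d in self.pairs]
        )

    def to_dict(self) -> dict:
        return {
            "sources": self.sources.tolist(),
            "detectors": self.detectors.tolist(),
            "pairs": [list(p) for p in self.pairs],
            "wavelengths": list(self.wavelengths),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeLayout":
        return cls(
            sources=np.asarray(d["sources"], dtype=float),
            detectors=np.asarray(d["detectors"], dtype=float),
            pairs=tuple(tuple(p) for p in d["pairs"]),
            wavelengths=tuple(d["wavelengths"]),
        )


@dataclass(frozen=True)
class VoxelGrid:
    """Voxel center coordinates (mm).

    Depth convention: the scalp/probe plane is at depth z = 0 and depth grows
    positive into the tissue.
    """

    coordinates: np.ndarray    # (V, 3) mm
    spacing: float             # mm

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise GeometryError("voxel coordinates must be a non-empty (V, 3) array")
        if len(np.unique(coords, axis=0)) != coords.shape[0]:
            raise GeometryError("voxel coordinates must be unique")
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_voxels(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class OpticalProperties:
    """Per-wavelength tissue optics and hemoglobin extinction coefficients.

    ``mua``/``musp`` are the absorption and reduced scattering coefficients in
    1/mm; ``extinction`` maps wavelength (nm) to ``(eps_HbO, eps_HbR)`` in
    1/(uM*mm), so that ``X @ beta`` is a dimensionless optical-density change
    when ``beta`` is in uM and the path sensitivity is in mm.
    """

    mua: dict = field(default_factory=dict)          # nm -> 1/mm
    musp: dict = field(default_factory=dict)         # nm -> 1/mm
    extinction: dict = field(default_factory=dict)   # nm -> (eps_HbO, eps_HbR)

    def __post_init__(self):
        for wl, v in {**self.mua, **self.musp}.items():
            if v <= 0:
                raise ConfigurationError(f"non-positive optical coefficient at {wl} nm")
        for wl, (eo, er) in self.extinction.items():
            if eo <= 0 or er <= 0:
                raise ConfigurationError(f"non-positive extinction at {wl} nm")

    @classmethod
    def default(cls) -> "OpticalProperties":
        # Literature molar extinction coefficients (base-10, converted from
        # 1/(cm*M) to 1/(uM*mm)) and typical adult-head bulk optics.
        return cls(
            mua={760.0: 0.0187, 850.0: 0.0186},
            musp={760.0: 1.1, 850.0: 1.0},
            extinction={
                760.0: (5.86e-5, 1.5485e-4),
                850.0: (1.058e-4, 6.9132e-5),
            },
        )


@dataclass(frozen=True)
class SensitivityModel:
    """The stacked forward operator of the linear measurement model.

    ``jacobian`` is N x P with P = 2V; columns 0..V-1 are the HbO block and
    columns V..2V-1 the HbR block, matching the stacking of ``beta``.
    """

    jacobian: np.ndarray
    probe: ProbeLayout
    grid: VoxelGrid

    def __post_init__(self):
        X = np.asarray(self.jacobian, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ConfigurationError("Jacobian contains non-finite entries")
        if X.shape != (self.probe.n_channels, 2 * self.grid.n_voxels):
            raise ConfigurationError(
                f"Jacobian shape {X.shape} inconsistent with "
                f"{self.probe.n_channels} channels x 2*{self.grid.n_voxels} voxels"
            )
        object.__setattr__(self, "jacobian", X)

    @property
    def n_channels(self) -> int:
        return self.jacobian.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.grid.n_voxels

    @property
    def n_coefficients(self) -> int:
        return self.jacobian.shape[1]


@dataclass(frozen=True)
class ChannelData:
    """Effect-level channel measurements: vector ``y`` and noise covariance."""

    y: np.ndarray       # (N,)
    cov: np.ndarray     # (N, N) SPD

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float).ravel()
        C = np.asarray(self.cov, dtype=float)
        if C.shape != (y.size, y.size):
            raise ConfigurationError("covariance shape inconsistent with y")
        if not np.allclose(C, C.T, atol=1e-10 * max(1.0, np.abs(C).max())):
            raise ConfigurationError("covariance is not symmetric")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "cov", C)


# ---------------------------------------------------------------------------
# probe construction
# ---------------------------------------------------------------------------

def build_probe(
    n_sources: int,
    n_detectors: int,
    src_spacing: float = 20.0,
    row_gap: float = 25.0,
    wavelengths=(760.0, 850.0),
) -> ProbeLayout:
    """Lay out an interleaved two-row probe and keep only the nearest pairs.

    Sources sit on the line y = 0 spaced ``src_spacing`` mm apart; detectors sit
    on the parallel line y = ``row_gap`` offset half a spacing, so every
    detector has flanking sources at equal minimal distance.  Optical density is
    measured only between each detector and its nearest source(s); ties within
    ``NEAREST_PAIR_TOL`` keep all minimal pairs.  The standard nearest-neighbor
    forehead montage (9 sources, 8 detectors, 20/25 mm) yields 16 pairs and,
    with two wavelengths, 32 channels.
    """
    if n_sources < 1 or n_detectors < 1:
        raise GeometryError("need at least one source and one detector")
    if src_spacing <= 0 or row_gap <= 0:
        raise GeometryError("spacings must be positive")
    if not wavelengths:
        raise ConfigurationError("need at least one wavelength")

    sources = np.column_stack(
        [np.arange(n_sources) * src_spacing,
         np.zeros(n_sources),
         np.zeros(n_sources)]
    ).astype(float)
    detectors = np.column_stack(
        [src_spacing / 2.0 + np.arange(n_detectors) * src_spacing,
         np.full(n_detectors, float(row_gap)),
         np.zeros(n_detectors)]
    ).astype(float)

    pairs = []
    for d in range(n_detectors):
        dist = np.linalg.norm(sources - detectors[d], axis=1)
        dmin = dist.min()
        for s in np.nonzero(dist <= dmin + NEAREST_PAIR_TOL)[0]:
            pairs.append((int(s), int(d)))

    return ProbeLayout(
        sources=sources,
        detectors=detectors,
        pairs=tuple(pairs),
        wavelengths=tuple(float(w) for w in wavelengths),
    )


def slab_grid(
    nx: int,
    ny: int,
    spacing: float = 10.0,
    depth: float = 15.0,
    x0: float = 0.0,
    y0: float = 0.0,
) -> VoxelGrid:
    """Regular nx x ny voxel lattice at a single depth below the probe plane."""
    if nx < 1 or ny < 1 or spacing <= 0:
        raise GeometryError("invalid slab dimensions")
    if depth <= 0:
        raise GeometryError("slab must lie strictly below the surface (depth > 0)")
    xs, ys = np.meshgrid(
        x0 + np.arange(nx) * spacing, y0 + np.arange(ny) * spacing, indexing="ij"
    )
    coords = np.column_stack([xs.ravel(), ys.ravel(), np.full(nx * ny, float(depth))])
    return VoxelGrid(coordinates=coords, spacing=float(spacing))


# ---------------------------------------------------------------------------
# diffusion sensitivity
# ---------------------------------------------------------------------------

def _greens_fluence(optode: np.ndarray, points: np.ndarray, mua: float, musp: float):
    """CW diffusion fluence at ``points`` from an optode on the z=0 surface.

    Semi-infinite homogeneous medium, extrapolated-boundary image source: the
    physical isotropic source sits one transport mean free path z0 below the
    surface, its negative image at -(z0 + 2*zb).
    """
    D = 1.0 / (3.0 * (mua + musp))
    mueff = np.sqrt(3.0 * mua * (mua + musp))
    z0 = 1.0 / (mua + musp)
    zb = 2.0 * D

    real_src = optode + np.array([0.0, 0.0, z0])
    image_src = optode - np.array([0.0, 0.0, z0 + 2.0 * zb])
    r1 = np.linalg.norm(points - real_src, axis=-1)
    r2 = np.linalg.norm(points - image_src, axis=-1)
    if np.any(r1 < 1e-9):
        raise GeometryError("field point coincides with an optode source location")
    return (np.exp(-mueff * r1) / r1 - np.exp(-mueff * r2) / r2) / (4.0 * np.pi * D)


def sensitivity_profile(
    probe: ProbeLayout, grid: VoxelGrid, optics: OpticalProperties
) -> dict:
    """Per-wavelength (n_pairs x V) photon-path sensitivities.

    Entry (c, v) is the Rytov product G(s_c, v) * G(v, d_c) / G(s_c, d_c) of
    semi-infinite diffusion Green's functions -- the familiar "banana" between
    source and detector.  Entries are non-negative, mirror-symmetric about the
    source-detector midplane, and decay monotonically as a voxel moves away from
    the source-detector midline at fixed depth.
    """
    coords = grid.coordinates
    if np.any(coords[:, 2] <= 0):
        raise GeometryError("all voxels must lie strictly below the surface plane")

    profiles = {}
    for wl in probe.wavelengths:
        if wl not in optics.mua or wl not in optics.musp:
            raise ConfigurationError(f"no optical properties for wavelength {wl} nm")
        mua, musp = optics.mua[wl], optics.musp[wl]
        mat = np.empty((probe.n_pairs, grid.n_voxels))
        for c, (s, d) in enumerate(probe.pairs):
            gs = _greens_fluence(probe.sources[s], coords, mua, musp)
            gd = _greens_fluence(probe.detectors[d], coords, mua, musp)
            gsd = _greens_fluence(
                probe.sources[s], probe.detectors[d][None, :], mua, musp
            )[0]
            mat[c] = gs * gd / gsd
        profiles[wl] = mat
    return profiles


def assemble_jacobian(
    profiles: dict,
    optics: OpticalProperties,
    probe: ProbeLayout,
    grid: VoxelGrid,
) -> SensitivityModel:
    """Scale path sensitivities by extinction coefficients into the stacked Jacobian.

    The row for channel (pair c, wavelength l) has HbO-block entries
    ``eps_HbO(l) * profile_l[c, v]`` and HbR-block entries
    ``eps_HbR(l) * profile_l[c, v]``; rows are ordered wavelength-major to match
    :class:`ProbeLayout` channel ordering.
    """
    V = grid.n_voxels
    rows = []
    for wl in probe.wavelengths:
        if wl not in optics.extinction:
            raise ConfigurationError(f"no extinction coefficients for {wl} nm")
        if wl not in profiles:
            raise ConfigurationError(f"no sensitivity profile for {wl} nm")
        eps_hbo, eps_hbr = optics.extinction[wl]
        prof = np.asarray(profiles[wl], dtype=float)
        if prof.shape != (probe.n_pairs, V):
            raise ConfigurationError("profile shape inconsistent with probe/grid")
        rows.append(np.hstack([eps_hbo * prof, eps_hbr * prof]))
    X = np.vstack(rows)
    return SensitivityModel(jacobian=X, probe=probe, grid=grid)


def build_sensitivity_model(
    probe: ProbeLayout, grid: VoxelGrid, optics: OpticalProperties | None = None
) -> SensitivityModel:
    """Convenience: sensitivity profile + Jacobian assembly in one call."""
    optics = optics or OpticalProperties.default()
    return assemble_jacobian(sensitivity_profile(probe, grid, optics), optics, probe, grid)


def prune_voxels(model: SensitivityModel, max_dist: float = 50.0):
    """Drop voxels further than ``max_dist`` mm from every channel midpoint.

    Low-density probes have blind spots: voxels far from all measured channels
    carry essentially no sensitivity and only inflate the inverse problem.
    Distances are measured to the nearest source-detector pair midpoint (a proxy
    for the sensitivity centroid).  Returns the pruned model and the array of
    surviving original voxel indices.
    """
    if max_dist <= 0:
        raise GeometryError("max_dist must be positive")
    mids = model.probe.pair_midpoints()
    coords = model.grid.coordinates
    dmin = np.min(
        np.linalg.norm(coords[:, None, :] - mids[None, :, :], axis=-1), axis=1
    )
    kept = np.nonzero(dmin <= max_dist)[0]
    if kept.size == 0:
        raise GeometryError("voxel pruning removed every voxel")
    V = model.n_voxels
    cols = np.concatenate([kept, V + kept])
    pruned = SensitivityModel(
        jacobian=model.jacobian[:, cols],
        probe=model.probe,
        grid=VoxelGrid(coordinates=coords[kept], spacing=model.grid.spacing),
    )
    return pruned, kept


def roi_sensitivity_table(model: SensitivityModel, parcellation) -> "pd.Series":
    """Scaled per-ROI sensitivity in [0, 1].

    Each region's value is the sum of all Jacobian entries over the region's
    voxels (both chromophore blocks, all channels) divided by the largest such
    sum; the most visible region scores exactly 1.  Used to screen which
    regions a given probe can plausibly detect.
    """
    import pandas as pd

    V = model.n_voxels
    sums = {}
    for label, voxels in zip(parcellation.labels, parcellation.groups):
        voxels = np.asarray(voxels, dtype=int)
        if voxels.size == 0:
            warnings.warn(f"ROI {label!r} contains no voxels; sensitivity set to 0")
            sums[label] = 0.0
            continue
        cols = np.concatenate([voxels, V + voxels])
        sums[label] = float(model.jacobian[:, cols].sum())
    top = max(sums.values()) if sums else 0.0
    if top <= 0:
        raise ConfigurationError("no ROI has positive sensitivity")
    return pd.Series({k: v / top for k, v in sums.items()}, name="scaled_sensitivity")


# ---------------------------------------------------------------------------
# whitening
# ---------------------------------------------------------------------------

def whiten(model: SensitivityModel, data: ChannelData):
    """Decorrelate channel noise: return (X*, y*, W) with W'W = C_nu^{-1}.

    W is taken as L^{-1} for the lower Cholesky factor L of C_nu, so the
    whitened residual covariance is the identity and least squares on
    (X*, y*, I) is equivalent to C_nu-weighted least squares on (X, y, C_nu).
    """
    C = data.cov
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        lam_min = float(np.linalg.eigvalsh(C).min())
        raise DecompositionError(
            f"noise covariance is not positive definite (min eigenvalue {lam_min:.3e})"
        ) from None
    W = solve_triangular(L, np.eye(C.shape[0]), lower=True)
    return W @ model.jacobian, W @ data.y, W
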