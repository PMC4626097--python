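"""Weighted-network core: atlas, connectome, normalized Laplacian, eigen-modes, diffusion.

The dynamical primitive of the whole pipeline is first-order linear diffusion
on a weighted undirected graph, ``dx/dt = -L x``, with ``L`` the symmetric
normalized Laplacian ``I - D^{-1/2} C D^{-1/2}``.  Rate constants are fixed to
1 and absorbed into the time axis (t is in units of the inverse rate), since
every downstream fit statistic is invariant to positive rescaling of time.

The assumed proportionality between regional gray-matter volume and weighted
degree is what collapses the per-region voxel counts into the normalized
Laplacian; it is baked into the operator and never parameterized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HEMISPHERES",
    "LOBES",
    "RegionAtlas",
    "Connectome",
    "LaplacianEigensystem",
    "GraphError",
    "IsolatedRegionError",
    "AsymmetricMatrixError",
    "DisconnectedGraphWarning",
    "weighted_degree",
    "normalized_laplacian",
    "eigendecompose",
    "diffuse",
]

HEMISPHERES = ("left", "right", "midline")
LOBES = ("frontal", "parietal", "occipital", "temporal", "cingulate", "subcortical")

#: eigenvalues with modulus below this are treated as exactly zero
ZERO_EIGENVALUE_TOL = 1e-10


class GraphError(ValueError):
    """Invalid network input."""


class IsolatedRegionError(GraphError):
    """A region has zero weighted degree."""


class AsymmetricMatrixError(GraphError):
    """Connectivity matrix is not symmetric within tolerance."""


class DisconnectedGraphWarning(UserWarning):
    """The graph has more than one connected component."""


@dataclass(frozen=True)
class RegionAtlas:
    """Region labels for an N-region parcellation.

    Parameters
    ----------
    names
        Region label per node, index order defines the node order everywhere.
    hemispheres
        One of ``left``, ``right``, ``midline`` per region.
    lobes
        One of :data:`LOBES` per region.
    homotopic
        Index of the mirror-hemisphere partner region, or ``-1`` for regions
        without one (midline structures).  Must be an involution.
    """

    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    lobes: tuple[str, ...]
    homotopic: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.hemispheres) == len(self.lobes) == len(self.homotopic) == n):
            raise GraphError("atlas columns have inconsistent lengths")
        if len(set(self.names)) != n:
            raise GraphError("duplicate region names in atlas")
        for h in self.hemispheres:
            if h not in HEMISPHERES:
                raise GraphError(f"unknown hemisphere label {h!r}")
        for lb in self.lobes:
            if lb not in LOBES:
                raise GraphError(f"unknown lobe label {lb!r}")
        for i, j in enumerate(self.homotopic):
            if j == -1:
                continue
            if not 0 <= j < n:
                raise GraphError(f"homotopic index {j} of region {i} out of range")
            if self.homotopic[j] != i:
                raise GraphError(
                    f"homotopic mapping is not an involution at regions {i}, {j}"
                )
            if i != j and self.hemispheres[i] == self.hemispheres[j]:
                raise GraphError(
                    f"homotopic partners {i}, {j} lie in the same hemisphere"
                )

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def flip(self, region: int) -> int:
        """Mirror-hemisphere partner of ``region`` (identity for midline)."""
        j = self.homotopic[region]
        return region if j == -1 else j

    def flip_permutation(self) -> np.ndarray:
        """Permutation sending each region to its homotopic partner."""
        return np.array([self.flip(i) for i in range(self.n_regions)], dtype=int)

    def regions_in_lobe(self, lobe: str, hemisphere: str | None = None) -> np.ndarray:
        """Region ids in ``lobe``, optionally restricted to one hemisphere."""
        if lobe not in LOBES:
            raise GraphError(f"unknown lobe label {lobe!r}")
        ids = [
            i
            for i in range(self.n_regions)
            if self.lobes[i] == lobe
            and (hemisphere is None or self.hemispheres[i] == hemisphere)
        ]
        return np.array(ids, dtype=int)


def _check_connectivity_matrix(C: np.ndarray, names: tuple[str, ...] | None) -> None:
    C = np.asarray(C)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise GraphError(f"connectivity matrix must be square, got {C.shape}")
    if not np.all(np.isfinite(C)):
        raise GraphError("connectivity matrix has non-finite entries")
    if np.any(C < 0):
        raise GraphError("connectivity weights must be nonnegative")
    scale = max(float(np.max(np.abs(C))), 1.0)
    if not np.allclose(C, C.T, atol=1e-10 * scale, rtol=0.0):
        raise AsymmetricMatrixError(
            "connectivity matrix is not symmetric; symmetrize upstream explicitly"
        )
    if np.any(np.diag(C) != 0):
        raise GraphError("connectivity matrix must have a zero diagonal")
    deg = C.sum(axis=1)
    dead = np.flatnonzero(deg <= 0)
    if dead.size:
        label = names[dead[0]] if names is not None else f"region {dead[0]}"
        raise IsolatedRegionError(
            f"isolated region with zero weighted degree: {label}"
        )


@dataclass(frozen=True)
class Connectome:
    """Region atlas plus symmetric nonnegative connectivity weights.

    ``delta`` holds the weighted degrees (row sums of ``C``); ``Delta`` the
    corresponding diagonal matrix.  Construction validates symmetry,
    nonnegativity, zero diagonal and strictly positive degrees.
    """

    atlas: RegionAtlas
    C: np.ndarray
    delta: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        C = np.array(self.C, dtype=float)
        if C.shape[0] != self.atlas.n_regions:
            raise GraphError(
                f"matrix size {C.shape[0]} does not match atlas size "
                f"{self.atlas.n_regions}"
            )
        _check_connectivity_matrix(C, self.atlas.names)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "delta", C.sum(axis=1))

    @property
    def n_regions(self) -> int:
        return self.atlas.n_regions

    @property
    def Delta(self) -> np.ndarray:
        return np.diag(self.delta)

    def eigensystem(self) -> "LaplacianEigensystem":
        """Normalized Laplacian and its full eigendecomposition."""
        return eigendecompose(normalized_laplacian(self), degrees=self.delta)


@dataclass(frozen=True)
class LaplacianEigensystem:
    """Symmetric normalized Laplacian with ascending eigen-modes.

    ``lambdas`` are ascending in ``[0, 2]``; the columns of ``U`` are the
    orthonormal eigen-modes, sign-fixed so the first component of largest
    magnitude is positive (eigenvector sign is arbitrary; all downstream
    statistics are sign-invariant, the fix only makes runs reproducible).
    """

    L: np.ndarray
    lambdas: np.ndarray
    U: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.lambdas.shape[0]

    @property
    def n_zero_modes(self) -> int:
        """Number of numerically-zero eigenvalues (= connected components)."""
        return int(np.sum(np.abs(self.lambdas) < ZERO_EIGENVALUE_TOL))

    def nonzero_modes(self) -> np.ndarray:
        """Indices of modes with numerically nonzero eigenvalue."""
        return np.flatnonzero(np.abs(self.lambdas) >= ZERO_EIGENVALUE_TOL)


def weighted_degree(connectome: Connectome) -> np.ndarray:
    """Weighted degree of each region: the sum of its connection weights."""
    return connectome.delta.copy()


def normalized_laplacian(connectome: Connectome) -> np.ndarray:
    """Symmetric normalized Laplacian ``I - D^{-1/2} C D^{-1/2}``."""
    d_isqrt = 1.0 / np.sqrt(connectome.delta)
    L = -d_isqrt[:, None] * connectome.C * d_isqrt[None, :]
    np.fill_diagonal(L, 1.0)
    return 0.5 * (L + L.T)  # kill rounding asymmetry


def eigendecompose(
    L: np.ndarray, degrees: np.ndarray | None = None
) -> LaplacianEigensystem:
    """Full symmetric eigendecomposition with ascending eigenvalues.

    Eigenvector signs are normalized (component of largest magnitude made
    positive).  More than one numerically-zero eigenvalue triggers a
    :class:`DisconnectedGraphWarning`; eigen-mode formulas downstream remain
    valid, but reports should flag the condition.
    """
    L = np.asarray(L, dtype=float)
    scale = max(float(np.max(np.abs(L))), 1.0)
    if not np.allclose(L, L.T, atol=1e-10 * scale, rtol=0.0):
        raise AsymmetricMatrixError("Laplacian is not symmetric within tolerance")
    lambdas, U = np.linalg.eigh(0.5 * (L + L.T))
    lambdas = np.where(np.abs(lambdas) < ZERO_EIGENVALUE_TOL, 0.0, lambdas)
    # reproducible sign convention
    anchors = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[anchors, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs[None, :]
    eig = LaplacianEigensystem(L=L, lambdas=lambdas, U=U)
    if eig.n_zero_modes > 1:
        warnings.warn(
            f"graph has {eig.n_zero_modes} connected components",
            DisconnectedGraphWarning,
            stacklevel=2,
        )
    if degrees is not None:
        sq = np.sqrt(np.asarray(degrees, dtype=float))
        sq /= np.linalg.norm(sq)
        if abs(abs(float(sq @ U[:, 0])) - 1.0) > 1e-8 and eig.n_zero_modes == 1:
            warnings.warn(
                "first eigen-mode deviates from the sqrt-degree vector",
                UserWarning,
                stacklevel=2,
            )
    return eig


def diffuse(
    eig: LaplacianEigensystem, x0: np.ndarray, beta_t: float
) -> np.ndarray:
    """Evolve ``dx/dt = -L x`` for dimensionless time ``beta_t``.

    Closed form via the eigen-modes: ``x(t) = sum_i exp(-lambda_i t) u_i (u_i' x0)``.
    """
    if beta_t < 0:
        raise GraphError(f"diffusion time must be nonnegative, got {beta_t}")
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (eig.n_regions,):
        raise GraphError(
            f"state vector has shape {x0.shape}, expected ({eig.n_regions},)"
        )
    coeffs = np.exp(-eig.lambdas * beta_t) * (eig.U.T @ x0)
    return eig.U @ coeffs
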