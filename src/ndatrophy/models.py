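"""The two competing atrophy predictors.

Model 1 treats atrophy as the lifetime integral of diffusing activity from a
seed configuration; the integral evaluates to a partial eigen-mode sum of the
Laplacian pseudo-inverse applied to the seed.  Model 2 treats atrophy itself
as the diffusing quantity and integrates the heat kernel up to a finite
diffusion depth ``t``, so Model 1 is Model 2 evaluated at ``t = infinity``.

The uniform (zero-eigenvalue) mode is excluded from both models by default:
its contribution to the time integral grows without bound and it represents
uniform recruitment of the whole network, which carries no pattern
information.  ``include_uniform_mode=True`` re-adds the analytic limit
``t * u1 (u1' y0)`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .graph_core import GraphError, LaplacianEigensystem

__all__ = [
    "SeedVector",
    "AtrophyEstimate",
    "model1_atrophy",
    "model2_atrophy",
    "model2_trajectory",
    "default_t_grid",
]


@dataclass(frozen=True)
class SeedVector:
    """Initial configuration of the spread process.

    ``values`` must be nonnegative with at least one positive entry;
    ``description`` records provenance (e.g. ``"bilateral temporal"`` or
    ``"node: Hippocampus-L"``).
    """

    values: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise GraphError("seed vector must be one-dimensional")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise GraphError("seed vector entries must be finite and nonnegative")
        if not np.any(v > 0):
            raise GraphError("seed vector must have at least one positive entry")
        object.__setattr__(self, "values", v)

    @classmethod
    def unit(cls, n_regions: int, region: int, description: str = "") -> "SeedVector":
        """Unit seed: 1 at ``region``, 0 elsewhere."""
        if not 0 <= region < n_regions:
            raise GraphError(f"seed region {region} out of range [0, {n_regions})")
        v = np.zeros(n_regions)
        v[region] = 1.0
        return cls(v, description or f"node: {region}")

    @classmethod
    def from_regions(
        cls, n_regions: int, regions: np.ndarray, description: str = ""
    ) -> "SeedVector":
        """Indicator seed over a set of regions."""
        regions = np.asarray(regions, dtype=int)
        if regions.size == 0:
            raise GraphError("seed region set is empty")
        v = np.zeros(n_regions)
        v[regions] = 1.0
        return cls(v, description)


@dataclass(frozen=True)
class AtrophyEstimate:
    """A model's predicted per-region atrophy pattern (arbitrary scale)."""

    values: np.ndarray
    model: Literal["model1", "model2"]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise GraphError("atrophy estimate has non-finite entries")
        object.__setattr__(self, "values", v)


def _mode_indices(eig: LaplacianEigensystem) -> np.ndarray:
    """Modes entering the sums: all with numerically nonzero eigenvalue.

    The uniform mode (and any extra zero modes of a disconnected graph) is
    skipped; without this the time integrals diverge.
    """
    return eig.nonzero_modes()


def model1_atrophy(
    eig: LaplacianEigensystem, x0: SeedVector, K: int
) -> AtrophyEstimate:
    """Activity-spread atrophy: partial pseudo-inverse sum over modes 2..K.

    ``K`` counts the largest included 1-based mode index, so ``K = 2`` uses the
    single mode ``u_2`` and ``K = n_regions`` recovers the full pseudo-inverse
    applied to the seed (up to numerically-zero modes, which are skipped).
    """
    n = eig.n_regions
    if not 2 <= K <= n:
        raise GraphError(f"K must lie in [2, {n}], got {K}")
    modes = _mode_indices(eig)
    modes = modes[modes <= K - 1]  # 1-based mode K -> 0-based index K-1
    U = eig.U[:, modes]
    coeffs = (U.T @ x0.values) / eig.lambdas[modes]
    return AtrophyEstimate(U @ coeffs, model="model1", params={"K": K})


def _phi2_coefficients(
    lambdas: np.ndarray, t: np.ndarray | float
) -> np.ndarray:
    """Per-mode weight ``(1 - exp(-lambda t)) / lambda`` (nonzero lambdas)."""
    t = np.asarray(t, dtype=float)
    return -np.expm1(-np.multiply.outer(lambdas, t)) / lambdas.reshape(
        lambdas.shape + (1,) * t.ndim
    )


def model2_atrophy(
    eig: LaplacianEigensystem,
    y0: SeedVector,
    t: float,
    include_uniform_mode: bool = False,
) -> AtrophyEstimate:
    """Degenerative-spread atrophy at diffusion depth ``t``.

    Closed form ``sum_i (1 - exp(-lambda_i t)) / lambda_i * u_i (u_i' y0)``
    over the nonzero modes; the zero-mode analytic limit ``t u_1 (u_1' y0)``
    is added only when ``include_uniform_mode`` is set.
    """
    if t < 0:
        raise GraphError(f"diffusion depth must be nonnegative, got {t}")
    modes = _mode_indices(eig)
    U = eig.U[:, modes]
    coeffs = _phi2_coefficients(eig.lambdas[modes], float(t)).ravel()
    values = U @ (coeffs * (U.T @ y0.values))
    if include_uniform_mode:
        zero = np.flatnonzero(np.abs(eig.lambdas) < 1e-10)
        Uz = eig.U[:, zero]
        values = values + t * (Uz @ (Uz.T @ y0.values))
    return AtrophyEstimate(values, model="model2", params={"t": float(t)})


def model2_trajectory(
    eig: LaplacianEigensystem,
    y0: SeedVector,
    t_grid: np.ndarray,
    include_uniform_mode: bool = False,
) -> list[AtrophyEstimate]:
    """Model-2 estimates at every depth of an ascending grid."""
    M = model2_trajectory_matrix(eig, y0, t_grid, include_uniform_mode)
    t_grid = np.asarray(t_grid, dtype=float)
    return [
        AtrophyEstimate(M[:, k], model="model2", params={"t": float(t_grid[k])})
        for k in range(t_grid.size)
    ]


def model2_trajectory_matrix(
    eig: LaplacianEigensystem,
    y0: SeedVector,
    t_grid: np.ndarray,
    include_uniform_mode: bool = False,
) -> np.ndarray:
    """Vectorized trajectory: column k is the Model-2 pattern at ``t_grid[k]``."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise GraphError("diffusion-depth grid is empty")
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) < 0) or np.any(t_grid < 0):
        raise GraphError("diffusion-depth grid must be ascending and nonnegative")
    modes = _mode_indices(eig)
    U = eig.U[:, modes]
    F = _phi2_coefficients(eig.lambdas[modes], t_grid)  # (modes, T)
    M = U @ (F * (U.T @ y0.values)[:, None])
    if include_uniform_mode:
        zero = np.flatnonzero(np.abs(eig.lambdas) < 1e-10)
        Uz = eig.U[:, zero]
        M = M + np.outer(Uz @ (Uz.T @ y0.values), t_grid)
    return M


def default_t_grid() -> np.ndarray:
    """Default diffusion-depth sampling: 900 points on [0, 100] plus 100 on
    [100.01, 500]."""
    return np.concatenate(
        [np.linspace(0.0, 100.0, 900), np.linspace(100.01, 500.0, 100)]
    )
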