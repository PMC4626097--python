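"""Measured atrophy from cohort volumetrics.

Group atrophy is the per-region two-sample t-statistic of healthy minus
patient volumes (unpooled variances), after side-flipping right-focus
patients so every epileptogenic focus sits in the left ("ipsilateral")
hemisphere.  Positive values mean smaller volumes in patients, i.e. atrophy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import GraphError, RegionAtlas

__all__ = [
    "VolumetricsTable",
    "AtrophyVector",
    "side_flip",
    "two_sample_tstat",
    "measured_atrophy",
]

GROUPS = ("healthy", "patient")
FOCUS_SIDES = ("left", "right", "none")


@dataclass(frozen=True)
class VolumetricsTable:
    """Per-subject regional volumes with group and focus-laterality labels."""

    subject_ids: tuple[str, ...]
    groups: tuple[str, ...]
    focus_sides: tuple[str, ...]
    volumes: np.ndarray  # subjects x regions, strictly positive

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        V = np.asarray(self.volumes, dtype=float)
        if V.ndim != 2 or V.shape[0] != n:
            raise GraphError(
                f"volumes must be a {n} x N matrix, got shape {V.shape}"
            )
        if len(self.groups) != n or len(self.focus_sides) != n:
            raise GraphError("label columns have inconsistent lengths")
        for g in self.groups:
            if g not in GROUPS:
                raise GraphError(f"unknown group label {g!r}")
        for g, s in zip(self.groups, self.focus_sides):
            if s not in FOCUS_SIDES:
                raise GraphError(f"unknown focus side {s!r}")
            if g == "healthy" and s != "none":
                raise GraphError("healthy subjects must have focus_side='none'")
            if g == "patient" and s == "none":
                raise GraphError("patients must have a left or right focus side")
        if not np.all(np.isfinite(V)) or np.any(V <= 0):
            raise GraphError("all volumes must be finite and strictly positive")
        object.__setattr__(self, "volumes", V)

    @property
    def n_regions(self) -> int:
        return self.volumes.shape[1]

    def group_volumes(self, group: str) -> np.ndarray:
        mask = np.array([g == group for g in self.groups])
        return self.volumes[mask]

    def normalized_by_icv(self, icv: np.ndarray) -> "VolumetricsTable":
        """Per-subject division by intracranial volume (optional)."""
        icv = np.asarray(icv, dtype=float)
        if icv.shape != (len(self.subject_ids),) or np.any(icv <= 0):
            raise GraphError("ICV must be one positive value per subject")
        return VolumetricsTable(
            self.subject_ids, self.groups, self.focus_sides,
            self.volumes / icv[:, None],
        )


def side_flip(table: VolumetricsTable, atlas: RegionAtlas) -> VolumetricsTable:
    """Mirror right-focus patients so all foci are ipsilateral-left.

    Homotopic region columns are swapped for every right-focus patient, whose
    label becomes ``left``.  Healthy subjects and midline regions are
    untouched.  A non-midline region without a homotopic partner is an error:
    flipping would silently misalign it.
    """
    if atlas.n_regions != table.n_regions:
        raise GraphError("atlas and volumetrics table disagree on region count")
    for i in range(atlas.n_regions):
        if atlas.homotopic[i] == -1 and atlas.hemispheres[i] != "midline":
            raise GraphError(
                f"region {atlas.names[i]} has no homotopic partner and is not midline"
            )
    perm = atlas.flip_permutation()
    V = table.volumes.copy()
    sides = list(table.focus_sides)
    for s, (g, side) in enumerate(zip(table.groups, table.focus_sides)):
        if g == "patient" and side == "right":
            V[s] = V[s, perm]
            sides[s] = "left"
    return VolumetricsTable(table.subject_ids, table.groups, tuple(sides), V)


@dataclass(frozen=True)
class AtrophyVector:
    """Per-region atrophy t-statistics; positive = volume loss in patients."""

    values: np.ndarray
    group_sizes: tuple[int, int]  # (n_healthy, n_patient)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise GraphError("atrophy vector has non-finite entries")
        object.__setattr__(self, "values", v)


def two_sample_tstat(
    healthy: np.ndarray,
    patient: np.ndarray,
    region_names: tuple[str, ...] | None = None,
) -> AtrophyVector:
    """Welch-style two-sample t-statistic per region, healthy minus patient.

    ``s = (mean_x - mean_y) / sqrt(var_x/n + var_y/m)`` with unbiased sample
    variances; ``x`` is the healthy group so positive ``s`` indicates atrophy.
    """
    x = np.asarray(healthy, dtype=float)
    y = np.asarray(patient, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[1] != y.shape[1]:
        raise GraphError("group matrices must be 2-D with matching region counts")
    n, m = x.shape[0], y.shape[0]
    if n < 2 or m < 2:
        raise GraphError("each group needs at least two subjects")
    se2 = x.var(axis=0, ddof=1) / n + y.var(axis=0, ddof=1) / m
    degenerate = np.flatnonzero(se2 <= 0)
    if degenerate.size:
        r = degenerate[0]
        label = region_names[r] if region_names is not None else f"region {r}"
        raise GraphError(f"zero pooled variance in {label}")
    s = (x.mean(axis=0) - y.mean(axis=0)) / np.sqrt(se2)
    return AtrophyVector(s, group_sizes=(n, m))


def measured_atrophy(
    table: VolumetricsTable,
    atlas: RegionAtlas,
    flip: bool = True,
    icv: np.ndarray | None = None,
) -> AtrophyVector:
    """Full group-atrophy derivation: optional ICV scaling, side-flip, t-stats."""
    if icv is not None:
        table = table.normalized_by_icv(icv)
    if flip:
        table = side_flip(table, atlas)
    return two_sample_tstat(
        table.group_volumes("healthy"),
        table.group_volumes("patient"),
        region_names=atlas.names,
    )
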