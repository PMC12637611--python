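"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelVolume",
    "FitResult",
    "FateLabel",
    "StateFeatures",
    "InsufficientDataError",
    "FATE_LABELS",
    "MYELOID_STATES",
]

#: The four fate categories a lesion trajectory can receive.
FATE_LABELS = ("progressing", "regressing_partial", "regressing_complete", "stable")

#: The four myeloid organizational states, ordered by increasing infiltration density.
MYELOID_STATES = ("basally_confined", "scattered", "multifocal", "confluent")


class InsufficientDataError(ValueError):
    """Raised when a trajectory has too few uncensored points to fit."""


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D scalar grid with physical voxel size.

    Parameters
    ----------
    values : ndarray, shape (z, y, x)
        Non-negative, finite intensities.
    voxel_size : tuple of float
        Edge length of one voxel per axis in micrometres, ordered (z, y, x).
    channel : str
        Channel label, e.g. ``"GFP"`` or ``"SHG"``.
    week : float, optional
        Imaging-session week, if the volume belongs to a time course.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = ""
    week: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"values must be 3D (z, y, x); got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if np.any(values < 0):
            raise ValueError("values must be non-negative")
        vs = tuple(float(s) for s in self.voxel_size)
        if len(vs) != 3 or any(s <= 0 for s in vs):
            raise ValueError(f"voxel_size must be 3 strictly positive lengths; got {self.voxel_size}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of a single voxel in cubic micrometres."""
        return float(np.prod(self.voxel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class FitResult:
    """Ordinary-least-squares fit of log2 volume on week.

    ``a`` is the intercept (log2 um^3), ``b`` the slope (log2 um^3 per week) and
    ``r2`` the coefficient of determination, defined as 0 for a zero-variance
    response.
    """

    a: float
    b: float
    r2: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 must lie in [0, 1]; got {self.r2}")


@dataclass(frozen=True)
class FateLabel:
    """Fate assigned to a lesion trajectory.

    ``endpoint_ratio`` is endpoint volume over peak volume, capped at 1.
    """

    label: str
    peak_volume: float
    endpoint_ratio: float

    def __post_init__(self) -> None:
        if self.label not in FATE_LABELS:
            raise ValueError(f"unknown fate label {self.label!r}")
        if not (0.0 <= self.endpoint_ratio <= 1.0):
            raise ValueError("endpoint_ratio must lie in [0, 1]")

    @property
    def is_regressing(self) -> bool:
        return self.label.startswith("regressing")


@dataclass(frozen=True)
class StateFeatures:
    """Per-lesion features feeding the four-state myeloid classifier.

    Attributes
    ----------
    displacement : float
        Intratumoral myeloid volume as percent of lesion volume, in [0, 100].
    n_niche_components : int
        Number of niche-forming (>= 5000 um^3 by default) myeloid components.
    largest_component_fraction : float
        Volume of the largest component over total intratumoral myeloid volume.
    basal_fraction : float
        Fraction of myeloid voxels lying within the basal band above the
        basement membrane.
    """

    displacement: float
    n_niche_components: int
    largest_component_fraction: float
    basal_fraction: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.displacement, self.largest_component_fraction, self.basal_fraction]).all():
            raise ValueError("features must be finite")
        if not (0.0 <= self.displacement <= 100.0):
            raise ValueError("displacement must lie in [0, 100]")
        for name in ("largest_component_fraction", "basal_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_niche_components < 0:
            raise ValueError("n_niche_components must be non-negative")
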