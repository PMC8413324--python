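"""Shared containers for image stacks, label volumes and 3D point patterns.

Coordinate convention used throughout the package: ``x`` is the in-plane axis
pointing toward the pial surface, ``y`` the orthogonal in-plane axis, and
``z`` the sectioning (stack) axis.  All public coordinates and spacings are in
micrometres.  Voxel arrays are indexed ``[z, y, x]`` (section, row, column)
while spacing tuples are given in axis order ``(dx, dy, dz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Box3D", "ImageStack", "MaskStack", "LabelVolume", "PointPattern3D"]


@dataclass(frozen=True)
class Box3D:
    """Axis-aligned box observation window, bounds in micrometres."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate window: lo={self.lo}, hi={self.hi}")

    @classmethod
    def from_lengths(cls, lengths) -> "Box3D":
        lx, ly, lz = (float(v) for v in lengths)
        return cls((0.0, 0.0, 0.0), (lx, ly, lz))

    @property
    def sides(self) -> np.ndarray:
        return np.asarray(self.hi, dtype=float) - np.asarray(self.lo, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.sides))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((pts >= lo) & (pts <= hi), axis=1)


def _check_spacing(spacing) -> tuple[float, float, float]:
    dx, dy, dz = (float(s) for s in spacing)
    if min(dx, dy, dz) <= 0:
        raise ValueError(f"voxel spacing must be strictly positive, got {spacing}")
    return (dx, dy, dz)


@dataclass
class ImageStack:
    """3D grayscale intensity grid with physical voxel spacing.

    ``data`` is indexed ``[z, y, x]``; ``spacing`` is ``(dx, dy, dz)`` in μm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageStack.data must be 3D (z, y, x)")
        self.spacing = _check_spacing(self.spacing)

    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (x, y, z) in μm."""
        nz, ny, nx = self.data.shape
        dx, dy, dz = self.spacing
        return (nx * dx, ny * dy, nz * dz)


@dataclass
class MaskStack:
    """Binary 0/1 stack (1 = cell pixel), same layout as :class:`ImageStack`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("MaskStack.data must be 3D (z, y, x)")
        vals = np.unique(arr)
        if vals.size and not np.isin(vals, (0, 1, 255)).all():
            raise ValueError("mask values must be binary (0/1 or 0/255)")
        self.data = (arr > 0).astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelVolume:
    """Labelled 3D grid (0 = background, objects numbered 1..n)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    edge_labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelVolume.data must be 3D (z, y, x)")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("labels must be integers")
        self.spacing = _check_spacing(self.spacing)

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.data)
        return lab[lab > 0]

    @property
    def n_objects(self) -> int:
        return int(self.labels.size)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


class PointPattern3D:
    """Point pattern in an axis-aligned box window; coordinates in μm."""

    def __init__(self, points: np.ndarray, window: Box3D,
                 marks: np.ndarray | None = None):
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        if points.size and not window.contains(points).all():
            raise ValueError("all points must lie inside the window")
        self.points = points
        self.window = window
        self.marks = None if marks is None else np.asarray(marks)
        if self.marks is not None and len(self.marks) != len(points):
            raise ValueError("marks must match number of points")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def intensity(self) -> float:
        """Estimated intensity ρ̂ = n / |W| in μm⁻³."""
        return self.n / self.window.volume

    def translated(self, shift) -> "PointPattern3D":
        shift = np.asarray(shift, dtype=float)
        win = Box3D(tuple(np.asarray(self.window.lo) + shift),
                    tuple(np.asarray(self.window.hi) + shift))
        return PointPattern3D(self.points + shift, win, self.marks)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PointPattern3D(n={self.n}, window={self.window.lo}-"
                f"{self.window.hi})")
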