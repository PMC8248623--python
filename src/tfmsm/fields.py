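"""Container types shared across the pipeline.

Coordinate convention (used consistently by every module): ``x`` is the
column index, ``y`` is the row index, and ``y`` increases downward.  Arrays
are indexed ``[row, col]`` = ``[y, x]``.  All physical lengths carried by the
containers are in micrometres unless a docstring says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ImagePair",
    "VectorField2D",
    "StressTensorField",
    "StrainTensorField",
    "MaskSet",
]


@dataclass
class ImagePair:
    """A tensed/relaxed pair of substrate (bead) images.

    Parameters
    ----------
    tensed, relaxed:
        2D grayscale intensity arrays of identical shape.  ``tensed`` is the
        image with cells attached and pulling; ``relaxed`` the force-free
        reference after cell detachment.
    pixel_size:
        Physical size of one pixel in micrometres.
    """

    tensed: np.ndarray
    relaxed: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.tensed = np.asarray(self.tensed, dtype=float)
        self.relaxed = np.asarray(self.relaxed, dtype=float)
        if self.tensed.ndim != 2 or self.relaxed.ndim != 2:
            raise ValueError("images must be 2D grayscale arrays")
        if self.tensed.shape != self.relaxed.shape:
            raise ValueError(
                f"image shapes differ: {self.tensed.shape} vs {self.relaxed.shape}"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tensed.shape


@dataclass
class VectorField2D:
    """A gridded 2D vector field (deformation in um, or traction in Pa).

    ``vx``/``vy`` are the x- (column direction) and y- (row direction)
    components sampled on a regular grid with physical spacing
    ``grid_spacing`` (um).  ``origin_offset`` locates grid point ``[0, 0]``
    in image pixel coordinates ``(x, y)`` so PIV grids can be registered
    back onto the source images.
    """

    vx: np.ndarray
    vy: np.ndarray
    grid_spacing: float
    origin_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.shape != self.vy.shape:
            raise ValueError("vx and vy must have equal shape")
        if not self.grid_spacing > 0:
            raise ValueError("grid_spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vx.shape

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def copy(self) -> "VectorField2D":
        return VectorField2D(
            self.vx.copy(), self.vy.copy(), self.grid_spacing, self.origin_offset
        )

    def save(self, basepath: str | Path) -> tuple[Path, Path]:
        """Save components as a pair of ``.npy`` files (``<base>_x/_y.npy``)."""
        base = Path(basepath)
        px, py = base.with_name(base.name + "_x.npy"), base.with_name(base.name + "_y.npy")
        np.save(px, self.vx)
        np.save(py, self.vy)
        return px, py

    @classmethod
    def load(
        cls, basepath: str | Path, grid_spacing: float,
        origin_offset: tuple[float, float] = (0.0, 0.0),
    ) -> "VectorField2D":
        base = Path(basepath)
        vx = np.load(base.with_name(base.name + "_x.npy"))
        vy = np.load(base.with_name(base.name + "_y.npy"))
        return cls(vx, vy, grid_spacing, origin_offset)


@dataclass
class StressTensorField:
    """Per-pixel symmetric 2x2 sheet stress tensor in N/m.

    The off-diagonal component is stored once (sigma_xy == sigma_yx by
    construction).  ``mask`` marks pixels where the tensor is defined
    (the FEM region); outside the mask the arrays hold zeros.
    """

    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    grid_spacing: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sxx = np.asarray(self.sxx, dtype=float)
        self.syy = np.asarray(self.syy, dtype=float)
        self.sxy = np.asarray(self.sxy, dtype=float)
        if not (self.sxx.shape == self.syy.shape == self.sxy.shape):
            raise ValueError("stress component shapes differ")
        if self.mask is None:
            self.mask = np.ones(self.sxx.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.sxx.shape:
                raise ValueError("mask shape differs from stress components")
        if not self.grid_spacing > 0:
            raise ValueError("grid_spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sxx.shape

    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        """Principal stresses (sigma1 >= sigma2) of the 2x2 tensor, per pixel."""
        center = 0.5 * (self.sxx + self.syy)
        radius = np.sqrt((0.5 * (self.sxx - self.syy)) ** 2 + self.sxy**2)
        return center + radius, center - radius

    @property
    def mean_normal(self) -> np.ndarray:
        """(sigma1 + sigma2)/2 == (sxx + syy)/2, per pixel."""
        return 0.5 * (self.sxx + self.syy)

    @property
    def max_shear(self) -> np.ndarray:
        """(sigma1 - sigma2)/2, per pixel."""
        s1, s2 = self.principal()
        return 0.5 * (s1 - s2)

    def save(self, basepath: str | Path) -> None:
        base = Path(basepath)
        for name, arr in (("xx", self.sxx), ("yy", self.syy), ("xy", self.sxy)):
            np.save(base.with_name(base.name + f"_{name}.npy"), arr)


@dataclass
class StrainTensorField:
    """Per-pixel symmetric strain tensor (dimensionless); e12 is the tensor shear."""

    e11: np.ndarray
    e22: np.ndarray
    e12: np.ndarray
    grid_spacing: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.e11 = np.asarray(self.e11, dtype=float)
        self.e22 = np.asarray(self.e22, dtype=float)
        self.e12 = np.asarray(self.e12, dtype=float)
        if not (self.e11.shape == self.e22.shape == self.e12.shape):
            raise ValueError("strain component shapes differ")
        if self.mask is None:
            self.mask = np.ones(self.e11.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class MaskSet:
    """User-selected analysis regions.

    ``traction_area`` is the region with visible tractions over which the FEM
    grid is spanned; ``cell_patch`` the cell outline over which stresses are
    averaged; ``boundaries`` holds cell-cell border polylines as (N, 2)
    arrays of (x, y) vertices in micrometres.
    """

    traction_area: np.ndarray
    cell_patch: np.ndarray | None = None
    boundaries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.traction_area = np.asarray(self.traction_area, dtype=bool)
        if self.cell_patch is not None:
            self.cell_patch = np.asarray(self.cell_patch, dtype=bool)
            if self.cell_patch.shape != self.traction_area.shape:
                raise ValueError("cell_patch and traction_area shapes differ")
        self.boundaries = [np.atleast_2d(np.asarray(b, dtype=float)) for b in self.boundaries]
        for b in self.boundaries:
            if b.shape[0] < 2 or b.shape[1] != 2:
                raise ValueError("each boundary polyline needs >= 2 (x, y) vertices")
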