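"""Synthetic ground truth for validating the TFM/MSM chain.

The reference experiment is a square "cell patch" carrying a uniform
biaxial tensile sheet stress, centered in a larger field.  From the stress
field the exact traction field follows from force balance (divergence of
the stress), and from the traction field the substrate deformation follows
from the forward Fourier map with the finite-thickness kernel.  Running the
deformation through FTTC and the FEM stress recovery and comparing against
the known input quantifies the accuracy of every downstream step.

Bead-image rendering closes the remaining gap to raw data: it draws the
same random Gaussian spots in a relaxed and a deformation-displaced tensed
configuration so the PIV front end can be tested end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fields import ImagePair, StressTensorField, VectorField2D
from .traction import ElasticSubstrate, deformation_from_traction

__all__ = [
    "SyntheticSpec",
    "make_square_stress",
    "patch_mask",
    "traction_from_stress",
    "ground_truth",
    "render_bead_images",
]

_UM = 1e-6


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic square-patch experiment.

    Defaults reproduce the reference validation conditions: a 150 um wide
    square patch under uniform biaxial tension (sigma0 in each normal
    component, zero shear) on a 100 um thick substrate, sampled at
    1 um/pixel over a 400 x 400 um field, with 3 um Gaussian traction
    smoothing in the reconstruction.  The stress magnitude is a nominal
    unit scale (stored in N/m); every recovery metric is normalized to it.
    """

    field_size_um: float = 400.0
    grid_spacing_um: float = 1.0
    patch_width_um: float = 150.0
    stress_magnitude: float = 1.0  # N/m
    # stiff (PDMS-like) default substrate: with the nominal unit stress the
    # bead displacements come out at a few pixels, the regime PIV handles;
    # every recovery metric is independent of this choice (the maps are linear)
    substrate: ElasticSubstrate = field(
        default_factory=lambda: ElasticSubstrate(
            youngs_modulus=500_000.0, poisson_ratio=0.49, thickness=100.0
        )
    )
    filter_sigma_um: float = 3.0
    seed: int = 0
    bead_density: float = 0.06  # beads per pixel^2 (dense seeding, as in TFM practice)
    bead_sigma_px: float = 1.2  # point-spread sigma of a rendered bead

    def __post_init__(self) -> None:
        if not self.patch_width_um < self.field_size_um:
            raise ValueError("patch must be smaller than the field")
        if self.bead_density < 0:
            raise ValueError("bead_density must be >= 0")

    @property
    def n_px(self) -> int:
        return int(round(self.field_size_um / self.grid_spacing_um))


def patch_mask(spec: SyntheticSpec, width_um: float | None = None) -> np.ndarray:
    """Boolean mask of the centered square patch (pixel centers inside)."""
    n = spec.n_px
    width = spec.patch_width_um if width_um is None else width_um
    coords = (np.arange(n) + 0.5) * spec.grid_spacing_um - spec.field_size_um / 2.0
    inside = np.abs(coords) <= width / 2.0
    return inside[:, None] & inside[None, :]


def make_square_stress(
    spec: SyntheticSpec, width_um: float | None = None
) -> StressTensorField:
    """Uniform biaxial tension on the centered square, zero outside.

    sigma_xx = sigma_yy = sigma0 inside the patch, sigma_xy = 0 everywhere.
    """
    mask = patch_mask(spec, width_um)
    s0 = spec.stress_magnitude
    sxx = np.where(mask, s0, 0.0)
    return StressTensorField(
        sxx, sxx.copy(), np.zeros_like(sxx), spec.grid_spacing_um, mask=None
    )


def traction_from_stress(stress: StressTensorField) -> VectorField2D:
    """Traction field (Pa) balancing a sheet stress field.

    Force balance of the sheet gives ``t = div(sigma)`` by central finite
    differences, with ``t`` the traction the cells exert on the substrate:
    for a tensile patch the tractions form inward-pointing (centripetal)
    bands along the patch edges.
    """
    a_m = stress.grid_spacing * _UM
    # axis 0 is y (rows), axis 1 is x (cols)
    tx = np.gradient(stress.sxx, a_m, axis=1) + np.gradient(stress.sxy, a_m, axis=0)
    ty = np.gradient(stress.sxy, a_m, axis=1) + np.gradient(stress.syy, a_m, axis=0)
    return VectorField2D(tx, ty, stress.grid_spacing)


def ground_truth(
    spec: SyntheticSpec, width_um: float | None = None, pad_factor: int = 2
) -> dict:
    """Full analytic chain: stress -> traction -> deformation.

    Returns a dict with the input stress tensor field, the patch mask, the
    traction field (Pa) and the forward-computed deformation field (um).
    """
    stress = make_square_stress(spec, width_um)
    mask = patch_mask(spec, width_um)
    t = traction_from_stress(stress)
    u = deformation_from_traction(t, spec.substrate, pad_factor=pad_factor)
    return {"stress": stress, "mask": mask, "traction": t, "deformation": u}


def _render_spots(
    shape: tuple[int, int], xy: np.ndarray, sigma: float, amplitude: float = 1.0
) -> np.ndarray:
    """Sum of unit Gaussians at sub-pixel positions ``xy`` (x, y in px)."""
    img = np.zeros(shape)
    rad = int(np.ceil(4 * sigma))
    offs = np.arange(-rad, rad + 1)
    for x, y in xy:
        r0, c0 = int(round(y)), int(round(x))
        rr = r0 + offs
        cc = c0 + offs
        rsel = (rr >= 0) & (rr < shape[0])
        csel = (cc >= 0) & (cc < shape[1])
        if not (rsel.any() and csel.any()):
            continue
        gy = np.exp(-((rr[rsel] - y) ** 2) / (2 * sigma**2))
        gx = np.exp(-((cc[csel] - x) ** 2) / (2 * sigma**2))
        img[np.ix_(rr[rsel], cc[csel])] += amplitude * np.outer(gy, gx)
    return img


def render_bead_images(u: VectorField2D, spec: SyntheticSpec) -> ImagePair:
    """Render a relaxed/tensed bead-image pair for a deformation field.

    The relaxed image holds Gaussian spots at uniform random positions; in
    the tensed image every spot is displaced by the (bilinearly
    interpolated) deformation at its location.  Both images share identical
    intensity statistics; no camera noise is modeled.
    """
    if spec.bead_density <= 0:
        raise ValueError("bead_density must be > 0 to render images")
    rng = np.random.default_rng(spec.seed)
    h, w = u.shape
    n_beads = int(round(spec.bead_density * h * w))
    xy = rng.uniform(low=0.0, high=[w, h], size=(n_beads, 2))
    # displacement (px) at each bead position, image coords -> grid coords
    ox, oy = u.origin_offset
    px = u.grid_spacing  # um per grid step; assume grid step == pixel here
    gx = (xy[:, 0] - ox)
    gy = (xy[:, 1] - oy)
    coords = np.stack([gy, gx])
    ux = ndimage.map_coordinates(u.vx, coords, order=1, mode="nearest") / px
    uy = ndimage.map_coordinates(u.vy, coords, order=1, mode="nearest") / px
    relaxed = _render_spots((h, w), xy, spec.bead_sigma_px)
    tensed = _render_spots((h, w), xy + np.stack([ux, uy], axis=1), spec.bead_sigma_px)
    return ImagePair(tensed, relaxed, pixel_size=u.grid_spacing)
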