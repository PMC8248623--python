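"""Fourier-space mapping between substrate deformation and traction (FTTC).

The surface displacement of a linearly elastic substrate under an in-plane
traction field ``t`` is the convolution ``u = K (*) t`` with the Boussinesq
Green's tensor ``K``.  In Fourier space the convolution becomes a per-wave-
vector 2x2 matrix multiplication, which makes both the forward map
(traction -> deformation, used to build synthetic data) and the inverse map
(Fourier Transform Traction Cytometry) a pointwise linear solve.

For a substrate layer of finite thickness ``h`` bonded to a rigid support,
the half-space tensor is multiplied by thickness corrections derived from
the bonded-layer elasticity problem (see :func:`layer_correction`); the
corrections approach 1 as ``k*h -> inf``.

Instead of explicit regularization, the inverse map optionally smooths the
reconstructed traction with an isotropic Gaussian (sigma in um, typically
3 um), which suppresses the high spatial frequencies that noise in the
deformation field would otherwise amplify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import VectorField2D

__all__ = [
    "ElasticSubstrate",
    "layer_correction",
    "greens_tensor",
    "deformation_from_traction",
    "traction_from_deformation",
]

_UM = 1e-6  # metres per micrometre


@dataclass(frozen=True)
class ElasticSubstrate:
    """Elastic properties of the TFM substrate.

    youngs_modulus : Young's modulus E in Pa.
    poisson_ratio  : Poisson's ratio (0..0.5); 0.49 is typical for PAA gels.
    thickness      : substrate thickness in um; ``inf`` for a half-space.
    """

    youngs_modulus: float
    poisson_ratio: float = 0.49
    thickness: float = np.inf

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError("youngs_modulus must be > 0")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        if not self.thickness > 0:
            raise ValueError("thickness must be > 0 (or inf for a half-space)")

    @property
    def is_infinite(self) -> bool:
        return np.isinf(self.thickness)


def layer_correction(s: np.ndarray, nu: float) -> tuple[np.ndarray, np.ndarray]:
    """Finite-thickness correction factors for the Fourier Green's tensor.

    For a layer of thickness ``h`` bonded to a rigid base, the longitudinal
    (parallel to the wavevector) and transverse surface responses of the
    half-space are each multiplied by a factor depending on ``s = k*h``:

        gamma_par  = ((3-4nu) sinh(s) cosh(s) + s)
                     / ((3-4nu) cosh(s)^2 + (1-2nu)^2 + s^2)
        gamma_perp = tanh(s)

    Both factors go to 1 for ``s -> inf`` (half-space limit) and to 0 for
    ``s -> 0`` (surface glued to the support; no displacement).

    Parameters
    ----------
    s : dimensionless ``k*h`` (any array shape).
    nu : substrate Poisson's ratio.
    """
    s = np.asarray(s, dtype=float)
    # cosh overflows for s >~ 350; beyond s=25 both factors are 1 to <1e-21
    sc = np.minimum(s, 25.0)
    ch, sh = np.cosh(sc), np.sinh(sc)
    a = 3.0 - 4.0 * nu
    gamma_par = (a * sh * ch + sc) / (a * ch**2 + (1.0 - 2.0 * nu) ** 2 + sc**2)
    gamma_perp = np.tanh(sc)
    return gamma_par, gamma_perp


def greens_tensor(
    kx: np.ndarray, ky: np.ndarray, substrate: ElasticSubstrate
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fourier-space Green's tensor components (Kxx, Kyy, Kxy) in m/Pa.

    ``kx``/``ky`` are angular wavenumbers in rad/m (broadcastable arrays).
    For an infinitely thick substrate this is the Boussinesq half-space
    tensor

        K = 2(1+nu)/(E k^3) * [[(1-nu)k^2 + nu ky^2,  -nu kx ky],
                               [-nu kx ky,            (1-nu)k^2 + nu kx^2]]

    For finite thickness the longitudinal/transverse eigencomponents are
    multiplied by :func:`layer_correction`.  The tensor is symmetric
    (Kxy == Kyx) and the ``k = 0`` entry is left as ``inf``; callers must
    handle the zero mode themselves.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    E, nu = substrate.youngs_modulus, substrate.poisson_ratio
    k2 = kx**2 + ky**2
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.sqrt(k2)
        # longitudinal / transverse eigenvalues of the half-space tensor
        k_par = 2.0 * (1.0 + nu) * (1.0 - nu) / (E * k)
        k_perp = 2.0 * (1.0 + nu) / (E * k)
        if not substrate.is_infinite:
            g_par, g_perp = layer_correction(k * substrate.thickness * _UM, nu)
            k_par = k_par * g_par
            k_perp = k_perp * g_perp
        # back to cartesian components: K = k_par khat khat^T + k_perp (I - khat khat^T)
        kxx = (k_par * kx**2 + k_perp * ky**2) / k2
        kyy = (k_par * ky**2 + k_perp * kx**2) / k2
        kxy = (k_par - k_perp) * kx * ky / k2
    return kxx, kyy, kxy


def _freq_grid(shape: tuple[int, int], spacing_m: float) -> tuple[np.ndarray, np.ndarray]:
    """Angular frequency grids (kx, ky) in rad/m for an FFT of ``shape``."""
    ky = 2.0 * np.pi * np.fft.fftfreq(shape[0], d=spacing_m)[:, None]
    kx = 2.0 * np.pi * np.fft.fftfreq(shape[1], d=spacing_m)[None, :]
    return kx, ky


def _padded_shape(shape: tuple[int, int], pad_factor: int) -> tuple[int, int]:
    return tuple(int(n * pad_factor) for n in shape)


def deformation_from_traction(
    t: VectorField2D,
    substrate: ElasticSubstrate,
    pad_factor: int = 2,
    balance_tol: float = 1e-6,
) -> VectorField2D:
    """Forward map: surface deformation (um) generated by a traction field (Pa).

    The traction components are (optionally zero-padded and) Fourier
    transformed, multiplied by the Green's tensor, and transformed back.
    The zero-frequency displacement is set to zero: a net-free traction
    field determines the deformation only up to a rigid translation.

    A warning is emitted when the net traction exceeds ``balance_tol``
    (relative to the mean traction magnitude).
    """
    tx, ty = t.vx, t.vy
    if not (np.all(np.isfinite(tx)) and np.all(np.isfinite(ty))):
        raise ValueError("traction field contains non-finite values")
    scale = np.mean(np.hypot(tx, ty))
    if scale > 0:
        net = np.hypot(tx.sum(), ty.sum()) / (scale * tx.size)
        if net > balance_tol:
            warnings.warn(
                "net traction is not balanced; deformation is defined only up "
                "to a rigid translation",
                stacklevel=2,
            )
    shape = tx.shape
    pshape = _padded_shape(shape, pad_factor)
    spacing_m = t.grid_spacing * _UM
    kx, ky = _freq_grid(pshape, spacing_m)
    kxx, kyy, kxy = greens_tensor(kx, ky, substrate)

    ftx = np.fft.fft2(tx, s=pshape)
    fty = np.fft.fft2(ty, s=pshape)
    fux = kxx * ftx + kxy * fty
    fuy = kxy * ftx + kyy * fty
    fux[0, 0] = 0.0
    fuy[0, 0] = 0.0
    ux = np.fft.ifft2(fux).real[: shape[0], : shape[1]]
    uy = np.fft.ifft2(fuy).real[: shape[0], : shape[1]]
    return VectorField2D(ux / _UM, uy / _UM, t.grid_spacing, t.origin_offset)


def traction_from_deformation(
    u: VectorField2D,
    substrate: ElasticSubstrate,
    filter_sigma: float = 3.0,
    pad_factor: int = 2,
) -> VectorField2D:
    """FTTC inverse map: traction field (Pa) from a deformation field (um).

    Per wavevector the 2x2 Green's tensor is inverted exactly; the zero
    mode is nulled, which enforces global force balance to machine
    precision.  ``filter_sigma`` (um) is the width of the Gaussian low-pass
    applied to the reconstructed traction components; 0 disables smoothing,
    making the op the algebraic inverse of :func:`deformation_from_traction`
    on a common periodic domain (``pad_factor=1``).
    """
    if filter_sigma < 0:
        raise ValueError("filter_sigma must be >= 0")
    ux, uy = u.vx * _UM, u.vy * _UM
    if not (np.all(np.isfinite(ux)) and np.all(np.isfinite(uy))):
        raise ValueError("deformation field contains non-finite values")
    shape = ux.shape
    pshape = _padded_shape(shape, pad_factor)
    spacing_m = u.grid_spacing * _UM
    kx, ky = _freq_grid(pshape, spacing_m)
    kxx, kyy, kxy = greens_tensor(kx, ky, substrate)

    fux = np.fft.fft2(ux, s=pshape)
    fuy = np.fft.fft2(uy, s=pshape)
    with np.errstate(divide="ignore", invalid="ignore"):
        det = kxx * kyy - kxy**2
        ftx = (kyy * fux - kxy * fuy) / det
        fty = (kxx * fuy - kxy * fux) / det
    ftx[0, 0] = 0.0
    fty[0, 0] = 0.0
    tx = np.fft.ifft2(ftx).real[: shape[0], : shape[1]]
    ty = np.fft.ifft2(fty).real[: shape[0], : shape[1]]
    if filter_sigma > 0:
        sigma_px = filter_sigma / u.grid_spacing
        tx = ndimage.gaussian_filter(tx, sigma_px)
        ty = ndimage.gaussian_filter(ty, sigma_px)
    # cropping (and filter edge handling) can reintroduce a tiny net traction;
    # remove it so global force balance holds to machine precision
    tx = tx - tx.mean()
    ty = ty - ty.mean()
    return VectorField2D(tx, ty, u.grid_spacing, u.origin_offset)
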