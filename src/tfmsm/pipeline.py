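"""Pipeline orchestration: config file in, arrays/plots/results table out.

A run is described by a TOML file with three sections::

    [images]
    tensed = "04_after.tif"      # substrate with cells pulling
    relaxed = "04_before.tif"    # substrate after cell detachment
    mask = "mask.png"            # label image: 1 = traction area, 2 = cell patch
    boundaries = "borders.csv"   # optional: boundary_id, x_um, y_um per vertex

    [parameters]
    pixel_size = 0.2             # um / px
    youngs_modulus = 49000.0     # Pa
    poisson_ratio = 0.49
    thickness = 100.0            # um; omit for an infinite half-space
    filter_sigma = 3.0           # um
    window_size = 50             # px
    overlap = 25                 # px
    snr_threshold = 1.03

    [stages]
    enabled = ["deformation", "traction", "stress", "metrics"]

Stages form a dependency chain; the enabled list must be a prefix of
``deformation -> traction -> stress -> metrics``.  Every stage writes its
field arrays as ``.npy`` files and a plot; the metrics stage writes the
tab-separated results table.  Reruns with identical inputs are
byte-identical.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from . import metrics as _metrics
from . import plotting
from .deformation import PIVParams, compute_deformation, correct_drift
from .fields import ImagePair, MaskSet, VectorField2D
from .monolayer_stress import stress_from_traction
from .traction import ElasticSubstrate, traction_from_deformation

__all__ = ["RunConfig", "load_config", "run_pipeline", "load_image", "load_masks"]

_STAGES = ("deformation", "traction", "stress", "metrics")


@dataclass
class RunConfig:
    tensed: Path
    relaxed: Path
    mask: Path | None
    boundaries: Path | None
    pixel_size: float
    substrate: ElasticSubstrate
    filter_sigma: float = 3.0
    piv: PIVParams = field(default_factory=PIVParams)
    stages: tuple[str, ...] = _STAGES
    cell_count: int | None = None

    def __post_init__(self) -> None:
        if tuple(self.stages) != _STAGES[: len(self.stages)]:
            raise ValueError(
                f"enabled stages must be a prefix of {list(_STAGES)}, got {list(self.stages)}"
            )
        for attr in ("tensed", "relaxed", "mask", "boundaries"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    images = raw.get("images", {})
    params = raw.get("parameters", {})
    stages = tuple(raw.get("stages", {}).get("enabled", _STAGES))

    def respath(key: str) -> Path | None:
        p = images.get(key)
        return (path.parent / p) if p else None

    substrate = ElasticSubstrate(
        youngs_modulus=float(params["youngs_modulus"]),
        poisson_ratio=float(params.get("poisson_ratio", 0.49)),
        thickness=float(params.get("thickness", np.inf)),
    )
    piv = PIVParams(
        window_size=int(params.get("window_size", 50)),
        overlap=int(params.get("overlap", 25)),
        snr_threshold=float(params.get("snr_threshold", 1.03)),
    )
    return RunConfig(
        tensed=respath("tensed"),
        relaxed=respath("relaxed"),
        mask=respath("mask"),
        boundaries=respath("boundaries"),
        pixel_size=float(params["pixel_size"]),
        substrate=substrate,
        filter_sigma=float(params.get("filter_sigma", 3.0)),
        piv=piv,
        stages=stages,
        cell_count=params.get("cell_count"),
    )


def load_image(path: str | Path) -> np.ndarray:
    """8/16-bit grayscale TIFF or PNG as a float array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:  # collapse RGB(A) to luminance
        img = img[..., :3].mean(axis=-1)
    return img


def load_masks(
    mask_path: str | Path | None, boundaries_path: str | Path | None,
    pixel_size: float,
) -> MaskSet | None:
    """Masks from a label image (1 = traction area, 2 = cell patch) + CSV polylines."""
    if mask_path is None:
        return None
    labels = load_image(mask_path).astype(int)
    traction_area = labels >= 1
    cell_patch = labels >= 2 if (labels == 2).any() else None
    boundaries = []
    if boundaries_path is not None:
        import pandas as pd

        df = pd.read_csv(boundaries_path)
        for _, grp in df.groupby("boundary_id", sort=True):
            boundaries.append(grp[["x_um", "y_um"]].to_numpy(dtype=float))
    return MaskSet(traction_area, cell_patch, boundaries)


def _mask_to_grid(mask: np.ndarray, u: VectorField2D, pixel_size: float) -> np.ndarray:
    """Sample an image-resolution mask at the PIV grid (window center) points."""
    ox, oy = u.origin_offset
    step = u.grid_spacing / pixel_size  # px between grid points
    rows = np.clip(np.round(oy + np.arange(u.shape[0]) * step).astype(int), 0, mask.shape[0] - 1)
    cols = np.clip(np.round(ox + np.arange(u.shape[1]) * step).astype(int), 0, mask.shape[1] - 1)
    return mask[np.ix_(rows, cols)]


def _boundaries_to_grid(
    boundaries: list[np.ndarray], u: VectorField2D, pixel_size: float
) -> list[np.ndarray]:
    """Polyline vertices (um, image frame) -> um in the analysis-grid frame."""
    ox, oy = u.origin_offset
    out = []
    for poly in boundaries:
        shifted = poly - np.array([ox * pixel_size, oy * pixel_size])
        out.append(shifted + 0.5 * u.grid_spacing)
    return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> _metrics.ResultsRecord:
    """Run the enabled stages and write arrays, plots and the results table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = _metrics.ResultsRecord()

    pair = ImagePair(
        load_image(config.tensed), load_image(config.relaxed), config.pixel_size
    )
    pair, drift = correct_drift(pair)
    (outdir / "drift_px.txt").write_text(f"{float(drift[0])!r}\t{float(drift[1])!r}\n")

    u = compute_deformation(pair, config.piv)
    u.save(outdir / "deformation")
    plotting.save_quiver(u, outdir / "deformation.png", title="deformation", units="um")
    if "traction" not in config.stages:
        return record

    t = traction_from_deformation(u, config.substrate, config.filter_sigma)
    t.save(outdir / "traction")
    plotting.save_quiver(t, outdir / "traction.png", title="traction", units="Pa")
    if "stress" not in config.stages:
        return record

    masks = load_masks(config.mask, config.boundaries, config.pixel_size)
    if masks is None:
        raise ValueError(
            "the stress stage needs a traction-area mask; provide images.mask"
        )
    area = _mask_to_grid(masks.traction_area, u, config.pixel_size)
    stress, system = stress_from_traction(t, area)
    stress.save(outdir / "stress")
    plotting.save_stress_maps(stress, outdir / "stress")
    if "metrics" not in config.stages:
        return record

    cell_mask = (
        _mask_to_grid(masks.cell_patch, u, config.pixel_size)
        if masks.cell_patch is not None
        else stress.mask
    )
    record.strain_energy = _metrics.strain_energy(u, t, stress.mask)
    _, record.contractility = _metrics.contractility(t, stress.mask)
    record.patch_area = float(cell_mask.sum()) * u.grid_spacing**2
    for key, val in _metrics.stress_scalars(stress, cell_mask).items():
        setattr(record, key, val)
    if masks.boundaries:
        grid_bounds = _boundaries_to_grid(masks.boundaries, u, config.pixel_size)
        _, averages = _metrics.line_tension(stress, grid_bounds)
        for key, val in averages.items():
            setattr(record, key, val)
    _metrics.write_results(record, outdir / "results.tsv")
    return record
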