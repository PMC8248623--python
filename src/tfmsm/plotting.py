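"""Quiver and heat-map display of deformation, traction and stress fields."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless tool: render to files only

import matplotlib.pyplot as plt
import numpy as np

from .fields import StressTensorField, VectorField2D

__all__ = ["show_quiver", "show_heatmap", "save_quiver", "save_heatmap"]


def show_quiver(
    field: VectorField2D, ax=None, subsample: int = 1, title: str | None = None,
    units: str = "",
):
    """Quiver plot of a vector field over a magnitude heat map."""
    if ax is None:
        _, ax = plt.subplots()
    mag = field.magnitude
    im = ax.imshow(mag, cmap="viridis", origin="upper")
    s = max(int(subsample), 1)
    ys, xs = np.mgrid[0 : mag.shape[0] : s, 0 : mag.shape[1] : s]
    ax.quiver(
        xs, ys, field.vx[::s, ::s], field.vy[::s, ::s],
        angles="xy", scale_units="xy", color="w",
    )
    cbar = ax.figure.colorbar(im, ax=ax)
    if units:
        cbar.set_label(units)
    if title:
        ax.set_title(title)
    ax.set_xlabel("x (grid)")
    ax.set_ylabel("y (grid)")
    return ax


def show_heatmap(
    array: np.ndarray, ax=None, title: str | None = None, units: str = "",
    mask: np.ndarray | None = None,
):
    """Heat map of a scalar field; masked-out pixels are blanked."""
    if ax is None:
        _, ax = plt.subplots()
    data = np.array(array, dtype=float)
    if mask is not None:
        data[~np.asarray(mask, dtype=bool)] = np.nan
    im = ax.imshow(data, cmap="inferno", origin="upper")
    cbar = ax.figure.colorbar(im, ax=ax)
    if units:
        cbar.set_label(units)
    if title:
        ax.set_title(title)
    return ax


def save_quiver(field: VectorField2D, path: str | Path, **kwargs) -> Path:
    fig, ax = plt.subplots()
    show_quiver(field, ax=ax, **kwargs)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def save_heatmap(array, path: str | Path, **kwargs) -> Path:
    fig, ax = plt.subplots()
    show_heatmap(array, ax=ax, **kwargs)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def save_stress_maps(stress: StressTensorField, basepath: str | Path) -> list[Path]:
    """Mean-normal and max-shear heat maps of a stress tensor field."""
    base = Path(basepath)
    paths = []
    for name, arr in (
        ("mean_normal", stress.mean_normal),
        ("max_shear", stress.max_shear),
    ):
        p = base.with_name(base.name + f"_{name}.png")
        save_heatmap(arr, p, mask=stress.mask, title=name.replace("_", " "), units="N/m")
        paths.append(p)
    return paths
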