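"""Scalar readouts of the deformation, traction and stress fields.

Force generation is summarized by the substrate strain energy
``U = 1/2 sum(u . t) a^2`` and by the contractility, the sum of all
traction forces projected toward the force epicenter (the point the
cell-generated forces collectively converge on).  The stress tensor field
is reduced to averages of its per-pixel principal-stress combinations
(max normal, max shear, mean normal) and the coefficient of variation of
the mean normal stress, a stress-heterogeneity measure.  Cell-cell force
transmission is measured by the line tension ``T = sigma . n`` along
user-drawn boundary polylines, split into normal and shear components.

All outputs are SI (N, J, N/m); the results table uses the conventional
row labels and can be written to / read from a tab-separated text file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path

import numpy as np
from scipy import ndimage

from .fields import StressTensorField, VectorField2D

__all__ = [
    "ResultsRecord",
    "LineTensionSegment",
    "strain_energy",
    "contractility",
    "stress_scalars",
    "line_tension",
    "write_results",
    "read_results",
    "compare_results",
]

_UM = 1e-6

#: TSV row label for each ResultsRecord field
_LABELS = {
    "contractility": "Contractility",
    "strain_energy": "Strain energy",
    "avg_max_normal_stress": "Avg. max. normal stress",
    "avg_max_shear_stress": "Avg. max. shear stress",
    "avg_mean_normal_stress": "Avg. mean normal stress",
    "cv_normal_stress": "CV normal stress",
    "avg_line_tension": "Avg. line tension",
    "avg_normal_line_tension": "Avg. normal line tension",
    "avg_shear_line_tension": "Avg. shear line tension",
    "patch_area": "Cell patch area",
}


@dataclass
class ResultsRecord:
    """Named scalar outputs of one analysis (SI units; area in um^2)."""

    contractility: float | None = None          # N
    strain_energy: float | None = None          # J
    avg_max_normal_stress: float | None = None  # N/m
    avg_max_shear_stress: float | None = None   # N/m
    avg_mean_normal_stress: float | None = None  # N/m
    cv_normal_stress: float | None = None       # dimensionless
    avg_line_tension: float | None = None       # N/m
    avg_normal_line_tension: float | None = None  # N/m
    avg_shear_line_tension: float | None = None  # N/m
    patch_area: float | None = None             # um^2

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


@dataclass
class LineTensionSegment:
    """Stress-tensor traction acting on one segment of a cell-cell border."""

    midpoint: np.ndarray      # (x, y) um
    normal: np.ndarray        # unit normal
    tangent: np.ndarray       # unit tangent
    tension: np.ndarray       # T = sigma . n, N/m
    normal_component: float   # T . n (signed: + tension, - compression)
    shear_component: float    # T . tangent (signed)
    length: float             # um


def strain_energy(u: VectorField2D, t: VectorField2D, area: np.ndarray | None = None) -> float:
    """Elastic energy stored in the substrate: ``1/2 sum(u . t) a^2`` (J)."""
    if u.shape != t.shape or u.grid_spacing != t.grid_spacing:
        raise ValueError("deformation and traction must share one grid")
    dot = u.vx * t.vx + u.vy * t.vy  # um * Pa
    if area is not None:
        area = np.asarray(area, dtype=bool)
        if area.shape != u.shape:
            raise ValueError("area mask shape differs from the fields")
        dot = dot[area]
    a2 = (u.grid_spacing * _UM) ** 2
    return float(0.5 * dot.sum() * _UM * a2)


def contractility(
    t: VectorField2D, area: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Force epicenter and contractility of a traction field.

    The epicenter is the least-squares intersection of the lines of action
    of all traction forces: it minimizes ``sum |t_i x (r_e - r_i)|^2``,
    a 2-unknown linear problem.  The contractility is the sum of the force
    components pointing from each pixel toward the epicenter,
    ``C = sum F_i . u_hat_i``; centripetal (inward pulling) fields give
    positive C.

    Returns ``(epicenter_xy_um, contractility_N)``.
    """
    if area is None:
        area = np.ones(t.shape, dtype=bool)
    area = np.asarray(area, dtype=bool)
    rows, cols = np.nonzero(area)
    tx = t.vx[rows, cols]
    ty = t.vy[rows, cols]
    x = (cols + 0.5) * t.grid_spacing
    y = (rows + 0.5) * t.grid_spacing
    # residual of pixel i: tx_i*ye - ty_i*xe - (tx_i*y_i - ty_i*x_i)
    a = np.stack([-ty, tx], axis=1)
    b = tx * y - ty * x
    gram = a.T @ a
    rhs = a.T @ b
    scale = np.trace(gram)
    if scale == 0:
        raise ValueError("degenerate epicenter system: no forces in the area")
    # the normal equations are rank deficient when all lines of action are
    # parallel; along such a direction the epicenter is indeterminate and is
    # completed with the force-weighted centroid (e.g. two exactly opposing
    # forces constrain the epicenter only to their common line)
    w = tx**2 + ty**2
    centroid = np.array([np.average(x, weights=w), np.average(y, weights=w)])
    evals, evecs = np.linalg.eigh(gram)
    good = evals > 1e-12 * scale
    epi = centroid.copy()
    for lam, vec in zip(evals[good], evecs[:, good].T):
        epi += vec * (vec @ rhs - lam * (vec @ centroid)) / lam
    resid = np.linalg.norm(a @ epi - b)
    if (~good).any() and resid > 1e-6 * max(np.linalg.norm(b), 1e-300):
        raise ValueError(
            "degenerate epicenter system: all traction lines of action are "
            "parallel and share no common point"
        )
    dx = epi[0] - x
    dy = epi[1] - y
    dist = np.hypot(dx, dy)
    dist[dist == 0] = np.inf  # a force at the epicenter has no projection
    a2 = (t.grid_spacing * _UM) ** 2
    c = np.sum((tx * dx + ty * dy) / dist) * a2
    return epi, float(c)


def stress_scalars(stress: StressTensorField, cell_mask: np.ndarray | None = None) -> dict:
    """Average principal-stress measures over the cell mask.

    Per pixel: max normal = sigma1, max shear = (sigma1 - sigma2)/2, mean
    normal = (sigma1 + sigma2)/2.  CV is std/mean of the per-pixel mean
    normal stress.
    """
    if cell_mask is None:
        cell_mask = stress.mask
    cell_mask = np.asarray(cell_mask, dtype=bool) & stress.mask
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    s1, s2 = stress.principal()
    mean_normal = 0.5 * (s1 + s2)
    mn = mean_normal[cell_mask]
    avg_mean = float(mn.mean())
    cv = float(mn.std() / abs(avg_mean)) if avg_mean != 0 else np.inf
    return {
        "avg_max_normal_stress": float(s1[cell_mask].mean()),
        "avg_max_shear_stress": float((0.5 * (s1 - s2))[cell_mask].mean()),
        "avg_mean_normal_stress": avg_mean,
        "cv_normal_stress": cv,
    }


def _interp_stress(stress: StressTensorField, xy_um: np.ndarray) -> np.ndarray:
    """Bilinearly interpolated (sxx, syy, sxy) at (x, y) um positions."""
    a = stress.grid_spacing
    cols = xy_um[:, 0] / a - 0.5
    rows = xy_um[:, 1] / a - 0.5
    coords = np.stack([rows, cols])
    out = np.empty((len(xy_um), 3))
    for i, comp in enumerate((stress.sxx, stress.syy, stress.sxy)):
        out[:, i] = ndimage.map_coordinates(comp, coords, order=1, mode="nearest")
    return out


def line_tension(
    stress: StressTensorField, boundaries: list[np.ndarray]
) -> tuple[list[LineTensionSegment], dict]:
    """Line tension along cell-cell boundary polylines.

    Each polyline segment contributes a tension vector ``T = sigma . n``
    with ``sigma`` interpolated at the segment midpoint and ``n`` the unit
    normal of the segment.  Averages are length-weighted; the normal
    component keeps its sign while the shear is averaged as a magnitude.
    Segments whose midpoint leaves the valid stress region are skipped with
    a warning.
    """
    segments: list[LineTensionSegment] = []
    a = stress.grid_spacing
    for poly in boundaries:
        poly = np.asarray(poly, dtype=float)
        mids = 0.5 * (poly[:-1] + poly[1:])
        vecs = np.diff(poly, axis=0)
        lens = np.linalg.norm(vecs, axis=1)
        keep = lens > 0
        mids, vecs, lens = mids[keep], vecs[keep], lens[keep]
        # validity check on the nearest pixel of each midpoint
        rr = np.clip((mids[:, 1] / a - 0.5).round().astype(int), 0, stress.shape[0] - 1)
        cc = np.clip((mids[:, 0] / a - 0.5).round().astype(int), 0, stress.shape[1] - 1)
        inside = stress.mask[rr, cc]
        if not inside.all():
            warnings.warn(
                f"{int((~inside).sum())} boundary segment(s) outside the valid "
                "stress region were skipped",
                stacklevel=2,
            )
        mids, vecs, lens = mids[inside], vecs[inside], lens[inside]
        if len(mids) == 0:
            continue
        tangents = vecs / lens[:, None]
        normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
        sig = _interp_stress(stress, mids)
        tvec = np.stack(
            [
                sig[:, 0] * normals[:, 0] + sig[:, 2] * normals[:, 1],
                sig[:, 2] * normals[:, 0] + sig[:, 1] * normals[:, 1],
            ],
            axis=1,
        )
        for i in range(len(mids)):
            segments.append(
                LineTensionSegment(
                    midpoint=mids[i],
                    normal=normals[i],
                    tangent=tangents[i],
                    tension=tvec[i],
                    normal_component=float(tvec[i] @ normals[i]),
                    shear_component=float(tvec[i] @ tangents[i]),
                    length=float(lens[i]),
                )
            )
    if not segments:
        return segments, {
            "avg_line_tension": np.nan,
            "avg_normal_line_tension": np.nan,
            "avg_shear_line_tension": np.nan,
        }
    w = np.array([s.length for s in segments])
    mag = np.array([np.linalg.norm(s.tension) for s in segments])
    nrm = np.array([s.normal_component for s in segments])
    shr = np.abs([s.shear_component for s in segments])
    averages = {
        "avg_line_tension": float(np.average(mag, weights=w)),
        "avg_normal_line_tension": float(np.average(nrm, weights=w)),
        "avg_shear_line_tension": float(np.average(shr, weights=w)),
    }
    return segments, averages


def write_results(record: ResultsRecord, path: str | Path) -> Path:
    """Write a results record as a two-column tab-separated text file."""
    path = Path(path)
    lines = []
    for name, label in _LABELS.items():
        value = getattr(record, name)
        if value is None:
            continue
        lines.append(f"{label}\t{value!r}\n")
    path.write_text("".join(lines))
    return path


def read_results(path: str | Path) -> ResultsRecord:
    """Read a results file written by :func:`write_results`."""
    by_label = {label: name for name, label in _LABELS.items()}
    record = ResultsRecord()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        label, _, value = line.partition("\t")
        name = by_label.get(label.strip())
        if name is not None:
            setattr(record, name, float(value))
    return record


def compare_results(paths: list[str | Path]):
    """Stack several result files into one DataFrame (one row per file)."""
    import pandas as pd

    rows = []
    for p in paths:
        d = read_results(p).to_dict()
        d["file"] = str(p)
        rows.append(d)
    return pd.DataFrame(rows).set_index("file")
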