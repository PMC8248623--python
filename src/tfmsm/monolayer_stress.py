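"""Monolayer stress recovery by plane-stress FEM on a pixel-quad grid.

The cell sheet is modeled as a linearly elastic 2D material spanning the
user-selected traction area.  One bilinear quadrilateral element is placed
per masked pixel, nodes sit on pixel corners.  Each node is loaded with a
force equal in magnitude and opposite in direction to the local traction
(times the tributary pixel area), after the net force and net torque of the
load have been removed.  The singular stiffness system (three rigid-body
null modes) is closed by whole-system zero-translation / zero-rotation
constraints and solved; strains follow from the shape-function derivatives
at element centers and stresses from the plane-stress constitutive law.

Because the loads, not the displacements, carry the physics, the sheet
Young's modulus cancels from the recovered stress and the Poisson's ratio
has only a minor influence; the defaults are E = 1 Pa and nu = 0.5 under a
unit-thickness convention, so stresses come out directly in N/m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import sparse
from scipy.sparse.linalg import splu

from .fields import StrainTensorField, StressTensorField, VectorField2D

__all__ = [
    "FEMGrid",
    "FEMSystem",
    "build_fem_grid",
    "q4_stiffness",
    "assemble_stiffness",
    "nodal_forces",
    "balance_forces",
    "solve_displacements",
    "stress_from_displacements",
    "stress_from_traction",
    "expand_mask",
    "expansion_scan",
]

logger = logging.getLogger(__name__)

_UM = 1e-6


@dataclass
class FEMGrid:
    """Quadrilateral element grid covering a pixel mask.

    nodes        : (N, 2) node coordinates (x, y) in um.
    elements     : (M, 4) node indices per element, corner order
                   (top-left, top-right, bottom-right, bottom-left) in
                   image convention (y down).
    pixel_index  : (M, 2) (row, col) of the source pixel of each element.
    mask         : the (hole-filled) boolean pixel mask the grid covers.
    grid_spacing : element edge length in um.
    """

    nodes: np.ndarray
    elements: np.ndarray
    pixel_index: np.ndarray
    mask: np.ndarray
    grid_spacing: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def center_of_mass(self) -> np.ndarray:
        return self.nodes.mean(axis=0)


@dataclass
class FEMSystem:
    """Assembled FEM problem: stiffness, balanced nodal loads, sheet constants."""

    grid: FEMGrid
    stiffness: sparse.spmatrix
    forces: np.ndarray
    e_sheet: float = 1.0
    nu_sheet: float = 0.5
    balance_angle: float = 0.0
    displacements: np.ndarray | None = field(default=None, repr=False)


def build_fem_grid(mask: np.ndarray, grid_spacing: float) -> FEMGrid:
    """Span a quad-element grid over a boolean pixel mask.

    Interior holes are filled (with a logged warning); a disconnected mask
    is an error because the rigid-body constraints assume a single body.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    filled = ndimage.binary_fill_holes(mask)
    if filled.sum() != mask.sum():
        logger.warning(
            "mask contained %d interior hole pixel(s); filled", int(filled.sum() - mask.sum())
        )
    mask = filled
    # 4-connectivity: elements must share edges to form one stiff body
    _, n_comp = ndimage.label(mask)
    if n_comp != 1:
        raise ValueError(
            f"mask has {n_comp} connected components; the FEM constraints "
            "require a single connected region"
        )
    rows, cols = np.nonzero(mask)
    # nodes live on the (H+1) x (W+1) pixel-corner lattice
    h, w = mask.shape
    corner_ids = -np.ones((h + 1, w + 1), dtype=np.int64)
    corners = np.concatenate(
        [
            np.stack([rows, cols], axis=1),
            np.stack([rows, cols + 1], axis=1),
            np.stack([rows + 1, cols + 1], axis=1),
            np.stack([rows + 1, cols], axis=1),
        ]
    )
    uniq = np.unique(corners, axis=0)
    corner_ids[uniq[:, 0], uniq[:, 1]] = np.arange(len(uniq))
    nodes = np.stack([uniq[:, 1].astype(float), uniq[:, 0].astype(float)], axis=1)
    nodes *= grid_spacing  # (x, y) in um
    elements = np.stack(
        [
            corner_ids[rows, cols],
            corner_ids[rows, cols + 1],
            corner_ids[rows + 1, cols + 1],
            corner_ids[rows + 1, cols],
        ],
        axis=1,
    )
    pixel_index = np.stack([rows, cols], axis=1)
    return FEMGrid(nodes, elements, pixel_index, mask, grid_spacing)


def q4_stiffness(e_modulus: float, nu: float) -> np.ndarray:
    """8x8 plane-stress stiffness of a square bilinear quad (2x2 Gauss).

    The element stiffness of a square element is independent of its edge
    length, so one matrix serves every pixel element.  DOF order is
    (ux1, uy1, ..., ux4, uy4) matching the element corner order.
    """
    d = e_modulus / (1.0 - nu**2) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    # corner order (-1,-1), (1,-1), (1,1), (-1,1) on the reference square
    xi_n = np.array([-1.0, 1.0, 1.0, -1.0])
    eta_n = np.array([-1.0, -1.0, 1.0, 1.0])
    ke = np.zeros((8, 8))
    for xi in gp:
        for eta in gp:
            dn_dxi = 0.25 * xi_n * (1.0 + eta * eta_n)
            dn_deta = 0.25 * eta_n * (1.0 + xi * xi_n)
            # jacobian of the unit-square map is (a/2) I; a cancels overall
            b = np.zeros((3, 8))
            b[0, 0::2] = dn_dxi * 2.0
            b[1, 1::2] = dn_deta * 2.0
            b[2, 0::2] = dn_deta * 2.0
            b[2, 1::2] = dn_dxi * 2.0
            ke += 0.25 * b.T @ d @ b  # weight 1 * detJ (a^2/4), times B ~ 1/a twice
    return ke


def assemble_stiffness(
    grid: FEMGrid, e_sheet: float = 1.0, nu_sheet: float = 0.5
) -> sparse.csr_matrix:
    """Global stiffness matrix (2N x 2N, N/m per unit-thickness convention)."""
    ke = q4_stiffness(e_sheet, nu_sheet)
    el = grid.elements
    dof = np.empty((grid.n_elements, 8), dtype=np.int64)
    dof[:, 0::2] = 2 * el
    dof[:, 1::2] = 2 * el + 1
    rows = np.repeat(dof, 8, axis=1).ravel()
    cols = np.tile(dof, (1, 8)).ravel()
    vals = np.tile(ke.ravel(), grid.n_elements)
    n = 2 * grid.n_nodes
    k = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return k


def nodal_forces(t: VectorField2D, grid: FEMGrid) -> np.ndarray:
    """Nodal load vector (N): minus the local traction times the pixel area.

    The traction sample of each masked pixel is converted to a force
    ``-t * a^2`` and shared equally among the pixel's four corner nodes.
    """
    h, w = grid.mask.shape
    if t.shape[0] < h or t.shape[1] < w:
        raise ValueError("traction field does not cover the FEM grid")
    a2 = (grid.grid_spacing * _UM) ** 2
    rows, cols = grid.pixel_index.T
    fx_el = -t.vx[rows, cols] * a2
    fy_el = -t.vy[rows, cols] * a2
    f = np.zeros(2 * grid.n_nodes)
    for corner in range(4):
        nid = grid.elements[:, corner]
        np.add.at(f, 2 * nid, 0.25 * fx_el)
        np.add.at(f, 2 * nid + 1, 0.25 * fy_el)
    return f


def balance_forces(
    f: np.ndarray, node_coords: np.ndarray
) -> tuple[np.ndarray, float]:
    """Remove the net force and net torque from a nodal load vector.

    The mean force vector is subtracted from every node; the residual torque
    about the grid's center of mass is then nulled by rotating every force
    vector by the closed-form angle ``alpha`` with
    ``tan(alpha) = -T0 / D0``, ``T0 = sum(r x f)``, ``D0 = sum(r . f)``.
    Returns the balanced vector and ``alpha`` (rad, typically < 5 deg).
    """
    f = np.asarray(f, dtype=float)
    if len(node_coords) < 2:
        raise ValueError("need at least 2 nodes to balance forces")
    fx, fy = f[0::2].copy(), f[1::2].copy()
    fx -= fx.mean()
    fy -= fy.mean()
    r = node_coords - node_coords.mean(axis=0)
    rx, ry = r[:, 0], r[:, 1]
    t0 = np.sum(rx * fy - ry * fx)
    d0 = np.sum(rx * fx + ry * fy)
    if t0 == 0.0 and d0 == 0.0:
        alpha = 0.0
    else:
        alpha = float(np.arctan2(-t0, d0))
    if alpha != 0.0:
        ca, sa = np.cos(alpha), np.sin(alpha)
        fx, fy = ca * fx - sa * fy, sa * fx + ca * fy
    out = np.empty_like(f)
    out[0::2] = fx
    out[1::2] = fy
    return out, alpha


def _constraint_rows(grid: FEMGrid) -> np.ndarray:
    """Zero-translation (x, y) and zero-rotation constraint rows (3, 2N)."""
    n = grid.n_nodes
    r = grid.nodes - grid.center_of_mass
    c = np.zeros((3, 2 * n))
    c[0, 0::2] = 1.0
    c[1, 1::2] = 1.0
    c[2, 0::2] = r[:, 1]   # sum(dx * ry - dy * rx) = 0
    c[2, 1::2] = -r[:, 0]
    return c


def solve_displacements(system: FEMSystem, scheme: str = "system") -> np.ndarray:
    """Solve ``K d = f`` with rigid-body motion removed.

    scheme="system" (default): the whole-system zero-translation and
    zero-rotation equations are imposed on top of ``K d = f``.  Because the
    balanced load is orthogonal to the three rigid-body null modes of
    ``K``, the combined system is consistent and its solution can be
    computed exactly by eliminating three anchoring degrees of freedom,
    solving the reduced nonsingular system, and then correcting the
    rigid-body component so that the three whole-system constraints hold
    to machine precision (this is algebraically identical to the
    least-squares/KKT solution of the stacked system, at a fraction of the
    factorization cost of the dense constraint rows).

    scheme="pinned": the classical alternative of pinning one node fully
    plus the y-displacement of a second node on the same grid row; the
    raw pinned solution is returned (its rigid positioning differs, but
    any strain/stress derived from it is identical).
    """
    k = system.stiffness.tocsr()
    f = system.forces
    if scheme == "system":
        d = _solve_anchored(k, f, system.grid, anchor="first")
        # exact whole-system constraint correction: shift by the rigid-body
        # combination that zeroes the three constraint equations
        c = _constraint_rows(system.grid)
        b = _rigid_basis(system.grid)
        coef = np.linalg.solve(c @ b.T, c @ d)
        d = d - b.T @ coef
    elif scheme == "pinned":
        d = _solve_anchored(k, f, system.grid, anchor="last")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if not np.isfinite(d).all():
        raise RuntimeError("FEM solve produced non-finite displacements")
    logger.debug(
        "rigid-motion constraint residual: %.3e", _constraint_residual(d, system.grid)
    )
    return d


def _solve_anchored(
    k: sparse.csr_matrix, f: np.ndarray, grid: FEMGrid, anchor: str
) -> np.ndarray:
    """Solve with three anchoring DOFs eliminated (node pinned + same-row dy)."""
    order = np.arange(grid.n_nodes) if anchor == "first" else np.arange(grid.n_nodes)[::-1]
    i0 = int(order[0])
    same_row = order[(grid.nodes[order, 1] == grid.nodes[i0, 1]) & (order != i0)]
    if len(same_row) == 0:
        raise RuntimeError("no second node available for the anchored solve")
    i1 = int(same_row[np.argmax(np.abs(grid.nodes[same_row, 0] - grid.nodes[i0, 0]))])
    fixed = np.array([2 * i0, 2 * i0 + 1, 2 * i1 + 1])
    free = np.setdiff1d(np.arange(k.shape[0]), fixed)
    d = np.zeros(k.shape[0])
    lu = splu(k[np.ix_(free, free)].tocsc(), permc_spec="MMD_AT_PLUS_A")
    d[free] = lu.solve(f[free])
    return d


def _rigid_basis(grid: FEMGrid) -> np.ndarray:
    n = grid.n_nodes
    r = grid.nodes - grid.center_of_mass
    basis = np.zeros((3, 2 * n))
    basis[0, 0::2] = 1.0
    basis[1, 1::2] = 1.0
    basis[2, 0::2] = -r[:, 1]
    basis[2, 1::2] = r[:, 0]
    return basis


def _project_out_rigid(d: np.ndarray, grid: FEMGrid) -> np.ndarray:
    basis = _rigid_basis(grid)
    for b in basis:
        d = d - (d @ b) / (b @ b) * b
    return d


def _constraint_residual(d: np.ndarray, grid: FEMGrid) -> float:
    c = _constraint_rows(grid)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        return 0.0
    return float(np.linalg.norm(c @ d / np.linalg.norm(c, axis=1)) / nrm)


def stress_from_displacements(
    d: np.ndarray,
    grid: FEMGrid,
    e_sheet: float = 1.0,
    nu_sheet: float = 0.5,
) -> tuple[StrainTensorField, StressTensorField]:
    """Strain and sheet stress (N/m) fields from nodal displacements.

    Strains are evaluated from the bilinear shape-function derivatives at
    each element center and assigned to the element's pixel; the stress
    follows from the plane-stress law
    ``(s11, s22, s12) = E/(1-nu^2) [[1, nu, 0], [nu, 1, 0], [0, 0, 1-nu]]
    (e11, e22, e12)`` (e12 is the tensor shear strain).
    """
    a_m = grid.grid_spacing * _UM
    el = grid.elements
    dx = d[2 * el]        # (M, 4) x-displacements of element corners, m
    dy = d[2 * el + 1]
    # center-point derivative weights for corners (-1,-1),(1,-1),(1,1),(-1,1)
    w_xi = np.array([-0.25, 0.25, 0.25, -0.25]) * 2.0 / a_m
    w_eta = np.array([-0.25, -0.25, 0.25, 0.25]) * 2.0 / a_m
    e11 = dx @ w_xi
    e22 = dy @ w_eta
    e12 = 0.5 * (dx @ w_eta + dy @ w_xi)
    fac = e_sheet / (1.0 - nu_sheet**2)
    s11 = fac * (e11 + nu_sheet * e22)
    s22 = fac * (nu_sheet * e11 + e22)
    s12 = fac * (1.0 - nu_sheet) * e12

    shape = grid.mask.shape
    rows, cols = grid.pixel_index.T

    def scatter(vals: np.ndarray) -> np.ndarray:
        out = np.zeros(shape)
        out[rows, cols] = vals
        return out

    strain = StrainTensorField(
        scatter(e11), scatter(e22), scatter(e12), grid.grid_spacing, grid.mask
    )
    stress = StressTensorField(
        scatter(s11), scatter(s22), scatter(s12), grid.grid_spacing, grid.mask
    )
    return strain, stress


def stress_from_traction(
    t: VectorField2D,
    mask: np.ndarray,
    e_sheet: float = 1.0,
    nu_sheet: float = 0.5,
    scheme: str = "system",
) -> tuple[StressTensorField, FEMSystem]:
    """Full monolayer-stress step: traction field + area mask -> stress tensor.

    Convenience wrapper chaining grid construction, load assembly, net
    force/torque balancing, the constrained solve and the strain/stress
    evaluation.  Returns the stress field and the solved system (whose
    ``balance_angle`` records the torque-nulling rotation).
    """
    grid = build_fem_grid(mask, t.grid_spacing)
    f = nodal_forces(t, grid)
    f, alpha = balance_forces(f, grid.nodes)
    k = assemble_stiffness(grid, e_sheet, nu_sheet)
    system = FEMSystem(grid, k, f, e_sheet, nu_sheet, balance_angle=alpha)
    d = solve_displacements(system, scheme=scheme)
    system.displacements = d
    _, stress = stress_from_displacements(d, grid, e_sheet, nu_sheet)
    return stress, system


def expand_mask(mask: np.ndarray, margin_um: float, grid_spacing: float) -> np.ndarray:
    """Grow a boolean mask by a Euclidean distance ``margin_um``."""
    mask = np.asarray(mask, dtype=bool)
    if margin_um <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=grid_spacing)
    return dist <= margin_um


def expansion_scan(
    t: VectorField2D,
    patch_mask: np.ndarray,
    margins_um: np.ndarray,
    eval_mask: np.ndarray | None = None,
    nu_sheet: float = 0.5,
):
    """Mean normal stress (and contractility) vs FEM-grid expansion margin.

    For each margin the FEM grid is spanned over the patch mask expanded by
    that distance; the mean normal stress is averaged over ``eval_mask``
    (default: the original patch outline) and the contractility is computed
    over the expanded area.  Returns a pandas DataFrame with columns
    ``margin_um``, ``mean_normal_stress``, ``contractility``.
    """
    import pandas as pd

    from .metrics import contractility as _contractility

    eval_mask = patch_mask if eval_mask is None else eval_mask
    rows = []
    for margin in np.asarray(margins_um, dtype=float):
        area = expand_mask(patch_mask, margin, t.grid_spacing)
        stress, _ = stress_from_traction(t, area, nu_sheet=nu_sheet)
        sel = eval_mask & stress.mask
        mean_normal = float(stress.mean_normal[sel].mean())
        _, contr = _contractility(t, area)
        rows.append(
            {"margin_um": float(margin), "mean_normal_stress": mean_normal,
             "contractility": contr}
        )
    return pd.DataFrame(rows)
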