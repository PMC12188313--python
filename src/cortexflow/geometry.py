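"""Elliptical embryo cross-section: geometry, triangulation and P1 finite elements.

The embryo cross-section is modelled as an ellipse (default semi-axes
27 x 15 µm, perimeter ~134 µm).  The cytoplasmic AIR-1 diffusion problem is
solved on a triangulation of this domain with linear (P1) elements.  Because
the ellipse is convex, a Delaunay triangulation of boundary + interior points
covers exactly the inscribed polygon, so no triangle culling is needed.

Conventions
-----------
* The boundary arclength origin sits at the *posterior pole* (the vertex on
  the positive x-axis) and runs counter-clockwise.
* Local refinement is expressed as (center, radius) disks; inside each disk
  the lattice spacing is reduced (default 4x, with an intermediate 2x annulus
  to grade the transition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import Delaunay


@dataclass(frozen=True)
class EmbryoGeometry:
    """Elliptical cross-section of the zygote, lengths in µm."""

    semi_major: float = 27.0
    semi_minor: float = 15.0

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError(
                "require semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})"
            )

    @property
    def perimeter(self) -> float:
        """Ellipse perimeter (µm), exact to machine precision."""
        from scipy.special import ellipe

        a, b = self.semi_major, self.semi_minor
        m = 1.0 - (b / a) ** 2  # eccentricity squared
        return 4.0 * a * float(ellipe(m))

    @property
    def area(self) -> float:
        return np.pi * self.semi_major * self.semi_minor

    def contains(self, pts: np.ndarray, shrink: float = 0.0) -> np.ndarray:
        """Boolean mask of points strictly inside the (optionally shrunk) ellipse."""
        pts = np.atleast_2d(pts)
        a = self.semi_major - shrink
        b = self.semi_minor - shrink
        return (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 < 1.0

    def boundary_points(self, target_edge: float) -> np.ndarray:
        """Arclength-uniform points on the ellipse, symmetric about both axes.

        The point count is rounded to a multiple of 4 so that both poles and
        both minor-axis vertices are mesh nodes and the ring is mirror
        symmetric, which the downstream symmetry invariants rely on.
        """
        n = int(np.ceil(self.perimeter / target_edge / 4.0)) * 4
        # invert the arclength function s(theta) on a fine parameter grid
        theta_fine = np.linspace(0.0, 2.0 * np.pi, 40 * n + 1)
        dx = -self.semi_major * np.sin(theta_fine)
        dy = self.semi_minor * np.cos(theta_fine)
        ds = np.hypot(dx, dy)
        s = np.concatenate(
            [[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(theta_fine))]
        )
        s_targets = np.arange(n) * s[-1] / n
        theta = np.interp(s_targets, s, theta_fine)
        # enforce exact mirror symmetry of the parameter set
        quarter = theta[: n // 4 + 1]
        theta_sym = np.concatenate(
            [
                quarter[:-1],
                np.pi - quarter[::-1][1:],
                np.pi + quarter[1:-1],
                2.0 * np.pi - quarter[::-1][:-1],
            ]
        )
        return np.column_stack(
            [self.semi_major * np.cos(theta_sym), self.semi_minor * np.sin(theta_sym)]
        )


@dataclass
class TriMesh:
    """P1 triangulation with an ordered (CCW) boundary loop.

    Attributes
    ----------
    points : (n, 2) node coordinates, µm.
    triangles : (m, 3) index triples, positively oriented.
    boundary : (nb,) node indices forming a closed CCW loop starting at the
        posterior pole.
    boundary_arclength : (nb,) cumulative polygonal arclength at each boundary
        node, starting at 0.
    """

    points: np.ndarray
    triangles: np.ndarray
    boundary: np.ndarray
    boundary_arclength: np.ndarray

    @property
    def boundary_perimeter(self) -> float:
        """Total polygonal perimeter (closing segment included)."""
        p = self.points[self.boundary]
        closing = np.linalg.norm(p[0] - p[-1])
        return float(self.boundary_arclength[-1] + closing)

    def signed_areas(self) -> np.ndarray:
        p = self.points
        t = self.triangles
        d1 = p[t[:, 1]] - p[t[:, 0]]
        d2 = p[t[:, 2]] - p[t[:, 0]]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    @property
    def area(self) -> float:
        return float(self.signed_areas().sum())


def _hex_lattice(geom: EmbryoGeometry, h: float) -> np.ndarray:
    """Hexagonal lattice covering the ellipse, mirror symmetric about y=0."""
    dy = h * np.sqrt(3.0) / 2.0
    jmax = int(np.ceil(geom.semi_minor / dy))
    rows = []
    for j in range(-jmax, jmax + 1):
        y = j * dy
        offset = 0.5 * h if (abs(j) % 2 == 1) else 0.0
        imax = int(np.ceil(geom.semi_major / h)) + 1
        x = np.arange(-imax, imax + 1) * h + offset
        rows.append(np.column_stack([x, np.full_like(x, y)]))
    return np.vstack(rows)


def build_mesh(
    geometry: EmbryoGeometry,
    target_edge_length: float = 0.5,
    refine_near: list[tuple[tuple[float, float], float]] | None = None,
    refine_factor: int = 4,
) -> TriMesh:
    """Triangulate the embryo cross-section.

    Parameters
    ----------
    target_edge_length : global lattice spacing, µm; must be positive and
        smaller than the minor semi-axis.
    refine_near : optional list of ((x, y), radius) disks; inside each the
        spacing is ``target_edge_length / refine_factor`` with a 2x-coarser
        grading annulus of equal width around it.
    """
    h = float(target_edge_length)
    if not (0.0 < h < geometry.semi_minor):
        raise ValueError("target_edge_length must be in (0, semi_minor)")

    ring = geometry.boundary_points(h)
    pts = [ring]

    interior = _hex_lattice(geometry, h)
    # keep interior points well inside the ring to avoid boundary slivers
    mask = geometry.contains(interior, shrink=0.55 * h)
    interior = interior[mask]

    refine_near = refine_near or []
    for center, radius in refine_near:
        c = np.asarray(center, dtype=float)
        if not geometry.contains(c[None, :])[0]:
            raise ValueError(f"refinement center {center} lies outside the ellipse")
        r_fine = float(radius)
        r_mid = 2.0 * r_fine
        d = np.linalg.norm(interior - c, axis=1)
        interior = interior[d > r_mid]
        for hh, rlo, rhi in (
            (h / 2.0, r_fine, r_mid),
            (h / refine_factor, 0.0, r_fine),
        ):
            patch = _hex_lattice(geometry, hh)
            patch = patch + c  # center the fine lattice on the source point
            dp = np.linalg.norm(patch - c, axis=1)
            sel = (dp >= rlo) & (dp < rhi)
            patch = patch[sel]
            patch = patch[geometry.contains(patch, shrink=0.55 * hh)]
            pts.append(patch)
    pts.insert(1, interior)
    points = np.vstack(pts)
    if refine_near:
        # overlapping refinement disks may duplicate lattice points
        _, keep_idx = np.unique(np.round(points / (1e-9 * h)), axis=0, return_index=True)
        keep_mask = np.zeros(len(points), dtype=bool)
        keep_mask[keep_idx] = True
        keep_mask[: len(ring)] = True  # never drop ring nodes
        order = np.concatenate(
            [np.arange(len(ring)), np.where(keep_mask[len(ring) :])[0] + len(ring)]
        )
        points = points[order]

    tri = Delaunay(points)
    triangles = tri.simplices.copy()
    # orient positively
    p = points
    d1 = p[triangles[:, 1]] - p[triangles[:, 0]]
    d2 = p[triangles[:, 2]] - p[triangles[:, 0]]
    areas = 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    flip = areas < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]
    # drop exactly degenerate triangles (co-linear points), if any
    keep = np.abs(areas) > 1e-12 * h * h
    triangles = triangles[keep]

    nb = len(ring)
    boundary = np.arange(nb)
    seg = np.linalg.norm(np.diff(points[boundary], axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])
    return TriMesh(
        points=points,
        triangles=triangles,
        boundary=boundary,
        boundary_arclength=arclength,
    )


@dataclass
class FemSystem:
    """Assembled P1 mass and stiffness matrices (CSR, symmetric)."""

    mass: sparse.csr_matrix
    stiffness: sparse.csr_matrix
    quadrature: str = "P1-consistent-mass / 7-point-source"


def assemble_fem(mesh: TriMesh) -> FemSystem:
    """Assemble consistent mass and stiffness matrices for linear elements.

    Element mass is |T|/12 * (1 + delta_ij); element stiffness follows the
    standard gradient formula for P1 basis functions.  Raises on inverted
    elements.
    """
    p = mesh.points
    t = mesh.triangles
    areas = mesh.signed_areas()
    if np.any(areas <= 0):
        raise ValueError("mesh contains inverted or degenerate triangles")

    n = len(p)
    x = p[t, 0]  # (m, 3)
    y = p[t, 1]
    # P1 gradient coefficients: grad(phi_i) = (b_i, c_i) / (2A)
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)

    rows, cols, kv, mv = [], [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(t[:, i])
            cols.append(t[:, j])
            kv.append((b[:, i] * b[:, j] + c[:, i] * c[:, j]) / (4.0 * areas))
            mv.append(areas / 12.0 * (2.0 if i == j else 1.0))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    K = sparse.coo_matrix((np.concatenate(kv), (rows, cols)), shape=(n, n)).tocsr()
    M = sparse.coo_matrix((np.concatenate(mv), (rows, cols)), shape=(n, n)).tocsr()
    return FemSystem(mass=M, stiffness=K)


# Dunavant 7-point rule, degree 5, for the Gaussian source term
_QP_BARY = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],
        [0.05971587178977, 0.47014206410512, 0.47014206410512],
        [0.47014206410512, 0.05971587178977, 0.47014206410512],
        [0.47014206410512, 0.47014206410512, 0.05971587178977],
        [0.79742698535309, 0.10128650732346, 0.10128650732346],
        [0.10128650732346, 0.79742698535309, 0.10128650732346],
        [0.10128650732346, 0.10128650732346, 0.79742698535309],
    ]
)
_QP_W = np.array(
    [
        0.225,
        0.13239415278851,
        0.13239415278851,
        0.13239415278851,
        0.12593918054483,
        0.12593918054483,
        0.12593918054483,
    ]
)


def assemble_load(mesh: TriMesh, f) -> np.ndarray:
    """Load vector b_i = int f * phi_i, via a degree-5 quadrature per element.

    ``f`` maps an (n, 2) array of points to source-density values.
    """
    p = mesh.points
    t = mesh.triangles
    areas = mesh.signed_areas()
    verts = p[t]  # (m, 3, 2)
    b = np.zeros(len(p))
    for bary, w in zip(_QP_BARY, _QP_W):
        qp = np.einsum("k,mkd->md", bary, verts)
        fv = np.asarray(f(qp))
        for i in range(3):
            np.add.at(b, t[:, i], w * areas * fv * bary[i])
    return b


def export_mesh(mesh: TriMesh, path) -> None:
    """Write the mesh as plain-text node / element / boundary tables."""
    with open(path, "w") as fh:
        fh.write(f"# nodes {len(mesh.points)}\n")
        np.savetxt(fh, mesh.points, fmt="%.10g")
        fh.write(f"# triangles {len(mesh.triangles)}\n")
        np.savetxt(fh, mesh.triangles, fmt="%d")
        fh.write(f"# boundary {len(mesh.boundary)}\n")
        np.savetxt(
            fh,
            np.column_stack([mesh.boundary, mesh.boundary_arclength]),
            fmt="%.10g",
        )


def import_mesh(path) -> TriMesh:
    """Read a mesh written by :func:`export_mesh`."""
    with open(path) as fh:
        lines = fh.readlines()
    idx = [i for i, ln in enumerate(lines) if ln.startswith("#")]
    n_nodes = int(lines[idx[0]].split()[-1])
    pts = np.loadtxt(lines[idx[0] + 1 : idx[0] + 1 + n_nodes])
    n_tri = int(lines[idx[1]].split()[-1])
    tris = np.loadtxt(lines[idx[1] + 1 : idx[1] + 1 + n_tri], dtype=int)
    n_b = int(lines[idx[2]].split()[-1])
    btab = np.loadtxt(lines[idx[2] + 1 : idx[2] + 1 + n_b])
    return TriMesh(
        points=pts,
        triangles=tris,
        boundary=btab[:, 0].astype(int),
        boundary_arclength=btab[:, 1],
    )
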