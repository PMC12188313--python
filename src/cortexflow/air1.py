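"""Steady AIR-1 diffusion from centrosomal sources to the cortex.

Aurora A kinase (AIR-1) is activated on the centrosome(s), diffuses through
the cytoplasm, is inactivated at a basal (phosphatase) rate, and cannot cross
the cell boundary.  Normalising by the cytoplasmic diffusivity D, the steady
concentration a(x) on the cross-section solves

    -laplacian(a) + kappa_hat * a = f(x)   in the ellipse,
    da/dn = 0                              on the boundary,

where f is a sum of isotropic Gaussians of width sigma_c centred on the
centrosomes, normalised so its domain integral is C0/D (split equally between
centrosomes), and kappa_hat (µm^-2) is the inactivation rate over D.  The
cortical AIR-1 input to the 1D contractility model is the trace of a(x) on
the boundary, interpolated onto a uniform periodic arclength grid.

Units: the absolute scale of a is arbitrary; the package fixes the unit by a
single calibration of the reference polarization profile (see
:func:`calibration_scale`), under which the AIR-1 saturation threshold
A_sat = 0.25 sits near posterior cytokinesis levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import splu

from .geometry import EmbryoGeometry, FemSystem, TriMesh, assemble_fem, assemble_load, build_mesh

# The AIR-1 unit is fixed by the myosin-free calibration: under the
# reference polarization profile (centrosomes 1.9 µm from the posterior
# pole) the steady ECT-2 asymmetry is 1.2 when the inhibition coupling is
# K_AE = 1.3.  These two constants define the scale of every profile.
CALIBRATION_K_AE = 1.3
CALIBRATION_ASYMMETRY = 1.2
POLARIZATION_DISTANCE = 1.9  # µm, centrosome pair to posterior cortex

# centrosome source widths (µm): half of the centrosome diameter
SIGMA_POLARIZATION = 0.175
SIGMA_CYTOKINESIS = 0.7
# cue strengths C0/D (arbitrary units; only the 32x ratio is meaningful)
C0_POLARIZATION = 1.0 / 32.0
C0_CYTOKINESIS = 1.0


@dataclass(frozen=True)
class CentrosomeCue:
    """Gaussian centrosome source(s).

    centers : tuple of (x, y) positions, µm, strictly inside the ellipse.
    sigma_c : Gaussian width, µm (~half the centrosome radius pair).
    C0_over_D : total source integral over the cross-section, split equally
        between centrosomes.
    """

    centers: tuple[tuple[float, float], ...]
    sigma_c: float
    C0_over_D: float

    def __post_init__(self) -> None:
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be positive")
        if self.C0_over_D <= 0:
            raise ValueError("C0_over_D must be positive")

    def validate_inside(self, geometry: EmbryoGeometry) -> None:
        pts = np.asarray(self.centers, dtype=float)
        if not np.all(geometry.contains(pts)):
            raise ValueError("centrosome centers must lie inside the ellipse")


def polarization_cue(
    distance: float = POLARIZATION_DISTANCE,
    geometry: EmbryoGeometry | None = None,
    sigma_c: float = SIGMA_POLARIZATION,
    C0_over_D: float = C0_POLARIZATION,
) -> CentrosomeCue:
    """Both (co-located) centrosomes ``distance`` µm from the posterior pole.

    The two immature centrosomes sit at the same point on the major axis,
    splitting the cue strength equally.
    """
    geometry = geometry or EmbryoGeometry()
    x = geometry.semi_major - distance
    return CentrosomeCue(
        centers=((x, 0.0), (x, 0.0)), sigma_c=sigma_c, C0_over_D=C0_over_D
    )


def cytokinesis_cue(
    centers: tuple[tuple[float, float], ...],
    sigma_c: float = SIGMA_CYTOKINESIS,
    C0_over_D: float = C0_CYTOKINESIS,
) -> CentrosomeCue:
    """Mature centrosome pair at explicit positions (µm)."""
    return CentrosomeCue(centers=tuple(centers), sigma_c=sigma_c, C0_over_D=C0_over_D)


def gaussian_source(cue: CentrosomeCue, points: np.ndarray) -> np.ndarray:
    """Source density f at ``points`` ((n, 2) array).

    Sum of 2D isotropic Gaussians with std sigma_c; each centrosome carries
    C0_over_D / n_centrosomes so the full-plane integral is C0_over_D.
    """
    pts = np.atleast_2d(points)
    out = np.zeros(len(pts))
    strength = cue.C0_over_D / len(cue.centers)
    norm = strength / (2.0 * np.pi * cue.sigma_c**2)
    for cx, cy in cue.centers:
        r2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
        out += norm * np.exp(-r2 / (2.0 * cue.sigma_c**2))
    return out


@dataclass
class Air1Field:
    """Nodal AIR-1 concentration on a mesh plus the rate used to produce it."""

    values: np.ndarray  # nodal a(x), arbitrary units
    kappa_hat: float  # µm^-2

    def __post_init__(self) -> None:
        if np.min(self.values) < -1e-12 * max(1.0, np.max(np.abs(self.values))):
            raise ValueError("AIR-1 field has significantly negative values")


@dataclass
class Air1Profile:
    """Periodic cortical AIR-1 profile on a uniform arclength grid.

    grid : x_hat in [0, 1), fraction of perimeter from the posterior pole
        (counter-clockwise); values sampled at the grid points.
    """

    grid: np.ndarray
    values: np.ndarray

    def at(self, x_hat: np.ndarray | float) -> np.ndarray | float:
        """Periodic linear interpolation."""
        xq = np.mod(np.asarray(x_hat, dtype=float), 1.0)
        gx = np.concatenate([self.grid, [1.0]])
        gv = np.concatenate([self.values, [self.values[0]]])
        out = np.interp(xq, gx, gv)
        return float(out) if np.isscalar(x_hat) else out

    def scaled(self, factor: float) -> "Air1Profile":
        return Air1Profile(grid=self.grid, values=self.values * factor)


def solve_steady_air1(
    fem: FemSystem,
    mesh: TriMesh,
    cue: CentrosomeCue,
    kappa_hat: float,
) -> Air1Field:
    """Solve (K + kappa_hat * M) a = b with the Gaussian load.

    kappa_hat must be positive: with pure-Neumann boundaries and a net
    source, the kappa_hat = 0 steady problem has no solution.
    """
    if kappa_hat <= 0:
        raise ValueError("kappa_hat must be positive (pure-Neumann steady "
                         "problem with a net source is inconsistent)")
    b = assemble_load(mesh, lambda p: gaussian_source(cue, p))
    A = (fem.stiffness + kappa_hat * fem.mass).tocsc()
    a = splu(A).solve(b)
    # clip roundoff-level negatives (maximum principle guarantees a >= 0)
    a[a < 0] = np.where(a[a < 0] > -1e-12, 0.0, a[a < 0])
    return Air1Field(values=a, kappa_hat=kappa_hat)


def extract_boundary_profile(
    field: Air1Field, mesh: TriMesh, n_grid: int = 1000
) -> Air1Profile:
    """Linear-in-arclength interpolation of boundary nodal values.

    The uniform grid has points at i/n_grid (i = 0 ... n_grid-1); point 0 is
    the posterior pole.  Periodic wrap is handled exactly by appending the
    closing boundary segment.
    """
    if n_grid < 64:
        raise ValueError("n_grid must be >= 64")
    s = mesh.boundary_arclength
    if np.any(np.diff(s) <= 0):
        raise ValueError("boundary arclength must be strictly increasing "
                         "(unordered boundary loop)")
    total = mesh.boundary_perimeter
    vals = field.values[mesh.boundary]
    s_ext = np.concatenate([s, [total]])
    v_ext = np.concatenate([vals, [vals[0]]])
    grid = np.arange(n_grid) / n_grid
    values = np.interp(grid * total, s_ext, v_ext)
    return Air1Profile(grid=grid, values=values)


def _pole_values(profile: Air1Profile) -> tuple[float, float]:
    """(posterior, anterior) boundary AIR-1."""
    return float(profile.at(0.0)), float(profile.at(0.5))


def choose_phosphatase_rate(
    geometry: EmbryoGeometry | None = None,
    target_ratio: float = 0.01,
    scan: np.ndarray | None = None,
    target_edge_length: float = 0.5,
    n_grid: int = 1000,
) -> float:
    """Smallest kappa_hat for which anterior AIR-1 < 1% of posterior AIR-1.

    Scans a logarithmic kappa_hat grid (default 1e-4 to 1 µm^-2, 25 points
    per decade) with the reference polarization cue (centrosomes 1.9 µm from
    the posterior pole).  The anterior/posterior ratio decreases with
    kappa_hat, so the scan stops at the first passing value.
    """
    geometry = geometry or EmbryoGeometry()
    if scan is None:
        scan = np.logspace(-4.0, 0.0, 101)
    cue = polarization_cue(geometry=geometry)
    cue.validate_inside(geometry)
    mesh = build_mesh(
        geometry,
        target_edge_length=target_edge_length,
        refine_near=[(cue.centers[0], 3.0 * cue.sigma_c)],
    )
    fem = assemble_fem(mesh)
    b = assemble_load(mesh, lambda p: gaussian_source(cue, p))
    last_ratio = np.inf
    for kappa in np.sort(np.asarray(scan, dtype=float)):
        A = (fem.stiffness + kappa * fem.mass).tocsc()
        a = splu(A).solve(b)
        prof = extract_boundary_profile(Air1Field(values=np.maximum(a, 0.0),
                                                  kappa_hat=kappa),
                                        mesh, n_grid=n_grid)
        post, ant = _pole_values(prof)
        last_ratio = ant / post
        if last_ratio < target_ratio:
            return float(kappa)
    raise RuntimeError(
        f"anterior/posterior criterion unreachable in scan range; best ratio "
        f"achieved {last_ratio:.3g}"
    )


def calibration_scale(
    reference_profile: Air1Profile,
    A_sat: float = 0.25,
    K_AE: float = CALIBRATION_K_AE,
    asymmetry: float = CALIBRATION_ASYMMETRY,
) -> float:
    """Factor putting the reference polarization profile in model units.

    The absolute AIR-1 scale is arbitrary; the model's unit is fixed by the
    myosin-depleted calibration: with inhibition K_AE = 1.3 the steady
    ECT-2 asymmetry under the reference polarization profile is 1.2.  In
    the myosin-free steady state E(x) is proportional to
    1 / (1 + K_AE * min(A, A_sat)), so the asymmetry condition is a scalar
    root-find on the scale factor.  The same factor applies to every other
    configuration, preserving the 32x cytokinesis/polarization
    cue-strength ratio.
    """
    from scipy.optimize import brentq

    A_max = float(np.max(reference_profile.values))
    A_min = float(np.min(reference_profile.values))

    def asym_minus_target(alpha: float) -> float:
        num = 1.0 + K_AE * min(alpha * A_max, A_sat)
        den = 1.0 + K_AE * min(alpha * A_min, A_sat)
        return num / den - asymmetry

    # cap the bracket where the peak reaches saturation: beyond that the
    # numerator clamps while the denominator keeps growing
    hi = A_sat / A_max
    if asym_minus_target(hi) < 0:
        raise RuntimeError("calibration target asymmetry unreachable "
                           "(profile too flat)")
    return float(brentq(asym_minus_target, 1e-12, hi, xtol=1e-12))


def boundary_profile_for_cue(
    cue: CentrosomeCue,
    kappa_hat: float,
    geometry: EmbryoGeometry | None = None,
    target_edge_length: float = 0.5,
    n_grid: int = 1000,
) -> Air1Profile:
    """Convenience pipeline: mesh (refined at the centrosomes), solve, extract."""
    geometry = geometry or EmbryoGeometry()
    cue.validate_inside(geometry)
    refine = [(c, 3.0 * cue.sigma_c) for c in set(cue.centers)]
    mesh = build_mesh(geometry, target_edge_length=target_edge_length,
                      refine_near=refine)
    fem = assemble_fem(mesh)
    field = solve_steady_air1(fem, mesh, cue, kappa_hat)
    return extract_boundary_profile(field, mesh, n_grid=n_grid)


def export_profile(profile: Air1Profile, path) -> None:
    """Two-column CSV: arclength fraction, AIR-1 (a.u.)."""
    np.savetxt(path, np.column_stack([profile.grid, profile.values]),
               delimiter=",", header="x_hat,air1", comments="")
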