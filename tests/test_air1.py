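"""Steady AIR-1 diffusion solve and cortical profile extraction."""

import numpy as np
import pytest
from scipy.integrate import solve_bvp

from cortexflow import air1
from cortexflow.geometry import EmbryoGeometry, assemble_fem, assemble_load, build_mesh


def test_gaussian_source_peaks_at_center_and_normalises(coarse_mesh):
    cue = air1.CentrosomeCue(centers=((20.0, 0.0),), sigma_c=0.5,
                             C0_over_D=2.0)
    at_center = air1.gaussian_source(cue, np.array([[20.0, 0.0]]))[0]
    elsewhere = air1.gaussian_source(cue, coarse_mesh.points)
    assert at_center >= elsewhere.max()
    b = assemble_load(coarse_mesh, lambda p: air1.gaussian_source(cue, p))
    assert b.sum() == pytest.approx(2.0, rel=1e-3)


def test_two_centrosomes_split_strength():
    cue = air1.polarization_cue()
    one = air1.CentrosomeCue(centers=(cue.centers[0],), sigma_c=cue.sigma_c,
                             C0_over_D=cue.C0_over_D)
    pts = np.array([[25.0, 0.5], [20.0, -3.0]])
    assert np.allclose(air1.gaussian_source(cue, pts),
                       air1.gaussian_source(one, pts))


def test_cue_validation():
    with pytest.raises(ValueError):
        air1.CentrosomeCue(centers=((0, 0),), sigma_c=0.0, C0_over_D=1.0)
    with pytest.raises(ValueError):
        air1.CentrosomeCue(centers=((0, 0),), sigma_c=1.0, C0_over_D=0.0)
    cue = air1.CentrosomeCue(centers=((40.0, 0.0),), sigma_c=1.0, C0_over_D=1.0)
    with pytest.raises(ValueError):
        cue.validate_inside(EmbryoGeometry())


def test_uniform_source_gives_constant_solution(coarse_mesh, coarse_fem):
    """With f = c the exact solution is a = c / kappa (K annihilates it)."""
    c, kappa = 0.7, 0.05
    b = assemble_load(coarse_mesh, lambda p: np.full(len(p), c))
    from scipy.sparse.linalg import spsolve

    a = spsolve((coarse_fem.stiffness + kappa * coarse_fem.mass).tocsc(), b)
    assert np.allclose(a, c / kappa, rtol=1e-8)


def test_kappa_zero_rejected(coarse_mesh, coarse_fem):
    with pytest.raises(ValueError):
        air1.solve_steady_air1(coarse_fem, coarse_mesh,
                               air1.polarization_cue(), 0.0)


def test_radial_oracle_on_disk():
    """Centered Gaussian source in a disk vs the radially symmetric ODE.

    The 1D oracle solves a'' + a'/r - kappa a = -f(r), a'(0) = a'(R) = 0,
    by independent two-point boundary-value integration.
    """
    R, sigma, kappa, C0 = 10.0, 0.5, 0.05, 1.0
    geom = EmbryoGeometry(semi_major=R, semi_minor=R)
    mesh = build_mesh(geom, target_edge_length=0.4,
                      refine_near=[((0.0, 0.0), 3 * sigma)])
    fem = assemble_fem(mesh)
    cue = air1.CentrosomeCue(centers=((0.0, 0.0),), sigma_c=sigma,
                             C0_over_D=C0)
    field = air1.solve_steady_air1(fem, mesh, cue, kappa)

    def f(r):
        return C0 / (2 * np.pi * sigma**2) * np.exp(-(r**2) / (2 * sigma**2))

    def rhs(r, y):
        r = np.maximum(r, 1e-9)
        return np.vstack([y[1], kappa * y[0] - f(r) - y[1] / r])

    def bc(ya, yb):
        return np.array([ya[1], yb[1]])

    r_grid = np.linspace(1e-6, R, 400)
    y0 = np.zeros((2, r_grid.size))
    sol = solve_bvp(rhs, bc, r_grid, y0, tol=1e-8, max_nodes=40000)
    assert sol.success

    radii = np.linalg.norm(mesh.points, axis=1)
    sample = (radii > 1.0) & (radii < R - 0.5)
    oracle = sol.sol(radii[sample])[0]
    rel = np.abs(field.values[sample] - oracle) / oracle.max()
    assert rel.max() < 0.01


def test_conservation_identity(coarse_mesh, coarse_fem):
    """kappa * integral(a) equals the injected source integral (no-flux)."""
    cue = air1.polarization_cue()
    kappa = 0.01
    field = air1.solve_steady_air1(coarse_fem, coarse_mesh, cue, kappa)
    total = kappa * float((coarse_fem.mass @ field.values).sum())
    assert total == pytest.approx(cue.C0_over_D, rel=0.01)
    assert field.values.min() >= -1e-12


def test_solution_linear_in_source_strength(coarse_mesh, coarse_fem):
    cue1 = air1.polarization_cue()
    cue3 = air1.polarization_cue(C0_over_D=3 * cue1.C0_over_D)
    a1 = air1.solve_steady_air1(coarse_fem, coarse_mesh, cue1, 0.01).values
    a3 = air1.solve_steady_air1(coarse_fem, coarse_mesh, cue3, 0.01).values
    assert np.allclose(a3, 3 * a1, rtol=1e-9, atol=1e-16)


def test_posterior_air1_decays_with_centrosome_distance(coarse_mesh, coarse_fem):
    values = []
    for d in (1.9, 5.0, 10.0):
        cue = air1.polarization_cue(distance=d)
        field = air1.solve_steady_air1(coarse_fem, coarse_mesh, cue, 0.01)
        prof = air1.extract_boundary_profile(field, coarse_mesh, n_grid=256)
        values.append(prof.at(0.0))
    assert values[0] > values[1] > values[2]


def test_symmetric_cue_gives_symmetric_profile(coarse_mesh, coarse_fem):
    """On-axis sources: reflection about the major axis maps x to 1-x."""
    cue = air1.cytokinesis_cue(((10.0, 0.0), (-10.0, 0.0)), sigma_c=1.0)
    field = air1.solve_steady_air1(coarse_fem, coarse_mesh, cue, 0.01)
    prof = air1.extract_boundary_profile(field, coarse_mesh, n_grid=512)
    mirrored = prof.values[::-1]
    mirrored = np.roll(mirrored, 1)  # x -> 1 - x keeps the pole sample fixed
    assert np.max(np.abs(prof.values - mirrored)) < 0.01 * prof.values.max()


def test_extract_constant_field_and_grid_refinement(coarse_mesh):
    const = air1.Air1Field(values=np.full(len(coarse_mesh.points), 2.5),
                           kappa_hat=1.0)
    prof = air1.extract_boundary_profile(const, coarse_mesh, n_grid=128)
    assert np.allclose(prof.values, 2.5)

    cue = air1.polarization_cue()
    fem = assemble_fem(coarse_mesh)
    field = air1.solve_steady_air1(fem, coarse_mesh, cue, 0.01)
    p1 = air1.extract_boundary_profile(field, coarse_mesh, n_grid=500)
    p2 = air1.extract_boundary_profile(field, coarse_mesh, n_grid=1000)
    # doubling the grid only adds points between linear interpolants
    change = np.max(np.abs(p2.values[::2] - p1.values))
    assert change < 1e-12 * p1.values.max()
    with pytest.raises(ValueError):
        air1.extract_boundary_profile(field, coarse_mesh, n_grid=32)


def test_unordered_boundary_rejected(coarse_mesh):
    import copy

    mesh = copy.deepcopy(coarse_mesh)
    mesh.boundary_arclength = mesh.boundary_arclength[::-1].copy()
    field = air1.Air1Field(values=np.zeros(len(mesh.points)), kappa_hat=1.0)
    with pytest.raises(ValueError):
        air1.extract_boundary_profile(field, mesh)


def test_phosphatase_rate_selection(coarse_mesh, coarse_fem):
    """Anterior/posterior ratio decreases in kappa; the returned rate is the
    smallest scanned value meeting the <1% criterion."""
    cue = air1.polarization_cue()
    ratios = []
    for kappa in (1e-3, 5e-3, 2e-2, 1e-1):
        field = air1.solve_steady_air1(coarse_fem, coarse_mesh, cue, kappa)
        prof = air1.extract_boundary_profile(field, coarse_mesh, n_grid=256)
        ratios.append(prof.at(0.5) / prof.at(0.0))
    assert all(a > b for a, b in zip(ratios, ratios[1:]))

    scan = np.logspace(-3, -1, 21)
    kap = air1.choose_phosphatase_rate(target_edge_length=1.0, scan=scan,
                                       n_grid=256)
    field = air1.solve_steady_air1(coarse_fem, coarse_mesh, cue, kap)
    prof = air1.extract_boundary_profile(field, coarse_mesh, n_grid=256)
    assert prof.at(0.5) / prof.at(0.0) < 0.01
    # smaller scanned value fails the criterion
    idx = np.searchsorted(scan, kap) - 1
    field_lo = air1.solve_steady_air1(coarse_fem, coarse_mesh, cue,
                                      scan[idx])
    prof_lo = air1.extract_boundary_profile(field_lo, coarse_mesh,
                                            n_grid=256)
    assert prof_lo.at(0.5) / prof_lo.at(0.0) >= 0.01


def test_boundary_profile_mesh_convergence():
    """Halving the edge length changes the boundary profile by <1%."""
    cue = air1.polarization_cue()
    vals = {}
    for edge in (1.0, 0.5):
        prof = air1.boundary_profile_for_cue(cue, 0.01,
                                             target_edge_length=edge,
                                             n_grid=500)
        vals[edge] = prof.values
    diff = np.max(np.abs(vals[1.0] - vals[0.5])) / vals[0.5].max()
    assert diff < 0.01


def test_calibration_scale_fixes_asymmetry():
    """The calibrated profile satisfies the myosin-free 1.2/1.3 relation."""
    cue = air1.polarization_cue()
    prof = air1.boundary_profile_for_cue(cue, 0.01, target_edge_length=1.0,
                                         n_grid=256)
    alpha = air1.calibration_scale(prof)
    A = prof.values * alpha
    sat = np.minimum(A, 0.25)
    asym = (1 + 1.3 * sat.max()) / (1 + 1.3 * sat.min())
    assert asym == pytest.approx(1.2, abs=1e-9)
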