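"""Dimensionless 1D periodic ECT-2 / myosin / flow model of the active cortex.

State variables on the periodic domain x_hat in [0, 1) (fraction of the
embryo perimeter, origin at the posterior pole):

* E — cortex-bound ECT-2, in units of the concentration were all ECT-2 bound;
* M — cortex-bound myosin, same convention;
* v — cortical flow velocity, in units of perimeter per myosin lifetime.

Time is measured in bound-myosin lifetimes (tau_M ~ 15 s).  The cytoplasm is
well mixed, so the free pools are the complements E_c = 1 - mean(E),
M_c = 1 - mean(M); total mass of each species is conserved by construction.

Dynamics:

    dE/dt = D_E d2E - d(vE) + Kon_E (1 + K_ME M) E_c
            - Koff_E (1 + K_AE min(A, A_sat)) E
    dM/dt = D_M d2M - d(vM) + K_EM E M_c - M - K_fb M^k
    (1 - l_hat^2 d2) v = V_hat dM,   mean(v) = 0

ECT-2 binds with a basal rate Kon_E, boosted by myosin-associated
recruitment (factor 1 + K_ME M); it unbinds at rate Koff_E, boosted by
AIR-1-dependent phosphorylation which saturates (hard clamp) at A_sat.
Myosin is activated by cortical ECT-2 and inactivated at a basal rate (the
time unit) plus a nonlinear RhoGAP-mediated term K_fb M^k.  The velocity
balances myosin-proportional active stress against viscosity and friction;
l_hat is the hydrodynamic length as a fraction of the perimeter.

Kon_E is not free: it is re-solved so that the uniform AIR-1-free steady
state keeps fraction f_E of ECT-2 bound (10%); K_EM/K_fb are chosen so that
the same state keeps ~30% of myosin bound.

Numerics: first-order upwind finite volumes for advection, implicit
three-point-Laplacian diffusion, explicit reactions, first-order-in-time
operator splitting.  The periodic centered-difference velocity solve and the
implicit diffusion solves are diagonalised exactly by the FFT.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .air1 import Air1Profile

#: dimensional anchors (µm, s) used for unit conversion helpers
PERIMETER_UM = 134.65371359544588  # 27 x 15 µm ellipse
TAU_M_S = 15.0


@dataclass(frozen=True)
class CortexParams:
    """Dimensionless parameters of the cortex model (myosin-lifetime units).

    Defaults are the fitted cytokinesis set for k = 2; polarization runs
    raise Koff_E by 20% (`polarization=True` in :func:`default_params`).
    V_hat has no universal default — it is fitted to a 10 µm/min peak flow
    (see paramfit) — but carries the value obtained from the canonical
    synthetic target profiles so the model is runnable out of the box.
    """

    D_E: float = 0.1 * TAU_M_S / PERIMETER_UM**2
    D_M: float = 0.1 * TAU_M_S / PERIMETER_UM**2
    l_hat: float = 0.1
    V_hat: float = 0.05
    Koff_E: float = 5.0
    K_ME: float = 2.5
    K_AE: float = 1.3
    A_sat: float = 0.25
    K_EM: float = 9.0
    K_fb: float = 3.6
    k: int = 2
    f_E: float = 0.1
    f_M: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.l_hat < 0.5):
            raise ValueError("l_hat must be in (0, 0.5)")
        if self.k < 1 or int(self.k) != self.k:
            raise ValueError("k must be an integer >= 1")
        for name in ("D_E", "D_M", "Koff_E", "K_ME", "K_AE", "A_sat",
                     "K_EM", "K_fb", "V_hat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    # -- derived quantities ------------------------------------------------
    def uniform_myosin(self) -> float:
        """Mean bound myosin at the AIR-1-free uniform steady state.

        Root of K_EM f_E (1 - M) = M + K_fb M^k in (0, 1).
        """
        from scipy.optimize import brentq

        g = lambda M: self.K_EM * self.f_E * (1.0 - M) - M - self.K_fb * M**self.k
        return float(brentq(g, 0.0, 1.0))

    @property
    def Kon_E(self) -> float:
        """Basal on-rate maintaining fraction f_E bound at the uniform state."""
        M0 = self.uniform_myosin()
        return self.Koff_E * self.f_E / ((1.0 + self.K_ME * M0) * (1.0 - self.f_E))


def default_params(k: int = 2, polarization: bool = False,
                   V_hat: float | None = None, **overrides) -> CortexParams:
    """The fitted default parameter set for k = 2 or k = 3.

    polarization=True raises the ECT-2 off-rate by 20% (faster FRAP recovery
    during polarization).
    """
    table = {2: dict(K_EM=9.0, K_fb=3.6, K_ME=2.5),
             3: dict(K_EM=6.5, K_fb=5.25, K_ME=1.5)}
    if k not in table:
        raise ValueError("k must be 2 or 3 for the fitted defaults")
    kw = dict(table[k], k=k)
    if polarization:
        kw["Koff_E"] = 5.0 * 1.2
    if V_hat is not None:
        kw["V_hat"] = V_hat
    kw.update(overrides)
    return CortexParams(**kw)


@dataclass
class CortexState:
    """Fields on the uniform periodic grid (cell centers at i/N)."""

    E: np.ndarray
    M: np.ndarray
    v: np.ndarray
    t: float = 0.0
    P: np.ndarray | None = None  # optional advected intermediary

    @property
    def n(self) -> int:
        return len(self.E)

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.n) / self.n

    @property
    def E_c(self) -> float:
        return 1.0 - float(np.mean(self.E))

    @property
    def M_c(self) -> float:
        return 1.0 - float(np.mean(self.M))

    def copy(self) -> "CortexState":
        return CortexState(E=self.E.copy(), M=self.M.copy(), v=self.v.copy(),
                           t=self.t, P=None if self.P is None else self.P.copy())


def uniform_state(params: CortexParams, n: int = 1000) -> CortexState:
    """The AIR-1-free uniform steady state (mean E = f_E, mean M from balance)."""
    M0 = params.uniform_myosin()
    return CortexState(E=np.full(n, params.f_E), M=np.full(n, M0),
                       v=np.zeros(n))


# ---------------------------------------------------------------------------
# spatial operators (uniform periodic grid)
# ---------------------------------------------------------------------------

class _Spectral:
    """Cached FFT symbols of the centered-difference and 3-point-Laplacian
    matrices on an N-cell periodic grid; diagonalisation is exact."""

    def __init__(self, n: int):
        self.n = n
        self.dx = 1.0 / n
        k = np.fft.rfftfreq(n, d=self.dx) * 2.0 * np.pi  # continuous wavenumber
        theta = k * self.dx
        self.sym_d1 = 1j * np.sin(theta) / self.dx  # centered first derivative
        self.sym_lap = -(2.0 - 2.0 * np.cos(theta)) / self.dx**2

    def deriv(self, u: np.ndarray) -> np.ndarray:
        return np.fft.irfft(np.fft.rfft(u) * self.sym_d1, n=self.n)


_SPECTRAL_CACHE: dict[int, _Spectral] = {}


def _spectral(n: int) -> _Spectral:
    if n not in _SPECTRAL_CACHE:
        _SPECTRAL_CACHE[n] = _Spectral(n)
    return _SPECTRAL_CACHE[n]


def solve_velocity(M: np.ndarray, l_hat: float, V_hat: float) -> np.ndarray:
    """Solve (I - l_hat^2 Lap) v = V_hat D M, periodic, with mean(v) = 0.

    Uses the centered-difference D and three-point Laplacian; the FFT
    diagonalises both exactly on the uniform periodic grid.
    """
    sp = _spectral(len(M))
    rhs = V_hat * sp.sym_d1 * np.fft.rfft(M)
    v_hat = rhs / (1.0 - l_hat**2 * sp.sym_lap)
    v_hat[0] = 0.0  # zero-mean flow: no net drift on a periodic cortex
    return np.fft.irfft(v_hat, n=len(M))


def advect_upwind(u: np.ndarray, v: np.ndarray, dt: float) -> np.ndarray:
    """One conservative first-order upwind step of d(u)/dt = -d(vu).

    Face velocities are the averages of adjacent cell-center values; the
    scheme conserves sum(u) to machine precision.
    """
    n = len(u)
    dx = 1.0 / n
    v_face = 0.5 * (v + np.roll(v, -1))  # face i+1/2 between cells i, i+1
    upwind = np.where(v_face > 0, u, np.roll(u, -1))
    flux = v_face * upwind
    return u - dt / dx * (flux - np.roll(flux, 1))


def diffuse_implicit(u: np.ndarray, D: float, dt: float) -> np.ndarray:
    """Backward-Euler step of du/dt = D Lap u (3-point Laplacian), exact via FFT."""
    if D == 0.0 or dt == 0.0:
        return u.copy()
    sp = _spectral(len(u))
    return np.fft.irfft(np.fft.rfft(u) / (1.0 - dt * D * sp.sym_lap), n=len(u))


def saturate(A: np.ndarray | float, A_sat: float) -> np.ndarray | float:
    """Hard clamp of AIR-1 activity at the saturation level."""
    return np.minimum(A, A_sat)


def reaction_fluxes(
    E: np.ndarray,
    M: np.ndarray,
    A: np.ndarray | float,
    params: CortexParams,
    E_c: float | None = None,
    M_c: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binding/unbinding fluxes (dE, dM) at the current fields.

    The cytoplasmic pools may be overridden (used when one field is imposed,
    e.g. during the myosin-parameter fit).
    """
    if np.min(E) < -1e-10 or np.min(M) < -1e-10:
        raise ValueError("negative concentrations passed to reaction_fluxes")
    E_c = 1.0 - float(np.mean(E)) if E_c is None else E_c
    M_c = 1.0 - float(np.mean(M)) if M_c is None else M_c
    on_E = params.Kon_E * (1.0 + params.K_ME * M) * E_c
    off_E = params.Koff_E * (1.0 + params.K_AE * saturate(A, params.A_sat)) * E
    dM = params.K_EM * E * M_c - M - params.K_fb * M**params.k
    return on_E - off_E, dM


def cfl_dt(v: np.ndarray, n: int, dt_max: float = 0.01, safety: float = 0.25) -> float:
    """Time step: safety * min(advective CFL bound, dt_max)."""
    vmax = float(np.max(np.abs(v)))
    dx = 1.0 / n
    bound = dx / vmax if vmax > 0 else np.inf
    return safety * min(bound, dt_max)


def step(state: CortexState, A: np.ndarray | float, params: CortexParams,
         dt: float) -> CortexState:
    """One operator-split step: velocity -> advection -> reaction -> diffusion.

    Raises if the advective CFL bound is violated (run() adapts dt instead).
    """
    n = state.n
    v = solve_velocity(state.M, params.l_hat, params.V_hat)
    vmax = float(np.max(np.abs(v)))
    if vmax * dt * n > 1.0 + 1e-12:
        raise ValueError(f"CFL violation: |v| dt / dx = {vmax * dt * n:.3f} > 1")
    E = advect_upwind(state.E, v, dt)
    M = advect_upwind(state.M, v, dt)
    dE, dM = reaction_fluxes(E, M, A, params)
    E = E + dt * dE
    M = M + dt * dM
    E = diffuse_implicit(E, params.D_E, dt)
    M = diffuse_implicit(M, params.D_M, dt)
    return CortexState(E=E, M=M, v=v, t=state.t + dt)


@dataclass
class Trajectory:
    """Kymograph record: fields sampled at the output cadence."""

    times: np.ndarray  # (nt,), myosin lifetimes
    E: np.ndarray  # (nt, n)
    M: np.ndarray
    v: np.ndarray
    unstable: bool = False
    P: np.ndarray | None = None

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.E.shape[1]) / self.E.shape[1]


def run(
    state0: CortexState,
    A,
    params: CortexParams,
    t_end: float,
    steady_tol: float = 0.0,
    output_dt: float = 0.1,
    dt_max: float = 0.01,
    blowup_factor: float = 10.0,
) -> tuple[Trajectory, CortexState]:
    """Integrate to ``t_end`` (myosin lifetimes) or until steady.

    ``A`` is the AIR-1 profile values on the grid, a scalar, or a callable
    ``A(t)`` returning either (used for transient cues).  Steadiness is
    declared when the max relative field change per unit time drops below
    ``steady_tol`` (0 disables).  Fields exceeding ``blowup_factor`` abort
    the run with the trajectory flagged unstable.
    """
    state = state0.copy()
    out_t = [state.t]
    out_E = [state.E.copy()]
    out_M = [state.M.copy()]
    out_v = [solve_velocity(state.M, params.l_hat, params.V_hat)]
    unstable = False
    next_out = state.t + output_dt
    A_of_t = A if callable(A) else (lambda _t: A)

    while state.t < t_end - 1e-12:
        v_now = solve_velocity(state.M, params.l_hat, params.V_hat)
        dt = cfl_dt(v_now, state.n, dt_max=dt_max)
        dt = min(dt, t_end - state.t, next_out - state.t)
        prev = state
        state = step(state, A_of_t(state.t), params, dt)
        if (np.max(state.E) > blowup_factor or np.max(state.M) > blowup_factor
                or not np.isfinite(state.E).all()):
            unstable = True
            break
        if state.t >= next_out - 1e-12:
            out_t.append(state.t)
            out_E.append(state.E.copy())
            out_M.append(state.M.copy())
            out_v.append(state.v.copy())
            next_out += output_dt
            if steady_tol > 0:
                rate = max(
                    np.max(np.abs(state.E - prev.E)),
                    np.max(np.abs(state.M - prev.M)),
                ) / dt
                scale = max(np.max(np.abs(state.E)), np.max(np.abs(state.M)))
                if rate < steady_tol * scale:
                    break
    traj = Trajectory(times=np.asarray(out_t), E=np.asarray(out_E),
                      M=np.asarray(out_M), v=np.asarray(out_v),
                      unstable=unstable)
    return traj, state


def dimensional_velocity(v_hat: np.ndarray | float,
                         L: float = PERIMETER_UM,
                         tau_M: float = TAU_M_S) -> np.ndarray | float:
    """Convert dimensionless velocity to µm/min (v * L / tau_M, then per min)."""
    if L <= 0 or tau_M <= 0:
        raise ValueError("L and tau_M must be positive")
    return v_hat * L / tau_M * 60.0


def export_kymograph(traj: Trajectory, prefix) -> None:
    """CSV matrices (rows = times, cols = grid) per species plus velocity."""
    for name, arr in (("ect2", traj.E), ("myosin", traj.M), ("velocity", traj.v)):
        header = ",".join(f"x{c}" for c in range(arr.shape[1]))
        np.savetxt(f"{prefix}_{name}.csv",
                   np.column_stack([traj.times, arr]),
                   delimiter=",", header="t," + header, comments="")
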