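"""Three-species cortex model with an explicit advected intermediary.

The minimal model folds the species that recruits ECT-2 into the myosin
field.  Here it is explicit: a third species P (a long-lived, flow-coupled
cortical component, e.g. a PIP2-organising factor) is advected by the same
cortical flow, diffuses, exchanges with its cytoplasmic pool, and replaces
myosin in the ECT-2 recruitment term:

    dP/dt = D_P d2P - d(vP) + Kon_P P_c - Koff_P P
    dE/dt = ...   + Kon_E (1 + K_PE P) E_c - Koff_E (1 + K_AE sat(A)) E

Myosin keeps its own dynamics; everything else matches the minimal model.
Koff_P corresponds to PAR-scale residence times (~100 s, i.e. a fraction of
a myosin lifetime per unit time); Kon_P is set so 30% of P is bound at the
uniform state, like myosin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cortex import (
    CortexParams,
    CortexState,
    Trajectory,
    advect_upwind,
    cfl_dt,
    diffuse_implicit,
    saturate,
    solve_velocity,
    uniform_state,
)

TAU_M_S = 15.0

#: PAR-like residence-time presets (seconds) for the intermediary
RESIDENCE_PRESETS_S = (100.0, 200.0)


@dataclass(frozen=True)
class ExtendedParams:
    """Minimal-model parameters plus the intermediary's."""

    base: CortexParams
    D_P: float = 0.1 * TAU_M_S / 134.65371359544588**2
    Koff_P: float = TAU_M_S / 100.0  # 100 s residence time
    K_PE: float = 2.5
    f_P: float = 0.3
    #: give P exactly myosin's reaction kinetics (activation by E, basal +
    #: nonlinear inactivation).  With matching diffusivity and initial data
    #: P then coincides with M and the model reduces to the minimal one —
    #: a consistency limit, not a biological scenario.
    myosin_kinetics_P: bool = False

    def __post_init__(self) -> None:
        for name in ("D_P", "Koff_P", "K_PE"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def Kon_P(self) -> float:
        """On-rate keeping fraction f_P of the intermediary bound."""
        return self.Koff_P * self.f_P / (1.0 - self.f_P)

    @property
    def Kon_E(self) -> float:
        """Basal ECT-2 on-rate with recruitment by P at its uniform level."""
        b = self.base
        return b.Koff_E * b.f_E / ((1.0 + self.K_PE * self.f_P)
                                   * (1.0 - b.f_E))


def uniform_state_extended(params: ExtendedParams, n: int = 1000) -> CortexState:
    st = uniform_state(params.base, n=n)
    st.P = np.full(n, params.f_P)
    return st


def step_extended(state: CortexState, A, params: ExtendedParams,
                  dt: float) -> CortexState:
    """Operator-split step with P advected, diffusing and exchanging."""
    if state.P is None:
        raise ValueError("state has no intermediary field P")
    b = params.base
    v = solve_velocity(state.M, b.l_hat, b.V_hat)
    vmax = float(np.max(np.abs(v)))
    if vmax * dt * state.n > 1.0 + 1e-12:
        raise ValueError("CFL violation")
    E = advect_upwind(state.E, v, dt)
    M = advect_upwind(state.M, v, dt)
    P = advect_upwind(state.P, v, dt)
    E_c = 1.0 - float(np.mean(E))
    M_c = 1.0 - float(np.mean(M))
    P_c = 1.0 - float(np.mean(P))
    dE = (params.Kon_E * (1.0 + params.K_PE * P) * E_c
          - b.Koff_E * (1.0 + b.K_AE * saturate(A, b.A_sat)) * E)
    dM = b.K_EM * E * M_c - M - b.K_fb * M**b.k
    if params.myosin_kinetics_P:
        dP = b.K_EM * E * P_c - P - b.K_fb * P**b.k
    else:
        dP = params.Kon_P * P_c - params.Koff_P * P
    E = diffuse_implicit(E + dt * dE, b.D_E, dt)
    M = diffuse_implicit(M + dt * dM, b.D_M, dt)
    P = diffuse_implicit(P + dt * dP, params.D_P, dt)
    out = CortexState(E=E, M=M, v=v, t=state.t + dt)
    out.P = P
    return out


def run_extended(
    state0: CortexState,
    A,
    params: ExtendedParams,
    t_end: float,
    steady_tol: float = 0.0,
    output_dt: float = 0.1,
    dt_max: float = 0.01,
    blowup_factor: float = 10.0,
) -> tuple[Trajectory, CortexState]:
    """Integrate the extended model (same contract as cortex.run)."""
    state = state0.copy()
    out = {k: [] for k in ("t", "E", "M", "v", "P")}

    def record(st: CortexState) -> None:
        out["t"].append(st.t)
        out["E"].append(st.E.copy())
        out["M"].append(st.M.copy())
        out["v"].append(solve_velocity(st.M, params.base.l_hat,
                                       params.base.V_hat))
        out["P"].append(st.P.copy())

    record(state)
    unstable = False
    next_out = state.t + output_dt
    A_of_t = A if callable(A) else (lambda _t: A)
    while state.t < t_end - 1e-12:
        v_now = solve_velocity(state.M, params.base.l_hat, params.base.V_hat)
        dt = cfl_dt(v_now, state.n, dt_max=dt_max)
        dt = min(dt, t_end - state.t, next_out - state.t)
        prev = state
        state = step_extended(state, A_of_t(state.t), params, dt)
        if (max(np.max(state.E), np.max(state.M), np.max(state.P))
                > blowup_factor or not np.isfinite(state.E).all()):
            unstable = True
            break
        if state.t >= next_out - 1e-12:
            record(state)
            next_out += output_dt
            if steady_tol > 0:
                rate = max(np.max(np.abs(state.E - prev.E)),
                           np.max(np.abs(state.M - prev.M)),
                           np.max(np.abs(state.P - prev.P))) / dt
                scale = max(np.max(state.E), np.max(state.M),
                            np.max(state.P))
                if rate < steady_tol * scale:
                    break
    traj = Trajectory(times=np.asarray(out["t"]), E=np.asarray(out["E"]),
                      M=np.asarray(out["M"]), v=np.asarray(out["v"]),
                      unstable=unstable, P=np.asarray(out["P"]))
    return traj, state


def sweep_intermediary(
    D_P_grid,
    Koff_P_grid,
    K_PE_grid,
    base: CortexParams,
    A,
    t_end: float = 40.0,
    n: int = 256,
) -> pd.DataFrame:
    """Steady-profile metrics over the intermediary parameter grid.

    Returns one row per (D_P, Koff_P, K_PE) with the steady ECT-2 asymmetry,
    posterior clearing and a stability flag.  Deterministic; identical
    inputs give identical tables.
    """
    rows = []
    for D_P in D_P_grid:
        for Koff_P in Koff_P_grid:
            for K_PE in K_PE_grid:
                p = ExtendedParams(base=base, D_P=float(D_P),
                                   Koff_P=float(Koff_P), K_PE=float(K_PE))
                st0 = uniform_state_extended(p, n=n)
                A_n = _resample(A, n)
                traj, fin = run_extended(st0, A_n, p, t_end=t_end,
                                         steady_tol=1e-6)
                # oscillation flag: residual frame-to-frame movement of the
                # ECT-2 field over the last quarter of the run
                tail = traj.E[-max(2, len(traj.E) // 4):]
                variability = float(np.max(np.std(tail, axis=0)))
                rows.append({
                    "D_P": D_P, "Koff_P": Koff_P, "K_PE": K_PE,
                    "ect2_asymmetry": float(np.max(fin.E) / np.min(fin.E)),
                    "posterior_clearing":
                        float(1.0 - fin.E[0] / base.f_E),
                    "stable": not traj.unstable,
                    "oscillatory": variability > 5e-3,
                    "variability": variability,
                })
    return pd.DataFrame(rows)


def _resample(A, n: int):
    if np.isscalar(A):
        return A
    A = np.asarray(A, float)
    if len(A) == n:
        return A
    x_src = np.arange(len(A)) / len(A)
    return np.interp(np.arange(n) / n, x_src, A, period=1.0)
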