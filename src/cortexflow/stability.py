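"""Linear stability of the uniform cortex state.

Perturbing (E, M) about the AIR-1-free uniform steady state with a single
Fourier mode ~ exp(2*pi*i*j*x), the velocity responds through the force
balance with transfer factor V_hat q / (1 + l_hat^2 q^2), q = 2*pi*j, and
the linearised dynamics of the mode amplitudes (dE_j, dM_j) are governed by
a real 2x2 matrix.  Modes j >= 1 leave the spatial means — and hence the
cytoplasmic pools — unchanged, so E_c, M_c enter at their base values.

The headline stability readout is the number of the first ten Fourier
modes with a positive-real-part eigenvalue, mapped over the flow strength /
recruitment plane (V_hat, K_ME), with the basal ECT-2 on-rate re-solved at
every K_ME to keep 10% of ECT-2 bound.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cortex import CortexParams


@dataclass(frozen=True)
class ModePerturbation:
    """Fourier mode j with its velocity transfer factor."""

    j: int
    l_hat: float
    V_hat: float

    @property
    def q(self) -> float:
        return 2.0 * np.pi * self.j

    @property
    def velocity_factor(self) -> float:
        """|v| response per unit myosin-mode amplitude."""
        return self.V_hat * self.q / (1.0 + self.l_hat**2 * self.q**2)


def growth_matrix(j: int, params: CortexParams) -> np.ndarray:
    """Linearised reaction + advection + diffusion matrix for mode j >= 1.

    The analysis is for the AIR-1-free base state (K_AE plays no role).
    Rows/columns ordered (dE, dM).
    """
    if j < 1:
        raise ValueError("mode j must be >= 1 (j = 0 is fixed by mass "
                         "conservation)")
    E0 = params.f_E
    M0 = params.uniform_myosin()
    Ec0 = 1.0 - E0
    Mc0 = 1.0 - M0
    q = 2.0 * np.pi * j
    adv = q**2 * params.V_hat / (1.0 + params.l_hat**2 * q**2)
    a11 = -params.Koff_E - params.D_E * q**2
    a12 = params.Kon_E * params.K_ME * Ec0 + E0 * adv
    a21 = params.K_EM * Mc0
    a22 = (-1.0 - params.k * params.K_fb * M0 ** (params.k - 1)
           - params.D_M * q**2 + M0 * adv)
    return np.array([[a11, a12], [a21, a22]])


def mode_eigenvalues(j: int, params: CortexParams) -> np.ndarray:
    return np.linalg.eigvals(growth_matrix(j, params))


def is_mode_unstable(j: int, params: CortexParams) -> bool:
    """Strict criterion: positive real part of either eigenvalue."""
    return bool(np.max(np.real(mode_eigenvalues(j, params))) > 0.0)


def determinant_shortcut_unstable(j: int, params: CortexParams) -> bool:
    """The negative-determinant shortcut (implies a positive real eigenvalue
    for a real 2x2 matrix; misses positive-trace oscillatory instabilities)."""
    return bool(np.linalg.det(growth_matrix(j, params)) < 0.0)


def count_unstable(params: CortexParams, j_max: int = 10,
                   log_discrepancies: list | None = None) -> int:
    """Number of unstable modes among j = 1 .. j_max (eigenvalue criterion).

    If ``log_discrepancies`` is a list, modes where the determinant shortcut
    disagrees with the eigenvalue criterion are appended to it.
    """
    count = 0
    for j in range(1, j_max + 1):
        eig = is_mode_unstable(j, params)
        if log_discrepancies is not None:
            if eig != determinant_shortcut_unstable(j, params):
                log_discrepancies.append((j, params.V_hat, params.K_ME))
        count += eig
    return count


@dataclass
class StabilityDiagram:
    """Unstable-mode counts over a (V_hat, K_ME) grid."""

    V_hat: np.ndarray
    K_ME: np.ndarray
    counts: np.ndarray  # shape (len(K_ME), len(V_hat))

    def to_csv(self, path) -> None:
        header = "K_ME\\V_hat," + ",".join(f"{v:g}" for v in self.V_hat)
        rows = np.column_stack([self.K_ME, self.counts])
        np.savetxt(path, rows, delimiter=",", header=header, comments="",
                   fmt="%g")


def stability_diagram(V_range: np.ndarray, K_ME_range: np.ndarray,
                      params: CortexParams, j_max: int = 10) -> StabilityDiagram:
    """Map count_unstable over the flow-strength / recruitment plane.

    Kon_E is re-solved at each K_ME (it is a property of CortexParams, so
    this happens automatically when the parameter set is replaced).
    """
    counts = np.zeros((len(K_ME_range), len(V_range)), dtype=int)
    for i, kme in enumerate(K_ME_range):
        for jj, v in enumerate(V_range):
            p = replace(params, K_ME=float(kme), V_hat=float(v))
            counts[i, jj] = count_unstable(p, j_max=j_max)
    return StabilityDiagram(V_hat=np.asarray(V_range),
                            K_ME=np.asarray(K_ME_range), counts=counts)
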