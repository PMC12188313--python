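"""Shared independent oracles for the test suite."""

import numpy as np

from cortexflow.cortex import step, uniform_state
from cortexflow.stability import growth_matrix


def measured_decay_rate(params, j, eps=1e-6, t0=0.3, t1=0.9):
    """Growth/decay rate of a single-mode perturbation from the nonlinear
    integrator, via the log-slope of the eigenvector projection."""
    J = growth_matrix(j, params)
    lam, vecs = np.linalg.eig(J)
    i = int(np.argmax(lam.real))
    lam_dom, vec = lam[i].real, vecs[:, i].real
    n = 512
    x = np.arange(n) / n
    st = uniform_state(params, n=n)
    st.E = st.E + eps * vec[0] * np.cos(2 * np.pi * j * x)
    st.M = st.M + eps * vec[1] * np.cos(2 * np.pi * j * x)
    left = np.linalg.inv(vecs)[i].real

    def amplitude(state):
        cE = 2 * np.real(np.fft.rfft(state.E)[j]) / n
        cM = 2 * np.real(np.fft.rfft(state.M)[j]) / n
        return left[0] * cE + left[1] * cM

    dt = 5e-4
    amps, times = [], []
    while st.t < t1:
        st = step(st, 0.0, params, dt)
        if st.t >= t0:
            times.append(st.t)
            amps.append(amplitude(st))
    slope = np.polyfit(times, np.log(np.abs(amps)), 1)[0]
    return slope, lam_dom
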