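"""Synthetic cortical target profiles and Fourier smoothing.

The parameter-fitting workflow needs quasi-steady ECT-2 and myosin profiles
from polarized embryos.  The real curves are image-derived; this module
generates seeded synthetic stand-ins: smooth, strictly positive, periodic,
mirror-symmetric about the A/P axis, with prescribed spatial mean and
max/min asymmetry.  The canonical targets are

* ECT-2: mean 0.1 (10% bound), asymmetry 1.9, broad anterior enrichment;
* myosin: mean 0.3 (30% bound), asymmetry 1.5, narrower anterior peak.

Both curves describe the same quasi-steady embryo, so their maxima sit in
the same (anterior) region — myosin is activated by cortical ECT-2 —
with the myosin peak the sharper of the two.

Profiles are built from a Gaussian bump (mirrored about the axis), truncated
to a low number of Fourier modes — emulating the Fourier-interpolant
smoothing applied to punctate microscopy data — and affinely rescaled to hit
the requested mean exactly and the asymmetry to high accuracy.  The seed
perturbs the bump width and mode weights slightly (different embryos),
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Recipe for one synthetic periodic profile."""

    mean: float
    asymmetry: float  # max/min ratio, >= 1
    peak_location: float = 0.25  # arclength fraction from the posterior pole
    width: float = 0.12  # Gaussian bump width (arclength fraction)
    n_modes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.asymmetry < 1.0:
            raise ValueError("asymmetry must be >= 1")
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.mean * self.asymmetry >= 1.0 and self.asymmetry > 1.0:
            # max value would reach/exceed the all-bound limit
            raise ValueError("requested mean/asymmetry violate positivity of "
                             "the free pool")


def fourier_smooth(samples: np.ndarray, n_modes: int) -> np.ndarray:
    """Truncate a uniformly-sampled periodic curve to its first n_modes modes.

    Exact reconstruction when the input already has <= n_modes modes.
    """
    c = np.fft.rfft(samples)
    c[n_modes + 1:] = 0.0
    return np.fft.irfft(c, n=len(samples))


def generate_profile(spec: SyntheticProfileSpec, n: int = 1000) -> np.ndarray:
    """Synthetic periodic profile on the uniform grid i/n.

    Deterministic per (spec, n); mean is exact, asymmetry within 0.5%.
    """
    if spec.asymmetry == 1.0:
        return np.full(n, spec.mean)
    rng = np.random.default_rng(spec.seed)
    width = spec.width * (1.0 + 0.1 * (rng.random() - 0.5))
    x = np.arange(n) / n
    # mirrored bumps at +/- peak_location (profiles are symmetric about the
    # A/P axis); periodic distance to each bump center
    g = np.zeros(n)
    for x0 in (spec.peak_location, -spec.peak_location):
        d = np.minimum(np.abs(x - x0 % 1.0), 1.0 - np.abs(x - x0 % 1.0))
        g += np.exp(-0.5 * (d / width) ** 2)
    g = fourier_smooth(g, spec.n_modes)
    # small seeded jitter on the retained harmonics
    c = np.fft.rfft(g)
    jitter = 1.0 + 0.05 * (rng.random(spec.n_modes) - 0.5)
    c[1 : spec.n_modes + 1] *= jitter
    g = np.fft.irfft(c, n=n)
    # affine rescale: P = a + b * (g - min) with (a + b*range)/a = asymmetry
    g = g - g.min()
    rng_g = g.max()
    mean_g = g.mean()
    R = spec.asymmetry
    a = spec.mean / (1.0 + (R - 1.0) * mean_g / rng_g)
    b = a * (R - 1.0) / rng_g
    p = a + b * g
    if p.min() <= 0:
        raise ValueError("generated profile not strictly positive")
    return p


def ect2_target(seed: int = 0, n: int = 1000) -> np.ndarray:
    """Canonical ECT-2 target: mean 0.1, asymmetry 1.9, broad anterior
    enrichment centred ~35% of the perimeter from the posterior pole."""
    return generate_profile(
        SyntheticProfileSpec(mean=0.1, asymmetry=1.9, peak_location=0.35,
                             width=0.25, seed=seed), n=n)


def myosin_target(seed: int = 0, n: int = 1000) -> np.ndarray:
    """Canonical myosin target: mean 0.3, asymmetry 1.5, sharper peak in the
    same anterior region as the ECT-2 enrichment."""
    return generate_profile(
        SyntheticProfileSpec(mean=0.3, asymmetry=1.5, peak_location=0.3,
                             width=0.12, seed=seed), n=n)


def asymmetry(profile: np.ndarray) -> float:
    """Max/min ratio of a spatial profile."""
    return float(np.max(profile) / np.min(profile))
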