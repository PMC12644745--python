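"""Haemodynamic response function kernels and convolution on the TR grid.

The canonical two-gamma HRF (peak ~5 s, undershoot ~15 s) is the default;
an arbitrary user kernel can be injected instead, since per-study HRFs vary.
Neural series are boxcars at the TR (one value per 1.4 s frame); they are
upsampled to a fine grid, convolved, and sampled back at TR onsets.

Convolution is circular over the run by default: a run is four identical
stimulus cycles and acquisition starts after the signal reaches steady
state, so the periodic (steady-state) response is the appropriate one.  A
constant input then maps exactly to a constant output — which is why a
constant adaptor regressor is absorbed by the GLM baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = ["HrfSpec", "hrf_kernel", "convolve_hrf"]


@dataclass(frozen=True)
class HrfSpec:
    """Two-gamma HRF parameters (SPM-style defaults), or a user kernel.

    Times are in seconds.  ``sample_interval_s`` is the fine grid on which
    the kernel is evaluated and the convolution carried out.
    """

    kind: str = "canonical_two_gamma"  # or "user_kernel"
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration_s: float = 32.0
    sample_interval_s: float = 0.1
    user_kernel: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("canonical_two_gamma", "user_kernel"):
            raise ValueError(f"unknown HRF kind {self.kind!r}")
        if self.kind == "user_kernel" and self.user_kernel is None:
            raise ValueError("user_kernel HRF requires a kernel")
        if self.peak_dispersion_s <= 0 or self.undershoot_dispersion_s <= 0:
            raise ValueError("HRF dispersions must be positive")
        if self.sample_interval_s <= 0:
            raise ValueError("sample interval must be positive")
        if self.duration_s < 24.0:
            raise ValueError("HRF kernel must cover at least 24 s")


def hrf_kernel(spec: HrfSpec = HrfSpec()) -> np.ndarray:
    """Sample the HRF on the spec's fine time grid, peak normalised to 1."""
    if spec.kind == "user_kernel":
        return np.asarray(spec.user_kernel, dtype=float)
    t = np.arange(0.0, spec.duration_s, spec.sample_interval_s)
    peak = _gamma.pdf(t, spec.peak_delay_s / spec.peak_dispersion_s,
                      scale=spec.peak_dispersion_s)
    under = _gamma.pdf(t, spec.undershoot_delay_s / spec.undershoot_dispersion_s,
                       scale=spec.undershoot_dispersion_s)
    h = peak - under / spec.peak_undershoot_ratio
    return h / h.max()


def convolve_hrf(
    series_tr: np.ndarray,
    spec: HrfSpec = HrfSpec(),
    tr_seconds: float = 1.4,
    circular: bool = True,
) -> np.ndarray:
    """Convolve a per-TR neural amplitude series with the HRF.

    The series is held boxcar-constant within each TR on the fine grid,
    convolved with the sampled kernel (circularly over the run by default),
    scaled by the grid step so the output approximates the continuous-time
    convolution integral, and sampled back at TR onsets.
    """
    series_tr = np.asarray(series_tr, dtype=float)
    kernel = hrf_kernel(spec)
    up = int(round(tr_seconds / spec.sample_interval_s))
    if abs(up * spec.sample_interval_s - tr_seconds) > 1e-9:
        raise ValueError("TR must be an integer multiple of the sample interval")
    fine = np.repeat(series_tr, up)
    if circular:
        n = len(fine)
        k = np.zeros(n)
        reps = -(-len(kernel) // n)  # kernel may wrap more than once
        for r in range(reps):
            seg = kernel[r * n:(r + 1) * n]
            k[: len(seg)] += seg
        out = np.real(np.fft.ifft(np.fft.fft(fine) * np.fft.fft(k)))
    else:
        out = np.convolve(fine, kernel)[: len(fine)]
    out *= spec.sample_interval_s
    return out[::up]
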