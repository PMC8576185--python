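"""Trigonometric Fourier encoding of pressure waveforms.

A record sampled at t_m = m*T/N (m = 0..N) is represented by coefficients
(a_k, b_k) of the synthesis formula

    u(t_m) = a_0/2 + sum_{k=1}^{K-1} [a_k cos(w_k t_m) + b_k sin(w_k t_m)],
    w_k = 2*k*pi/T.

Coefficients are computed by real FFT over the first N samples (the sample
at t_N starts the next period of the implied T-periodic extension).
Truncation at order K keeps (2K-1) numbers, c = (a_0..a_{K-1}, b_1..b_{K-1}).
At full order (K = N/2 + 1, Nyquist included with its closure weight) the
synthesis reproduces the record exactly at every grid node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FourierSpec",
    "fourier_encode",
    "fourier_reconstruct",
    "build_feature_vector",
    "feature_length",
]


@dataclass(frozen=True)
class FourierSpec:
    """Sampling contract of the encoder: period T (s), grid count N (even),
    truncation order K (number of retained cosine orders)."""

    T: float = 30.0
    N: int = 2000
    K: int = 50

    def __post_init__(self) -> None:
        if self.N % 2 != 0:
            raise ValueError("N must be even")
        if not 1 <= self.K <= self.N // 2 + 1:
            raise ValueError("K must satisfy 1 <= K <= N/2 + 1")

    @property
    def full_order(self) -> int:
        """K at which encode -> reconstruct is the identity on the grid."""
        return self.N // 2 + 1

    def omega(self, k) -> np.ndarray:
        return 2.0 * np.pi * np.asarray(k) / self.T


def fourier_encode(u: np.ndarray, spec: FourierSpec, K: int | None = None
                   ) -> np.ndarray:
    """Encode a (N+1)-sample record into the coefficient vector
    (a_0..a_{K-1}, b_1..b_{K-1}) of length 2K-1."""
    u = np.asarray(u, dtype=float)
    if u.shape != (spec.N + 1,):
        raise ValueError(f"series length {u.shape} does not match grid "
                         f"({spec.N + 1} samples)")
    K = spec.K if K is None else K
    if not 1 <= K <= spec.N // 2 + 1:
        raise ValueError("K out of range")
    N = spec.N
    spectrum = np.fft.rfft(u[:N])
    a = 2.0 / N * spectrum.real
    b = -2.0 / N * spectrum.imag
    if K == spec.full_order:
        # Nyquist closure: with only N samples the k = N/2 cosine carries
        # half weight in the inverse DFT
        a[N // 2] *= 0.5
    return np.concatenate([a[:K], b[1:K]])


def fourier_reconstruct(coeffs: np.ndarray, spec: FourierSpec,
                        times: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the synthesis formula for a (2K-1)-coefficient vector."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size % 2 != 1:
        raise ValueError("coefficient vector must have odd length 2K-1")
    K = (coeffs.size + 1) // 2
    a = coeffs[:K]
    b = np.concatenate([[0.0], coeffs[K:]])
    if times is None:
        times = np.arange(spec.N + 1) * (spec.T / spec.N)
    times = np.asarray(times, dtype=float)
    k = np.arange(1, K)
    wt = np.outer(times, spec.omega(k))
    return a[0] / 2.0 + np.cos(wt) @ a[1:] + np.sin(wt) @ b[1:]


def feature_length(K: int) -> int:
    """Input size of the estimator: two (2K-1) blocks plus the pump speed."""
    return 2 * (2 * K - 1) + 1


def build_feature_vector(sim, spec: FourierSpec) -> np.ndarray:
    """x = (c_SAP, c_PAP, w_c): truncated coefficients of both arterial
    pressures plus the pump *set* speed (not the pulse-modulated one)."""
    if sim.N != spec.N or abs(sim.T - spec.T) > 1e-9:
        raise ValueError("simulation grid does not match the Fourier spec")
    c_sap = fourier_encode(sim.sap, spec)
    c_pap = fourier_encode(sim.pap, spec)
    rpm = sim.pump.rpm if sim.pump.enabled else 0.0
    return np.concatenate([c_sap, c_pap, [rpm]])
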