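"""Tunable Q-factor wavelet transform (TQWT).

An invertible, oversampled iterated two-channel filter bank whose wavelet
Q-factor (center frequency / bandwidth) is a free design parameter.  The
transform is implemented in the DFT domain: at each level the unitary DFT of
the running low-pass signal is split into a low-pass spectrum of length
``2*round(alpha*N/2)`` and a high-pass spectrum of length
``2*round(beta*N/2)``, with a power-complementary raised-cosine transition
band between them.  Because every DFT bin is either copied or split by an
orthonormal 2-vector, the analysis is a Parseval tight frame: subband
energies sum to the signal energy and the adjoint (synthesis) bank inverts
the transform exactly.

High Q yields narrow-band, sustained-oscillation wavelets; low Q yields
wide-band, pulse-like wavelets.  The two regimes provide the oscillatory
(F-wave) and transient (QRST) dictionaries used by
:mod:`fwavekit.decompose`.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as _fft

__all__ = [
    "TqwtParams",
    "TqwtCoeffs",
    "compute_scaling_params",
    "max_levels",
    "tqwt_forward",
    "tqwt_inverse",
    "subband_wavelet_norms",
]


def compute_scaling_params(Q: float, r: float) -> tuple[float, float]:
    """Return the (alpha, beta) filter-bank scale parameters.

    ``beta = 2/(Q+1)`` is the high-pass scaling and ``alpha = 1 - beta/r``
    the low-pass scaling, where ``r > 1`` is the redundancy (oversampling
    rate) of the bank.  Oversampling guarantees ``alpha + beta > 1``.

    Parameters
    ----------
    Q : float
        Quality factor, ``>= 1``.
    r : float
        Redundancy, ``> 1``.
    """
    if not np.isfinite(Q) or Q < 1:
        raise ValueError(f"Q must be >= 1, got {Q!r}")
    if not np.isfinite(r) or r <= 1:
        raise ValueError(f"r must be > 1, got {r!r}")
    beta = 2.0 / (Q + 1.0)
    alpha = 1.0 - beta / r
    return alpha, beta


def max_levels(N: int, Q: float, r: float) -> int:
    """Largest usable decomposition depth for a length-``N`` signal.

    The low-pass branch shrinks by ``alpha`` per level; the depth is capped
    so the coarsest low-pass band keeps at least 8 samples:
    ``L = floor(log(beta*N/8) / log(1/alpha))``.

    Raises
    ------
    ValueError
        If the signal is too short to support even one level.
    """
    alpha, beta = compute_scaling_params(Q, r)
    if N < 8:
        raise ValueError(f"signal too short for TQWT: N={N} < 8")
    L = int(math.floor(math.log(beta * N / 8.0) / math.log(1.0 / alpha)))
    if L < 1:
        raise ValueError(
            f"signal too short for requested (Q={Q}, r={r}): N={N} admits no levels"
        )
    return L


@dataclass(frozen=True)
class TqwtParams:
    """Transform configuration: quality factor, redundancy, depth."""

    Q: float
    r: float = 3.0
    J: int = 1

    def __post_init__(self) -> None:
        compute_scaling_params(self.Q, self.r)  # validates Q, r
        if int(self.J) != self.J or self.J < 1:
            raise ValueError(f"J must be a positive integer, got {self.J!r}")

    @property
    def alpha(self) -> float:
        return compute_scaling_params(self.Q, self.r)[0]

    @property
    def beta(self) -> float:
        return compute_scaling_params(self.Q, self.r)[1]


@dataclass
class TqwtCoeffs:
    """Subband coefficients of one forward transform.

    ``subbands[0..J-1]`` are the level-1..J high-pass outputs (fine to
    coarse) and ``subbands[J]`` is the final low-pass band.
    ``original_length`` is the caller's signal length before the one-sample
    zero pad applied to odd-length inputs (``padded`` records it).
    """

    subbands: list[np.ndarray]
    params: TqwtParams
    original_length: int
    padded: bool = field(default=False)

    @property
    def J(self) -> int:
        return self.params.J

    def energy(self) -> float:
        return float(sum(np.sum(b * b) for b in self.subbands))


def _subband_lengths(N: int, alpha: float, beta: float, J: int) -> tuple[list[int], list[int]]:
    """Per-level (input length, high-pass length) schedule for even N."""
    ins, highs = [], []
    for j in range(1, J + 1):
        n_in = 2 * round(alpha ** (j - 1) * N / 2)
        n_hi = 2 * round(beta * alpha ** (j - 1) * N / 2)
        ins.append(n_in)
        highs.append(n_hi)
    return ins, highs


@functools.lru_cache(maxsize=4096)
def _transition(T: int) -> np.ndarray:
    # Power-complementary raised-cosine (Daubechies) transition:
    # theta(w)^2 + theta(pi-w)^2 = 1.
    if T <= 0:
        return np.empty(0)
    w = np.arange(1, T + 1) * (np.pi / (T + 1))
    out = 0.5 * (1.0 + np.cos(w)) * np.sqrt(2.0 - np.cos(w))
    out.setflags(write=False)
    return out


def _afb(X: np.ndarray, N: int, N0: int, N1: int) -> tuple[np.ndarray, np.ndarray]:
    """Analysis bank on one-sided (rfft) spectra: split X into low/high.

    ``X`` has ``N//2 + 1`` bins for the length-``N`` real signal; outputs
    have ``N0//2 + 1`` and ``N1//2 + 1`` bins.
    """
    P = (N - N1) // 2
    T = (N0 + N1 - N) // 2 - 1
    S = (N - N0) // 2
    if P < 0 or T < 0 or S < 0:  # cannot occur for valid schedules
        raise ValueError("inconsistent filter-bank lengths")
    theta = _transition(T)

    V0 = np.zeros(N0 // 2 + 1, dtype=complex)
    V0[0] = X[0]
    V0[1 : P + 1] = X[1 : P + 1]
    V0[P + 1 : P + 1 + T] = X[P + 1 : P + 1 + T] * theta
    # stop band and Nyquist of V0 stay zero

    V1 = np.zeros(N1 // 2 + 1, dtype=complex)
    V1[1 : T + 1] = X[P + 1 : P + 1 + T] * theta[::-1]
    V1[T + 1 : T + 1 + S] = X[P + T + 1 : P + T + 1 + S]
    V1[N1 // 2] = X[N // 2]
    return V0, V1


def _sfb(V0: np.ndarray, V1: np.ndarray, N: int) -> np.ndarray:
    """Synthesis bank (adjoint of :func:`_afb`) on one-sided spectra."""
    N0, N1 = 2 * (len(V0) - 1), 2 * (len(V1) - 1)
    P = (N - N1) // 2
    T = (N0 + N1 - N) // 2 - 1
    S = (N - N0) // 2
    theta = _transition(T)

    Y = np.zeros(N // 2 + 1, dtype=complex)
    Y[0] = V0[0]
    Y[1 : P + 1] = V0[1 : P + 1]
    Y[P + 1 : P + 1 + T] = V0[P + 1 : P + 1 + T] * theta + V1[1 : T + 1] * theta[::-1]
    Y[P + T + 1 : P + T + 1 + S] = V1[T + 1 : T + 1 + S]
    Y[N // 2] = V1[N1 // 2]
    return Y


def tqwt_forward(x: np.ndarray, params: TqwtParams) -> TqwtCoeffs:
    """Decompose ``x`` into ``J+1`` subbands (J high-pass + final low-pass).

    Odd-length inputs are zero-padded by one sample (recorded in the result
    and removed again by :func:`tqwt_inverse`).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite samples")
    n_orig = len(x)
    padded = bool(n_orig % 2)
    if padded:
        x = np.concatenate([x, [0.0]])
    N = len(x)
    alpha, beta = params.alpha, params.beta
    if params.J > max_levels(N, params.Q, params.r):
        raise ValueError(
            f"J={params.J} exceeds max_levels={max_levels(N, params.Q, params.r)} for N={N}"
        )
    ins, highs = _subband_lengths(N, alpha, beta, params.J)

    subbands: list[np.ndarray] = []
    X = _fft.rfft(x, norm="ortho")
    n_run = N
    for j in range(params.J):
        N0 = ins[j + 1] if j + 1 < params.J else 2 * round(alpha ** params.J * N / 2)
        X, W = _afb(X, n_run, N0, highs[j])
        subbands.append(_fft.irfft(W, n=highs[j], norm="ortho"))
        n_run = N0
    subbands.append(_fft.irfft(X, n=n_run, norm="ortho"))
    return TqwtCoeffs(subbands=subbands, params=params, original_length=n_orig, padded=padded)


def tqwt_inverse(coeffs: TqwtCoeffs) -> np.ndarray:
    """Reconstruct the signal from :class:`TqwtCoeffs` (exact inverse)."""
    p = coeffs.params
    N = coeffs.original_length + (1 if coeffs.padded else 0)
    if len(coeffs.subbands) != p.J + 1:
        raise ValueError(
            f"expected {p.J + 1} subbands, got {len(coeffs.subbands)}"
        )
    alpha, beta = p.alpha, p.beta
    ins, highs = _subband_lengths(N, alpha, beta, p.J)
    low_len = 2 * round(alpha ** p.J * N / 2)
    expected = highs + [low_len]
    for j, (b, e) in enumerate(zip(coeffs.subbands, expected)):
        if len(b) != e:
            raise ValueError(f"subband {j} has length {len(b)}, expected {e}")

    X = _fft.rfft(np.asarray(coeffs.subbands[p.J], dtype=float), norm="ortho")
    for j in range(p.J - 1, -1, -1):
        W = _fft.rfft(np.asarray(coeffs.subbands[j], dtype=float), norm="ortho")
        X = _sfb(X, W, ins[j])
    x = _fft.irfft(X, n=N, norm="ortho")
    return x[: coeffs.original_length]


def subband_wavelet_norms(params: TqwtParams, N: int) -> np.ndarray:
    """ℓ2 norm of each synthesis wavelet, one per subband.

    Obtained by inverting a centered unit impulse placed in each subband in
    turn.  Used to scale per-subband ℓ1 thresholds so regularization is
    uniform in signal units across scales.
    """
    if N % 2:
        N = N + 1
    alpha, beta = params.alpha, params.beta
    _, highs = _subband_lengths(N, alpha, beta, params.J)
    low_len = 2 * round(alpha ** params.J * N / 2)
    lengths = highs + [low_len]
    norms = np.empty(params.J + 1)
    for j, L in enumerate(lengths):
        subbands = [np.zeros(Lk) for Lk in lengths]
        subbands[j][L // 2] = 1.0
        w = tqwt_inverse(
            TqwtCoeffs(subbands=subbands, params=params, original_length=N)
        )
        norms[j] = np.linalg.norm(w)
    return norms
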