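"""Tunable Q-factor wavelet transform (TQWT), analysis and synthesis.

The transform is an iterated two-channel filter bank realised directly
in the frequency domain. A level maps a band of length N onto a
low-pass band of length about alpha*N and a high-pass band of length
about beta*N, where beta = 2/(Q+1) and alpha = 1 - beta/r; Q is the
quality factor and r the redundancy. Transition bands use the
Daubechies frequency response theta(w) = (1 + cos w) sqrt(2 - cos w)/2,
which satisfies theta(w)^2 + theta(pi - w)^2 = 1, so the bank is a
tight (Parseval) frame with perfect reconstruction. J levels give J+1
subbands: details at levels 1..J (highest frequency first) plus the
final low-pass.

The four parameterizations used by the grasp pipeline are
(Q, r, J) = (1,2,6), (2,4,24), (3,6,46), (4,8,73), producing
7 + 25 + 47 + 74 = 153 subbands of a 6000-sample signal.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "TQWTParams",
    "SubbandSet",
    "DEFAULT_PARAMS",
    "max_levels",
    "tqwt_decompose",
    "tqwt_reconstruct",
    "multi_tqwt",
]


@dataclasses.dataclass(frozen=True)
class TQWTParams:
    """Quality factor Q >= 1, redundancy r > 1, level count J >= 1."""

    Q: float
    r: float
    J: int

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        if self.r <= 1:
            raise ValueError("r must be > 1")
        if self.J < 1:
            raise ValueError("J must be >= 1")

    @property
    def beta(self) -> float:
        return 2.0 / (self.Q + 1.0)

    @property
    def alpha(self) -> float:
        return 1.0 - self.beta / self.r


#: The pipeline's four parameter sets, in application order.
DEFAULT_PARAMS: tuple[TQWTParams, ...] = (
    TQWTParams(1, 2, 6),
    TQWTParams(2, 4, 24),
    TQWTParams(3, 6, 46),
    TQWTParams(4, 8, 73),
)


@dataclasses.dataclass
class SubbandSet:
    """J+1 real coefficient sequences from one TQWT parameterization."""

    params: TQWTParams
    bands: list[np.ndarray]
    source_length: int
    padded: bool = False

    def __post_init__(self) -> None:
        if len(self.bands) != self.params.J + 1:
            raise ValueError("band count must equal J + 1")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)


def max_levels(n: int, params: TQWTParams) -> int:
    """Largest admissible J for an n-sample signal."""
    return int(math.floor(math.log(params.beta * n / 8.0) / math.log(1.0 / params.alpha)))


def _round_even(x: float) -> int:
    """2*round(x/2) with MATLAB-style round-half-away, guaranteeing even."""
    return 2 * int(math.floor(x / 2.0 + 0.5))


def _daub(T: int) -> np.ndarray:
    v = np.arange(1, T + 1) * np.pi / (T + 1)
    return (1.0 + np.cos(v)) * np.sqrt(2.0 - np.cos(v)) / 2.0


def _level_lengths(n: int, params: TQWTParams) -> list[tuple[int, int]]:
    """(low-pass, high-pass) output lengths for levels 1..J."""
    a, b = params.alpha, params.beta
    return [
        (_round_even(a ** j * n), _round_even(b * a ** (j - 1) * n))
        for j in range(1, params.J + 1)
    ]


def _afb(V: np.ndarray, n0: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """One analysis level on a conjugate-symmetric spectrum of even length."""
    m = V.size
    p = (m - n1) // 2           # low-pass pass-band samples (besides DC)
    t = (n0 + n1 - m) // 2 - 1  # transition-band samples
    if p < 0 or t < 0 or n0 > m:
        raise ValueError("inconsistent band lengths; signal too short for this level")
    trans = _daub(t)

    v0 = np.zeros(n0, dtype=complex)
    v0[0] = V[0]
    v0[1 : p + 1] = V[1 : p + 1]
    v0[p + 1 : p + t + 1] = V[p + 1 : p + t + 1] * trans
    # new Nyquist bin (index n0/2) stays zero
    v0[n0 // 2 + 1 :] = np.conj(v0[1 : n0 // 2][::-1])

    v1 = np.zeros(n1, dtype=complex)
    v1[1 : t + 1] = V[p + 1 : p + t + 1] * trans[::-1]
    v1[t + 1 : n1 // 2] = V[p + t + 1 : m // 2]
    v1[n1 // 2] = V[m // 2]
    v1[n1 // 2 + 1 :] = np.conj(v1[1 : n1 // 2][::-1])
    return v0, v1


def _sfb(v0: np.ndarray, v1: np.ndarray, m: int) -> np.ndarray:
    """One synthesis level, inverse of :func:`_afb`."""
    n0, n1 = v0.size, v1.size
    p = (m - n1) // 2
    t = (n0 + n1 - m) // 2 - 1
    trans = _daub(t)

    V = np.zeros(m, dtype=complex)
    V[0] = v0[0]
    V[1 : p + 1] = v0[1 : p + 1]
    V[p + 1 : p + t + 1] = v0[p + 1 : p + t + 1] * trans + v1[1 : t + 1] * trans[::-1]
    V[p + t + 1 : m // 2] = v1[t + 1 : n1 // 2]
    V[m // 2] = v1[n1 // 2]
    V[m // 2 + 1 :] = np.conj(V[1 : m // 2][::-1])
    return V


def tqwt_decompose(signal, params: TQWTParams) -> SubbandSet:
    """Analyse a signal into J+1 subbands.

    Odd-length inputs are zero-padded by one sample (recorded on the
    returned set and undone by :func:`tqwt_reconstruct`).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    source_length = x.size
    if x.size < 8:
        raise ValueError("signal length must be >= 8")
    padded = x.size % 2 == 1
    if padded:
        x = np.concatenate([x, [0.0]])
    n = x.size
    jmax = max_levels(n, params)
    if params.J > jmax:
        raise ValueError(
            f"J={params.J} exceeds J_max={jmax} for signal length {n} "
            f"(Q={params.Q}, r={params.r})"
        )
    V = np.fft.fft(x) / math.sqrt(n)
    bands: list[np.ndarray] = []
    for n0, n1 in _level_lengths(n, params):
        V, W = _afb(V, n0, n1)
        bands.append(np.real(np.fft.ifft(W)) * math.sqrt(n1))
    bands.append(np.real(np.fft.ifft(V)) * math.sqrt(V.size))
    return SubbandSet(params, bands, source_length, padded)


def tqwt_reconstruct(sb: SubbandSet) -> np.ndarray:
    """Perfectly reconstruct the source signal from its subbands."""
    n = sb.source_length + (1 if sb.padded else 0)
    lengths = _level_lengths(n, sb.params)
    expected = [n1 for _, n1 in lengths] + [lengths[-1][0]]
    for band, exp in zip(sb.bands, expected):
        if band.size != exp:
            raise ValueError(f"band length {band.size} inconsistent (expected {exp})")
    V = np.fft.fft(np.asarray(sb.bands[-1], dtype=float)) / math.sqrt(expected[-1])
    for j in range(sb.params.J - 1, -1, -1):
        n1 = lengths[j][1]
        W = np.fft.fft(np.asarray(sb.bands[j], dtype=float)) / math.sqrt(n1)
        m = lengths[j - 1][0] if j > 0 else n
        V = _sfb(V, W, m)
    x = np.real(np.fft.ifft(V)) * math.sqrt(n)
    return x[: sb.source_length]


def multi_tqwt(signal, params_list: tuple[TQWTParams, ...] = DEFAULT_PARAMS) -> list[np.ndarray]:
    """All subbands of the multi-parameter decomposition, in order.

    With the default four parameter sets this yields 153 bands: within
    each set the detail bands come first (level 1..J), then the final
    low-pass band.
    """
    return [band for params in params_list for band in tqwt_decompose(signal, params)]
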