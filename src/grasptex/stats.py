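"""Statistical moments computed on a signal and on its absolute value.

Fifteen descriptors per source — mean, median, variance, Shannon
entropy, log-energy entropy, maximum, minimum, standard deviation,
range, SURE entropy, kurtosis, skewness, Higuchi fractal dimension,
energy, root mean square — evaluated on the raw samples and again on
their absolute values, giving 30 features. The entropies follow the
wavelet-coefficient (unnormalised, squared-coefficient) conventions,
since they are applied to wavelet subbands.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "STAT_NAMES",
    "statistical_features",
    "wavelet_entropies",
    "higuchi_fd",
    "feature_names",
]

STAT_NAMES = (
    "mean",
    "median",
    "variance",
    "shannon_entropy",
    "log_entropy",
    "maximum",
    "minimum",
    "std",
    "range",
    "sure_entropy",
    "kurtosis",
    "skewness",
    "higuchi",
    "energy",
    "rms",
)

DEFAULT_SURE_EPS = 3.0
DEFAULT_HIGUCHI_KMAX = 10


def wavelet_entropies(signal, sure_eps: float = DEFAULT_SURE_EPS) -> tuple[float, float, float]:
    """Shannon, log-energy and SURE entropies of a coefficient sequence.

    shannon = -sum x_i^2 ln x_i^2 (0 ln 0 := 0);
    log_energy = sum ln x_i^2 (ln 0 := 0);
    sure = n - #{|x_i| <= eps} + sum min(x_i^2, eps^2).
    """
    if sure_eps <= 0:
        raise ValueError("sure_eps must be positive")
    x = np.asarray(signal, dtype=float)
    sq = x * x
    nz = sq > 0
    logs = np.zeros_like(sq)
    logs[nz] = np.log(sq[nz])
    shannon = float(-(sq * logs).sum())
    log_energy = float(logs.sum())
    sure = float(x.size - np.count_nonzero(np.abs(x) <= sure_eps) + np.minimum(sq, sure_eps**2).sum())
    return shannon, log_energy, sure


def higuchi_fd(signal, kmax: int = DEFAULT_HIGUCHI_KMAX) -> float:
    """Higuchi fractal dimension via curve lengths over decimated sub-series.

    For each scale k = 1..kmax and offset m, the normalised curve length
    L_m(k) is averaged over offsets; the FD is the least-squares slope of
    ln L(k) against ln(1/k). A constant signal returns 1.0 by convention.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if n <= kmax:
        raise ValueError(f"signal length {n} must exceed kmax {kmax}")
    if np.ptp(x) == 0:
        return 1.0
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    k_arr = np.arange(1, kmax + 1)
    valid = lk > 0
    if valid.sum() < 2:
        return 1.0
    slope, _ = np.polyfit(np.log(1.0 / k_arr[valid]), np.log(lk[valid]), 1)
    return float(slope)


def _moments(x: np.ndarray, sure_eps: float, higuchi_kmax: int) -> list[float]:
    shannon, log_energy, sure = wavelet_entropies(x, sure_eps)
    energy = float((x * x).sum())
    mean = float(np.mean(x))
    dev = x - mean
    m2 = float(np.mean(dev**2))
    # population skewness and Pearson (non-excess) kurtosis; zero for a
    # constant signal (scipy's biased-estimator convention, computed directly
    # to avoid per-call wrapper overhead)
    if m2 > 0:
        skew = float(np.mean(dev**3)) / m2**1.5
        kurt = float(np.mean(dev**4)) / m2**2
    else:
        skew = kurt = 0.0
    return [
        mean,
        float(np.median(x)),
        float(np.var(x, ddof=1)),
        shannon,
        log_energy,
        float(np.max(x)),
        float(np.min(x)),
        float(np.std(x, ddof=1)),
        float(np.ptp(x)),
        sure,
        kurt,
        skew,
        higuchi_fd(x, higuchi_kmax),
        energy,
        float(np.sqrt(energy / x.size)),
    ]


def statistical_features(
    signal,
    sure_eps: float = DEFAULT_SURE_EPS,
    higuchi_kmax: int = DEFAULT_HIGUCHI_KMAX,
) -> np.ndarray:
    """The 30 statistical features: 15 moments of x, then 15 of |x|."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be one-dimensional with length >= 2")
    kmax = min(higuchi_kmax, x.size - 1)
    return np.array(_moments(x, sure_eps, kmax) + _moments(np.abs(x), sure_eps, kmax))


def feature_names() -> list[str]:
    return [f"{name}_{part}" for part in ("raw", "abs") for name in STAT_NAMES]
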