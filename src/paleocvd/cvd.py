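"""Change/variability decomposition (CVD) of univariate climate series.

The decomposition detrends and z-scores a series, performs singular
spectrum analysis (SSA) with embedding dimension ``M`` (23 slices =
23,000 years by default, one precession cycle), and splits the
reconstructed components into a leading "change" set (EOFs ``1..w``)
and a residual "variability" set (EOFs ``w+1..M``). ``w`` is the
smallest value for which the summed residual components are consistent
with white noise, judged in the frequency domain: under white noise
each raw periodogram ordinate is exponentially distributed around the
series variance, so ordinates falling outside the pointwise central
95% band are counted and compared against a binomial quantile.

The percentage of variance carried by the variability component (the
sum of the trailing normalized eigenvalues) is the pipeline's proxy for
climate *unpredictability*: white-noise-like variance has no
autocorrelation to learn from.

SSA is computed by SVD of the Broomhead-King trajectory matrix with
diagonal averaging (Hankelization), which makes the completeness
identity -- the reconstructed components sum exactly to the analyzed
series -- hold to numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PreprocessRecord",
    "SSADecomposition",
    "CVDResult",
    "detrend_zscore",
    "ssa",
    "periodogram",
    "is_white_noise",
    "cvd_decompose",
    "unpredictability",
]

DEFAULT_M = 23
DEFAULT_ALPHA = 0.05

#: Residuals with variance below this are treated as exactly zero
#: (noise-free remainder), which guarantees the w-search terminates.
_DEGENERATE_VAR = 1e-12


class ConstantSeriesError(ValueError):
    """The series has no residual variance after detrending; CVD undefined."""


@dataclass(frozen=True)
class PreprocessRecord:
    slope: float
    intercept: float
    scale: float


@dataclass(frozen=True)
class SSADecomposition:
    M: int
    N: int
    #: normalized eigenvalues, descending, summing to 100
    eigenvalues: np.ndarray
    #: EOFs as columns of an (M, M) orthonormal matrix
    eofs: np.ndarray
    #: reconstructed components, shape (M, N); rcs.sum(axis=0) == series
    rcs: np.ndarray


@dataclass(frozen=True)
class CVDResult:
    w: int
    M: int
    alpha: float
    change: np.ndarray
    variability: np.ndarray
    pct_change: float
    pct_variability: float
    eigenvalues: np.ndarray
    preprocessing: PreprocessRecord


def detrend_zscore(series):
    """Remove the OLS linear trend and scale to unit sample variance.

    Returns ``(preprocessed, PreprocessRecord)``. Raises
    :class:`ConstantSeriesError` if the detrended residual is
    numerically constant.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1-D with at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    t = np.arange(x.size, dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    resid = x - (slope * t + intercept)
    sd = resid.std(ddof=1)
    if sd * sd < _DEGENERATE_VAR:
        raise ConstantSeriesError(
            "series is constant after detrending; decomposition undefined"
        )
    return resid / sd, PreprocessRecord(
        slope=float(slope), intercept=float(intercept), scale=float(sd)
    )


def ssa(series, M: int) -> SSADecomposition:
    """Singular spectrum analysis via SVD of the trajectory matrix.

    The trajectory matrix stacks the K = N - M + 1 lagged windows of
    length ``M``; eigenvalues are squared singular values normalized to
    sum to 100; reconstructed components come from diagonal averaging
    of the rank-one terms of the SVD.
    """
    x = np.asarray(series, dtype=float)
    N = x.size
    if not M >= 2:
        raise ValueError(f"M must be >= 2, got {M}")
    if N <= M:
        raise ValueError(f"series length {N} must exceed M={M}")
    K = N - M + 1
    # columns are lagged windows: traj[i, j] = x[i + j]
    traj = np.lib.stride_tricks.sliding_window_view(x, M).T  # (M, K)
    u, s, vt = np.linalg.svd(traj, full_matrices=True)  # u is (M, M)
    r = s.size  # = min(M, K); trailing components are exactly zero
    lam = np.zeros(M)
    lam[:r] = s * s
    total = lam.sum()
    norm = 100.0 * lam / total if total > 0 else lam

    # all rank-one terms at once: elem[i] = s_i * u[:, i] outer vt[i]
    elem = s[:, None, None] * u.T[:r, :, None] * vt[:r, None, :]  # (r, M, K)
    antidiag = (np.arange(M)[:, None] + np.arange(K)[None, :]).ravel()
    counts = np.bincount(antidiag, minlength=N).astype(float)
    rcs = np.zeros((M, N))
    for i in range(r):
        rcs[i] = np.bincount(
            antidiag, weights=elem[i].ravel(), minlength=N
        ) / counts
    return SSADecomposition(M=M, N=N, eigenvalues=norm, eofs=u, rcs=rcs)


def periodogram(series):
    """Raw periodogram at positive Fourier frequencies.

    Excludes the zero frequency and, for even length, the Nyquist
    ordinate. Normalization is ``|X_j|^2 / n`` so the mean ordinate of
    a white-noise series estimates its variance.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError(f"series too short for a periodogram (n={n})")
    spec = np.fft.rfft(x)
    power = (spec.real**2 + spec.imag**2) / n
    hi = n // 2 if n % 2 == 0 else n // 2 + 1
    freqs = np.arange(1, hi) / n
    return freqs, power[1:hi]


def is_white_noise(series, alpha: float = DEFAULT_ALPHA) -> bool:
    """Frequency-domain consistency check against white noise.

    Degenerate (numerically zero-variance) series count as consistent.
    Otherwise each periodogram ordinate is referred to an exponential
    with mean equal to the series variance, and two complementary
    criteria must both hold:

    * band count -- the number of ordinates above the upper edge of the
      pointwise central (1 - alpha) interval does not exceed the
      (1 - alpha) binomial quantile of the exceedance count (sensitive
      to diffuse excess power);
    * peak -- the largest ordinate stays below the simultaneous
      (1 - alpha) upper band for the maximum of n i.i.d. exponentials
      (sensitive to variance concentrated at one frequency, which the
      band count alone cannot detect).

    Only *excess* power counts against whiteness: a residual left by
    removing leading SSA components carries a genuine power deficit
    around the removed frequencies, and deficient ordinates mean less
    predictable structure, not more.
    """
    x = np.asarray(series, dtype=float)
    var = x.var()
    if var < _DEGENERATE_VAR:
        return True
    _, power = periodogram(x)
    n = power.size
    hi = var * -np.log(alpha / 2.0)
    n_out = int(np.count_nonzero(power > hi))
    threshold = int(stats.binom.ppf(1.0 - alpha, n, alpha / 2.0))
    # P(max of n exponentials <= q) = (1 - e^{-q/var})^n = 1 - alpha
    peak_limit = -var * np.log1p(-((1.0 - alpha) ** (1.0 / n)))
    return n_out <= threshold and float(power.max()) <= peak_limit


def cvd_decompose(
    series, M: int = DEFAULT_M, alpha: float = DEFAULT_ALPHA
) -> CVDResult:
    """Full change/variability decomposition of a raw series.

    Searches w upward from 0 and selects the smallest w whose residual
    (summed EOFs w+1..M) passes :func:`is_white_noise`; the degenerate
    zero residual at w = M guarantees termination. The percentage split
    is the corresponding partition of the normalized eigenvalues.
    """
    x = np.asarray(series, dtype=float)
    pre, record = detrend_zscore(x)
    if pre.size < 2 * M:
        warnings.warn(
            f"series length {pre.size} < 2*M={2 * M}; "
            "eigen-spectrum estimates may be unstable",
            stacklevel=2,
        )
    dec = ssa(pre, M)
    # residual at w is the tail sum of RCs; compute all tails in one pass
    tails = np.cumsum(dec.rcs[::-1], axis=0)[::-1]  # tails[w] = sum rcs[w:]
    w = M
    for cand in range(M):
        if is_white_noise(tails[cand], alpha=alpha):
            w = cand
            break
    change = dec.rcs[:w].sum(axis=0) if w > 0 else np.zeros_like(pre)
    variability = tails[w] if w < M else np.zeros_like(pre)
    pct_change = float(dec.eigenvalues[:w].sum())
    return CVDResult(
        w=w,
        M=M,
        alpha=alpha,
        change=change,
        variability=variability,
        pct_change=pct_change,
        pct_variability=float(100.0 - pct_change),
        eigenvalues=dec.eigenvalues,
        preprocessing=record,
    )


def unpredictability(result: CVDResult) -> float:
    """Percent variance in the variability component (higher = less
    predictable)."""
    return result.pct_variability
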