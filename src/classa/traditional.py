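"""Traditional HRV comparison metrics: HR, SDNN, spectral band powers,
sample entropy and permutation entropy.

All operations take a :class:`~classa.preprocess.UniformHRV` window (RR
values in seconds on a uniform grid).  Conventions:

* HR is the mean of 60/x(n) over the window, in beats per minute (note this
  is the mean of instantaneous rates, not 60 over the mean interval).
* SDNN is the sample standard deviation (denominator N-1), reported in ms.
* Spectral powers come from the Hamming-windowed one-sided periodogram of
  the demeaned signal, with window-energy compensation so that a pure
  sinusoid of amplitude A recovers a band power of A^2/2; band powers are
  trapezoidal integrals of the power density over the band.  LF is
  0.04-0.15 Hz, HF 0.15-0.4 Hz and the normalisation band Np 0.04-0.5 Hz;
  a bin falling exactly on a shared edge is assigned to the higher band.
  Powers are in (input unit)^2, i.e. s^2 for RR values in seconds.
* Sample entropy follows Richman-Moorman: Chebyshev distance, self-matches
  excluded, tolerance r = r_factor * SD(x), SE = -ln(A/B) with A and B the
  (m+1)- and m-template match counts over the same N-m template set.
* Permutation entropy follows Bandt-Pompe: Shannon entropy of the ordinal
  pattern distribution of length m_pe, normalised by log(m_pe!) to [0, 1];
  rank ties are broken by order of occurrence (stable sort).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .preprocess import UniformHRV

__all__ = [
    "PeriodogramSpectrum",
    "SpectralBandPowers",
    "EntropyParams",
    "TraditionalMetrics",
    "heart_rate",
    "sdnn",
    "periodogram",
    "band_powers",
    "sample_entropy",
    "permutation_entropy",
    "compute_all",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TOTAL_BAND = (0.04, 0.50)


@dataclass
class PeriodogramSpectrum:
    freqs: np.ndarray  # Hz, ascending, one-sided
    power: np.ndarray  # power density, (input unit)^2 per Hz
    fs: float
    window_kind: str = "hamming"


@dataclass
class SpectralBandPowers:
    """Absolute band powers (input unit squared) and percentages of the
    0.04-0.5 Hz normalisation power Np."""

    aLF: float
    aHF: float
    Np: float
    nLF: float  # percent; nan when Np == 0
    nHF: float

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.nLF) or math.isnan(self.nHF))


@dataclass
class EntropyParams:
    m_se: int = 2
    r_factor: float = 0.15
    m_pe: int = 6

    def __post_init__(self) -> None:
        if self.m_se < 1:
            raise ValueError("m_se must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")
        if not 3 <= self.m_pe <= 7:
            raise ValueError("m_pe should lie in [3, 7]")


@dataclass
class TraditionalMetrics:
    hr: float
    sdnn: float
    bands: SpectralBandPowers
    se: float
    pe: float
    window_start: float = 0.0


def heart_rate(x: UniformHRV) -> float:
    """Mean instantaneous heart rate, 60/x(n) averaged over the window (bpm)."""
    v = x.values
    if np.any(v <= 0):
        raise ValueError("heart rate undefined for non-positive RR values")
    return float(np.mean(60.0 / v))


def sdnn(x: UniformHRV) -> float:
    """Sample standard deviation of the window, in milliseconds."""
    if len(x) < 2:
        raise ValueError("SDNN needs at least 2 samples")
    return float(np.std(x.values, ddof=1) * 1000.0)


def periodogram(x: UniformHRV, window_kind: str = "hamming") -> PeriodogramSpectrum:
    """One-sided windowed periodogram of the demeaned window.

    Power density normalisation divides by the taper energy sum(w^2) so the
    integral of the density over frequency recovers the signal's mean
    power: a pure in-band sinusoid of amplitude A integrates to A^2/2.
    """
    if len(x) < 8:
        raise ValueError("periodogram needs at least 8 samples")
    f, p = signal.periodogram(
        x.values,
        fs=x.rate,
        window=window_kind,
        detrend="constant",
        scaling="density",
    )
    return PeriodogramSpectrum(freqs=f, power=p, fs=x.rate, window_kind=window_kind)


def _band_integral(spec: PeriodogramSpectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the density over bins with lo <= f < hi.

    The half-open interval implements the shared-edge rule: a bin exactly on
    a band boundary belongs to the higher band.
    """
    m = (spec.freqs >= lo) & (spec.freqs < hi)
    if np.count_nonzero(m) < 2:
        return 0.0
    return float(np.trapezoid(spec.power[m], spec.freqs[m]))


def band_powers(spec: PeriodogramSpectrum) -> SpectralBandPowers:
    """LF/HF/total band powers and the normalised percentages nLF, nHF."""
    if spec.freqs[-1] < TOTAL_BAND[1]:
        raise ValueError("spectrum does not cover the 0.04-0.5 Hz band")
    a_lf = _band_integral(spec, *LF_BAND)
    a_hf = _band_integral(spec, *HF_BAND)
    np_pow = _band_integral(spec, *TOTAL_BAND)
    if np_pow > 0:
        n_lf = 100.0 * a_lf / np_pow
        n_hf = 100.0 * a_hf / np_pow
    else:
        warnings.warn("zero normalisation power; nLF/nHF undefined", stacklevel=2)
        n_lf = n_hf = float("nan")
    return SpectralBandPowers(aLF=a_lf, aHF=a_hf, Np=np_pow, nLF=n_lf, nHF=n_hf)


def total_power(spec: PeriodogramSpectrum) -> float:
    """Trapezoidal integral of the density over the whole one-sided axis."""
    return float(np.trapezoid(spec.power, spec.freqs))


def sample_entropy(x: UniformHRV, params: EntropyParams | None = None) -> float:
    """Sample entropy SE(m, r) of the window.

    Returns nan (with a warning) when the tolerance degenerates to zero
    (constant input) or when either template count is zero, rather than
    silently producing an infinite value.
    """
    params = params or EntropyParams()
    v = x.values
    m = params.m_se
    n = v.size
    if n <= m + 1:
        raise ValueError("window too short for sample entropy")
    # explicit constancy check: summation rounding can leave std() of a
    # constant window at ~1e-16 instead of exactly zero
    if np.all(v == v[0]):
        warnings.warn("zero tolerance (constant window); SE undefined", stacklevel=2)
        return float("nan")
    r = params.r_factor * float(np.std(v))
    b = _template_matches(v, m, r, n_templates=n - m)
    a = _template_matches(v, m + 1, r, n_templates=n - m)
    if a == 0 or b == 0:
        warnings.warn("no template matches; SE undefined", stacklevel=2)
        return float("nan")
    return float(-math.log(a / b))


def _template_matches(v: np.ndarray, m: int, r: float, n_templates: int) -> int:
    """Number of ordered template pairs (i != j) whose length-m templates
    are within Chebyshev distance r.  Both the m- and (m+1)-counts use the
    same first N-m template start indices, per Richman-Moorman."""
    X = sliding_window_view(v, m)[:n_templates]
    count = 0
    for i in range(len(X) - 1):
        d = np.max(np.abs(X[i + 1 :] - X[i]), axis=1)
        count += int(np.count_nonzero(d <= r))
    return 2 * count  # ordered pairs; the factor cancels in A/B


def _ordinal_codes(v: np.ndarray, m: int) -> np.ndarray:
    """Integer code of the ordinal pattern of every length-m window.

    Patterns are the permutation that sorts each window; ties are resolved
    by order of occurrence (stable sort), so equal values keep their
    original relative order.
    """
    W = sliding_window_view(v, m)
    perm = np.argsort(W, axis=1, kind="stable")
    # encode each permutation row as a single integer (mixed-radix)
    codes = np.zeros(len(W), dtype=np.int64)
    for k in range(m):
        codes = codes * m + perm[:, k]
    return codes


def permutation_entropy(x: UniformHRV, params: EntropyParams | None = None) -> float:
    """Normalised permutation entropy in [0, 1] of the window."""
    params = params or EntropyParams()
    v = x.values
    m = params.m_pe
    if v.size < m + 1:
        raise ValueError("window too short for permutation entropy")
    if math.factorial(m) > v.size:
        warnings.warn(
            f"m_pe!={math.factorial(m)} exceeds window length {v.size}; "
            "the pattern distribution is under-sampled",
            stacklevel=2,
        )
    codes = _ordinal_codes(v, m)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-np.sum(p * np.log(p)))
    return h / math.log(math.factorial(m))


def compute_all(
    x: UniformHRV, params: EntropyParams | None = None
) -> TraditionalMetrics:
    """All eight traditional metrics of one window."""
    params = params or EntropyParams()
    bands = band_powers(periodogram(x))
    return TraditionalMetrics(
        hr=heart_rate(x),
        sdnn=sdnn(x),
        bands=bands,
        se=sample_entropy(x, params),
        pe=permutation_entropy(x, params),
        window_start=x.start_time,
    )
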