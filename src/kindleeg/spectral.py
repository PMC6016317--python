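"""Welch power spectra of AD segments and their band-power decomposition.

The analysis follows the standard quantitative-EEG recipe: each segment is
split into 50 %-overlapping sub-segments, each sub-segment is linearly
detrended and Hann-tapered, and the modified periodograms are averaged
(Welch's method, density scaling, so that the integrated density equals the
signal variance). The averaged density is then reduced to absolute and
relative power in the conventional rodent sub-bands

    delta [1, 4) Hz, theta [4, 8), alpha [8, 12), beta [12, 28), gamma [28, 40)

and their aggregates

    LFB = delta + theta [1, 8), MFB = alpha [8, 12), HFB = beta + gamma [12, 40),

plus the theta/alpha power ratio. Fractions are normalized by total power in
[1, 40) Hz; energy below 1 Hz (DC, electrode drift) is excluded throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import (
    InsufficientDataError,
    ParameterError,
    UndefinedFractionError,
    UndefinedRatioError,
)
from .records import EEGRecord

SUB_BANDS = ("delta", "theta", "alpha", "beta", "gamma")
AGGREGATES = ("LFB", "MFB", "HFB")


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands (half-open intervals [low, high), Hz).

    The five sub-bands must tile ``total`` contiguously, and the three
    aggregates must tile it as LFB = delta∪theta, MFB = alpha,
    HFB = beta∪gamma.
    """

    bands: dict = field(
        default_factory=lambda: {
            "delta": (1.0, 4.0),
            "theta": (4.0, 8.0),
            "alpha": (8.0, 12.0),
            "beta": (12.0, 28.0),
            "gamma": (28.0, 40.0),
        }
    )
    aggregates: dict = field(
        default_factory=lambda: {
            "LFB": (1.0, 8.0),
            "MFB": (8.0, 12.0),
            "HFB": (12.0, 40.0),
        }
    )
    total: tuple = (1.0, 40.0)

    def __post_init__(self) -> None:
        edges = [self.bands[name] for name in SUB_BANDS]
        for (lo, hi) in edges:
            if hi <= lo:
                raise ParameterError(f"band edges must increase: {(lo, hi)}")
        for (_, hi1), (lo2, _) in zip(edges[:-1], edges[1:]):
            if hi1 != lo2:
                raise ParameterError("sub-bands must be contiguous and non-overlapping")
        if (edges[0][0], edges[-1][1]) != tuple(self.total):
            raise ParameterError("sub-bands must tile the total range")
        if self.aggregates["LFB"] != (self.bands["delta"][0], self.bands["theta"][1]):
            raise ParameterError("LFB must equal delta ∪ theta")
        if self.aggregates["MFB"] != self.bands["alpha"]:
            raise ParameterError("MFB must equal alpha")
        if self.aggregates["HFB"] != (self.bands["beta"][0], self.bands["gamma"][1]):
            raise ParameterError("HFB must equal beta ∪ gamma")

    def all_bands(self) -> dict:
        out = dict(self.bands)
        out.update(self.aggregates)
        return out


DEFAULT_BANDS = BandScheme()


@dataclass
class PSDResult:
    """One-sided averaged power spectral density.

    ``density`` is in µV²/Hz on a uniform frequency grid from 0 to Nyquist.
    """

    frequencies: np.ndarray
    density: np.ndarray
    segment_length: float
    n_averages: int
    sampling_rate: float

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class BandFractions:
    """Absolute (µV²) and relative band powers of one segment.

    Fractions are relative to total power in the scheme's ``total`` range.
    ``theta_alpha_ratio`` is None when alpha power is exactly zero; use
    :func:`theta_alpha_ratio` to get the error-raising accessor.
    """

    absolute: dict
    fraction: dict
    total_power: float
    theta_alpha_ratio: float | None


def welch_psd(
    segment: EEGRecord,
    segment_length: float = 2.0,
    overlap: float = 0.5,
    window: str = "hann",
    detrend: str = "linear",
    nfft: int | None = None,
) -> PSDResult:
    """Averaged modified-periodogram PSD of a segment.

    Parameters
    ----------
    segment_length : float
        Welch sub-segment length, seconds. The default 2 s gives 0.5 Hz
        resolution, so a minimum-length 6 s AD yields 5 averaged
        periodograms at 50 % overlap.
    overlap : float
        Fractional overlap between consecutive sub-segments in [0, 1).
    nfft : int, optional
        Zero-padded FFT length for a finer display grid (does not add
        resolution).
    """
    if not 0 <= overlap < 1:
        raise ParameterError("overlap must lie in [0, 1)")
    fs = segment.sampling_rate
    nperseg = int(round(segment_length * fs))
    if nperseg < 2:
        raise ParameterError("segment_length too short for the sampling rate")
    if segment.n_samples < nperseg:
        raise InsufficientDataError(
            f"segment of {segment.duration:.3f} s shorter than one "
            f"{segment_length:.3f} s sub-segment"
        )
    noverlap = int(round(nperseg * overlap))
    freqs, density = sps.welch(
        segment.samples,
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        detrend=detrend,
        scaling="density",
    )
    step = nperseg - noverlap
    n_averages = 1 + (segment.n_samples - nperseg) // step
    return PSDResult(
        frequencies=freqs,
        density=density,
        segment_length=segment_length,
        n_averages=int(n_averages),
        sampling_rate=fs,
    )


def _integrate(psd: PSDResult, lo: float, hi: float) -> float:
    # rectangle rule on the uniform grid; half-open band [lo, hi)
    mask = (psd.frequencies >= lo) & (psd.frequencies < hi)
    return float(np.sum(psd.density[mask]) * psd.df)


def band_fractions(psd: PSDResult, scheme: BandScheme = DEFAULT_BANDS) -> BandFractions:
    """Reduce a PSD to absolute band powers and fractions of 1-40 Hz power."""
    nyquist = psd.sampling_rate / 2.0
    if scheme.total[1] > nyquist:
        raise ParameterError(
            f"band scheme upper edge {scheme.total[1]} Hz exceeds Nyquist {nyquist} Hz"
        )
    absolute = {name: _integrate(psd, lo, hi) for name, (lo, hi) in scheme.all_bands().items()}
    total = _integrate(psd, *scheme.total)
    if total <= 0:
        raise UndefinedFractionError("zero total power in the analysis range")
    fraction = {name: p / total for name, p in absolute.items()}
    alpha = absolute["alpha"]
    ratio = absolute["theta"] / alpha if alpha > 0 else None
    return BandFractions(
        absolute=absolute, fraction=fraction, total_power=total, theta_alpha_ratio=ratio
    )


def theta_alpha_ratio(fractions: BandFractions) -> float:
    """Theta-to-alpha power ratio; raises rather than returning infinity."""
    if fractions.theta_alpha_ratio is None:
        raise UndefinedRatioError("alpha band power is zero; ratio undefined")
    return fractions.theta_alpha_ratio


def find_spectral_peaks(
    segment: EEGRecord | PSDResult,
    freq_range: tuple = (0.0, 8.0),
    prominence: float = 0.25,
    grid_spacing: float = 0.05,
    segment_length: float = 2.0,
) -> list[float]:
    """Locate spectral peaks inside ``freq_range``.

    ``prominence`` is a fraction of the maximum density within the range.
    When given a raw segment, the PSD is recomputed on a zero-padded grid
    with spacing ≤ ``grid_spacing`` Hz so peak frequencies are refined below
    the native resolution; a precomputed :class:`PSDResult` is used on its
    own grid.
    """
    lo, hi = freq_range
    if hi <= lo:
        raise ParameterError("empty frequency range")
    if isinstance(segment, EEGRecord):
        nperseg = int(round(segment_length * segment.sampling_rate))
        nfft = int(2 ** np.ceil(np.log2(segment.sampling_rate / grid_spacing)))
        nfft = max(nfft, nperseg)
        psd = welch_psd(segment, segment_length=segment_length, nfft=nfft)
    else:
        psd = segment
    mask = (psd.frequencies >= lo) & (psd.frequencies <= hi)
    if not np.any(mask):
        raise ParameterError("frequency range outside the PSD grid")
    f = psd.frequencies[mask]
    d = psd.density[mask]
    if d.max() <= 0:
        return []
    idx, _ = sps.find_peaks(d, prominence=prominence * d.max())
    return [float(f[i]) for i in idx]
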