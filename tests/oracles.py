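"""Independent reference implementations used only to check the package.

These deliberately avoid scipy.signal: the Welch oracle is a direct
O(N²) DFT periodogram average, written from the definition.
"""
from __future__ import annotations

import numpy as np


def dft_direct(x: np.ndarray) -> np.ndarray:
    """One-sided DFT by direct summation (no FFT)."""
    n = x.size
    k = np.arange(n // 2 + 1)
    phase = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    return phase @ x


def welch_psd_bruteforce(
    x: np.ndarray, fs: float, nperseg: int, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged modified periodogram from first principles.

    Linear detrend per sub-segment (least squares), periodic Hann taper,
    density scaling 1/(fs·Σw²), one-sided doubling except DC and Nyquist.
    """
    x = np.asarray(x, dtype=float)
    step = nperseg - int(round(nperseg * overlap))
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nperseg) / nperseg)
    t = np.arange(nperseg, dtype=float)
    design = np.column_stack([t, np.ones(nperseg)])
    spectra = []
    for start in range(0, x.size - nperseg + 1, step):
        seg = x[start : start + nperseg].copy()
        beta, *_ = np.linalg.lstsq(design, seg, rcond=None)
        seg = seg - design @ beta
        X = dft_direct(seg * w)
        p = np.abs(X) ** 2 / (fs * np.sum(w * w))
        p[1:] *= 2.0
        if nperseg % 2 == 0:
            p[-1] /= 2.0
        spectra.append(p)
    freqs = np.arange(nperseg // 2 + 1) * fs / nperseg
    return freqs, np.mean(spectra, axis=0)


def sliding_rms_bruteforce(x: np.ndarray, fs: float, window: float, hop: float):
    """Windowed RMS by explicit slicing."""
    w = int(round(window * fs))
    h = int(round(hop * fs))
    out = []
    for start in range(0, x.size - w + 1, h):
        seg = x[start : start + w]
        out.append(np.sqrt(np.mean(seg * seg)))
    return np.asarray(out)


def permutation_pearson_p(x, y, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the Pearson correlation."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def _r(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    observed = abs(_r(x, y))
    hits = 0
    for _ in range(n_perm):
        if abs(_r(x, rng.permutation(y))) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
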