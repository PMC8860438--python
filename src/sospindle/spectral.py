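"""Power spectra, fractal/oscillatory separation (IRASA) and peak finding.

The individualization step of the coupling pipeline: average Hanning-taper
spectra over 15-s windows slid in 1-s steps across continuous runs of the
requested sleep stages, estimate the 1/f fractal component by irregular
resampling (pairwise stretching/compressing the signal by factors
1.10 ... 1.90 and median-averaging the geometric means of each resampled
pair's spectra), and subtract it to expose the oscillatory residual from
which each channel's slow-oscillation and spindle peak frequencies are
read.

Windows never cross a stage-run boundary ("continuous" sleep only); all
windows are averaged with equal weight.  The resampled spectra live on a
finer/coarser frequency grid and are linearly interpolated onto the grid
of the unresampled 15-s window before pairing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len
from scipy.signal import resample_poly

from .core import Hypnogram, Recording

__all__ = [
    "SpectrumSet",
    "OscillatoryPeaks",
    "znorm_signal",
    "compute_spectrum",
    "irasa_fractal",
    "compute_spectra",
    "find_peaks",
]

#: resampling factors 1.10 ... 1.90 in steps of 0.05
IRASA_FACTORS = tuple(np.round(np.arange(1.10, 1.901, 0.05), 2))


@dataclass
class SpectrumSet:
    """Total, fractal and oscillatory-residual spectra per channel."""

    freqs: np.ndarray          # Hz, strictly increasing
    total: np.ndarray          # (n_channels, n_freqs)
    fractal: np.ndarray
    channel_labels: tuple

    def __post_init__(self):
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        self.residual = self.total - self.fractal

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, ch in enumerate(self.channel_labels):
            rows.append(pd.DataFrame({
                "channel": ch, "freq": self.freqs,
                "total": self.total[ci], "fractal": self.fractal[ci],
                "residual": self.residual[ci]}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class OscillatoryPeaks:
    """Per-channel SO and spindle peak frequency/amplitude (1/f-corrected)."""

    table: pd.DataFrame  # channel, band, peak_freq, peak_amp, is_local_max

    def peak(self, channel: str, band: str) -> float:
        sel = self.table[(self.table.channel == channel) & (self.table.band == band)]
        if sel.empty:
            raise KeyError(f"no {band} peak for channel {channel}")
        return float(sel.peak_freq.iloc[0])


def znorm_signal(recording: Recording) -> Recording:
    """Z-normalize each channel over the full recording (mean 0, SD 1)."""
    sig = recording.signal
    sd = sig.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(
            f"zero-variance channel(s): {[recording.channel_labels[i] for i in bad]}"
        )
    out = (sig - sig.mean(axis=1, keepdims=True)) / sd[:, None]
    return Recording(out, recording.sampling_rate, recording.channel_labels)


def _window_starts(recording, hypnogram, stages, window: float, step: float,
                   max_windows: int | None = None) -> np.ndarray:
    fs = recording.sampling_rate
    L = int(round(window * fs))
    stepn = int(round(step * fs))
    starts = []
    for a, b in hypnogram.runs(stages):
        i0 = int(round(a * fs))
        i1 = min(int(round(b * fs)), recording.n_samples)
        starts.extend(range(i0, i1 - L + 1, stepn))
        if max_windows is not None and len(starts) >= max_windows:
            starts = starts[:max_windows]
            break
    return np.asarray(starts, dtype=int)


def _psd_windows(x: np.ndarray, starts: np.ndarray, L: int, fs: float,
                 nfft: int | None = None) -> np.ndarray:
    """Hanning-taper power of windows of length L at given starts.

    ``x`` may be (n_samples,) or (n_channels, n_samples); returns
    (..., n_win, n_rfft) with windows on the second-to-last axis.  An
    ``nfft`` larger than L zero-pads (finer frequency sampling of the
    same tapered periodogram; the power scale is unchanged).
    """
    wins = np.lib.stride_tricks.sliding_window_view(x, L, axis=-1)[..., starts, :]
    taper = np.hanning(L)
    scale = 2.0 / (fs * (taper**2).sum())
    return np.abs(np.fft.rfft(wins * taper, axis=-1, n=nfft)) ** 2 * scale


def compute_spectrum(recording: Recording, hypnogram: Hypnogram, stages=("N2", "N3"),
                     fmin: float = 0.1, fmax: float = 30.0, *, window: float = 15.0,
                     step: float = 1.0, max_windows: int | None = None):
    """Average Hanning-window power spectrum; returns ``(freqs, power)``.

    ``power`` has shape (n_channels, n_freqs) on the FFT grid of the 15-s
    window restricted to [fmin, fmax].
    """
    fs = recording.sampling_rate
    L = int(round(window * fs))
    starts = _window_starts(recording, hypnogram, stages, window, step, max_windows)
    if starts.size == 0:
        raise ValueError(
            f"no continuous {window:.0f}-s run of stages {tuple(stages)} available"
        )
    freqs = np.fft.rfftfreq(L, 1.0 / fs)
    sel = (freqs >= fmin) & (freqs <= fmax)
    power = _psd_windows(recording.signal, starts, L, fs)[..., sel].mean(axis=-2)
    return freqs[sel], power


def _interp_uniform(psd: np.ndarray, df_src: float, f_target: np.ndarray) -> np.ndarray:
    """Linear interpolation from a uniform grid (spacing df_src, origin 0),
    acting on the last axis."""
    idx = f_target / df_src
    i0 = np.clip(idx.astype(int), 0, psd.shape[-1] - 2)
    w = np.clip(idx - i0, 0.0, 1.0)
    return psd[..., i0] * (1 - w) + psd[..., i0 + 1] * w


def irasa_fractal(recording: Recording, hypnogram: Hypnogram, stages=("N2", "N3"),
                  fmin: float = 0.1, fmax: float = 30.0, *, window: float = 15.0,
                  step: float = 1.0, factors=IRASA_FACTORS,
                  max_windows: int | None = None):
    """Fractal (1/f) spectrum by irregular resampling; ``(freqs, fractal)``.

    For every window and factor h the spectra of the h-stretched and
    h-compressed signal are geometrically averaged (which cancels the
    h^(alpha-1) scale factors of a 1/f^alpha process but displaces any
    oscillatory peak), the median is taken across factors, and the result
    is averaged over windows on the same grid as :func:`compute_spectrum`.
    """
    fs = recording.sampling_rate
    L = int(round(window * fs))
    starts = _window_starts(recording, hypnogram, stages, window, step, max_windows)
    if starts.size == 0:
        raise ValueError(
            f"no continuous {window:.0f}-s run of stages {tuple(stages)} available"
        )
    freqs = np.fft.rfftfreq(L, 1.0 / fs)
    sel = (freqs >= fmin) & (freqs <= fmax)
    f_out = freqs[sel]

    # rational approximations of the resampling factors (exact for 0.05 steps)
    rationals = []
    for h in factors:
        fr = Fraction(h).limit_denominator(1000)
        if abs(fr - h) > 1e-3:
            raise ValueError(f"no rational approximation for factor {h}")
        rationals.append((fr.numerator, fr.denominator))

    # crop to the span actually covered by windows (pad one window on each
    # side so resampling-filter edges stay clear of the analyzed stretch)
    i0 = max(int(starts.min()) - L, 0)
    i1 = min(int(starts.max()) + 2 * L, recording.n_samples)
    X = recording.signal[:, i0:i1]
    st_local = starts - i0

    # Spectra are averaged across windows *before* the geometric pairing:
    # pairing raw single-window periodograms first would carry the
    # E[sqrt(P1*P2)] ~ 0.785 chi-square bias of unaveraged spectra into the
    # fractal estimate (a ~20% spurious "oscillatory" residual everywhere),
    # while pairing the window-averaged spectra is asymptotically unbiased.
    geo = np.empty((len(factors), recording.n_channels, f_out.size))
    for hi, (p, q) in enumerate(rationals):
        pair = []
        for up, down in ((p, q), (q, p)):
            h = up / down
            xr = resample_poly(X, up, down, axis=1)
            Lh = int(round(L * h))
            nfft = int(next_fast_len(Lh))
            st = np.clip(np.round(st_local * h).astype(int), 0, xr.shape[1] - Lh)
            psd = _psd_windows(xr, st, Lh, fs, nfft=nfft).mean(axis=-2)
            pair.append(_interp_uniform(psd, fs / nfft, f_out))
        geo[hi] = np.sqrt(pair[0] * pair[1])
    fractal = np.median(geo, axis=0)
    return f_out, fractal


def compute_spectra(recording: Recording, hypnogram: Hypnogram, stages=("N2", "N3"),
                    fmin: float = 0.1, fmax: float = 30.0, **kw) -> SpectrumSet:
    """Total + fractal + residual in one call (shared windows and grid)."""
    freqs, total = compute_spectrum(recording, hypnogram, stages, fmin, fmax, **kw)
    _, fractal = irasa_fractal(recording, hypnogram, stages, fmin, fmax, **kw)
    return SpectrumSet(freqs, total, fractal, recording.channel_labels)


def find_peaks(spectra: SpectrumSet, so_band=(0.0, 2.0),
               spindle_band=(10.0, 17.0)) -> OscillatoryPeaks:
    """Highest oscillatory-residual peak per channel in each band.

    A peak must be a local maximum of the residual (strictly above both
    neighbors); a band without any local maximum is flagged and its global
    maximum returned with a warning.
    """
    rows = []
    for name, (lo, hi) in (("so", so_band), ("spindle", spindle_band)):
        sel = (spectra.freqs > lo) & (spectra.freqs <= hi)
        if not sel.any():
            raise ValueError(f"frequency grid does not cover the {name} band {lo}-{hi} Hz")
        idx = np.where(sel)[0]
        for ci, ch in enumerate(spectra.channel_labels):
            r = spectra.residual[ci]
            local = [i for i in idx
                     if 0 < i < len(r) - 1 and r[i] > r[i - 1] and r[i] > r[i + 1]]
            if local:
                best = max(local, key=lambda i: r[i])
                is_local = True
            else:
                best = idx[np.argmax(r[idx])]
                is_local = False
                warnings.warn(
                    f"channel {ch}: no local residual maximum in the {name} band; "
                    "returning the band's global maximum", RuntimeWarning,
                    stacklevel=2)
            rows.append({"channel": ch, "band": name,
                         "peak_freq": float(spectra.freqs[best]),
                         "peak_amp": float(r[best]), "is_local_max": is_local})
    return OscillatoryPeaks(pd.DataFrame(rows))
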