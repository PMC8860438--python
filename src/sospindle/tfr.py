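"""SO-trough-locked time-frequency representations with bootstrap baseline.

Power is computed per trial with a 500-ms Hanning window slid in 50-ms
steps (times -2 ... 2 s around the slow-oscillation trough) at 5 ... 30 Hz
in 0.5-Hz steps, then averaged across trials.  Baseline correction
z-scores every (time, frequency) bin against the mean and SD of a
bootstrap distribution of the trial-averaged baseline power (trials
resampled with replacement) in a fixed pre-trough interval, which makes
the z-map invariant to a global rescaling of the trials.  Time points
whose analysis window would extend beyond the epoch are reported as NaN
and excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventSet

__all__ = ["TFRResult", "compute_tfr", "bootstrap_baseline_z"]


@dataclass
class TFRResult:
    times: np.ndarray            # s, relative to SO trough
    freqs: np.ndarray            # Hz
    power: np.ndarray            # (n_times, n_freqs), trial average
    trial_power: np.ndarray      # (n_trials, n_times, n_freqs)
    zpower: np.ndarray | None = None


def compute_tfr(so_events: EventSet, *, tmin: float = -2.0, tmax: float = 2.0,
                tstep: float = 0.05, fmin: float = 5.0, fmax: float = 30.0,
                fstep: float = 0.5, window: float = 0.5) -> TFRResult:
    """Short-time Hanning-taper power around each SO trough."""
    if len(so_events) < 1:
        raise ValueError("need at least one slow-oscillation epoch")
    fs = so_events.sampling_rate
    X = so_events.epochs
    n_samp = X.shape[1]
    if n_samp < int(round(window * fs)):
        raise ValueError("epochs shorter than the analysis window")
    Lw = int(round(window * fs))
    times = np.round(np.arange(tmin, tmax + tstep / 2, tstep), 10)
    freqs = np.round(np.arange(fmin, fmax + fstep / 2, fstep), 10)
    center0 = (n_samp - 1) // 2  # sample index of t = 0 (the trough)
    taper = np.hanning(Lw)
    # DFT kernels at the requested frequencies
    t_rel = np.arange(Lw) / fs
    kern = np.exp(-2j * np.pi * freqs[:, None] * t_rel[None, :]) * taper
    scale = 2.0 / (fs * (taper**2).sum())

    starts = np.round(times * fs).astype(int) + center0 - Lw // 2
    valid = (starts >= 0) & (starts + Lw <= n_samp)
    segs = np.lib.stride_tricks.sliding_window_view(X, Lw, axis=1)
    trial_power = np.full((X.shape[0], times.size, freqs.size), np.nan)
    sel = segs[:, starts[valid], :]                       # (trials, t, Lw)
    spec = np.einsum("ntl,fl->ntf", sel, kern)
    trial_power[:, valid, :] = (np.abs(spec) ** 2) * scale
    return TFRResult(times, freqs, trial_power.mean(axis=0), trial_power)


def bootstrap_baseline_z(tfr: TFRResult, baseline=(-2.0, -1.5),
                         iterations: int = 10000, seed: int | None = None) -> TFRResult:
    """Z-score ``tfr.power`` against a bootstrapped baseline distribution.

    Per frequency, each bootstrap iteration resamples the trials with
    replacement and computes the trial-averaged power of every baseline
    time bin; the draws are pooled over iterations and baseline bins, and
    z = (power - mean) / SD of that pooled distribution.  Pooling the bins
    (rather than averaging across them first) keeps the SD on the scale of
    a single trial-averaged bin, so the z-scored baseline itself has unit
    spread.  Deterministic given ``seed``.
    """
    n_trials = tfr.trial_power.shape[0]
    if n_trials < 2:
        raise ValueError("bootstrap baseline needs at least 2 trials")
    bmask = (tfr.times >= baseline[0]) & (tfr.times <= baseline[1])
    if not bmask.any():
        raise ValueError("baseline interval outside the epoch time grid")
    base = tfr.trial_power[:, bmask, :]
    valid = ~np.isnan(base).any(axis=(0, 2))
    if not valid.any():
        raise ValueError("baseline interval has no valid time bins")
    base = base[:, valid, :]                            # (trials, bins, freqs)
    n_bins, n_freqs = base.shape[1], base.shape[2]
    rng = np.random.default_rng(seed)
    # multinomial counts over trials == resampling with replacement
    weights = rng.multinomial(n_trials, np.full(n_trials, 1.0 / n_trials),
                              size=iterations) / n_trials
    boot = weights @ base.reshape(n_trials, -1)         # (iters, bins*freqs)
    boot = boot.reshape(iterations, n_bins, n_freqs)
    mu = boot.mean(axis=(0, 1))
    sd = boot.std(axis=(0, 1))
    z = (tfr.power - mu[None, :]) / sd[None, :]
    return TFRResult(tfr.times, tfr.freqs, tfr.power, tfr.trial_power, z)
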