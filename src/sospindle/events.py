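"""Individualized spindle / slow-oscillation detection and co-occurrence.

Spindles: band-pass +/-2 Hz around each channel's individual spindle peak
(zero-phase Butterworth, order 3 per pass), Hilbert envelope smoothed with
a 200-ms centered moving average, threshold at the 75th percentile of the
smoothed envelope over stage-eligible samples, events are supra-threshold
runs lasting 0.5-3 s, centered on the largest positive peak of the
band-filtered signal within the run.

Slow oscillations: 0.16 Hz high-pass + 2 Hz low-pass, candidates are the
stretches between successive positive-to-negative zero crossings holding
exactly one negative then one positive half-wave and lasting 0.8-2 s;
events are candidates whose trough-to-peak amplitude reaches the 75th
percentile of all stage-eligible candidate amplitudes on that channel
(ties kept), centered on the filtered-signal trough.

Both detectors extract +/-2.5-s epochs from the raw (unfiltered) signal.
Because both thresholds are quantiles of the ongoing activity, detection
is invariant to a global gain change, and some detections on pure noise
are inherent: the threshold presumes genuine events dominate the upper
quartile of the reference distribution (true of real NREM sleep, and of
fixtures planted at matching densities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt

from .core import Hypnogram, Recording
from .spectral import OscillatoryPeaks

__all__ = [
    "EventSet",
    "CoupledEvents",
    "amplitude_threshold_mask",
    "detect_spindles",
    "detect_slow_oscillations",
    "znorm_epochs",
    "gate_cooccurrence",
    "cooccurrence_rate",
]

EVENT_COLUMNS = ["channel", "center_time", "onset", "offset",
                 "duration", "amplitude", "stage"]


@dataclass
class EventSet:
    """Detected transient events with raw (and optionally z-scored) epochs."""

    kind: str                      # "spindle" | "slow_oscillation"
    events: pd.DataFrame           # EVENT_COLUMNS
    epochs: np.ndarray             # (n_events, epoch_samples), raw signal
    sampling_rate: float
    epoch_margin: float = 2.5      # s on each side of center
    norm_epochs: np.ndarray | None = None
    dropped: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def select(self, index) -> "EventSet":
        idx = np.asarray(index)
        return EventSet(
            self.kind, self.events.iloc[idx].reset_index(drop=True),
            self.epochs[idx], self.sampling_rate, self.epoch_margin,
            None if self.norm_epochs is None else self.norm_epochs[idx],
            dict(self.dropped))


@dataclass
class CoupledEvents:
    """Spindle events retained by the co-occurrence gate, with SO partner."""

    events: pd.DataFrame           # EVENT_COLUMNS + partner_time, lag
    epochs: np.ndarray
    sampling_rate: float
    epoch_margin: float = 2.5
    norm_epochs: np.ndarray | None = None
    window: float = 2.5

    def __len__(self) -> int:
        return len(self.events)


def _runs(mask: np.ndarray):
    d = np.diff(np.r_[0, mask.astype(np.int8), 0])
    return np.where(d == 1)[0], np.where(d == -1)[0]


def amplitude_threshold_mask(amplitudes, percentile: float) -> np.ndarray:
    """Inclusive percentile criterion: keep amplitudes >= the percentile.

    Percentiles use linear interpolation between order statistics; the
    comparison is inclusive, so a set of identical amplitudes passes in
    its entirety (the tie rule of the SO amplitude criterion).
    """
    amps = np.asarray(amplitudes, dtype=float)
    return amps >= np.percentile(amps, percentile)


def _extract_epoch(x: np.ndarray, center: int, half: int):
    if center - half < 0 or center + half + 1 > len(x):
        return None
    return x[center - half: center + half + 1]


def detect_spindles(recording: Recording, hypnogram: Hypnogram,
                    peaks: OscillatoryPeaks, stages=("N3",), *,
                    percentile: float = 75.0, duration_bounds=(0.5, 3.0),
                    smooth: float = 0.2, half_band: float = 2.0,
                    epoch_margin: float = 2.5) -> EventSet:
    """Detect spindles around each channel's individual peak frequency."""
    fs = recording.sampling_rate
    if recording.duration <= 2 * epoch_margin:
        raise ValueError("recording shorter than twice the epoch margin")
    half = int(round(epoch_margin * fs))
    mask = hypnogram.sample_mask(stages, fs, recording.n_samples)
    if not mask.any():
        raise ValueError(f"no samples in stages {tuple(stages)}")
    win = int(round(smooth * fs)) | 1  # odd => exactly centered
    rows, epochs = [], []
    dropped = {"out_of_stage": 0, "epoch_bounds": 0}
    for ci, ch in enumerate(recording.channel_labels):
        f0 = peaks.peak(ch, "spindle")
        lo, hi = f0 - half_band, f0 + half_band
        if lo <= 0:
            raise ValueError(f"spindle band edge below 0 Hz on channel {ch}")
        sos = butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
        bp = sosfiltfilt(sos, recording.signal[ci])
        env = uniform_filter1d(np.abs(hilbert(bp)), win, mode="nearest")
        thr = np.percentile(env[mask], percentile)
        starts, ends = _runs(env >= thr)
        for a, b in zip(starts, ends):
            dur = (b - a) / fs
            if not duration_bounds[0] <= dur <= duration_bounds[1]:
                continue
            center = a + int(np.argmax(bp[a:b]))
            if not mask[center]:
                dropped["out_of_stage"] += 1
                continue
            epoch = _extract_epoch(recording.signal[ci], center, half)
            if epoch is None:
                dropped["epoch_bounds"] += 1
                continue
            rows.append({"channel": ch, "center_time": center / fs,
                         "onset": a / fs, "offset": b / fs, "duration": dur,
                         "amplitude": float(env[a:b].max()),
                         "stage": hypnogram.stage_at(center / fs)})
            epochs.append(epoch)
    return EventSet("spindle", pd.DataFrame(rows, columns=EVENT_COLUMNS),
                    np.array(epochs) if epochs else np.empty((0, 2 * half + 1)),
                    fs, epoch_margin, dropped=dropped)


def detect_slow_oscillations(recording: Recording, hypnogram: Hypnogram,
                             stages=("N3",), *, percentile: float = 75.0,
                             band=(0.16, 2.0), duration_bounds=(0.8, 2.0),
                             epoch_margin: float = 2.5) -> EventSet:
    """Detect slow oscillations by zero-crossing + amplitude criterion."""
    fs = recording.sampling_rate
    if recording.duration < 10:
        raise ValueError("recording shorter than 10 s")
    half = int(round(epoch_margin * fs))
    mask = hypnogram.sample_mask(stages, fs, recording.n_samples)
    if not mask.any():
        raise ValueError(f"no samples in stages {tuple(stages)}")
    hp = butter(3, band[0], btype="highpass", fs=fs, output="sos")
    lp = butter(3, band[1], btype="lowpass", fs=fs, output="sos")
    rows, epochs = [], []
    dropped = {"epoch_bounds": 0, "short_channels": []}
    for ci, ch in enumerate(recording.channel_labels):
        y = sosfiltfilt(lp, sosfiltfilt(hp, recording.signal[ci]))
        pos = y > 0
        ptn = np.where(pos[:-1] & ~pos[1:])[0] + 1  # first sample <= 0
        cands = []
        for a, b in zip(ptn[:-1], ptn[1:]):
            dur = (b - a) / fs
            if not duration_bounds[0] <= dur <= duration_bounds[1]:
                continue
            seg = y[a:b]
            ntp = np.sum(~pos[a:b - 1] & pos[a + 1:b])
            if ntp != 1:  # exactly one negative then one positive half-wave
                continue
            itr = int(np.argmin(seg))
            ipk = itr + int(np.argmax(seg[itr:]))
            if not (seg[itr] < 0 < seg[ipk]):
                continue
            if not mask[a + itr]:
                continue
            cands.append((a, b, a + itr, a + ipk, float(seg[ipk] - seg[itr]),
                          float(seg[itr])))
        if len(cands) < 4:
            warnings.warn(
                f"channel {ch}: only {len(cands)} slow-oscillation candidates; "
                "amplitude percentile ill-defined, returning no events",
                RuntimeWarning, stacklevel=2)
            dropped["short_channels"].append(ch)
            continue
        amps = np.array([c[4] for c in cands])
        keep = amplitude_threshold_mask(amps, percentile)
        for (a, b, itr, ipk, amp, trough_amp), ok in zip(cands, keep):
            if not ok:
                continue
            epoch = _extract_epoch(recording.signal[ci], itr, half)
            if epoch is None:
                dropped["epoch_bounds"] += 1
                continue
            rows.append({"channel": ch, "center_time": itr / fs,
                         "onset": a / fs, "offset": b / fs,
                         "duration": (b - a) / fs, "amplitude": amp,
                         "stage": hypnogram.stage_at(itr / fs)})
            epochs.append(epoch)
    return EventSet("slow_oscillation", pd.DataFrame(rows, columns=EVENT_COLUMNS),
                    np.array(epochs) if epochs else np.empty((0, 2 * half + 1)),
                    fs, epoch_margin, dropped=dropped)


def znorm_epochs(events: EventSet) -> EventSet:
    """Z-score each raw epoch in the time domain (raw retained alongside).

    Zero-variance epochs cannot be normalized and are dropped with a
    warning.
    """
    sd = events.epochs.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance epoch(s)",
            RuntimeWarning, stacklevel=2)
    out = events.select(np.where(keep)[0])
    mu = out.epochs.mean(axis=1, keepdims=True)
    out.norm_epochs = (out.epochs - mu) / out.epochs.std(axis=1, keepdims=True)
    out.dropped = dict(events.dropped, zero_variance=int((~keep).sum()))
    return out


def gate_cooccurrence(spindles: EventSet, sos: EventSet, window: float = 2.5,
                      stages=("N3",)) -> CoupledEvents:
    """Keep spindles with a same-channel SO trough within ``window`` s.

    The co-occurrence window is symmetric: ``|SO trough - spindle peak| <=
    window``; the partner is the nearest qualifying SO.  The stage
    restriction is applied to both event sets before gating.
    """
    sp = spindles.events
    so = sos.events
    if stages is not None:
        sp_keep = sp.stage.isin(stages).to_numpy()
        so = so[so.stage.isin(stages)]
    else:
        sp_keep = np.ones(len(sp), dtype=bool)
    so_by_ch = {ch: grp.center_time.to_numpy() for ch, grp in so.groupby("channel")}
    idx, partners, lags = [], [], []
    for i in np.where(sp_keep)[0]:
        troughs = so_by_ch.get(sp.channel.iloc[i])
        if troughs is None or troughs.size == 0:
            continue
        lag = troughs - sp.center_time.iloc[i]  # SO trough minus spindle peak
        j = int(np.argmin(np.abs(lag)))
        if abs(lag[j]) <= window:
            idx.append(i)
            partners.append(troughs[j])
            lags.append(lag[j])
    idx = np.asarray(idx, dtype=int)
    ev = sp.iloc[idx].reset_index(drop=True).copy()
    ev["partner_time"] = partners
    ev["lag"] = lags
    return CoupledEvents(
        ev, spindles.epochs[idx] if len(idx) else spindles.epochs[:0],
        spindles.sampling_rate, spindles.epoch_margin,
        None if spindles.norm_epochs is None else
        (spindles.norm_epochs[idx] if len(idx) else spindles.norm_epochs[:0]),
        window)


def cooccurrence_rate(spindles: EventSet, sos: EventSet, hypnogram: Hypnogram,
                      window: float = 2.5) -> pd.DataFrame:
    """Fraction of spindles with a gated SO partner, per stage and channel.

    Stages without any spindle yield NaN (undefined, not zero).
    """
    sp = spindles.events
    stages_present = sorted(set(sp.stage)) if len(sp) else []
    rows = []
    for stage in stages_present:
        gated = gate_cooccurrence(spindles, sos, window, stages=(stage,))
        for ch in sorted(set(sp.channel)):
            n_all = int(((sp.stage == stage) & (sp.channel == ch)).sum())
            n_gated = int((gated.events.channel == ch).sum())
            rows.append({"stage": stage, "channel": ch,
                         "rate": n_gated / n_all if n_all else np.nan,
                         "n_spindles": n_all})
    return pd.DataFrame(rows, columns=["stage", "channel", "rate", "n_spindles"])
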