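"""Ground-truth synthetic sleep EEG, hypnograms and behavioral cohorts.

The generator is a verification instrument for the analysis chain rather
than a biophysical model: it produces multichannel 1/f ("fractal") noise
with slow oscillations (SO; single negative-then-positive half-wave pair)
and spindle bursts (Gaussian-enveloped sinusoid at a subject-specific
frequency) planted at known times in stage-eligible sleep, and records
every plant.  Coupled spindles have their envelope peak placed where the
local SO waveform phase equals a von Mises(mu, kappa) draw, using the same
cosine phase convention as the coupling read-out (SO up-state peak = 0 rad,
trough = +/-pi).  Uncoupled spindles are kept at least ``so_exclusion`` s
away from any SO trough so they act as clean negative controls for the
co-occurrence gate.

Behavioral cohorts map a per-subject concentration kappa onto an overnight
change in task proficiency through a Gaussian copula so that the rank
correlation between the two approaches a configurable target as the cohort
grows, and emit block-level cascade-count tables consistent with the
learning-curve model (noisy linear trend, counts truncated at zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erfinv

from .core import MONTAGE_11, Hypnogram, Recording

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_recording",
    "generate_cohort",
    "fractal_noise",
]

#: default stage plan: brief wake, one long N3 bout, trailing N2
DEFAULT_PLAN = (("W", 30.0), ("N3", 600.0), ("N2", 120.0))


@dataclass
class SimConfig:
    """Parameters of one synthetic recording (one subject, one night)."""

    sampling_rate: float = 128.0
    channel_labels: tuple = MONTAGE_11
    stage_plan: tuple = DEFAULT_PLAN
    fractal_slope: float = 2.0       # spectral exponent alpha, power ~ 1/f^alpha
    fractal_offset: float = 10.0     # noise RMS amplitude, uV
    so_rate: float = 4.0             # events/min in eligible stages
    so_freq: float = 0.8             # Hz, < 2
    so_amplitude: float = 75.0       # uV half-wave amplitude
    so_stages: tuple = ("N3",)
    spindle_rate: float = 2.0        # events/min in eligible stages
    spindle_freq: float = 13.0       # Hz, subject-specific, in [10, 17]
    spindle_duration: float = 1.0    # s, in [0.5, 3]
    spindle_amplitude: float = 20.0  # uV envelope peak
    spindle_stages: tuple = ("N3",)
    coupling_mu: float = 0.3         # rad, preferred SO phase of spindle peak
    coupling_kappa: float = 4.0      # von Mises concentration, >= 0
    coupled_fraction: float = 0.8    # fraction of spindles tied to an SO
    so_exclusion: float = 3.0        # s, min gap of uncoupled spindles to SO troughs
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 < self.so_freq < 2:
            raise ValueError("so_freq must lie in (0, 2) Hz")
        if not 10 <= self.spindle_freq <= 17:
            raise ValueError("spindle_freq must lie in [10, 17] Hz")
        if not 0.5 <= self.spindle_duration <= 3:
            raise ValueError("spindle_duration must lie in [0.5, 3] s")
        if self.coupling_kappa < 0:
            raise ValueError("coupling_kappa must be >= 0")
        if not 0 <= self.coupled_fraction <= 1:
            raise ValueError("coupled_fraction must lie in [0, 1]")
        if self.so_rate < 0 or self.spindle_rate < 0:
            raise ValueError("event rates must be >= 0")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.stage_plan))


@dataclass
class GroundTruth:
    """Record of every planted event and latent parameter."""

    so_events: pd.DataFrame        # channel, trough_time
    spindle_events: pd.DataFrame   # channel, peak_time, frequency, coupled, phase
    placement_log: dict = field(default_factory=dict)
    subject_kappa: dict | None = None
    behavior_latents: pd.DataFrame | None = None


def fractal_noise(n_samples: int, sampling_rate: float, slope: float,
                  rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^slope, scaled to ``rms``."""
    w = rng.standard_normal(n_samples)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n_samples, 1.0 / sampling_rate)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-slope / 2.0)
    x = np.fft.irfft(spec * shape, n_samples)
    sd = x.std()
    if sd == 0:
        return x
    return x * (rms / sd)


def so_waveform(so_freq: float, amplitude: float, sampling_rate: float) -> np.ndarray:
    """One negative half-wave followed by one positive half-wave.

    With the cosine convention (analytic-signal angle of the < 2 Hz trace,
    up-peak = 0), the waveform phase at offset tau from its onset is
    ``2*pi*so_freq*tau + pi/2``: trough (tau = T/4) maps to pi, up-peak
    (tau = 3T/4) to 0.
    """
    period = 1.0 / so_freq
    k = np.arange(int(round(period * sampling_rate)))
    return -amplitude * np.sin(2 * np.pi * so_freq * k / sampling_rate)


def spindle_waveform(freq: float, amplitude: float, duration: float,
                     sampling_rate: float) -> np.ndarray:
    """Sinusoid under a Gaussian envelope (sigma = duration/6), carrier
    peak aligned with the envelope peak at the segment center."""
    sigma = duration / 6.0
    half = int(round(duration / 2.0 * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    return amplitude * np.cos(2 * np.pi * freq * t) * np.exp(-t**2 / (2 * sigma**2))


def _phase_offset_map(so_freq: float, sampling_rate: float,
                      epoch_margin: float = 2.5):
    """Invert the coupling phase read-out for the SO waveform.

    The idealized waveform phase ``2*pi*f*tau + pi/2`` differs by up to
    ~0.3 rad from the analytic-signal angle of an isolated single-cycle
    waveform seen through the epoch read-out (low-pass + Hilbert on a
    +/-2.5 s segment).  Since the phase convention is defined by the
    read-out, the generator places spindle peaks by numerically inverting
    it: returns ``(read_phase_grid_unwrapped, tau_grid)`` suitable for
    interpolation.
    """
    from .coupling import phase_readout

    period = 1.0 / so_freq
    half = int(round(epoch_margin * sampling_rate))
    n = 2 * half + 1
    # the analytic phase of the isolated cycle spans less than 2*pi inside
    # [0, T); extending tau slightly beyond the cycle covers the full circle
    taus = np.linspace(-0.3 * period, 1.3 * period, 385)
    t = (np.arange(n) - half) / sampling_rate      # 0 = spindle peak
    ts = t[None, :] + taus[:, None]                # time since SO onset
    epochs = np.where((ts >= 0) & (ts < period),
                      -np.sin(2 * np.pi * so_freq * ts), 0.0)
    read = phase_readout(epochs, sampling_rate)
    read_u = np.unwrap(read)
    # safeguard strict monotonicity for interpolation
    read_u = np.maximum.accumulate(read_u)
    return read_u, taus


def _phase_offset(phase: np.ndarray, so_freq: float, phase_map=None) -> np.ndarray:
    """Time offset from SO onset at which the *read* phase equals ``phase``."""
    if phase_map is None:  # idealized linear map (used only as fallback)
        return np.mod(phase - np.pi / 2.0, 2 * np.pi) / (2 * np.pi * so_freq)
    read_u, taus = phase_map
    # shift each phase onto the unwrapped branch nearest the map's center
    center = 0.5 * (read_u[0] + read_u[-1])
    ph = np.asarray(phase, dtype=float)
    ph = ph + 2 * np.pi * np.round((center - ph) / (2 * np.pi))
    ph = np.clip(ph, read_u[0], read_u[-1])
    return np.interp(ph, read_u, taus)


def _grid_times(intervals, n: int, min_sep: float, margin: float,
                rng: np.random.Generator) -> np.ndarray:
    """Place exactly n times on a jittered grid inside the intervals.

    Counts are allocated proportionally to interval length (largest
    remainder); grid spacing below ``min_sep`` raises, which is the
    "duration too short for the requested events" error path.
    """
    usable = [(a + margin, b - margin) for a, b in intervals if b - a > 2 * margin]
    lengths = np.array([b - a for a, b in usable])
    if len(usable) == 0 or lengths.sum() <= 0:
        if n > 0:
            raise ValueError("no eligible time to place events")
        return np.array([])
    if n == 0:
        return np.array([])
    frac = n * lengths / lengths.sum()
    counts = np.floor(frac).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(frac - counts))
    counts[order[:rem]] += 1
    times = []
    for (a, b), k in zip(usable, counts):
        if k == 0:
            continue
        spacing = (b - a) / k
        if spacing < min_sep:
            raise ValueError(
                f"eligible duration too short: {k} events in {b - a:.0f} s "
                f"needs spacing >= {min_sep:.1f} s"
            )
        base = a + (np.arange(k) + 0.5) * spacing
        jitter = rng.uniform(-0.5, 0.5, k) * (spacing - min_sep)
        times.append(base + jitter)
    return np.sort(np.concatenate(times))


def _rejection_times(intervals, n: int, min_sep: float, margin: float,
                     avoid: np.ndarray, avoid_gap: float,
                     rng: np.random.Generator, max_tries: int = 400):
    """Uniform placement avoiding ``avoid`` times; returns (times, shortfall)."""
    usable = [(a + margin, b - margin) for a, b in intervals if b - a > 2 * margin]
    if not usable or n == 0:
        return np.array([]), n
    lengths = np.array([b - a for a, b in usable])
    cdf = np.cumsum(lengths) / lengths.sum()
    placed = []
    tries = 0
    while len(placed) < n and tries < max_tries * n:
        tries += 1
        u = rng.random()
        i = int(np.searchsorted(cdf, u))
        a, b = usable[i]
        t = rng.uniform(a, b)
        if avoid.size and np.min(np.abs(avoid - t)) < avoid_gap:
            continue
        if placed and np.min(np.abs(np.array(placed) - t)) < min_sep:
            continue
        placed.append(t)
    return np.sort(np.array(placed)), n - len(placed)


def generate_recording(config: SimConfig):
    """Simulate one night: returns ``(Recording, Hypnogram, GroundTruth)``.

    Deterministic given ``config.seed``; per-channel noise and plants are
    independent, the spindle carrier frequency is shared across channels
    (one subject, one oscillator).
    """
    fs = config.sampling_rate
    hyp = Hypnogram.from_plan(config.stage_plan)
    n = int(round(hyp.duration * fs))
    rng = np.random.default_rng(config.seed)

    so_runs = hyp.runs(config.so_stages)
    sp_runs = hyp.runs(config.spindle_stages)
    so_minutes = sum(b - a for a, b in so_runs) / 60.0
    sp_minutes = sum(b - a for a, b in sp_runs) / 60.0
    n_so = int(round(config.so_rate * so_minutes))
    n_sp = int(round(config.spindle_rate * sp_minutes))
    n_coupled = int(round(config.coupled_fraction * n_sp))
    if n_coupled > n_so:
        raise ValueError(
            f"{n_coupled} coupled spindles requested but only {n_so} slow "
            "oscillations planted; raise so_rate or lower coupled_fraction"
        )

    so_period = 1.0 / config.so_freq
    so_wave = so_waveform(config.so_freq, config.so_amplitude, fs)
    sp_wave = spindle_waveform(config.spindle_freq, config.spindle_amplitude,
                               config.spindle_duration, fs)
    sp_half = (len(sp_wave) - 1) // 2
    margin = max(3.0, so_period)
    phase_map = _phase_offset_map(config.so_freq, fs) if n_coupled else None

    signal = np.empty((len(config.channel_labels), n))
    so_rows, sp_rows = [], []
    log = {"uncoupled_shortfall": 0}
    for ci, ch in enumerate(config.channel_labels):
        x = fractal_noise(n, fs, config.fractal_slope, config.fractal_offset, rng)

        so_onsets = np.array([])
        troughs = np.array([])
        if n_so:
            # grid spacing guards against overlapping SO waveforms
            so_onsets = _grid_times(so_runs, n_so, max(2.5, 1.5 * so_period),
                                    margin, rng) - so_period / 4.0
            troughs = so_onsets + so_period / 4.0
            for t0 in so_onsets:
                i0 = int(round(t0 * fs))
                x[i0:i0 + len(so_wave)] += so_wave  # margins keep plants in range
            so_rows.extend({"channel": ch, "trough_time": t} for t in troughs)

        if n_sp:
            chosen = rng.choice(n_so, size=n_coupled, replace=False) if n_coupled else np.array([], int)
            phases = rng.vonmises(config.coupling_mu, config.coupling_kappa, n_coupled) \
                if n_coupled else np.array([])
            phases = np.where(phases <= -np.pi, np.pi, phases)
            peaks_c = (so_onsets[chosen.astype(int)]
                       + _phase_offset(phases, config.so_freq, phase_map)) \
                if n_coupled else np.array([])
            peaks_u, short = _rejection_times(
                sp_runs, n_sp - n_coupled, 2.0 * config.spindle_duration, margin,
                troughs, config.so_exclusion, rng)
            log["uncoupled_shortfall"] += short
            for t, ph, coup in (
                [(t, p, True) for t, p in zip(peaks_c, phases)]
                + [(t, np.nan, False) for t in peaks_u]
            ):
                ip = int(round(t * fs))
                if ip - sp_half < 0 or ip + sp_half + 1 > n:  # margins should prevent this
                    continue
                x[ip - sp_half: ip + sp_half + 1] += sp_wave
                sp_rows.append({"channel": ch, "peak_time": t,
                                "frequency": config.spindle_freq,
                                "coupled": coup, "phase": ph})
        signal[ci] = x

    truth = GroundTruth(
        so_events=pd.DataFrame(so_rows, columns=["channel", "trough_time"]),
        spindle_events=pd.DataFrame(
            sp_rows, columns=["channel", "peak_time", "frequency", "coupled", "phase"]),
        placement_log=log,
    )
    rec = Recording(signal, fs, config.channel_labels)
    return rec, hyp, truth


# ---------------------------------------------------------------------------
# behavioral cohort
# ---------------------------------------------------------------------------

#: per-night stage plan used for cohort subjects (scaled-down night:
#: one consolidated N3 bout instead of full sleep cycles)
COHORT_PLAN = (("W", 30.0), ("N3", 1200.0), ("N2", 120.0))


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Rank-based normal scores (van der Waerden)."""
    n = len(values)
    ranks = pd.Series(values).rank().to_numpy()
    return math.sqrt(2) * erfinv(2 * (ranks - 0.5) / n - 1)


def generate_cohort(n_subjects: int, kappa_range=(1.0, 8.0), target_rho: float = 0.6,
                    seed: int = 0, *, base_config: SimConfig | None = None,
                    blocks=None, gain_mean: float = 3.0, gain_sd: float = 4.0,
                    curve_coupling: float = -0.5, block_noise_sd: float = 1.0,
                    age_effect: bool = True):
    """Simulate a cohort: per-subject recordings configs + behavior table.

    Per-subject kappa is uniform on ``kappa_range``; the latent overnight
    change in task proficiency is tied to kappa through a Gaussian copula
    whose Pearson parameter ``2*sin(pi*target_rho/6)`` yields the requested
    Spearman correlation in the large-sample limit.  The overnight change
    in the learning curve is ``curve_coupling`` times the (centered)
    proficiency change plus noise with half its spread, emulating the
    strong inverse proficiency/learning-curve relation of dynamic motor
    learning.  Returns ``(configs, behavior_table, truth)`` where configs
    is a list of per-subject :class:`SimConfig` (the learning night; use
    :func:`dataclasses.replace` with a fresh seed for additional nights).
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    if abs(target_rho) > 1:
        raise ValueError("|target_rho| must be <= 1")
    rng = np.random.default_rng(seed)
    if base_config is None:
        base_config = SimConfig(
            stage_plan=COHORT_PLAN, so_rate=3.0, spindle_rate=12.0,
            coupled_fraction=0.25, coupling_kappa=np.nan,  # filled per subject
        )

    kappa = rng.uniform(kappa_range[0], kappa_range[1], n_subjects)
    rho_pearson = 2 * np.sin(np.pi * target_rho / 6.0)
    z_k = _normal_scores(kappa)
    noise = rng.standard_normal(n_subjects)
    gain = gain_mean + gain_sd * (rho_pearson * z_k
                                  + np.sqrt(1 - rho_pearson**2) * noise)

    # age split: adults tend to have higher coupling concentration
    if age_effect:
        score = _normal_scores(kappa) + rng.standard_normal(n_subjects)
        adult = score >= np.median(score)
    else:
        adult = rng.random(n_subjects) < 0.5

    d_gain = gain - gain.mean()
    dm = curve_coupling * d_gain + 0.5 * np.abs(curve_coupling) * gain_sd \
        * rng.standard_normal(n_subjects)

    spindle_freqs = rng.uniform(11.0, 16.0, n_subjects)
    configs, latents, rows = [], [], []
    for i in range(n_subjects):
        cfg = replace(
            base_config,
            spindle_freq=float(round(spindle_freqs[i], 2)),
            coupling_kappa=float(kappa[i]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        configs.append(cfg)
        nb = (blocks if blocks is not None
              else (5 if adult[i] else 3))
        y1 = (8.0 if adult[i] else 5.0) + 3.0 * rng.standard_normal()
        y1 = max(y1, 1.0)
        m = max(1.5 + 0.6 * rng.standard_normal(), 0.1)
        y1_t = {1: y1, 2: y1 + gain[i], 3: y1 + gain[i] + 1.0 + rng.standard_normal()}
        m_t = {1: m, 2: m + dm[i], 3: m + dm[i] + 0.3 * rng.standard_normal()}
        for test in (1, 2, 3):
            c = y1_t[test] - m_t[test]
            for b in range(1, nb + 1):
                latent = c + m_t[test] * b
                score = latent + block_noise_sd * rng.standard_normal()
                rows.append({
                    "subject": f"s{i:02d}",
                    "group": "sleep_first",
                    "age_group": "adult" if adult[i] else "adolescent",
                    "test": test, "block": b,
                    "cascades": int(max(0, round(score))),
                })
        latents.append({"subject": f"s{i:02d}", "kappa": kappa[i],
                        "gain": gain[i], "curve_change": dm[i],
                        "y1_pre": y1, "m_pre": m,
                        "age_group": "adult" if adult[i] else "adolescent"})

    behavior = pd.DataFrame(rows)
    truth = GroundTruth(
        so_events=pd.DataFrame(columns=["channel", "trough_time"]),
        spindle_events=pd.DataFrame(
            columns=["channel", "peak_time", "frequency", "coupled", "phase"]),
        subject_kappa={f"s{i:02d}": float(kappa[i]) for i in range(n_subjects)},
        behavior_latents=pd.DataFrame(latents),
    )
    return configs, behavior, truth
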