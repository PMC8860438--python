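"""Core containers: multichannel recordings, 30-s epoch hypnograms, file IO.

All times are seconds from recording start, sample indices are 0-based and
intervals are half-open ``[onset, offset)``.  Signals are stored channels x
samples in microvolts.  Recordings are exchanged on disk as raw float32
binary plus a JSON side-car header (lossless for our purposes, and free of
the amplitude quantization an EDF round-trip would introduce).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Vigilance-state labels used throughout (AASM-style).
STAGES = ("W", "N1", "N2", "N3", "REM")

#: The 11-electrode scalp montage of the study design.
MONTAGE_11 = ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "O2")


class PipelineError(RuntimeError):
    """Raised when an analysis stage cannot proceed; names the stage."""


@dataclass
class Recording:
    """Multichannel EEG signal with sampling rate and channel labels."""

    signal: np.ndarray
    sampling_rate: float
    channel_labels: tuple

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows vs "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy(self) -> "Recording":
        return Recording(self.signal.copy(), self.sampling_rate, self.channel_labels)


@dataclass
class Hypnogram:
    """Sleep stages scored in fixed-length (30 s) epochs."""

    stages: tuple
    epoch_length: float = 30.0

    def __post_init__(self):
        self.stages = tuple(self.stages)
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")

    @classmethod
    def from_plan(cls, plan, epoch_length: float = 30.0) -> "Hypnogram":
        """Build from a sequence of ``(stage, duration_s)`` pairs.

        Durations are rounded up to whole epochs.
        """
        stages = []
        for stage, dur in plan:
            n = int(np.ceil(dur / epoch_length - 1e-9))
            stages.extend([stage] * max(n, 0))
        return cls(tuple(stages), epoch_length)

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_length

    def stage_at(self, time_s: float) -> str:
        idx = int(time_s // self.epoch_length)
        if not 0 <= idx < self.n_epochs:
            raise ValueError(f"time {time_s} s outside scored range")
        return self.stages[idx]

    def runs(self, stages) -> list:
        """Half-open ``(onset_s, offset_s)`` intervals of contiguous epochs
        whose label is in ``stages`` (consecutive matching epochs merged)."""
        want = set(stages)
        out = []
        start = None
        for i, s in enumerate(self.stages):
            if s in want and start is None:
                start = i
            elif s not in want and start is not None:
                out.append((start * self.epoch_length, i * self.epoch_length))
                start = None
        if start is not None:
            out.append((start * self.epoch_length, self.n_epochs * self.epoch_length))
        return out

    def sample_mask(self, stages, sampling_rate: float, n_samples: int) -> np.ndarray:
        """Boolean mask over samples belonging to the requested stages."""
        mask = np.zeros(n_samples, dtype=bool)
        for a, b in self.runs(stages):
            i0 = int(round(a * sampling_rate))
            i1 = min(int(round(b * sampling_rate)), n_samples)
            mask[i0:i1] = True
        return mask

    def minutes(self, stages) -> float:
        return sum(b - a for a, b in self.runs(stages)) / 60.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(self.n_epochs),
                "onset_s": np.arange(self.n_epochs) * self.epoch_length,
                "stage": list(self.stages),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, epoch_length: float = 30.0) -> "Hypnogram":
        df = pd.read_csv(path)
        if len(df) > 1:
            epoch_length = float(df["onset_s"].iloc[1] - df["onset_s"].iloc[0])
        return cls(tuple(df["stage"]), epoch_length)


def write_recording(recording: Recording, stem) -> None:
    """Write ``<stem>.dat`` (float32, channel-major) + ``<stem>.json`` header."""
    stem = Path(stem)
    recording.signal.astype(np.float32).tofile(stem.with_suffix(".dat"))
    header = {
        "sampling_rate": recording.sampling_rate,
        "channel_labels": list(recording.channel_labels),
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "dtype": "float32",
        "unit": "uV",
        "order": "channel_major",
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=2))


def read_recording(stem) -> Recording:
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".dat"), dtype=np.float32)
    sig = data.reshape(header["n_channels"], header["n_samples"]).astype(float)
    return Recording(sig, header["sampling_rate"], tuple(header["channel_labels"]))
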