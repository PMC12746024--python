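"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import ElectrodeMontage

__all__ = ["ContinuousRecording", "EventSequence", "EpochSet"]

STANDARD = "standard"
DEVIANT = "deviant"


@dataclass
class ContinuousRecording:
    """Continuous multi-channel EEG in microvolts.

    ``data`` is channels x samples; row order matches ``montage.channel_names``.
    ``metadata`` carries subject / session (T1, T2, T3) / language
    (native, nonnative) identifiers.
    """

    data: np.ndarray
    sampling_rate: float
    montage: ElectrodeMontage
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EventSequence:
    """Stimulus events: 0-based sample onsets plus standard/deviant labels."""

    onsets: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.onsets.shape != self.labels.shape or self.onsets.ndim != 1:
            raise ValueError("onsets and labels must be equal-length 1-D arrays")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        bad = set(self.labels) - {STANDARD, DEVIANT}
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")
        dev = self.labels == DEVIANT
        if np.any(dev[:-1] & dev[1:]):
            raise ValueError("deviant events must never appear in succession")

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass
class EpochSet:
    """Epoched EEG: trials x channels x time, with a rejection mask.

    ``window_ms`` is the closed epoch window in milliseconds relative to
    stimulus onset, e.g. (-200, 799) giving 1000 samples at 1000 Hz.
    ``rejection_mask`` is True for rejected trials; ``rejection_reason``
    holds a code from {voltage, step, kurtosis, manual} for rejected trials
    and the empty string otherwise.
    """

    data: np.ndarray
    window_ms: tuple[float, float]
    sampling_rate: float
    trial_labels: np.ndarray
    trial_onsets: np.ndarray
    channel_names: tuple[str, ...]
    rejection_mask: np.ndarray = None
    rejection_reason: np.ndarray = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x time)")
        n_trials, n_ch, n_t = self.data.shape
        self.channel_names = tuple(self.channel_names)
        if n_ch != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        expected = int(round((self.window_ms[1] - self.window_ms[0] + 1)
                             * self.sampling_rate / 1000.0))
        if n_t != expected:
            raise ValueError(
                f"time axis has {n_t} samples; window {self.window_ms} at "
                f"{self.sampling_rate} Hz implies {expected}"
            )
        self.trial_labels = np.asarray(self.trial_labels, dtype=object)
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=int)
        if self.rejection_mask is None:
            self.rejection_mask = np.zeros(n_trials, dtype=bool)
        self.rejection_mask = np.asarray(self.rejection_mask, dtype=bool)
        if self.rejection_reason is None:
            self.rejection_reason = np.array([""] * n_trials, dtype=object)
        self.rejection_reason = np.asarray(self.rejection_reason, dtype=object)
        for arr, name in ((self.trial_labels, "trial_labels"),
                          (self.trial_onsets, "trial_onsets"),
                          (self.rejection_mask, "rejection_mask"),
                          (self.rejection_reason, "rejection_reason")):
            if arr.shape != (n_trials,):
                raise ValueError(f"{name} must have one entry per trial")
        if np.any((self.rejection_reason != "") & ~self.rejection_mask):
            raise ValueError("rejection reasons may only be set on rejected trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms (closed window, first sample at window start)."""
        n_t = self.data.shape[2]
        return self.window_ms[0] + np.arange(n_t) * 1000.0 / self.sampling_rate

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.rejection_mask)

    def retained_by_label(self, label: str) -> np.ndarray:
        return np.flatnonzero((~self.rejection_mask) & (self.trial_labels == label))

    def copy_with(self, **kwargs) -> "EpochSet":
        fields = dict(
            data=self.data, window_ms=self.window_ms,
            sampling_rate=self.sampling_rate, trial_labels=self.trial_labels,
            trial_onsets=self.trial_onsets, channel_names=self.channel_names,
            rejection_mask=self.rejection_mask,
            rejection_reason=self.rejection_reason,
        )
        fields.update(kwargs)
        return EpochSet(**fields)
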