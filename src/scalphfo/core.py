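"""Core containers shared across the pipeline.

Times are seconds from recording start; intervals are half-open
``[onset, offset)``.  Signals are microvolts, shaped (n_channels, n_samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 19 analysis channels of the international 10-20 system used for
#: scalp HFO review (the full clinical montage has more electrodes; these
#: are the ones entering the average reference).
TEN_TWENTY_CHANNELS = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
]

ICTAL_ACTIVE = "ictal_active"
INTERICTAL_ACTIVE = "interictal_active"
INTERICTAL_SEIZURE_FREE = "interictal_seizure_free"
UNASSIGNED = "unassigned"
EPOCH_LABELS = (ICTAL_ACTIVE, INTERICTAL_ACTIVE, INTERICTAL_SEIZURE_FREE)

SPIKE_RIPPLE = "spike_ripple"
RIPPLE = "ripple"


class AnnotationError(ValueError):
    """Inconsistent epoch/spike annotations (overlap, unknown labels...)."""


class MontageError(ValueError):
    """Montage operation impossible (e.g. single channel)."""


class DataError(ValueError):
    """Malformed signal data (NaN, empty, length mismatch)."""


@dataclass
class EegRecording:
    """Multichannel scalp EEG.

    Parameters
    ----------
    data
        Array (n_channels, n_samples), microvolts.
    sfreq
        Sampling rate in Hz.
    channels
        Electrode labels, 10-20 names.
    montage
        ``"referential"`` or ``"average"``.
    """

    data: np.ndarray
    sfreq: float
    channels: list[str] = field(default_factory=list)
    montage: str = "referential"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise DataError(
                f"{len(self.channels)} labels for {self.data.shape[0]} channels"
            )
        if self.sfreq <= 0:
            raise DataError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise DataError(f"unknown channel {label!r}") from None

    def copy(self) -> "EegRecording":
        return replace(self, data=self.data.copy(), channels=list(self.channels))


@dataclass(frozen=True)
class EpochInterval:
    """Labelled analysis interval (seizure state x epoch type)."""

    onset: float
    offset: float
    label: str

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise AnnotationError("epoch offset must exceed onset")
        if self.label not in EPOCH_LABELS:
            raise AnnotationError(f"unknown epoch label {self.label!r}")

    def contains(self, t: float) -> bool:
        return self.onset <= t < self.offset


@dataclass(frozen=True)
class SpikeAnnotation:
    """Peak time of an interictal epileptiform discharge (IED, 'spike')."""

    channel: str
    time: float


@dataclass
class HfoEvent:
    """A detected oscillatory event in the ripple band."""

    channel: str
    onset: float
    offset: float
    kind: str | None = None          # spike_ripple / ripple, set by classifier
    epoch: str = UNASSIGNED
    peak_envelope: float = float("nan")
    est_frequency: float = float("nan")   # Hz, crest-interval estimate
    est_cycles: float = float("nan")

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise DataError("event offset must exceed onset")

    @property
    def duration(self) -> float:
        """Seconds."""
        return self.offset - self.onset

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.onset + self.offset)


def check_epochs_disjoint(epochs: list[EpochInterval]) -> None:
    """Raise :class:`AnnotationError` if any two epoch intervals overlap."""
    ordered = sorted(epochs, key=lambda e: e.onset)
    for a, b in zip(ordered, ordered[1:]):
        if b.onset < a.offset:
            raise AnnotationError(
                f"overlapping epochs: [{a.onset}, {a.offset}) and "
                f"[{b.onset}, {b.offset})"
            )
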