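"""Two-stage Hilbert detector for ripple-band scalp HFOs.

Stage one band-pass filters the average-montage EEG to 80-250 Hz with a
zero-phase FIR and computes the analytic-signal envelope.  Stage two
thresholds the envelope (mean + k x SD over the whole recording, per
channel), turns contiguous supra-threshold runs into candidate events,
and discards candidates with fewer than four estimated cycles or an
estimated frequency outside the band.  Events co-occurring across
channels are deduplicated; events are then classified as spike ripples
(superimposed on an IED) or plain ripples, and assigned to their epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .core import (
    DataError,
    EegRecording,
    EpochInterval,
    HfoEvent,
    MontageError,
    RIPPLE,
    SPIKE_RIPPLE,
    SpikeAnnotation,
    UNASSIGNED,
    check_epochs_disjoint,
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables of the Hilbert detector.

    ``threshold_mode="mean_plus_sd"`` sets the per-channel threshold at
    mean(envelope) + multiplier x SD(envelope); ``"sd_only"`` uses
    multiplier x SD alone.
    """

    band: tuple[float, float] = (80.0, 250.0)
    threshold_multiplier: float = 2.0
    threshold_mode: str = "mean_plus_sd"
    min_cycles: float = 4.0
    merge_gap_ms: float = 3.0
    spike_window_ms: float = 75.0
    dedup_overlap: float = 0.5
    amplitude_ceiling: float = 1000.0   # uV peak-to-peak artifact gate

    def __post_init__(self) -> None:
        if not self.band[0] < self.band[1]:
            raise ConfigError("band low edge must be below high edge")
        if self.threshold_multiplier <= 0:
            raise ConfigError("threshold_multiplier must be positive")
        if self.min_cycles < 1:
            raise ConfigError("min_cycles must be >= 1")
        if self.threshold_mode not in ("mean_plus_sd", "sd_only"):
            raise ConfigError(f"unknown threshold_mode {self.threshold_mode!r}")


def apply_average_montage(recording: EegRecording) -> EegRecording:
    """Re-reference every channel to the instantaneous cross-channel mean."""
    if recording.n_channels < 2:
        raise MontageError("average montage needs at least two channels")
    out = recording.copy()
    out.data -= out.data.mean(axis=0, keepdims=True)
    out.montage = "average"
    return out


def design_ripple_fir(
    fs: float, band: tuple[float, float], transition_hz: float = 10.0
) -> np.ndarray:
    """Linear-phase Kaiser-window FIR: <1 dB pass-band ripple, >=40 dB
    stop-band at the band edges +/- ``transition_hz``."""
    lo, hi = band
    nyq = fs / 2.0
    if hi >= nyq:
        raise ConfigError(f"band edge {hi} Hz at or above Nyquist ({nyq} Hz)")
    if lo <= 0:
        raise ConfigError("band low edge must be positive")
    numtaps, beta = signal.kaiserord(40.0, transition_hz / nyq)
    numtaps |= 1  # odd length -> exactly linear phase, integer group delay
    return signal.firwin(
        numtaps,
        [lo - transition_hz / 2, hi + transition_hz / 2],
        window=("kaiser", beta),
        pass_zero=False,
        fs=fs,
    )


def bandpass_ripple(
    recording: EegRecording, band: tuple[float, float] = (80.0, 250.0)
) -> EegRecording:
    """Zero-phase ripple-band filtering (forward-backward FIR)."""
    taps = design_ripple_fir(recording.sfreq, band)
    out = recording.copy()
    out.data = signal.filtfilt(taps, [1.0], recording.data, axis=1)
    return out


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude |analytic signal| along the last axis."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DataError("empty signal")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite values in signal")
    return np.abs(signal.hilbert(x, axis=-1))


def envelope_threshold(envelope: np.ndarray, config: DetectorConfig) -> np.ndarray:
    """Per-channel detection threshold over the entire recording."""
    env = np.atleast_2d(envelope)
    sd = env.std(axis=1)
    if config.threshold_mode == "mean_plus_sd":
        return env.mean(axis=1) + config.threshold_multiplier * sd
    return config.threshold_multiplier * sd


def _supra_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _crest_frequency(seg: np.ndarray, fs: float) -> tuple[float, int]:
    """Crest-interval frequency estimate and crest count for one segment.

    The frequency is the reciprocal mean crest-to-crest interval (a median
    would be quantized to whole samples, which near the 250 Hz band edge
    at 1024 Hz flips in-band events out of band).  The features stage
    recomputes the definitive estimate on the final event window.
    """
    floor = 0.1 * np.max(np.abs(seg)) if seg.size else 0.0
    crests, _ = signal.find_peaks(seg, prominence=floor)
    if crests.size < 2:
        return float("nan"), int(crests.size)
    return fs / float(np.mean(np.diff(crests))), int(crests.size)


def _half_peak_core(env_seg: np.ndarray, smooth: int = 7) -> tuple[int, int]:
    """Contiguous index window around the envelope maximum where the
    (lightly smoothed) envelope stays above half its peak.

    The ~7-sample moving average damps the fast Rayleigh dips that noise
    superimposes on a burst's envelope, so the core reflects the event's
    overall energy profile rather than single-sample excursions."""
    if env_seg.size > smooth > 1:
        kernel = np.ones(smooth) / smooth
        sm = np.convolve(env_seg, kernel, mode="same")
    else:
        sm = env_seg
    peak = int(np.argmax(sm))
    half = 0.5 * sm[peak]
    s = peak
    while s > 0 and sm[s - 1] >= half:
        s -= 1
    e = peak + 1
    while e < sm.size and sm[e] >= half:
        e += 1
    return s, e


def _core_cycles(seg: np.ndarray, cs: int, ce: int, fs: float) -> float:
    """Cycles spanned by the half-peak core at the core's own crest rate."""
    floor = 0.1 * np.max(np.abs(seg)) if seg.size else 0.0
    crests, _ = signal.find_peaks(seg, prominence=floor)
    core_crests = crests[(crests >= cs) & (crests < ce)]
    if core_crests.size < 2:
        return 0.0
    rate = fs / float(np.mean(np.diff(core_crests)))
    return (ce - cs) / fs * rate


def detect_events(
    filtered: EegRecording,
    config: DetectorConfig = DetectorConfig(),
    envelope: np.ndarray | None = None,
) -> list[HfoEvent]:
    """Threshold the envelope and emit validated candidate events.

    ``filtered`` must be the average-montage, band-passed recording.
    Precomputed envelopes may be passed to avoid repeating the transform.
    """
    if filtered.montage != "average":
        raise DataError("detector requires an average-montage recording")
    if filtered.n_samples == 0:
        raise DataError("empty recording")
    fs = filtered.sfreq
    env = hilbert_envelope(filtered.data) if envelope is None else envelope
    thresholds = envelope_threshold(env, config)
    gap = max(1, int(round(config.merge_gap_ms / 1000.0 * fs)))
    events: list[HfoEvent] = []
    for ci, label in enumerate(filtered.channels):
        runs = _merge_runs(_supra_runs(env[ci] > thresholds[ci]), gap)
        for s, e in runs:
            seg = filtered.data[ci, s:e]
            freq, n_crests = _crest_frequency(seg, fs)
            if not np.isfinite(freq):
                continue
            # Validity gate: the supra-threshold run can outlast the
            # oscillation proper (taper fringe, zero-phase filter smear,
            # background continuing the rhythm at threshold level), so a
            # run-duration cycle count overstates the event's cycles.
            # Count instead over the envelope's half-peak core, at the
            # crest rate measured within that core.
            cs, ce = _half_peak_core(env[ci, s:e])
            cycles = _core_cycles(seg, cs, ce, fs)
            if cycles < config.min_cycles:
                continue
            if not config.band[0] <= freq <= config.band[1]:
                continue
            if np.ptp(seg) > config.amplitude_ceiling:
                continue
            events.append(
                HfoEvent(
                    channel=label,
                    onset=s / fs,
                    offset=e / fs,
                    peak_envelope=float(env[ci, s:e].max()),
                    est_frequency=freq,
                    est_cycles=cycles,
                )
            )
    return _deduplicate(events, config.dedup_overlap)


def _deduplicate(events: list[HfoEvent], min_overlap: float) -> list[HfoEvent]:
    """Merge cross-channel co-occurrences: events overlapping by at least
    ``min_overlap`` of the shorter interval collapse onto the event with
    the largest peak envelope."""
    order = sorted(events, key=lambda ev: (-ev.peak_envelope, ev.onset, ev.channel))
    kept: list[HfoEvent] = []
    for ev in order:
        duplicate = False
        for k in kept:
            ov = min(ev.offset, k.offset) - max(ev.onset, k.onset)
            shorter = min(ev.duration, k.duration)
            if shorter > 0 and ov / shorter >= min_overlap:
                duplicate = True
                break
        if not duplicate:
            kept.append(ev)
    kept.sort(key=lambda ev: (ev.onset, ev.channel))
    return kept


def classify_spike_ripple(
    events: list[HfoEvent],
    spikes: list[SpikeAnnotation],
    spike_window_ms: float = 75.0,
) -> list[HfoEvent]:
    """Label each event spike_ripple iff its interval intersects any spike's
    +/- window (on any channel); otherwise ripple."""
    w = spike_window_ms / 1000.0
    out = []
    for ev in events:
        hit = any(ev.onset < s.time + w and ev.offset > s.time - w for s in spikes)
        out.append(replace(ev, kind=SPIKE_RIPPLE if hit else RIPPLE))
    return out


def assign_epochs(
    events: list[HfoEvent], epochs: list[EpochInterval]
) -> list[HfoEvent]:
    """Attach the label of the epoch interval containing each event midpoint."""
    check_epochs_disjoint(epochs)
    out = []
    for ev in events:
        label = UNASSIGNED
        for ep in epochs:
            if ep.contains(ev.midpoint):
                label = ep.label
                break
        out.append(replace(ev, epoch=label))
    return out


def run_detector(
    recording: EegRecording,
    spikes: list[SpikeAnnotation],
    epochs: list[EpochInterval],
    config: DetectorConfig = DetectorConfig(),
) -> tuple[list[HfoEvent], EegRecording]:
    """Full detection stage: montage -> band-pass -> detect -> classify -> epochs.

    Returns the labelled events and the filtered average-montage recording
    (reused by the feature extractor).
    """
    avg = apply_average_montage(recording)
    filt = bandpass_ripple(avg, config.band)
    events = detect_events(filt, config)
    events = classify_spike_ripple(events, spikes, config.spike_window_ms)
    events = assign_epochs(events, epochs)
    return events, filt


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa for two raters: (p_o - p_e) / (1 - p_e)."""
    from sklearn.metrics import cohen_kappa_score

    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.size == 0:
        raise DataError("rating vectors must be non-empty and equal length")
    return float(cohen_kappa_score(a, b))
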