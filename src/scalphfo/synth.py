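"""Synthetic scalp-EEG scenes and synthetic HFO feature tables.

Two generators live here:

* a *scene* generator that builds annotated multichannel EEG — pink-noise
  background, 3-Hz spike-and-wave trains inside ictal intervals, biphasic
  IED spikes, and Tukey-tapered ripple-band bursts (80-250 Hz) with exact
  ground truth — so the detector and feature extractor can be validated
  against known events;
* a *feature-space* generator that draws (frequency, duration, amplitude,
  cycles) rows from a 3-component mixture whose component parameters mirror
  the published cluster centroids of scalp HFOs in pediatric absence
  epilepsy, so the clustering and statistics stages can be validated at
  realistic sample sizes (n = 163).

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import (
    EPOCH_LABELS,
    ICTAL_ACTIVE,
    EegRecording,
    EpochInterval,
    SpikeAnnotation,
    TEN_TWENTY_CHANNELS,
    check_epochs_disjoint,
)

MIN_CYCLES = 4.0           # validity rule: >= 4 cycles within 80-250 Hz
RIPPLE_BAND = (80.0, 250.0)
MIN_ICTAL_SECONDS = 3.0    # minimum absence-seizure duration for inclusion

# Normal quantile at 0.75; links a log-normal's IQR to its log-scale sigma.
_Z75 = 0.6744897501960817


class SynthSpecError(ValueError):
    """Invalid scene/burst/mixture specification."""


@dataclass(frozen=True)
class SynthBurstSpec:
    """A planted ripple-band burst: Tukey-tapered sinusoid.

    ``amplitude`` is the peak of the sinusoid in microvolts (peak-to-peak is
    twice that).  ``taper_fraction`` is the Tukey window's alpha: fraction
    of the duration spent in the cosine ramps.
    """

    channel: str
    onset: float                 # seconds from recording start
    center_frequency: float      # Hz
    duration_ms: float
    amplitude: float             # microvolts, sinusoid peak
    taper_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.duration_ms <= 0 or self.amplitude <= 0:
            raise SynthSpecError("burst duration and amplitude must be positive")
        if not 0 < self.taper_fraction <= 1:
            raise SynthSpecError("taper_fraction must be in (0, 1]")
        if self.center_frequency <= 0:
            raise SynthSpecError("center_frequency must be positive")

    @property
    def n_cycles(self) -> float:
        """Ground-truth cycle count = f x duration."""
        return self.center_frequency * self.duration_ms / 1000.0

    @property
    def detectable(self) -> bool:
        """True when the burst satisfies the >=4-cycle, in-band rule."""
        return (
            self.n_cycles >= MIN_CYCLES
            and RIPPLE_BAND[0] <= self.center_frequency <= RIPPLE_BAND[1]
        )

    @property
    def offset(self) -> float:
        return self.onset + self.duration_ms / 1000.0


@dataclass
class SceneSpec:
    """Plan for one synthetic recording."""

    duration: float                         # seconds
    n_channels: int = 19
    sampling_rate: float = 1024.0
    epochs: list[EpochInterval] = field(default_factory=list)
    spikes: list[SpikeAnnotation] = field(default_factory=list)
    bursts: list[SynthBurstSpec] = field(default_factory=list)
    noise_exponent: float = 1.0             # 1/f^a spectral slope
    noise_rms: float = 10.0                 # per-channel microvolts RMS
    swd_frequency: float = 3.0              # Hz, applied in ictal intervals
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise SynthSpecError("scene duration must be positive")
        if self.sampling_rate < 512:
            raise SynthSpecError("sampling rate below 512 Hz cannot carry ripples")
        if self.n_channels < 1:
            raise SynthSpecError("need at least one channel")
        check_epochs_disjoint(self.epochs)
        for ep in self.epochs:
            if ep.label == ICTAL_ACTIVE and ep.offset - ep.onset < MIN_ICTAL_SECONDS:
                raise SynthSpecError(
                    f"ictal interval shorter than {MIN_ICTAL_SECONDS} s"
                )
        for b in self.bursts:
            if b.onset < 0 or b.offset > self.duration:
                raise SynthSpecError(f"burst at {b.onset}s outside recording")

    @property
    def channel_names(self) -> list[str]:
        if self.n_channels <= len(TEN_TWENTY_CHANNELS):
            return TEN_TWENTY_CHANNELS[: self.n_channels]
        return TEN_TWENTY_CHANNELS + [
            f"X{i}" for i in range(self.n_channels - len(TEN_TWENTY_CHANNELS))
        ]


def generate_background(scene: SceneSpec) -> EegRecording:
    """Gaussian 1/f^a background, zero mean, ``noise_rms`` microvolts RMS.

    Shaped in the frequency domain: white Gaussian spectrum scaled by
    f^(-a/2), DC removed, then normalized per channel.
    """
    rng = np.random.default_rng(scene.seed)
    n = int(round(scene.duration * scene.sampling_rate))
    if n < 2:
        raise SynthSpecError("scene too short")
    freqs = np.fft.rfftfreq(n, d=1.0 / scene.sampling_rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-scene.noise_exponent / 2.0)
    data = np.empty((scene.n_channels, n))
    for c in range(scene.n_channels):
        spec = (
            rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
        ) * shape
        x = np.fft.irfft(spec, n=n)
        x -= x.mean()
        rms = np.sqrt(np.mean(x**2))
        data[c] = x * (scene.noise_rms / rms) if rms > 0 else x
    return EegRecording(data, scene.sampling_rate, scene.channel_names)


def inject_burst(
    recording: EegRecording, spec: SynthBurstSpec
) -> tuple[EegRecording, dict]:
    """Add a Tukey-windowed sinusoid; return (new recording, truth record).

    The truth record carries the planned channel, interval, frequency,
    amplitude and exact cycle count, plus a ``detectable`` flag for bursts
    violating the >=4-cycle / in-band rule.
    """
    fs = recording.sfreq
    i0 = int(round(spec.onset * fs))
    n = int(round(spec.duration_ms / 1000.0 * fs))
    if i0 < 0 or i0 + n > recording.n_samples:
        raise SynthSpecError("burst outside recording bounds")
    ci = recording.channel_index(spec.channel)
    t = np.arange(n) / fs
    wave = spec.amplitude * np.sin(2 * np.pi * spec.center_frequency * t)
    wave *= signal.windows.tukey(n, alpha=spec.taper_fraction)
    out = recording.copy()
    out.data[ci, i0 : i0 + n] += wave
    truth = {
        "channel": spec.channel,
        "onset": spec.onset,
        "offset": spec.offset,
        "center_frequency": spec.center_frequency,
        "duration_ms": spec.duration_ms,
        "amplitude": spec.amplitude,
        "n_cycles": spec.n_cycles,
        "detectable": spec.detectable,
    }
    return out, truth


def spike_template(fs: float, width_ms: float = 70.0) -> np.ndarray:
    """Biphasic IED template: sharp negative phase then slower positive phase.

    The canonical 70 ms template splits 30 ms / 40 ms; other widths scale
    both phases proportionally.  Peak magnitude is 1 (scale by amplitude).
    """
    if not 20.0 <= width_ms <= 70.0 * 2:
        raise SynthSpecError("spike width outside plausible IED range")
    n_sharp = max(2, int(round(width_ms * 30.0 / 70.0 / 1000.0 * fs)))
    n_slow = max(2, int(round(width_ms * 40.0 / 70.0 / 1000.0 * fs)))
    sharp = -np.sin(np.pi * np.arange(n_sharp) / n_sharp)
    slow = 0.5 * np.sin(np.pi * np.arange(n_slow) / n_slow)
    return np.concatenate([sharp, slow])


def inject_spike(
    recording: EegRecording,
    channel: str,
    time: float,
    amplitude: float,
    width_ms: float = 70.0,
) -> EegRecording:
    """Add a biphasic spike transient centered at ``time`` on one channel."""
    fs = recording.sfreq
    tmpl = amplitude * spike_template(fs, width_ms)
    center = int(round(time * fs))
    i0 = center - tmpl.size // 2
    if i0 < 0 or i0 + tmpl.size > recording.n_samples:
        raise SynthSpecError("spike outside recording bounds")
    out = recording.copy()
    out.data[recording.channel_index(channel), i0 : i0 + tmpl.size] += tmpl
    return out


def inject_swd_train(
    recording: EegRecording,
    interval: tuple[float, float],
    swd_frequency: float = 3.0,
    amplitude: float = 100.0,
) -> tuple[EegRecording, int]:
    """Add a generalized spike-and-wave train on all channels.

    One complex per period: a biphasic spike followed by a slow half-sine
    wave filling the remainder of the period.  Returns the recording and
    the number of complete complexes injected.
    """
    lo, hi = interval
    if hi - lo < MIN_ICTAL_SECONDS:
        raise SynthSpecError(
            f"spike-wave interval must span at least {MIN_ICTAL_SECONDS} s"
        )
    if not 2.5 <= swd_frequency <= 5.5:
        raise SynthSpecError("spike-wave frequency outside 2.5-5.5 Hz")
    fs = recording.sfreq
    period = int(round(fs / swd_frequency))
    spk = spike_template(fs, 70.0)
    n_wave = period - spk.size
    complex_ = np.concatenate(
        [spk, 0.6 * np.sin(np.pi * np.arange(max(n_wave, 0)) / max(n_wave, 1))]
    )[:period]
    n_complexes = int(np.floor((hi - lo) * swd_frequency))
    train = np.tile(complex_, n_complexes) * amplitude
    i0 = int(round(lo * fs))
    if i0 < 0 or i0 + train.size > recording.n_samples:
        raise SynthSpecError("spike-wave train outside recording bounds")
    out = recording.copy()
    out.data[:, i0 : i0 + train.size] += train[None, :]
    return out, n_complexes


def realize_scene(scene: SceneSpec) -> tuple[EegRecording, pd.DataFrame]:
    """Build the full scene: background + SWD in ictal epochs + spikes + bursts.

    Returns the (referential-montage) recording and the ground-truth burst
    table (one row per planted burst, schema as in :func:`inject_burst`).
    """
    rec = generate_background(scene)
    for ep in scene.epochs:
        if ep.label == ICTAL_ACTIVE:
            rec, _ = inject_swd_train(
                rec, (ep.onset, ep.offset), scene.swd_frequency
            )
    for spk in scene.spikes:
        rec = inject_spike(rec, spk.channel, spk.time, amplitude=50.0)
    truths = []
    for b in scene.bursts:
        rec, truth = inject_burst(rec, b)
        truths.append(truth)
    truth_df = pd.DataFrame(
        truths,
        columns=[
            "channel", "onset", "offset", "center_frequency",
            "duration_ms", "amplitude", "n_cycles", "detectable",
        ],
    )
    return rec, truth_df


def band_noise_rms(scene: SceneSpec) -> np.ndarray:
    """Per-channel RMS of the average-montage, ripple-band background.

    Used to express burst amplitudes as a signal-to-noise ratio against
    the in-band background the detector actually sees.
    """
    from .detect import apply_average_montage, bandpass_ripple

    bg = generate_background(scene)
    filt = bandpass_ripple(apply_average_montage(bg))
    return filt.data.std(axis=1)


def make_detection_scene(
    seed: int,
    duration: float = 60.0,
    n_bursts: int = 10,
    snr_range: tuple[float, float] = (5.0, 10.0),
    n_subthreshold: int = 3,
    spike_fraction: float = 0.6,
    n_channels: int = 19,
) -> tuple[EegRecording, pd.DataFrame, list[SpikeAnnotation], SceneSpec]:
    """A standard validation scene for the detector.

    Plants ``n_bursts`` detectable bursts (frequency 90-240 Hz, planned
    cycle count >= 5, SNR drawn from ``snr_range`` against the in-band
    background) at well-separated onsets, a fraction of them co-onset
    with an IED spike, plus ``n_subthreshold`` three-cycle bursts
    (80 Hz, 37.5 ms, high amplitude) that a valid detector must reject.
    SNR is the sinusoid peak over the average-montage ripple-band
    background RMS (montage attenuation of (1 - 1/n_channels) is
    compensated at injection).

    Returns (recording, ground-truth burst table, spike annotations,
    scene spec).  The truth table's ``detectable`` column marks the
    plantings that satisfy the >=4-cycle rule.
    """
    rng = np.random.default_rng(seed)
    scene = SceneSpec(duration=duration, n_channels=n_channels, seed=seed)
    sigma = band_noise_rms(scene)
    rec = generate_background(scene)
    names = scene.channel_names
    total = n_bursts + n_subthreshold
    slot = (duration - 4.0) / total
    spikes: list[SpikeAnnotation] = []
    bursts: list[SynthBurstSpec] = []
    montage_gain = 1.0 - 1.0 / n_channels
    for i in range(total):
        ch = names[rng.integers(0, n_channels)]
        onset = 2.0 + i * slot + rng.uniform(0, 0.3 * slot)
        ci = names.index(ch)
        if i < n_bursts:
            # rejection-sample the support constraint (>=5 planned cycles)
            # so the population has no boundary atom
            while True:
                freq = rng.uniform(90.0, 240.0)
                dur = rng.uniform(30.0, 90.0)
                if freq * dur / 1000.0 >= 5.0:
                    break
            amp = rng.uniform(*snr_range) * sigma[ci] / montage_gain
            bursts.append(SynthBurstSpec(ch, onset, freq, dur, amp))
            if rng.uniform() < spike_fraction:
                spikes.append(SpikeAnnotation(ch, onset + dur / 2000.0))
        else:
            amp = 8.0 * sigma[ci] / montage_gain
            bursts.append(SynthBurstSpec(ch, onset, 80.0, 37.5, amp))
    truths = []
    for b in bursts:
        rec, tr = inject_burst(rec, b)
        truths.append(tr)
    for s in spikes:
        rec = inject_spike(rec, s.channel, s.time, amplitude=50.0)
    return rec, pd.DataFrame(truths), spikes, scene


# ---------------------------------------------------------------------------
# Feature-space mixture
# ---------------------------------------------------------------------------

def lognormal_from_median_iqr(
    median: float, q25: float, q75: float
) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and IQR.

    mu = ln(median); sigma = (ln q75 - ln q25) / (2 * z_0.75).
    """
    if not 0 < q25 <= median <= q75:
        raise SynthSpecError("need 0 < q25 <= median <= q75")
    mu = np.log(median)
    sigma = (np.log(q75) - np.log(q25)) / (2 * _Z75)
    return mu, float(sigma)


@dataclass(frozen=True)
class ComponentSpec:
    """One mixture component in (frequency, duration, amplitude, cycles) space.

    Frequency and duration are normal on the raw scale; amplitude and cycle
    count are log-normal, parameterized by (mu, sigma) of the log.
    """

    size: int
    freq_mean: float
    freq_sd: float
    dur_mean: float
    dur_sd: float
    log_amp_mu: float
    log_amp_sigma: float
    log_cyc_mu: float
    log_cyc_sigma: float

    def __post_init__(self) -> None:
        if self.size < 1:
            raise SynthSpecError("component size must be >= 1")
        for s in (self.freq_sd, self.dur_sd, self.log_amp_sigma, self.log_cyc_sigma):
            if s < 0:
                raise SynthSpecError("dispersions must be non-negative")


@dataclass(frozen=True)
class MixtureSpec:
    components: tuple[ComponentSpec, ...]
    seed: int = 0

    @property
    def n_total(self) -> int:
        return sum(c.size for c in self.components)


def _c(size, f, f_sd, d, d_sd, amp_med, amp_q25, amp_q75, cyc_med, cyc_q25, cyc_q75):
    am, asg = lognormal_from_median_iqr(amp_med, amp_q25, amp_q75)
    cm, csg = lognormal_from_median_iqr(cyc_med, cyc_q25, cyc_q75)
    return ComponentSpec(size, f, f_sd, d, d_sd, am, asg, cm, csg)


def paper_mixture(seed: int = 0) -> MixtureSpec:
    """The published-centroid fixture: 3 components, sizes 65/70/28 (n=163).

    Printed cells (cluster means/medians of the published phenotypes):
    component 1 duration 35.3 +/- 7.3 ms and amplitude median 6.2 [5.6-7.4];
    component 2 frequency 118.1 +/- 10.5 Hz; component 3 duration
    70.2 +/- 15.4 ms and cycles median 9.8 [8.8-11.5].

    Cells the publication does not print are closed from its epoch-level
    statistics and the cluster-by-epoch composition (see docs/methods.md):
    component 1 frequency 145 +/- 18 Hz, cycles median 5.1 [4.5-5.8];
    component 2 duration 44.7 +/- 12.0 ms, amplitude median 8.9 [6.9-11.7];
    component 3 frequency 140 +/- 15 Hz, amplitude median 6.3 [5.3-7.5].
    Only the printed cells are asserted by tests.
    """
    return MixtureSpec(
        components=(
            _c(65, 145.0, 18.0, 35.3, 7.3, 6.2, 5.6, 7.4, 5.1, 4.5, 5.8),
            _c(70, 118.1, 10.5, 44.7, 12.0, 8.9, 6.9, 11.7, 5.3, 4.4, 6.1),
            _c(28, 140.0, 15.0, 70.2, 15.4, 6.3, 5.3, 7.5, 9.8, 8.8, 11.5),
        ),
        seed=seed,
    )


FEATURE_COLUMNS = ["avg_frequency_hz", "duration_ms", "amplitude_z", "n_cycles"]


def generate_feature_table(mix: MixtureSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the event-by-feature table from the mixture.

    Features are drawn independently per component (normal for frequency
    and duration, log-normal for amplitude and cycles); rows are shuffled.
    Returns (table, true component labels 1..K aligned with the rows).
    """
    rng = np.random.default_rng(mix.seed)
    rows, labels = [], []
    for k, comp in enumerate(mix.components, start=1):
        n = comp.size
        freq = rng.normal(comp.freq_mean, comp.freq_sd, n)
        dur = rng.normal(comp.dur_mean, comp.dur_sd, n)
        amp = rng.lognormal(comp.log_amp_mu, comp.log_amp_sigma, n)
        cyc = rng.lognormal(comp.log_cyc_mu, comp.log_cyc_sigma, n)
        rows.append(np.column_stack([freq, dur, amp, cyc]))
        labels.append(np.full(n, k))
    data = np.vstack(rows)
    labels = np.concatenate(labels)
    order = rng.permutation(len(labels))
    table = pd.DataFrame(data[order], columns=FEATURE_COLUMNS)
    table.insert(0, "event_id", np.arange(len(labels)))
    return table, labels[order]


def write_annotations(
    epochs: list[EpochInterval],
    spikes: list[SpikeAnnotation],
    epochs_path,
    spikes_path,
) -> None:
    """Write epoch and spike annotation CSVs (onset_s/offset_s/label schema)."""
    pd.DataFrame(
        [{"onset_s": e.onset, "offset_s": e.offset, "label": e.label} for e in epochs]
    ).to_csv(epochs_path, index=False)
    pd.DataFrame(
        [{"channel": s.channel, "time_s": s.time} for s in spikes]
    ).to_csv(spikes_path, index=False)


def read_epoch_annotations(path) -> list[EpochInterval]:
    df = pd.read_csv(path)
    return [
        EpochInterval(r.onset_s, r.offset_s, r.label) for r in df.itertuples()
    ]


def read_spike_annotations(path) -> list[SpikeAnnotation]:
    df = pd.read_csv(path)
    return [SpikeAnnotation(r.channel, r.time_s) for r in df.itertuples()]
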