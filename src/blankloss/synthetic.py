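"""Ground-truth generator: Gamma-renewal spike trains and extracellular-like
traces with stimulation artifacts and hardware-style blanking.

Emulates cell-attached-quality recordings of a tonically firing neuron
during periodic stimulation: biphasic spike waveforms on Gaussian noise,
a large biphasic stimulus artifact with a capacitive decay tail at every
stimulus pulse (sampled at the trace rate, which reproduces the aliasing
distortion seen when digitizing rectangular pulses), and a blanking stage
that sets samples inside each blanking window to exactly zero.

The stimulus train starts at t = 0 and is strictly periodic; the blanking
``phase`` parameter shifts the blanked windows relative to the stimulus
onsets to emulate trigger-to-blank alignment (the artifact itself does not
move).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .blanking import StimulationProtocol
from .isi import GammaISI

__all__ = [
    "SpikeTrain",
    "SpikeTemplate",
    "ArtifactModel",
    "Trace",
    "generate_spike_train",
    "default_template",
    "synthesize_trace",
    "apply_blanking_trace",
    "apply_blanking_train",
    "write_spike_train_csv",
    "read_spike_train_csv",
    "write_trace",
    "read_trace",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike peak times (s) on [0, duration)."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def rate_hz(self) -> float:
        """Empirical rate: count / duration."""
        return len(self) / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class SpikeTemplate:
    """Biphasic spike waveform sampled at ``sampling_rate``.

    ``waveform`` holds the samples (arbitrary pA-like units, main
    deflection negative), ``width`` the waveform span in seconds and
    ``peak_offset`` the time of the (negative) peak from waveform start.
    """

    waveform: np.ndarray
    width: float
    peak_offset: float
    sampling_rate: float

    def __post_init__(self) -> None:
        w = np.asarray(self.waveform, dtype=float)
        object.__setattr__(self, "waveform", w)
        if not self.width > 0:
            raise ValueError("template width must be > 0")
        if not (0 <= self.peak_offset < self.width):
            raise ValueError("peak_offset must lie in [0, width)")

    @property
    def amplitude(self) -> float:
        """Peak magnitude of the waveform."""
        return float(np.max(np.abs(self.waveform)))


def default_template(
    sampling_rate: float = 20_000.0, width: float = 1.5e-3, amplitude: float = 1.0
) -> SpikeTemplate:
    """Biphasic (negative-then-positive) spike template, unit amplitude.

    A Hann-windowed sine period: sharp negative deflection followed by a
    shallower positive rebound, zero at both ends — a generic extracellular
    action-potential shape.
    """
    n = max(int(round(width * sampling_rate)), 4)
    t = np.arange(n) / sampling_rate
    base = -np.sin(2 * np.pi * t / width) * np.sin(np.pi * t / width) ** 2
    wf = base / np.max(np.abs(base)) * amplitude
    peak = int(np.argmin(wf))
    return SpikeTemplate(
        waveform=wf, width=n / sampling_rate, peak_offset=peak / sampling_rate,
        sampling_rate=sampling_rate,
    )


@dataclass(frozen=True)
class ArtifactModel:
    """Stimulation-artifact shape: biphasic pulse plus capacitive tail.

    ``pulse_width`` is the biphasic pulse window (default 65 us),
    ``amplitude`` the pulse magnitude in template units, ``decay_tau`` the
    exponential time constant of the post-pulse discharge tail.
    """

    pulse_width: float = 65e-6
    amplitude: float = 3.0
    decay_tau: float = 0.5e-3

    def __post_init__(self) -> None:
        if self.pulse_width < 0 or self.amplitude < 0 or self.decay_tau < 0:
            raise ValueError("artifact parameters must be >= 0")

    def kernel(self, sampling_rate: float) -> np.ndarray:
        """Artifact sampled at the trace rate.

        Evaluating the continuous pulse at the (coarse) sample grid is what
        produces the aliased, non-rectangular artifact shapes seen in
        digitized recordings.
        """
        span = self.pulse_width + 6.0 * self.decay_tau
        n = max(int(np.ceil(span * sampling_rate)), 1)
        t = np.arange(n) / sampling_rate
        out = np.zeros(n)
        in_pulse = t < self.pulse_width
        first_half = t < 0.5 * self.pulse_width
        out[in_pulse & first_half] = self.amplitude
        out[in_pulse & ~first_half] = -self.amplitude
        tail = ~in_pulse
        if self.decay_tau > 0:
            out[tail] = self.amplitude * np.exp(
                -(t[tail] - self.pulse_width) / self.decay_tau
            )
        return out


@dataclass
class Trace:
    """Sampled extracellular-like signal with provenance metadata.

    ``metadata`` records the generating protocol, seed, ground-truth spike
    times and any blanked intervals, so detection results can always be
    scored against the truth.
    """

    sampling_rate: float
    samples: np.ndarray
    t0: float = 0.0
    metadata: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample timestamps t0 + i / sampling_rate."""
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


def generate_spike_train(
    model: GammaISI, duration: float, seed: int
) -> SpikeTrain:
    """Gamma-renewal spike train on [0, duration).

    Successive ISIs are i.i.d. Gamma(a, b) draws; the first event is one
    ISI draw after t = 0.  Reproducible for a fixed seed.
    """
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    rng = np.random.default_rng(seed)
    if duration == 0:
        return SpikeTrain(times=np.empty(0), duration=0.0)
    # draw in blocks until past the horizon
    expected = max(int(duration * model.rate_hz * 1.2) + 16, 16)
    times = np.array([], dtype=float)
    t_end = 0.0
    while t_end < duration:
        isis = rng.gamma(model.shape_a, model.scale_b, size=expected)
        block = t_end + np.cumsum(isis)
        times = np.concatenate([times, block])
        t_end = times[-1]
    return SpikeTrain(times=times[times < duration], duration=duration)


def synthesize_trace(
    train: SpikeTrain,
    template: SpikeTemplate,
    artifact: ArtifactModel | None,
    protocol: StimulationProtocol | None,
    noise_sd: float,
    sampling_rate: float,
    seed: int,
) -> Trace:
    """Render a spike train into a noisy sampled trace with artifacts.

    trace = Gaussian noise + spike template at each spike peak time
    + artifact transient at each stimulus onset k * t_st (if ``artifact``
    and ``protocol`` are given).  Ground truth goes into ``metadata``.
    """
    if sampling_rate < 2.0 / template.width:
        raise ValueError(
            "sampling_rate too low to resolve the spike template "
            f"({sampling_rate} Hz for width {template.width} s)"
        )
    rng = np.random.default_rng(seed)
    n = int(round(train.duration * sampling_rate))
    samples = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)

    wf = template.waveform
    peak_i = int(round(template.peak_offset * sampling_rate))
    for t_spk in train.times:
        start = int(round(t_spk * sampling_rate)) - peak_i
        lo, hi = max(start, 0), min(start + wf.size, n)
        if hi > lo:
            samples[lo:hi] += wf[lo - start : hi - start]

    stim_times = []
    if artifact is not None and protocol is not None:
        kern = artifact.kernel(sampling_rate)
        k = 0
        while True:
            t_stim = k * protocol.t_st
            if t_stim >= train.duration:
                break
            start = int(round(t_stim * sampling_rate))
            lo, hi = start, min(start + kern.size, n)
            if hi > lo:
                samples[lo:hi] += kern[: hi - lo]
            stim_times.append(t_stim)
            k += 1

    meta = {
        "seed": int(seed),
        "spike_times_s": [float(t) for t in train.times],
        "stim_times_s": [float(t) for t in stim_times],
        "blanked_intervals_s": [],
        "noise_sd": float(noise_sd),
        "template_width_s": float(template.width),
        "template_peak_offset_s": float(template.peak_offset),
        "template_amplitude": float(template.amplitude),
    }
    if protocol is not None:
        meta["protocol"] = {
            "f_st_hz": protocol.f_st,
            "pw_s": protocol.pw,
            "t_m_s": protocol.t_m,
        }
    return Trace(sampling_rate=sampling_rate, samples=samples, t0=0.0, metadata=meta)


def _blanked_intervals(
    duration: float, t0: float, protocol: StimulationProtocol, phase: float
):
    """Half-open blanked intervals [k*t_st + phase, ... + t_b) covering the span."""
    t_st, t_b = protocol.t_st, protocol.t_b
    if t_b == 0:
        return []
    k_min = int(np.floor((t0 - phase) / t_st)) - 1
    k_max = int(np.ceil((t0 + duration - phase) / t_st)) + 1
    out = []
    for k in range(k_min, k_max + 1):
        start = k * t_st + phase
        if start + t_b <= t0 or start >= t0 + duration:
            continue
        out.append((start, start + t_b))
    return out


def apply_blanking_trace(
    trace: Trace, protocol: StimulationProtocol, phase: float = 0.0
) -> Trace:
    """Zero every sample whose time lies in a blanked window.

    Samples with time in ``[k*t_st + phase, k*t_st + phase + t_b)`` are set
    to exactly 0; all other samples are bit-identical to the input.  The
    blanked intervals are appended to the metadata.
    """
    samples = trace.samples.copy()
    n = samples.size
    fs = trace.sampling_rate
    intervals = _blanked_intervals(trace.duration, trace.t0, protocol, phase)
    # fuzz (in sample units) absorbs float error in start*fs without ever
    # moving an index by a whole sample
    eps = 1e-6
    for start, end in intervals:
        # sample i (time t0 + i/fs) is blanked iff start <= t < end
        i0 = int(np.ceil((start - trace.t0) * fs - eps))
        i1 = int(np.ceil((end - trace.t0) * fs - eps))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 > i0:
            samples[i0:i1] = 0.0
    meta = dict(trace.metadata)
    meta["blanked_intervals_s"] = [[float(a), float(b)] for a, b in intervals]
    meta["blanking_phase_s"] = float(phase)
    return Trace(
        sampling_rate=fs, samples=samples, t0=trace.t0, metadata=meta
    )


def apply_blanking_train(
    train: SpikeTrain, protocol: StimulationProtocol, phase: float = 0.0
) -> tuple[SpikeTrain, int]:
    """Remove spikes whose peak time lies in a blanked window.

    Returns the surviving train and the lost count (surviving + lost equals
    the input count).  This peak-in-window rule is the train-level
    counterpart of the analytic ISI-bin nullification; partial waveform
    clipping is the stricter trace-level notion handled by the detector.
    """
    if len(train) == 0 or protocol.t_b == 0:
        return train, 0
    # windows repeat every t_st for all integer k, so the peak-in-window test
    # reduces to a modular comparison; t_b >= t_st tiles the whole line
    rel = np.mod(train.times - phase, protocol.t_st)
    lost_mask = rel < min(protocol.t_b, protocol.t_st)
    surviving = SpikeTrain(times=train.times[~lost_mask], duration=train.duration)
    return surviving, int(np.count_nonzero(lost_mask))


# ---------------------------------------------------------------------------
# plain-text I/O


def write_spike_train_csv(path, train: SpikeTrain) -> None:
    """Single-column CSV with header ``spike_time_s``."""
    with open(path, "w") as fh:
        fh.write("spike_time_s\n")
        for t in train.times:
            fh.write(f"{float(t)!r}\n")


def read_spike_train_csv(path, duration: float | None = None) -> SpikeTrain:
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    times = df["spike_time_s"].to_numpy(dtype=float)
    if duration is None:
        duration = float(times[-1]) + 1e-9 if times.size else 0.0
    return SpikeTrain(times=times, duration=duration)


def write_trace(path_prefix, trace: Trace, binary: bool = False) -> tuple[str, str]:
    """Write a trace as a raw sample file plus a JSON sidecar.

    ``binary=False`` (default) writes samples as a single-column CSV
    (header ``sample``); ``binary=True`` writes flat 64-bit floats.  The
    sidecar carries sampling_rate, t0 and the full metadata.  Returns the
    two paths written.
    """
    path_prefix = str(path_prefix)
    if binary:
        raw_path = path_prefix + ".f64"
        trace.samples.astype("<f8").tofile(raw_path)
    else:
        raw_path = path_prefix + ".csv"
        with open(raw_path, "w") as fh:
            fh.write("sample\n")
            np.savetxt(fh, trace.samples, fmt="%.17g")
    sidecar = path_prefix + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "sampling_rate_hz": trace.sampling_rate,
                "t0_s": trace.t0,
                "n_samples": int(trace.samples.size),
                "raw_format": "f64" if binary else "csv",
                "metadata": trace.metadata,
            },
            fh,
            indent=1,
        )
    return raw_path, sidecar


def read_trace(raw_path, sidecar_path) -> Trace:
    with open(sidecar_path) as fh:
        side = json.load(fh)
    if side.get("raw_format") == "f64":
        samples = np.fromfile(raw_path, dtype="<f8")
    else:
        samples = np.loadtxt(raw_path, skiprows=1, dtype=float, ndmin=1)
    return Trace(
        sampling_rate=float(side["sampling_rate_hz"]),
        samples=samples,
        t0=float(side.get("t0_s", 0.0)),
        metadata=side.get("metadata", {}),
    )
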