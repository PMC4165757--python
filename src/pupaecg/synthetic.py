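"""Synthetic Drosophila pupal ECG generation.

Real pupal ECG recordings are short, single-channel voltage traces
contaminated by 60 Hz powerline pickup, broadband amplifier noise and slow
baseline wander; invasive (needle) recordings additionally drift in both
beat amplitude and period as the puncture wound degrades the preparation.
This module generates traces with exactly that statistical structure so the
downstream preprocessing, beat-period and stability analyses can be
exercised and calibrated without any recorded data.

The beat itself is a trapezoid with an optional undershoot: a piecewise
linear shape whose positive duration and rising/falling slopes are known in
closed form, which makes the waveform-feature extractors testable against
analytic geometry.  Three phenotype presets encode the ordering observed
across fly strains — wild-type Canton-S beats fastest, the NP1029-GAL4
driver control is intermediate, and SERCA-depleted hearts are slowest.
The preset rates and amplitudes are illustrative defaults, not literature
values (none are published numerically); every field is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

logger = logging.getLogger("pupaecg")

__all__ = [
    "BeatShape",
    "SyntheticConfig",
    "ECGTrace",
    "PHENOTYPE_PRESETS",
    "make_beat_template",
    "generate_trace",
    "add_powerline",
    "apply_amplifier",
    "preset_config",
]

DEFAULT_SAMPLING_RATE = 2604.0  # Hz, matches the recording hardware


class ParameterError(ValueError):
    """Raised when an operation receives parameters violating its contract."""


@dataclass(frozen=True)
class BeatShape:
    """Piecewise-linear (trapezoidal) beat morphology.

    amplitude : V, peak height above baseline (baseline is 0 V)
    rise_time / plateau_time / fall_time : s, segment durations
    undershoot_fraction : depth of the post-beat undershoot as a fraction
        of ``amplitude``; the undershoot is a triangular dip lasting
        ``fall_time`` after the falling edge returns to baseline.
    """

    amplitude: float = 1e-3
    rise_time: float = 0.010
    plateau_time: float = 0.030
    fall_time: float = 0.020
    undershoot_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if min(self.rise_time, self.plateau_time, self.fall_time) < 0:
            raise ParameterError("durations must be >= 0")
        if self.rise_time + self.plateau_time + self.fall_time <= 0:
            raise ParameterError("beat must have positive total duration")
        if not 0 <= self.undershoot_fraction < 1:
            raise ParameterError("undershoot_fraction must be in [0, 1)")

    @property
    def width(self) -> float:
        """Total beat width in seconds, including any undershoot lobe."""
        w = self.rise_time + self.plateau_time + self.fall_time
        if self.undershoot_fraction > 0:
            w += self.fall_time
        return w


@dataclass
class ECGTrace:
    """Uniformly sampled single-channel voltage series.

    ``metadata`` carries free-form recording context; the keys
    ``phenotype`` and ``method`` (invasive / noninvasive / simulated) are
    used by the comparison tooling, and the generator stores its true beat
    onset times under ``beat_onsets`` for oracle checks.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ParameterError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def copy_with(self, samples: np.ndarray, **meta) -> "ECGTrace":
        md = dict(self.metadata)
        md.update(meta)
        return ECGTrace(np.asarray(samples, float), self.sampling_rate,
                        self.start_time, md)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic recording.

    Drift rates are fractions per minute: amplitude decays compound as
    ``(1 - amplitude_drift_rate)**(t/60)`` and the beat period inflates
    additively as ``base_period * (1 + period_drift_rate * t/60)``,
    emulating the progressive deterioration of invasive preparations.
    """

    heart_rate: float = 2.0               # Hz
    duration: float = 30.0                # s
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    beat_shape: BeatShape = field(default_factory=BeatShape)
    powerline_amplitude: float = 0.0      # V
    powerline_freq: float = 60.0          # Hz
    white_noise_sd: float = 0.0           # V
    baseline_wander_amplitude: float = 0.0  # V
    baseline_wander_freq: float = 0.3     # Hz
    period_jitter_sd: float = 0.0         # s
    amplitude_drift_rate: float = 0.0     # fraction / min
    period_drift_rate: float = 0.0        # fraction / min
    seed: int = 0
    phenotype_label: str = "custom"

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ParameterError("heart_rate must be > 0")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if self.sampling_rate <= 2 * self.powerline_freq:
            raise ParameterError("sampling_rate must exceed twice powerline_freq")
        mins = self.duration / 60.0
        if self.amplitude_drift_rate >= 1 or (1 - self.amplitude_drift_rate) ** mins <= 0:
            raise ParameterError("amplitude drift would drive amplitude non-positive")
        if 1 + self.period_drift_rate * mins <= 0:
            raise ParameterError("period drift would drive the period non-positive")


# Preset rates honour only the published ordering (CS fastest, NP
# intermediate, SERCA-depleted slowest); magnitudes are implementer choices.
PHENOTYPE_PRESETS: dict[str, SyntheticConfig] = {
    "CS": SyntheticConfig(heart_rate=4.0, phenotype_label="CS",
                          beat_shape=BeatShape(amplitude=1e-3)),
    "NP": SyntheticConfig(heart_rate=3.0, phenotype_label="NP",
                          beat_shape=BeatShape(amplitude=1e-3)),
    "SERCA-depleted": SyntheticConfig(heart_rate=1.5,
                                      phenotype_label="SERCA-depleted",
                                      beat_shape=BeatShape(amplitude=1e-3)),
}


def preset_config(label: str, **overrides) -> SyntheticConfig:
    """Return a phenotype preset, optionally with fields overridden."""
    try:
        base = PHENOTYPE_PRESETS[label]
    except KeyError:
        raise ParameterError(
            f"unknown phenotype preset {label!r}; "
            f"choose from {sorted(PHENOTYPE_PRESETS)}") from None
    return replace(base, **overrides) if overrides else base


def make_beat_template(shape: BeatShape, sampling_rate: float) -> np.ndarray:
    """Sample one beat at ``sampling_rate``.

    Linear rise, flat plateau, linear fall, then an optional triangular
    undershoot of depth ``undershoot_fraction * amplitude`` lasting
    ``fall_time``.  First and last samples sit at baseline 0 V.
    """
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be > 0")
    a, r, p, f = shape.amplitude, shape.rise_time, shape.plateau_time, shape.fall_time
    knots_t = [0.0, r, r + p, r + p + f]
    knots_v = [0.0, a, a, 0.0]
    if shape.undershoot_fraction > 0 and f > 0:
        knots_t += [r + p + 1.5 * f, r + p + 2.0 * f]
        knots_v += [-shape.undershoot_fraction * a, 0.0]
    total = knots_t[-1]
    # last sample lands at or beyond the final knot so it sits exactly at 0
    n = int(np.ceil(total * sampling_rate - 1e-9)) + 1
    t = np.arange(n) / sampling_rate
    return np.interp(t, knots_t, knots_v)


def _beat_schedule(cfg: SyntheticConfig, rng: np.random.Generator):
    """Onset times, per-beat periods and amplitude factors for one trace.

    Onsets start at t=0 and advance by the (drifted, jittered) period; the
    schedule is the generator's ground truth and is kept in metadata.
    """
    base = 1.0 / cfg.heart_rate
    width = cfg.beat_shape.width
    if base < width:
        raise ParameterError(
            f"beats overlap: period {base:.4f}s < beat width {width:.4f}s")
    onsets, amps = [], []
    t = 0.0
    while t < cfg.duration:
        onsets.append(t)
        amps.append((1.0 - cfg.amplitude_drift_rate) ** (t / 60.0))
        period = base * (1.0 + cfg.period_drift_rate * t / 60.0)
        if cfg.period_jitter_sd > 0:
            jitter = rng.normal(0.0, cfg.period_jitter_sd)
            # truncate so jitter never collapses the period below the beat width
            period = max(period + jitter, width, 1e-6)
        t += period
    return np.asarray(onsets), np.asarray(amps)


def generate_trace(config: SyntheticConfig) -> ECGTrace:
    """Generate a synthetic pupal ECG trace; deterministic for a given seed.

    The trace is a beat train at ``heart_rate`` (with jitter and drift as
    configured) plus powerline sinusoid, white noise and baseline wander.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    y = np.zeros(n)

    template = make_beat_template(config.beat_shape, config.sampling_rate)
    onsets, amps = _beat_schedule(config, rng)
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset * config.sampling_rate))
        i1 = min(i0 + template.size, n)
        if i0 < n:
            y[i0:i1] += amp * template[: i1 - i0]

    if config.powerline_amplitude:
        y += config.powerline_amplitude * np.sin(
            2 * np.pi * config.powerline_freq * t)
    if config.white_noise_sd:
        y += rng.normal(0.0, config.white_noise_sd, n)
    if config.baseline_wander_amplitude:
        y += config.baseline_wander_amplitude * np.sin(
            2 * np.pi * config.baseline_wander_freq * t)

    meta = {
        "phenotype": config.phenotype_label,
        "method": "simulated",
        "heart_rate_hz": config.heart_rate,
        "seed": config.seed,
        "beat_onsets": onsets.tolist(),
    }
    return ECGTrace(y, config.sampling_rate, 0.0, meta)


def add_powerline(trace: ECGTrace, amplitude: float, freq: float = 60.0) -> ECGTrace:
    """Return ``trace`` plus a ``amplitude * sin(2*pi*freq*t)`` component."""
    if freq >= trace.sampling_rate / 2:
        raise ParameterError("powerline frequency must be below Nyquist")
    contaminated = trace.samples + amplitude * np.sin(2 * np.pi * freq * trace.times)
    return trace.copy_with(contaminated)


def apply_amplifier(trace: ECGTrace, gain_db: float = 0.0,
                    highpass_hz: float = 5.0, lowpass_hz: float = 10_000.0) -> ECGTrace:
    """Optional AC-coupled front-end: first-order band-pass plus gain.

    Models an instrumentation amplifier passband (default 5 Hz – 10 kHz);
    off by default in the generator.  The low-pass corner is clipped to
    just below Nyquist when it exceeds it.
    """
    nyq = trace.sampling_rate / 2
    lowpass_hz = min(lowpass_hz, 0.99 * nyq)
    if not 0 < highpass_hz < lowpass_hz:
        raise ParameterError("require 0 < highpass_hz < lowpass_hz")
    y = trace.samples
    for btype, fc in (("highpass", highpass_hz), ("lowpass", lowpass_hz)):
        b, a = _sig.butter(1, fc / nyq, btype=btype)
        y = _sig.lfilter(b, a, y)
    y = y * 10 ** (gain_db / 20.0)
    return trace.copy_with(y, amplifier=f"bp {highpass_hz}-{lowpass_hz} Hz, {gain_db} dB")
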