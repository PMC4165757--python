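"""Waveform-feature extraction and invasive/noninvasive comparison.

Three per-beat morphology features summarise a pupal ECG waveform:

* **positive duration** — time the beat spends above baseline (trace
  median), from the up-crossing before the peak to the down-crossing after;
* **depolarization slope** — least-squares slope over the 10–90 % segment
  of the rising edge (V/s, >= 0);
* **repolarization slope** — likewise on the falling edge (<= 0).

The 10–90 % convention (rather than a peak derivative) is robust to the
heavy smoothing the preprocessing applies.  Passing an invasive recording
through the GaIn relative transfer H(s) widens the positive duration and
flattens both slopes — the signature of its low-pass character — and
``fit_relative_transfer`` inverts that observation: given a paired
(V_needle, V_GaIn) recording it estimates the first-order interface model
(DC gain g and time constant τ = R·C of the GaIn contact) whose simulated
output best matches the noninvasive trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize as _opt

from .electrodes import TransferFunction, first_order_tf, simulate_response
from .processing import BeatSeries
from .synthetic import ECGTrace, ParameterError

logger = logging.getLogger("pupaecg")

__all__ = [
    "WaveformFeatures",
    "MethodComparison",
    "FittedInterface",
    "extract_features",
    "compare_methods",
    "fit_relative_transfer",
]


@dataclass(frozen=True)
class WaveformFeatures:
    """Across-beat mean morphology of one trace."""

    positive_duration: float      # s
    depolarization_slope: float   # V/s, >= 0
    repolarization_slope: float   # V/s, <= 0
    peak_amplitude: float         # V above baseline
    n_beats: int
    n_skipped: int = 0


@dataclass(frozen=True)
class MethodComparison:
    """Noninvasive / invasive feature ratios and mean-period difference."""

    duration_ratio: float
    depol_slope_ratio: float
    repol_slope_ratio: float
    period_difference: float      # s, noninvasive mean - invasive mean


@dataclass(frozen=True)
class FittedInterface:
    """First-order interface model recovered from a paired recording."""

    dc_gain: float
    time_constant: float          # s
    residual_rms: float           # V

    def as_transfer(self) -> TransferFunction:
        return first_order_tf(self.dc_gain, self.time_constant)


def _beat_features(y: np.ndarray, peak: int, baseline: float, fs: float):
    """Features of one beat around sample index ``peak``; None if the beat
    never crosses baseline on both sides."""
    up = peak
    while up > 0 and y[up - 1] > baseline:
        up -= 1
    down = peak
    while down < y.size - 1 and y[down + 1] > baseline:
        down += 1
    if up == 0 and y[0] > baseline:
        return None
    if down == y.size - 1 and y[-1] > baseline:
        return None
    duration = (down - up + 1) / fs

    amp = y[peak] - baseline
    lo_thr = baseline + 0.1 * amp
    hi_thr = baseline + 0.9 * amp

    def _segment_slope(idx: np.ndarray) -> float | None:
        seg = idx[(y[idx] >= lo_thr) & (y[idx] <= hi_thr)]
        if seg.size < 2:
            return None
        return float(np.polyfit(seg / fs, y[seg], 1)[0])

    depol = _segment_slope(np.arange(up, peak + 1))
    # the falling edge runs from the end of the plateau to the down-crossing
    repol = _segment_slope(np.arange(peak, down + 1))
    if depol is None or repol is None:
        return None
    return duration, depol, repol, amp


def extract_features(trace: ECGTrace, beats: BeatSeries) -> WaveformFeatures:
    """Across-beat mean waveform features of ``trace`` at the detected beats.

    Beats whose waveform never returns to baseline on one side (trace
    edges) or whose edges are too short to fit a slope are skipped; the
    skipped count is reported.
    """
    if len(beats) < 1:
        raise ParameterError("need at least one detected beat")
    y = trace.samples
    fs = trace.sampling_rate
    baseline = float(np.median(y))
    peaks = np.round((beats.beat_times - trace.start_time) * fs).astype(int)
    rows = []
    skipped = 0
    for p in peaks:
        out = _beat_features(y, int(p), baseline, fs)
        if out is None:
            skipped += 1
        else:
            rows.append(out)
    if not rows:
        raise ParameterError("no beat had measurable features")
    arr = np.asarray(rows)
    return WaveformFeatures(
        positive_duration=float(np.mean(arr[:, 0])),
        depolarization_slope=float(np.mean(arr[:, 1])),
        repolarization_slope=float(np.mean(arr[:, 2])),
        peak_amplitude=float(np.mean(arr[:, 3])),
        n_beats=len(rows),
        n_skipped=skipped,
    )


def compare_methods(inv: WaveformFeatures, noninv: WaveformFeatures,
                    inv_beats: BeatSeries,
                    noninv_beats: BeatSeries) -> MethodComparison:
    """Feature ratios (noninvasive / invasive) and mean-period difference."""
    if inv.n_beats < 1 or noninv.n_beats < 1:
        raise ParameterError("both feature sets must come from >= 1 beat")
    if inv.depolarization_slope == 0 or inv.repolarization_slope == 0:
        raise ParameterError("invasive slopes are zero; ratios undefined")
    return MethodComparison(
        duration_ratio=noninv.positive_duration / inv.positive_duration,
        depol_slope_ratio=noninv.depolarization_slope / inv.depolarization_slope,
        repol_slope_ratio=noninv.repolarization_slope / inv.repolarization_slope,
        period_difference=float(np.mean(noninv_beats.periods)
                                - np.mean(inv_beats.periods)),
    )


# deterministic coarse start grid for the first-order fit
_GAIN_GRID = np.linspace(0.2, 2.0, 10)
_TAU_GRID = np.concatenate(([0.0], np.logspace(-4, -1, 10)))


def fit_relative_transfer(v_needle: ECGTrace, v_gain: ECGTrace) -> FittedInterface:
    """Fit a first-order model g/(τs+1) mapping V_needle to V_GaIn.

    Minimises the RMS difference between ``simulate_response`` of the model
    applied to ``v_needle`` and the measured ``v_gain``, using a
    deterministic coarse grid over (g, τ) followed by Nelder–Mead
    refinement — no random starts, so the fit is reproducible.
    """
    if v_needle.samples.size != v_gain.samples.size:
        raise ParameterError("paired traces must have equal length")
    if v_needle.sampling_rate != v_gain.sampling_rate:
        raise ParameterError("paired traces must share a sampling rate")
    if np.var(v_needle.samples) == 0:
        raise ParameterError("input trace has zero variance; fit is undefined")

    target = v_gain.samples

    # grid probes legitimately sweep corners up to Nyquist; don't warn per probe
    prev_level = logger.level
    logger.setLevel(max(prev_level, logging.ERROR))

    def rms(params) -> float:
        g, log_tau = params
        tau = np.exp(log_tau)
        sim = simulate_response(first_order_tf(g, tau), v_needle)
        return float(np.sqrt(np.mean((sim.samples - target) ** 2)))

    dt = 1.0 / v_needle.sampling_rate
    try:
        best, best_val = None, np.inf
        for g in _GAIN_GRID:
            for tau in _TAU_GRID:
                sim = simulate_response(first_order_tf(g, tau), v_needle)
                val = float(np.sqrt(np.mean((sim.samples - target) ** 2)))
                if val < best_val:
                    best, best_val = (g, max(tau, dt / 100)), val
        res = _opt.minimize(rms, x0=[best[0], np.log(best[1])],
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-14,
                                     "maxiter": 2000})
    finally:
        logger.setLevel(prev_level)
    g_hat, tau_hat = float(res.x[0]), float(np.exp(res.x[1]))
    resid = min(best_val, float(res.fun))
    if best_val < res.fun:  # refinement should not regress below the grid
        g_hat, tau_hat = best
    return FittedInterface(g_hat, tau_hat, resid)
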