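"""Plain-text trace files, model/config files, and tabular report output.

Traces are stored as two delimited columns (``time_s``, ``voltage``)
preceded by a ``#``-prefixed key/value header carrying at least
``sampling_rate_hz``, ``units``, ``phenotype`` and ``method``.  The time
grid must be uniform; the voltage column may be in V, mV, uV (µV) or nV —
pupal signals are on the order of nanovolts before amplification — and is
converted to volts on read.

Electrode-model and synthetic-generator configs are flat YAML key/value
files mirroring the dataclass field names.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import electrodes, synthetic
from .processing import BeatSeries, PeriodSummary
from .synthetic import BeatShape, ECGTrace, ParameterError, SyntheticConfig

logger = logging.getLogger("pupaecg")

__all__ = [
    "read_trace",
    "write_trace",
    "read_synthetic_config",
    "read_electrode_model",
    "write_period_summaries",
    "write_beats",
    "FormatError",
]

_UNIT_SCALE = {"V": 1.0, "mV": 1e-3, "uV": 1e-6, "µV": 1e-6, "nV": 1e-9}
_TIME_TOL = 1e-9  # s, allowed deviation from a uniform grid

ELECTRODE_MODEL_REGISTRY = {
    "needle": electrodes.NeedleElectrodeModel,
    "gelled": electrodes.GelledElectrodeModel,
    "gain": electrodes.GaInElectrodeModel,
}


class FormatError(ValueError):
    """Raised when a trace file violates the on-disk format contract."""


def _coerce_numbers(mapping: dict) -> dict:
    """YAML 1.1 reads exponents without a sign (2.0e8) as strings; fix that."""
    out = {}
    for key, val in mapping.items():
        if isinstance(val, str):
            try:
                val = float(val)
            except ValueError:
                pass
        out[key] = val
    return out


def write_trace(trace: ECGTrace, path, units: str = "V") -> None:
    """Write a trace file (deterministic fixed-precision formatting)."""
    if trace.samples.size < 1:
        raise ParameterError("refusing to write a zero-length trace")
    if units not in _UNIT_SCALE:
        raise FormatError(f"unknown unit {units!r}")
    scale = _UNIT_SCALE[units]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate_hz: {trace.sampling_rate:.10g}\n")
        fh.write(f"# units: {units}\n")
        fh.write(f"# start_time_s: {trace.start_time:.10g}\n")
        for key, val in trace.metadata.items():
            if key == "beat_onsets":
                continue  # generator ground truth stays in memory
            fh.write(f"# {key}: {val}\n")
        fh.write("time_s\tvoltage\n")
        times = trace.times
        for t, v in zip(times, trace.samples / scale):
            fh.write(f"{t:.10f}\t{v:.12e}\n")
    logger.info("wrote %d samples to %s", trace.samples.size, path)


def read_trace(path) -> ECGTrace:
    """Read a trace file; validates grid uniformity and units."""
    path = Path(path)
    header: dict[str, str] = {}
    times, volts = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                header[key.strip()] = val.strip()
                continue
            if line.startswith("time_s"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            times.append(float(parts[0]))
            volts.append(float(parts[1]))
    if not times:
        raise FormatError(f"{path}: no samples")
    units = header.get("units", "V")
    if units not in _UNIT_SCALE:
        raise FormatError(f"{path}: unknown unit {units!r}")
    try:
        fs = float(header["sampling_rate_hz"])
    except KeyError:
        raise FormatError(f"{path}: missing sampling_rate_hz header") from None

    t = np.asarray(times)
    if t.size > 1:
        dt = np.diff(t)
        bad = np.nonzero(np.abs(dt - 1.0 / fs) > _TIME_TOL)[0]
        if bad.size:
            raise FormatError(
                f"{path}: non-uniform time grid at data row {int(bad[0]) + 2} "
                f"(step {dt[bad[0]]:.3e} s, expected {1.0 / fs:.3e} s)")
    meta = {k: v for k, v in header.items()
            if k not in ("sampling_rate_hz", "units", "start_time_s")}
    return ECGTrace(np.asarray(volts) * _UNIT_SCALE[units], fs,
                    float(header.get("start_time_s", t[0])), meta)


def read_synthetic_config(path) -> SyntheticConfig:
    """Load a SyntheticConfig from a flat YAML file.

    ``phenotype_label`` selects a preset whose fields the file's other keys
    then override; beat-shape fields are nested under ``beat_shape``.
    """
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: expected a key/value mapping")
    raw = _coerce_numbers(raw)
    shape_kwargs = raw.pop("beat_shape", None)
    if shape_kwargs:
        shape_kwargs = _coerce_numbers(shape_kwargs)
    label = raw.get("phenotype_label")
    if label and label in synthetic.PHENOTYPE_PRESETS:
        base = asdict(synthetic.PHENOTYPE_PRESETS[label])
        base_shape = base.pop("beat_shape")
        base.update(raw)
        raw = base
        shape_kwargs = {**base_shape, **(shape_kwargs or {})}
    if shape_kwargs:
        raw["beat_shape"] = BeatShape(**shape_kwargs)
    return SyntheticConfig(**raw)


def read_electrode_model(path, kind: str | None = None):
    """Load an electrode model from a flat YAML key/value file.

    The model class comes from the ``kind`` argument or a ``kind:`` key in
    the file (one of needle / gelled / gain).
    """
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    raw = _coerce_numbers(raw)
    kind = kind or raw.pop("kind", None)
    if kind not in ELECTRODE_MODEL_REGISTRY:
        raise FormatError(
            f"unknown electrode model kind {kind!r}; "
            f"choose from {sorted(ELECTRODE_MODEL_REGISTRY)}")
    raw.pop("kind", None)
    return ELECTRODE_MODEL_REGISTRY[kind](**raw)


def write_beats(beats: BeatSeries, path, params: dict | None = None) -> None:
    """Write detected beat times and periods as delimited text."""
    with Path(path).open("w") as fh:
        for key, val in (params or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("beat_time_s\tperiod_s\n")
        periods = beats.periods
        for i, t in enumerate(beats.beat_times):
            per = f"{periods[i - 1]:.6f}" if i > 0 else "nan"
            fh.write(f"{t:.6f}\t{per}\n")


def write_period_summaries(summaries: list[PeriodSummary], path,
                           params: dict | None = None) -> None:
    """Write period summaries (offset, n, mean_s, sd_s, valid) as text."""
    with Path(path).open("w") as fh:
        for key, val in (params or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("offset_s\tn\tmean_s\tsd_s\tvalid\n")
        for s in summaries:
            fh.write(f"{s.offset:g}\t{s.n_cycles}\t{s.mean_period:.6f}\t"
                     f"{s.sd_period:.6f}\t{int(s.valid)}\n")
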