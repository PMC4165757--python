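"""Electrode–tissue equivalent-circuit models and transfer-function tools.

Three lumped RC models of the pupa–electrode interface are implemented:

* **Needle (invasive)** — the tungsten probe penetrates the puparium, so the
  signal path is source → (C_EH ∥ R_EH) probe–hemolymph interface →
  R_Body hemocoel bulk → amplifier load (R_load ∥ C_load).  The voltage
  across the load is V_needle.

* **Gelled (noninvasive, wet)** — electrolyte gel on the intact puparium:
  source → (C_PH ∥ R_PH) puparium–hemolymph interface → R_P puparium bulk
  → R_E electrolyte bulk → (C_EE ∥ R_EE) electrode–electrolyte interface →
  load.  Because the puparium is an ion-semipermeable membrane, a Nernst
  potential E_PE appears in series; it is a DC/motion-artifact offset and
  is therefore exposed separately rather than folded into the (linear,
  offset-free) transfer function.

* **GaIn (noninvasive, dry)** — liquid-metal contact on the puparium: only
  an interface impedance (R_IP ∥ C_IP) and a series DC resistance matter:
  source → R_series → (R_IP ∥ C_IP) → load.  The voltage across the load
  is V_GaIn.

Each model yields a rational transfer function in the Laplace variable s
from the cardiac source voltage to the measured voltage, built by
series/parallel impedance-divider algebra.  The relative transfer
H(s) = V_GaIn / V_needle between the two recording methods behaves as a
mild low-pass filter — the parallel R_IP ∥ C_IP rolls off the high
frequencies — which is what widens the positive duration and flattens the
slopes of noninvasively recorded beats.  ``bode`` and ``simulate_response``
characterise H in the frequency and time domains respectively.

Default component values are illustrative (chosen to place the H corner
near 30 Hz, inside the signal band); no published values exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .synthetic import ECGTrace, ParameterError

logger = logging.getLogger("pupaecg")

__all__ = [
    "NeedleElectrodeModel",
    "GelledElectrodeModel",
    "GaInElectrodeModel",
    "NernstInput",
    "TransferFunction",
    "nernst_potential",
    "needle_transfer",
    "gelled_transfer",
    "gain_transfer",
    "relative_transfer",
    "first_order_tf",
    "bode",
    "simulate_response",
]

GAS_CONSTANT = 8.314462618      # J / (mol K), CODATA 2018
FARADAY_CONSTANT = 96485.33212  # C / mol, CODATA 2018


# --------------------------------------------------------------------------
# rational-function plumbing


def _trim(c: np.ndarray) -> np.ndarray:
    """Strip leading near-zero coefficients (descending powers of s)."""
    c = np.atleast_1d(np.asarray(c, float))
    scale = np.max(np.abs(c)) or 1.0
    nz = np.nonzero(np.abs(c) > 1e-300 * scale)[0]
    return c[nz[0]:] if nz.size else np.array([0.0])


@dataclass(frozen=True)
class TransferFunction:
    """Rational function of s; coefficients in descending powers."""

    numerator: tuple
    denominator: tuple

    def __post_init__(self) -> None:
        num = _trim(self.numerator)
        den = _trim(self.denominator)
        if den[0] == 0 or not np.any(den):
            raise ParameterError("leading denominator coefficient must be nonzero")
        if num.size > den.size:
            raise ParameterError("transfer function must be proper "
                                 "(deg num <= deg den)")
        # normalise so the leading denominator coefficient is 1
        object.__setattr__(self, "numerator", tuple(num / den[0]))
        object.__setattr__(self, "denominator", tuple(den / den[0]))

    def __call__(self, s: complex | np.ndarray) -> complex | np.ndarray:
        return (np.polyval(self.numerator, s)
                / np.polyval(self.denominator, s))

    def at_frequency(self, freq_hz) -> np.ndarray:
        """Evaluate at s = j·2πf."""
        return self(1j * 2 * np.pi * np.asarray(freq_hz, float))

    @property
    def dc_gain(self) -> float:
        return float(np.real(self(0.0)))

    def __mul__(self, other: "TransferFunction") -> "TransferFunction":
        return TransferFunction(
            tuple(np.polymul(self.numerator, other.numerator)),
            tuple(np.polymul(self.denominator, other.denominator)))


@dataclass(frozen=True)
class _Rational:
    """Internal num/den pair for impedance algebra (no properness check)."""

    num: tuple
    den: tuple

    def __add__(self, o):
        return _Rational(
            tuple(np.polyadd(np.polymul(self.num, o.den),
                             np.polymul(o.num, self.den))),
            tuple(np.polymul(self.den, o.den)))

    def __truediv__(self, o):
        return _Rational(tuple(np.polymul(self.num, o.den)),
                         tuple(np.polymul(self.den, o.num)))


def _resistor(r: float) -> _Rational:
    return _Rational((r,), (1.0,))


def _parallel_rc(r: float, c: float) -> _Rational:
    """Impedance of R in parallel with C: R / (1 + sRC)."""
    if c <= 0:
        return _resistor(r)
    return _Rational((r,), (r * c, 1.0))


def _divider(series: list[_Rational], load: _Rational) -> TransferFunction:
    """V_load / V_source for a series chain of impedances into ``load``."""
    total = load
    for z in series:
        total = total + z
    h = load / total
    return TransferFunction(h.num, h.den)


# --------------------------------------------------------------------------
# electrode models


@dataclass(frozen=True)
class NeedleElectrodeModel:
    """Invasive tungsten-needle interface (probe–hemolymph RC, hemocoel bulk)."""

    c_eh: float = 100e-9    # F, probe-hemolymph interface capacitance
    r_eh: float = 1e6       # ohm, probe-hemolymph interface resistance
    r_body: float = 50e3    # ohm, hemocoel bulk DC resistance
    r_load: float = 10e6    # ohm, amplifier input resistance
    c_load: float = 0.0     # F, amplifier input capacitance

    def __post_init__(self) -> None:
        _check_rc(self)


@dataclass(frozen=True)
class GelledElectrodeModel:
    """Wet-gel interface on the intact puparium, with Nernst offset E_PE."""

    r_e: float = 20e3       # ohm, electrolyte bulk resistance
    r_p: float = 500e3      # ohm, puparium bulk resistance
    c_ee: float = 1e-6      # F, electrode-electrolyte interface capacitance
    r_ee: float = 100e3     # ohm, electrode-electrolyte interface resistance
    c_ph: float = 50e-9     # F, puparium-hemolymph interface capacitance
    r_ph: float = 1e6       # ohm, puparium-hemolymph interface resistance
    e_pe: float = 0.0       # V, Nernst potential across the puparium
    r_load: float = 10e6
    c_load: float = 0.0

    def __post_init__(self) -> None:
        _check_rc(self)


@dataclass(frozen=True)
class GaInElectrodeModel:
    """Dry liquid-metal interface: R_IP ∥ C_IP plus a series DC resistance.

    The contact sits on the intact (insulating) puparium, so the interface
    resistance is large; driving the amplifier's input capacitance through
    it is what produces the mild low-pass between V_GaIn and V_needle.
    Defaults put that corner near 30 Hz, inside the signal band, with the
    interface zero 1/(2π R_IP C_IP) above the band so the response is
    monotonically non-increasing up to 1 kHz.
    """

    r_ip: float = 100e6     # ohm, GaIn-puparium interface resistance
    c_ip: float = 10e-12    # F, GaIn-puparium interface capacitance
    r_series: float = 100e3  # ohm, series DC (bulk) resistance
    r_load: float = 10e6
    c_load: float = 560e-12

    def __post_init__(self) -> None:
        _check_rc(self)


def _check_rc(model) -> None:
    for name, val in vars(model).items():
        if name.startswith("r_") and val <= 0:
            raise ParameterError(f"{name} must be > 0")
        if name.startswith("c_") and val < 0:
            raise ParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class NernstInput:
    """Inputs to the Nernst equation for the trans-puparium potential."""

    temperature: float       # K
    valence: int
    conc_outside: float      # mol/L
    conc_inside: float       # mol/L

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ParameterError("temperature must be > 0 K")
        if self.valence == 0:
            raise ParameterError("valence must be nonzero")
        if self.conc_outside <= 0 or self.conc_inside <= 0:
            raise ParameterError("concentrations must be > 0")


def nernst_potential(inp: NernstInput) -> float:
    """Equilibrium potential (V) across an ion-semipermeable membrane.

    E = (R·T)/(z·F) · ln(c_out / c_in).
    """
    return (GAS_CONSTANT * inp.temperature
            / (inp.valence * FARADAY_CONSTANT)
            * np.log(inp.conc_outside / inp.conc_inside))


# --------------------------------------------------------------------------
# transfer functions


def _load_z(model) -> _Rational:
    return _parallel_rc(model.r_load, model.c_load)


def needle_transfer(model: NeedleElectrodeModel) -> TransferFunction:
    """Source → V_needle: (C_EH ∥ R_EH) — R_Body — load divider."""
    return _divider([_parallel_rc(model.r_eh, model.c_eh),
                     _resistor(model.r_body)], _load_z(model))


def gelled_transfer(model: GelledElectrodeModel) -> TransferFunction:
    """Source → gelled-electrode voltage (E_PE offset handled separately)."""
    return _divider([_parallel_rc(model.r_ph, model.c_ph),
                     _resistor(model.r_p),
                     _resistor(model.r_e),
                     _parallel_rc(model.r_ee, model.c_ee)], _load_z(model))


def gain_transfer(model: GaInElectrodeModel) -> TransferFunction:
    """Source → V_GaIn: R_series — (R_IP ∥ C_IP) — load divider."""
    return _divider([_resistor(model.r_series),
                     _parallel_rc(model.r_ip, model.c_ip)], _load_z(model))


def _cancel_common_roots(num: np.ndarray, den: np.ndarray, rtol=1e-8):
    """Cancel shared roots (to tolerance) of two polynomials."""
    nr = list(np.roots(num)) if num.size > 1 else []
    dr = list(np.roots(den)) if den.size > 1 else []
    kept_d = []
    for root in dr:
        scale = max(abs(root), 1.0)
        match = next((i for i, z in enumerate(nr)
                      if abs(z - root) <= rtol * scale), None)
        if match is None:
            kept_d.append(root)
        else:
            nr.pop(match)
    kn = num[0] if num.size else 0.0
    kd = den[0]
    new_num = np.real_if_close(kn * np.poly(nr)) if nr else np.array([kn])
    new_den = np.real_if_close(kd * np.poly(kept_d)) if kept_d else np.array([kd])
    return np.real(new_num), np.real(new_den)


def relative_transfer(gain_tf: TransferFunction,
                      needle_tf: TransferFunction) -> TransferFunction:
    """H(s) = V_GaIn / V_needle, reduced to lowest terms.

    With a resistive needle path and a capacitive GaIn interface this is a
    low-pass response: the noninvasive recording is a slightly smoothed
    version of the invasive one.
    """
    if abs(needle_tf.dc_gain) < 1e-300:
        raise ParameterError("needle transfer has a zero at s=0; "
                             "H = V_GaIn/V_needle is degenerate")
    num = np.polymul(gain_tf.numerator, needle_tf.denominator)
    den = np.polymul(gain_tf.denominator, needle_tf.numerator)
    num, den = _cancel_common_roots(_trim(num), _trim(den))
    probe = np.abs(np.polyval(den, 1j * 2 * np.pi
                              * np.logspace(-2, 4, 13)))
    if not np.all(probe > 0):
        raise ParameterError("needle transfer vanishes in band; "
                             "relative transfer is degenerate")
    return TransferFunction(tuple(num), tuple(den))


def first_order_tf(dc_gain: float, time_constant: float) -> TransferFunction:
    """Single-pole low-pass g / (τs + 1); τ = 0 gives a pure gain."""
    if time_constant < 0:
        raise ParameterError("time_constant must be >= 0")
    if time_constant == 0:
        return TransferFunction((dc_gain,), (1.0,))
    return TransferFunction((dc_gain,), (time_constant, 1.0))


def bode(tf: TransferFunction, freqs) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude (dB) and phase (degrees) of ``tf`` at each frequency in Hz."""
    freqs = np.atleast_1d(np.asarray(freqs, float))
    if freqs.size == 0:
        raise ParameterError("frequency list must be non-empty")
    if np.any(freqs <= 0):
        raise ParameterError("frequencies must be > 0")
    h = tf.at_frequency(freqs)
    mag_db = 20 * np.log10(np.abs(h))
    phase_deg = np.degrees(np.angle(h))
    return mag_db, phase_deg


def simulate_response(tf: TransferFunction, trace: ECGTrace) -> ECGTrace:
    """Apply ``tf`` to a sampled trace via bilinear-transform discretization.

    The continuous-time rational function is mapped to a digital filter at
    the trace's sampling rate (no pre-warping: corners of interest sit far
    below Nyquist) and run causally over the samples.  Output length,
    rate and start time match the input; metadata method = "simulated".
    """
    fs = trace.sampling_rate
    poles = np.roots(tf.denominator) if len(tf.denominator) > 1 else np.array([])
    # judge by the dominant (slowest) pole; faster poles are settled within
    # a sample and harmless to discretize
    if poles.size and np.min(np.abs(poles)) / (2 * np.pi) > fs / 2:
        logger.warning("transfer-function corner above Nyquist (%.0f Hz); "
                       "discretization will be inaccurate", fs / 2)
    if len(tf.denominator) == 1:  # static gain, nothing to discretize
        y = np.asarray(tf.numerator)[-1] / tf.denominator[0] * trace.samples
    else:
        b, a = _sig.bilinear(tf.numerator, tf.denominator, fs)
        y = _sig.lfilter(b, a, trace.samples)
    return trace.copy_with(y, method="simulated")
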