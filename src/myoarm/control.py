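"""Control-signal streams and the synthetic surface-EMG chain.

Two kinds of control streams feed the simulator:

* bang-bang (keyboard/mouse-like): the excitation level is fixed and the
  user only chooses when each side is on;
* proportional (EMG-like): graded excitations in [0, 1] per side, allowing
  flexor/extensor co-activation.

The EMG chain emulates a consumer-grade sensor pipeline: muscle activation
amplitude-modulates zero-mean Gaussian noise (the raw interference signal),
the sensor full-wave rectifies and low-pass filters it into a linear
envelope, a 10-bit ADC digitizes the envelope, and a rest/MVC calibration
normalizes it into an excitation in [0, 1] at the simulation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, InputValidationError

__all__ = [
    "ControlSample",
    "EmgChainParams",
    "Calibration",
    "bang_bang_stream",
    "synthesize_raw_emg",
    "linear_envelope",
    "adc_quantize",
    "emg_to_excitation",
]


@dataclass(frozen=True)
class ControlSample:
    """Flexor/extensor excitations at one timestep, both in [0, 1]."""

    u_f: float = 0.0
    u_e: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_f <= 1.0 and 0.0 <= self.u_e <= 1.0):
            raise InputValidationError(
                f"excitations must lie in [0, 1], got u_f={self.u_f}, u_e={self.u_e}"
            )


@dataclass(frozen=True)
class EmgChainParams:
    """Parameters of the synthetic raw-EMG -> envelope -> ADC pipeline."""

    fs_raw: float = 1000.0   # raw EMG sample rate (Hz)
    f_env: float = 2.0       # envelope low-pass cutoff (Hz)
    gain: float = 3.3        # amplifier gain (V RMS per unit activation)
    adc_bits: int = 10       # quantizer resolution (bits)
    v_ref: float = 3.3       # ADC full scale (V)
    noise_seed: int = 0      # seed for the interference-noise generator

    def __post_init__(self) -> None:
        if not self.fs_raw >= 500:
            raise InputValidationError("fs_raw must be >= 500 Hz")
        if not 0 < self.f_env < self.fs_raw / 2:
            raise InputValidationError("f_env must lie in (0, fs_raw/2)")
        if not self.adc_bits >= 1:
            raise InputValidationError("adc_bits must be >= 1")
        if not self.v_ref > 0:
            raise InputValidationError("v_ref must be positive")


@dataclass(frozen=True)
class Calibration:
    """Rest/MVC envelope levels used to normalize each channel."""

    baseline_f: float
    baseline_e: float
    mvc_f: float
    mvc_e: float

    def __post_init__(self) -> None:
        for base, mvc, ch in (
            (self.baseline_f, self.mvc_f, "flexor"),
            (self.baseline_e, self.mvc_e, "extensor"),
        ):
            if not (0 <= base < mvc):
                raise CalibrationError(
                    f"{ch} calibration degenerate: baseline {base} must be < MVC {mvc}"
                )


def bang_bang_stream(schedule, level: float, dt: float, duration: float) -> list[ControlSample]:
    """Expand an on/off schedule to a per-step excitation stream.

    ``schedule`` is a list of ``(t_on, t_off, side)`` with side 'flexor' or
    'extensor'.  Inside each interval (``t_on <= t < t_off``) the named side
    is at ``level``; outside, zero.  At most one side is active per sample;
    when intervals of opposite sides overlap, the later-starting one wins.
    """
    if not 0 < level <= 1:
        raise InputValidationError(f"bang-bang level must be in (0, 1], got {level}")
    if not (dt > 0 and duration > 0):
        raise InputValidationError("dt and duration must be positive")
    per_side: dict[str, list[tuple[float, float]]] = {"flexor": [], "extensor": []}
    for i, (t_on, t_off, side) in enumerate(schedule):
        if side not in per_side:
            raise InputValidationError(f"schedule row {i}: side must be flexor|extensor")
        if not (np.isfinite(t_on) and np.isfinite(t_off) and t_on < t_off):
            raise InputValidationError(f"schedule row {i}: need t_on < t_off")
        per_side[side].append((float(t_on), float(t_off)))
    for side, ivals in per_side.items():
        ivals.sort()
        for (a0, b0), (a1, _) in zip(ivals, ivals[1:]):
            if a1 < b0:
                raise InputValidationError(f"overlapping {side} intervals at t={a1}")

    n = round(duration / dt) + 1
    times = np.arange(n) * dt
    samples = []
    for t in times:
        u_f = u_e = 0.0
        winner_start = -np.inf
        for side, ivals in per_side.items():
            for t_on, t_off in ivals:
                if t_on <= t < t_off and t_on >= winner_start:
                    winner_start = t_on
                    u_f = level if side == "flexor" else 0.0
                    u_e = level if side == "extensor" else 0.0
        samples.append(ControlSample(u_f=u_f, u_e=u_e))
    return samples


def synthesize_raw_emg(activation_trace, p: EmgChainParams) -> np.ndarray:
    """Raw surface-EMG-like voltage: activation-modulated Gaussian noise.

    The instantaneous noise standard deviation is ``gain * activation``, so
    the RMS of the raw signal tracks the activation level.  Seeded and
    reproducible.
    """
    a = np.asarray(activation_trace, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise InputValidationError("activation trace values must lie in [0, 1]")
    rng = np.random.default_rng(p.noise_seed)
    return p.gain * a * rng.standard_normal(a.shape)


def linear_envelope(raw, p: EmgChainParams) -> np.ndarray:
    """Full-wave rectification followed by a first-order low-pass at f_env.

    The filter is the exact zero-order-hold discretization of a unity-DC-gain
    RC stage with time constant 1/(2*pi*f_env); output is non-negative.
    """
    x = np.abs(np.asarray(raw, dtype=float))
    if not np.all(np.isfinite(x)):
        raise InputValidationError("raw trace must be finite")
    tau = 1.0 / (2.0 * np.pi * p.f_env)
    alpha = 1.0 - np.exp(-1.0 / (p.fs_raw * tau))
    from scipy.signal import lfilter

    y = lfilter([alpha], [1.0, alpha - 1.0], x)
    return np.asarray(y)


def adc_quantize(trace, p: EmgChainParams) -> np.ndarray:
    """Clip to [0, v_ref] and round to the nearest of 2**adc_bits levels.

    Returned in volts (level * v_ref / (2**adc_bits - 1)); idempotent.
    """
    x = np.clip(np.asarray(trace, dtype=float), 0.0, p.v_ref)
    n_levels = 2**p.adc_bits - 1
    return np.round(x / p.v_ref * n_levels) / n_levels * p.v_ref


def emg_to_excitation(
    env_f,
    env_e,
    cal: Calibration,
    fs_in: float,
    dt_out: float,
) -> list[ControlSample]:
    """Normalize two envelope channels into a ControlSample stream.

    Per channel ``u = clip((env - baseline) / (mvc - baseline), 0, 1)``;
    the normalized signals are resampled to the simulation rate by averaging
    the input samples falling inside each output interval.  Co-activation is
    preserved: both channels may be nonzero simultaneously.
    """
    env_f = np.asarray(env_f, dtype=float)
    env_e = np.asarray(env_e, dtype=float)
    if env_f.shape != env_e.shape or env_f.ndim != 1:
        raise InputValidationError("envelope channels must be 1-D and equally long")
    if not (fs_in > 0 and dt_out > 0):
        raise InputValidationError("fs_in and dt_out must be positive")
    u_f = np.clip((env_f - cal.baseline_f) / (cal.mvc_f - cal.baseline_f), 0.0, 1.0)
    u_e = np.clip((env_e - cal.baseline_e) / (cal.mvc_e - cal.baseline_e), 0.0, 1.0)
    t_in = np.arange(env_f.size) / fs_in
    n_out = int(np.floor(t_in[-1] / dt_out)) + 1 if env_f.size else 0
    samples = []
    for k in range(n_out):
        lo, hi = k * dt_out, (k + 1) * dt_out
        mask = (t_in >= lo) & (t_in < hi)
        if not mask.any():  # output grid finer than input: hold nearest earlier sample
            idx = np.searchsorted(t_in, lo, side="right") - 1
            mask = np.zeros_like(t_in, dtype=bool)
            mask[max(idx, 0)] = True
        samples.append(ControlSample(u_f=float(u_f[mask].mean()), u_e=float(u_e[mask].mean())))
    return samples
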