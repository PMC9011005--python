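"""Event-level data model for pulse sequences.

All times are seconds in the object model.  Event times are quantized to
fixed raster times: 1 us for RF envelopes, ADC timing and delays, 10 us for
gradient ramp segments.  RF amplitudes are in Hz (gamma * B1), gradient
amplitudes in Hz/m (gamma * G), following the Pulseq unit convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RF_RASTER = 1e-6  # s, also the ADC/delay/block raster
GRAD_RASTER = 1e-5  # s

RF_USE_EXCITATION = "excitation"
RF_USE_REFOCUSING = "refocusing"
RF_USE_INVERSION = "inversion"
RF_USES = (RF_USE_EXCITATION, RF_USE_REFOCUSING, RF_USE_INVERSION)


class SequenceError(ValueError):
    """Invalid sequence, event or timing construction."""


class InfeasibleTimingError(SequenceError):
    """Requested nominal intervals cannot be realized by the event timeline."""


def quantize_time(t: float, raster: float = RF_RASTER) -> float:
    """Round a time to the raster grid (round-half-up)."""
    n = np.floor(t / raster + 0.5)
    return float(n) * raster


def _us(t: float) -> int:
    """Time in integer microseconds (round-half-up); raises if off-raster."""
    n = int(np.floor(t * 1e6 + 0.5))
    if abs(t * 1e6 - n) > 1e-3:
        raise SequenceError(f"time {t!r} s is not on the 1 us raster")
    return n


@dataclass
class RFEvent:
    """An RF pulse: complex envelope (Hz) sampled on the RF raster.

    ``flip_angle`` must equal 2*pi * integral |envelope| dt; the envelope is
    piecewise-constant over raster intervals so the integral is an exact sum.
    ``center_offset`` is the time of the pulse center within the event
    (after ``delay``); the hard-pulse simulator applies the whole rotation
    there.
    """

    waveform: np.ndarray  # complex, Hz, sampled at RF_RASTER
    duration: float
    flip_angle: float
    phase_offset: float = 0.0
    center_offset: float | None = None
    use: str = RF_USE_EXCITATION
    freq_offset: float = 0.0
    delay: float = 0.0
    slice_index: int | None = None

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=complex)
        if self.duration <= 0:
            raise SequenceError("RF duration must be > 0")
        if self.use not in RF_USES:
            raise SequenceError(f"unknown RF use tag {self.use!r}")
        if self.center_offset is None:
            self.center_offset = self.duration / 2.0
        if not (0.0 <= self.center_offset <= self.duration):
            raise SequenceError("RF center_offset outside [0, duration]")
        integral = 2.0 * np.pi * float(np.sum(np.abs(self.waveform))) * RF_RASTER
        if integral > 0 and abs(integral - self.flip_angle) > 1e-9 * max(
            1.0, abs(self.flip_angle)
        ):
            raise SequenceError(
                f"flip_angle {self.flip_angle} inconsistent with envelope "
                f"integral {integral}"
            )

    @property
    def end(self) -> float:
        return self.delay + self.duration

    @property
    def center_time(self) -> float:
        """Pulse center relative to block start."""
        return self.delay + self.center_offset

    @property
    def peak_amplitude(self) -> float:
        return float(np.max(np.abs(self.waveform)))

    @property
    def power_integral(self) -> float:
        """integral |b1(t)|^2 dt over the pulse, in Hz^2 * s."""
        return float(np.sum(np.abs(self.waveform) ** 2)) * RF_RASTER


def make_rf(
    flip_angle: float,
    duration: float,
    phase: float = 0.0,
    use: str = RF_USE_EXCITATION,
    freq_offset: float = 0.0,
    delay: float = 0.0,
    shape: str = "block",
    tbw: float = 4.0,
) -> RFEvent:
    """Build a symmetric RF pulse scaled to the requested flip angle.

    ``shape`` is 'block' (constant envelope) or 'sinc' (Hamming-apodized
    sinc with time-bandwidth product ``tbw``).  The pulse center is at
    duration/2 for both shapes.
    """
    duration = quantize_time(duration)
    n = int(round(duration / RF_RASTER))
    if n < 1:
        raise SequenceError("RF duration shorter than the RF raster")
    if shape == "block":
        env = np.ones(n)
    elif shape == "sinc":
        t = (np.arange(n) + 0.5) / n - 0.5  # in [-1/2, 1/2)
        env = np.sinc(tbw * t) * np.hamming(n)
    else:
        raise SequenceError(f"unknown RF shape {shape!r}")
    scale = flip_angle / (2.0 * np.pi * np.sum(np.abs(env)) * RF_RASTER)
    wf = scale * env.astype(complex)
    flip = 2.0 * np.pi * float(np.sum(np.abs(wf))) * RF_RASTER
    return RFEvent(
        waveform=wf,
        duration=duration,
        flip_angle=flip,
        phase_offset=phase,
        use=use,
        freq_offset=freq_offset,
        delay=quantize_time(delay),
    )


def rf_bandwidth(rf: RFEvent, shape: str = "block", tbw: float = 4.0) -> float:
    """Nominal bandwidth (Hz) used for slice-gradient calibration."""
    if shape == "sinc":
        return tbw / rf.duration
    return 1.0 / rf.duration


@dataclass
class GradEvent:
    """Trapezoidal gradient on one axis (plateau amplitude in Hz/m)."""

    axis: str
    amplitude: float
    rise_time: float
    flat_time: float
    fall_time: float
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y", "z"):
            raise SequenceError(f"unknown gradient axis {self.axis!r}")
        if self.rise_time < 0 or self.fall_time < 0 or self.flat_time < 0:
            raise SequenceError("gradient segment times must be >= 0")
        for name in ("rise_time", "flat_time", "fall_time", "delay"):
            setattr(self, name, quantize_time(getattr(self, name), GRAD_RASTER))

    @property
    def duration(self) -> float:
        return self.rise_time + self.flat_time + self.fall_time

    @property
    def end(self) -> float:
        return self.delay + self.duration

    @property
    def area(self) -> float:
        """Hz*s/m = m^-1 of k-space traversal."""
        return self.amplitude * (
            self.flat_time + self.rise_time / 2.0 + self.fall_time / 2.0
        )

    def area_until(self, t):
        """Area swept from block start up to block-relative time(s) ``t``."""
        tau = np.clip(np.asarray(t, dtype=float) - self.delay, 0.0, self.duration)
        r, f, fl, a = self.rise_time, self.fall_time, self.flat_time, self.amplitude
        out = np.zeros_like(tau)
        if r > 0:
            tr = np.minimum(tau, r)
            out += a * tr * tr / (2.0 * r)
        out += a * np.clip(tau - r, 0.0, fl)
        if f > 0:
            tf = np.clip(tau - r - fl, 0.0, f)
            out += a * (tf - tf * tf / (2.0 * f))
        return out if out.ndim else float(out)

    def area_between(self, t0: float, t1: float) -> float:
        return float(self.area_until(t1) - self.area_until(t0))


def trap_for_area(
    axis: str,
    area: float,
    rise_time: float = 1e-4,
    flat_time: float = 2e-4,
    fall_time: float = 1e-4,
    delay: float = 0.0,
) -> GradEvent:
    """Trapezoid of fixed shape scaled to a target area (Hz*s/m)."""
    denom = flat_time + rise_time / 2.0 + fall_time / 2.0
    return GradEvent(
        axis=axis,
        amplitude=area / denom,
        rise_time=rise_time,
        flat_time=flat_time,
        fall_time=fall_time,
        delay=delay,
    )


@dataclass
class AdcEvent:
    """A readout window of ``num_samples`` samples spaced ``dwell_time``.

    Samples are taken at block-relative times delay + j*dwell, so for even
    ``num_samples`` the sample j = num/2 sits exactly at the window's
    temporal center delay + num*dwell/2 (where spin echoes are aligned).
    ``slice_index`` and ``pe_line`` are acquisition annotations; they are not
    serialized and can be re-derived from the event timeline.
    """

    num_samples: int
    dwell_time: float
    delay: float = 0.0
    echo_index: int = 1
    freq: float = 0.0
    phase: float = 0.0
    slice_index: int | None = None
    pe_line: int | None = None

    def __post_init__(self) -> None:
        if self.num_samples < 1:
            raise SequenceError("ADC needs at least one sample")
        if self.echo_index < 1:
            raise SequenceError("echo_index is 1-based")
        if self.dwell_time <= 0:
            raise SequenceError("dwell_time must be > 0")
        self.delay = quantize_time(self.delay)

    @property
    def duration(self) -> float:
        return self.num_samples * self.dwell_time

    @property
    def end(self) -> float:
        return self.delay + self.duration

    @property
    def center_time(self) -> float:
        """Temporal center of the window, relative to block start."""
        return self.delay + self.duration / 2.0

    @property
    def sample_times(self) -> np.ndarray:
        return self.delay + np.arange(self.num_samples) * self.dwell_time


@dataclass
class Block:
    """One sequence block: at most one RF, one gradient per axis, one ADC,
    plus an optional pure delay that can pad the block duration."""

    rf: RFEvent | None = None
    gx: GradEvent | None = None
    gy: GradEvent | None = None
    gz: GradEvent | None = None
    adc: AdcEvent | None = None
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise SequenceError("block delay must be >= 0")
        self.delay = quantize_time(self.delay)
        if self.gx is not None and self.gx.axis != "x":
            raise SequenceError("gx event must be on axis x")
        if self.gy is not None and self.gy.axis != "y":
            raise SequenceError("gy event must be on axis y")
        if self.gz is not None and self.gz.axis != "z":
            raise SequenceError("gz event must be on axis z")

    @property
    def duration(self) -> float:
        ends = [self.delay]
        for ev in (self.rf, self.gx, self.gy, self.gz, self.adc):
            if ev is not None:
                ends.append(ev.end)
        return round(max(ends) * 1e6) * 1e-6

    def gradients(self):
        return [g for g in (self.gx, self.gy, self.gz) if g is not None]

    def grad_area_until(self, axis: str, t) -> float:
        g = {"x": self.gx, "y": self.gy, "z": self.gz}[axis]
        if g is None:
            t = np.asarray(t, dtype=float)
            z = np.zeros_like(t)
            return z if z.ndim else 0.0
        return g.area_until(t)


def delay_block(duration: float) -> Block:
    return Block(delay=duration)
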