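"""Isochromat Bloch simulator with exact piecewise closed-form evolution.

The engine uses the hard-pulse approximation: each RF pulse is an
instantaneous rotation applied at the pulse center (no relaxation during
RF), and between pulses every isochromat evolves under free precession
with exact exponential relaxation and gradient phase integrated
analytically over the trapezoid segments -- there is no time-stepping
error anywhere.  Refocusing and inversion pulses are full physical
rotations (a 180 deg pulse inverts the recovering longitudinal
magnetization).  Ideal spoiling zeroes the transverse magnetization
immediately before every excitation pulse, the closed-form equivalent of
the crusher schemes used by spin-echo sequences.

Rotation convention: a pulse of flip angle a and phase 0 rotates +z
toward -y (mxy = -i for a 90 deg pulse on equilibrium); refocusing pulses
are applied with phase pi/2 relative to excitation (CPMG) so echo trains
are stable.

Slices are ideal and independent: for each slice, only that slice's RF
and ADC events act on the (2D) phantom, while all gradients apply.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .events import (
    RF_USE_EXCITATION,
    SequenceError,
)
from .phantoms import Phantom, isochromat_arrays
from .sequence import Sequence, annotate_readouts


@dataclass
class Magnetization:
    """Single-isochromat state: complex transverse + longitudinal parts."""

    mxy: complex = 0.0
    mz: float = 1.0
    m0: float = 1.0


def apply_rf(m: Magnetization, flip: float, phase: float = 0.0) -> Magnetization:
    """Instantaneous rotation by ``flip`` about the transverse axis at
    angle ``phase``; preserves the magnetization norm."""
    c2 = np.cos(flip / 2.0) ** 2
    s2 = np.sin(flip / 2.0) ** 2
    sa = np.sin(flip)
    eip = np.exp(1j * phase)
    mxy = c2 * m.mxy + s2 * eip * eip * np.conj(m.mxy) - 1j * sa * eip * m.mz
    mz = m.mz * np.cos(flip) + sa * np.imag(m.mxy * np.conj(eip))
    return Magnetization(mxy=complex(mxy), mz=float(mz), m0=m.m0)


def free_precess(
    m: Magnetization, dt: float, t1: float, t2: float, dphi: float = 0.0
) -> Magnetization:
    """Relaxation + precession over ``dt``: mxy decays with T2 and gains
    phase -dphi; mz recovers toward m0 with T1."""
    if dt < 0:
        raise SequenceError("dt must be >= 0")
    e2 = np.exp(-dt / t2)
    e1 = np.exp(-dt / t1)
    return Magnetization(
        mxy=m.mxy * e2 * np.exp(-1j * dphi),
        mz=m.m0 + (m.mz - m.m0) * e1,
        m0=m.m0,
    )


@dataclass
class RawKSpace:
    """Raw signal: complex samples (samples, channels, readouts) plus
    per-readout acquisition metadata, mirroring the deposited layout."""

    samples: np.ndarray
    meta: dict  # arrays: slice, pe_line, echo, time, contrast
    dwell_time: float
    attrs: dict = field(default_factory=dict)

    @property
    def n_readouts(self) -> int:
        return self.samples.shape[2]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("raw", data=self.samples)
            g = f.create_group("readout_meta")
            for k, v in self.meta.items():
                g.create_dataset(k, data=np.asarray(v))
            f.attrs["dwell_time"] = self.dwell_time
            for k, v in self.attrs.items():
                if v is None:
                    continue
                f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "RawKSpace":
        with h5py.File(path, "r") as f:
            meta = {k: f["readout_meta"][k][:] for k in f["readout_meta"]}
            attrs = {k: v for k, v in f.attrs.items() if k != "dwell_time"}
            return cls(
                samples=f["raw"][:],
                meta=meta,
                dwell_time=float(f.attrs["dwell_time"]),
                attrs=attrs,
            )


def concat_raw(raws: list[RawKSpace], contrasts: list[float]) -> RawKSpace:
    """Concatenate per-sequence acquisitions (e.g. the 10 TI runs) along
    the readout axis, tagging each readout with its contrast value."""
    samples = np.concatenate([r.samples for r in raws], axis=2)
    meta: dict = {}
    for key in raws[0].meta:
        meta[key] = np.concatenate([r.meta[key] for r in raws])
    meta["contrast"] = np.concatenate(
        [np.full(r.n_readouts, c) for r, c in zip(raws, contrasts)]
    )
    return RawKSpace(
        samples=samples,
        meta=meta,
        dwell_time=raws[0].dwell_time,
        attrs=dict(raws[0].attrs),
    )


# ---------------------------------------------------------------------------
# compiled engine

class _Free:
    __slots__ = ("dt", "ax", "ay")

    def __init__(self):
        self.dt = 0.0
        self.ax = 0.0
        self.ay = 0.0


def _compile_slice(seq: Sequence, s: int):
    """Compile the block timeline into ops for slice ``s``:
    ('free', dt, ax, ay), ('rot', flip, phase, spoil), and
    ('sample', dts, axs, ays, meta)."""
    ops = []
    pend = _Free()

    def flush():
        nonlocal pend
        if pend.dt > 0 or pend.ax != 0 or pend.ay != 0:
            ops.append(("free", pend.dt, pend.ax, pend.ay))
        pend = _Free()

    def advance(block, t0, t1):
        pend.dt += t1 - t0
        pend.ax += float(
            block.grad_area_until("x", t1) - block.grad_area_until("x", t0)
        )
        pend.ay += float(
            block.grad_area_until("y", t1) - block.grad_area_until("y", t0)
        )

    for t_abs, b in zip(seq.block_starts(), seq.blocks):
        dur = b.duration
        rf = b.rf
        adc = b.adc
        rf_active = rf is not None and (rf.slice_index in (None, s))
        adc_active = adc is not None and (adc.slice_index in (None, s))
        if not rf_active and not adc_active:
            advance(b, 0.0, dur)
            continue
        t_cursor = 0.0
        marks = []
        if rf_active:
            marks.append((rf.center_time, "rf"))
        if adc_active:
            marks.append((adc.delay, "adc"))
        marks.sort()
        for t, kind in marks:
            if kind == "rf":
                advance(b, t_cursor, t)
                t_cursor = t
                flush()
                ops.append(
                    (
                        "rot",
                        rf.flip_angle,
                        rf.phase_offset,
                        rf.use == RF_USE_EXCITATION,
                    )
                )
            else:
                # sample phases/decays are relative to the state at the
                # current cursor; do not advance the cursor (the trailing
                # 'advance' covers the whole remaining block)
                flush()
                dts = adc.sample_times - t_cursor
                axs = np.asarray(b.grad_area_until("x", adc.sample_times)) - float(
                    b.grad_area_until("x", t_cursor)
                )
                ays = np.asarray(b.grad_area_until("y", adc.sample_times)) - float(
                    b.grad_area_until("y", t_cursor)
                )
                ops.append(
                    (
                        "sample",
                        dts,
                        axs,
                        ays,
                        {
                            "slice": s,
                            "pe_line": adc.pe_line,
                            "echo": adc.echo_index,
                            "time": float(t_abs + adc.center_time),
                        },
                    )
                )
        advance(b, t_cursor, dur)
    flush()
    return ops


def simulate(
    seq: Sequence,
    ph: Phantom,
    sensitivities: list[np.ndarray] | None = None,
    seed: int = 0,
) -> RawKSpace:
    """Run the event timeline against a phantom and collect raw k-space.

    ``sensitivities``: optional per-channel complex maps on the phantom
    grid; default is a single uniform channel.  The simulation itself is
    deterministic; ``seed`` is accepted for interface symmetry with the
    noise-injection step.
    """
    if not seq.has_adc():
        raise SequenceError("sequence has no ADC events")
    if seq.metadata.get("fov") and seq.metadata.get("matrix_n"):
        annotate_readouts(seq)

    pd, t1, t2, x, y = isochromat_arrays(ph)
    if pd.size == 0:
        warnings.warn("empty phantom: simulated signal is identically zero")
    if sensitivities is None:
        coil = [np.ones_like(pd, dtype=complex)]
    else:
        sel = ph.pd_map > 0
        coil = [np.asarray(c, dtype=complex)[sel] for c in sensitivities]
    weights = [pd * c for c in coil]

    slices = sorted(
        {
            b.adc.slice_index if b.adc.slice_index is not None else 0
            for b in seq.blocks
            if b.adc is not None
        }
    )

    readouts = []  # (time, meta, samples[n_samp, n_ch])
    for s in slices:
        mxy = np.zeros(pd.shape, dtype=complex)
        mz = np.ones(pd.shape)
        inv_t1 = 1.0 / t1 if pd.size else t1
        inv_t2 = 1.0 / t2 if pd.size else t2
        for op in _compile_slice(seq, s):
            kind = op[0]
            if kind == "free":
                _, dt, ax, ay = op
                phase = 2.0 * np.pi * (ax * x + ay * y)
                mxy = mxy * np.exp(-dt * inv_t2 - 1j * phase)
                mz = 1.0 + (mz - 1.0) * np.exp(-dt * inv_t1)
            elif kind == "rot":
                _, flip, phase, spoil = op
                if spoil:
                    mxy = np.zeros_like(mxy)
                c2 = np.cos(flip / 2.0) ** 2
                s2 = np.sin(flip / 2.0) ** 2
                sa = np.sin(flip)
                eip = np.exp(1j * phase)
                mxy_new = (
                    c2 * mxy + s2 * eip * eip * np.conj(mxy) - 1j * sa * eip * mz
                )
                mz = mz * np.cos(flip) + sa * np.imag(mxy * np.conj(eip))
                mxy = mxy_new
            else:
                _, dts, axs, ays, meta = op
                # (n_samp, n_iso) propagator from the current state
                phase = 2.0 * np.pi * (
                    np.outer(axs, x) + np.outer(ays, y)
                )
                prop = np.exp(-np.outer(dts, inv_t2) - 1j * phase)
                state = prop * mxy[None, :]
                sig = np.stack([state @ w for w in weights], axis=1)
                readouts.append((meta["time"], meta, sig))

    readouts.sort(key=lambda r: r[0])
    n_samp = readouts[0][2].shape[0]
    if any(r[2].shape[0] != n_samp for r in readouts):
        raise SequenceError("readouts with mixed sample counts")
    samples = np.stack([r[2] for r in readouts], axis=2)

    te_list = seq.metadata.get("te_list")
    meta = {
        "slice": np.array([r[1]["slice"] for r in readouts], dtype=int),
        "pe_line": np.array([r[1]["pe_line"] for r in readouts], dtype=int),
        "echo": np.array([r[1]["echo"] for r in readouts], dtype=int),
        "time": np.array([r[1]["time"] for r in readouts]),
    }
    if te_list is not None:
        meta["contrast"] = np.array([te_list[e - 1] for e in meta["echo"]])
    else:
        meta["contrast"] = np.full(len(readouts), np.nan)

    dwell = next(b.adc.dwell_time for b in seq.blocks if b.adc is not None)
    attrs = {
        "sequence_name": seq.metadata.get("name", ""),
        "matrix_n": seq.metadata.get("matrix_n"),
        "fov": seq.metadata.get("fov"),
        "n_slices": seq.metadata.get("n_slices", 1),
        "quantitative": bool(seq.metadata.get("quantitative", False)),
    }
    return RawKSpace(samples=samples, meta=meta, dwell_time=dwell, attrs=attrs)


def steady_state_prep(seq: Sequence, n_dummy: int) -> Sequence:
    """Prepend ``n_dummy`` copies of the first TR with ADCs removed, so
    sampling starts from the periodic steady state."""
    if n_dummy < 0:
        raise SequenceError("n_dummy must be >= 0")
    if n_dummy == 0:
        return seq
    tr = seq.metadata.get("tr")
    if tr is None:
        raise SequenceError("steady_state_prep requires tr metadata")
    tr_us = round(tr * 1e6)
    acc = 0
    prefix = []
    for b in seq.blocks:
        if acc >= tr_us:
            break
        from dataclasses import replace as _rep

        nb = _rep(b)
        if nb.adc is not None:
            # keep the block duration, drop the sampling
            dur = nb.duration
            nb = _rep(nb, adc=None, delay=max(nb.delay, dur))
        prefix.append(nb)
        acc += round(b.duration * 1e6)
    if acc != tr_us:
        raise SequenceError("block boundaries do not tile the nominal TR")
    blocks = [b for _ in range(n_dummy) for b in prefix] + list(seq.blocks)
    out = Sequence(blocks=blocks, metadata=dict(seq.metadata))
    return annotate_readouts(out) if seq.metadata.get("fov") else out
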