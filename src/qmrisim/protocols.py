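"""Protocol presets: IRSE, TSE, multi-echo TSE and the 10-TI T1 protocol.

Each generator lays out an explicit event timeline per repetition.  Within
one TR the slices are excited sequentially in a randomized order (recorded
with its seed), each in a slot of TR/n_slices; echo timing is computed
center-to-center so the audited TE/TI/TR land exactly on the nominal
values.

Spin-echo segment anatomy (times are pulse/echo centers)::

    [inversion]---TI---[90 exc]--[encode]--[180 ref]--...--[ADC echo]
                                  TE/2 exc->ref          TE/2 ref->echo

Turbo trains repeat [180 ref]-[PE blip]-[ADC]-[PE rewind] every
``echo_spacing`` seconds; the phase-encode polarity bookkeeping accounts
for the phase conjugation of each refocusing pulse.  The readout prephaser
area is chosen so the gradient-echo center coincides with the spin-echo
center at the ADC temporal center.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .events import (
    AdcEvent,
    Block,
    GradEvent,
    InfeasibleTimingError,
    SequenceError,
    delay_block,
    make_rf,
    trap_for_area,
    RF_USE_EXCITATION,
    RF_USE_INVERSION,
    RF_USE_REFOCUSING,
)
from .sequence import Sequence, annotate_readouts, slice_positions

# fixed micro-timing of the building blocks (seconds)
RF_DUR = 1.0e-3          # symmetric RF pulse duration
GZ_RISE = 1.0e-4         # slice-gradient ramp
ENC_RISE = 1.0e-4        # encode/blip trapezoid ramps
ENC_FLAT = 2.0e-4
ADC_RISE = 1.0e-4        # readout-gradient ramp; ADC delay equals this


class ConfigurationError(SequenceError):
    pass


@dataclass
class ProtocolParams:
    """Parameter set for one protocol (Table-style acquisition values)."""

    name: str = "custom"
    kind: str = "irse"  # irse | tse | multiecho_tse | irse_t1map
    fov: float = 0.25
    matrix_n: int = 128
    n_slices: int = 1
    slice_thickness: float = 0.005
    tr: float = 4.5
    te: float = 0.01
    ti: float | None = None
    flip_excitation: float = np.pi / 2
    flip_refocus: float = np.pi
    etl: int = 1
    center_echo: int = 2
    echo_spacing: float | None = None
    ti_list: list[float] | None = None
    te_list: list[float] | None = None
    slice_order_seed: int = 0
    adc_dwell: float = 2.0e-5
    rf_shape: str = "block"
    rf_tbw: float = 4.0
    quantitative: bool = False

    def __post_init__(self) -> None:
        if self.matrix_n <= 0:
            raise ConfigurationError("matrix_n must be > 0")
        if self.etl < 1:
            raise ConfigurationError("etl must be >= 1")
        if self.ti_list is not None and np.any(np.diff(self.ti_list) <= 0):
            raise ConfigurationError("ti_list must be strictly increasing")
        if self.te_list is not None and len(self.te_list) > 1:
            steps = np.diff(self.te_list)
            if not np.allclose(steps, steps[0], atol=1e-9):
                raise ConfigurationError(
                    "te_list must be an arithmetic progression"
                )
            if self.echo_spacing is None:
                self.echo_spacing = float(steps[0])
            elif abs(self.echo_spacing - steps[0]) > 1e-9:
                raise ConfigurationError(
                    "te_list step does not match echo_spacing"
                )


@dataclass
class SliceOrder:
    permutation: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        p = np.asarray(self.permutation)
        if sorted(p.tolist()) != list(range(len(p))):
            raise ConfigurationError("not a valid slice permutation")
        self.permutation = p


def random_slice_order(n_slices: int, seed: int = 0) -> SliceOrder:
    """Uniformly random slice excitation order, reproducible from seed."""
    if n_slices < 1:
        raise ConfigurationError("n_slices must be >= 1")
    rng = np.random.default_rng(seed)
    return SliceOrder(permutation=rng.permutation(n_slices), seed=seed)


@dataclass
class PhaseEncodeOrder:
    """PE-line index per (echo, excitation); covers every line exactly once."""

    table: np.ndarray  # shape (n_echoes, n_excitations)

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=int)
        flat = sorted(t.ravel().tolist())
        if flat != list(range(t.size)):
            raise ConfigurationError(
                "phase-encode table must cover each line exactly once"
            )
        self.table = t

    @property
    def n_echoes(self) -> int:
        return self.table.shape[0]

    @property
    def n_excitations(self) -> int:
        return self.table.shape[1]


def tse_pe_order(matrix_n: int, etl: int, center_echo: int) -> PhaseEncodeOrder:
    """Centric-banded TSE phase-encode order.

    k-space is split into ``etl`` contiguous bands of matrix_n/etl lines;
    the band containing the center line (index matrix_n//2) is acquired at
    ``center_echo`` (1-based), the others by cyclic rotation.
    """
    if matrix_n % etl != 0:
        raise ConfigurationError("matrix_n must be divisible by etl")
    if not (1 <= center_echo <= etl):
        raise ConfigurationError("center_echo must be in 1..etl")
    band = matrix_n // etl
    center_band = (matrix_n // 2) // band
    table = np.empty((etl, band), dtype=int)
    for e in range(1, etl + 1):
        b = (center_band + (e - center_echo)) % etl
        table[e - 1] = np.arange(b * band, (b + 1) * band)
    return PhaseEncodeOrder(table=table)


# ---------------------------------------------------------------------------
# timeline builder


class _Timeline:
    """Accumulates blocks; all bookkeeping in integer microseconds."""

    def __init__(self):
        self.blocks: list[Block] = []
        self.t_us = 0

    def add(self, block: Block) -> None:
        self.blocks.append(block)
        self.t_us += round(block.duration * 1e6)

    def delay(self, dur_s: float, interval: str) -> None:
        dur_us = round(dur_s * 1e6)
        if dur_us < 0:
            raise InfeasibleTimingError(
                f"negative delay while realizing {interval} "
                f"({dur_us} us short)"
            )
        if dur_us > 0:
            self.add(delay_block(dur_us * 1e-6))

    def pad_to(self, t_target_us: int, interval: str) -> None:
        self.delay((t_target_us - self.t_us) * 1e-6, interval)


def _slice_rf_block(
    params: ProtocolParams, flip: float, phase: float, use: str, z: float
) -> Block:
    bw = (params.rf_tbw if params.rf_shape == "sinc" else 1.0) / RF_DUR
    gz_amp = bw / params.slice_thickness if params.n_slices > 1 else 0.0
    rf = make_rf(
        flip,
        RF_DUR,
        phase=phase,
        use=use,
        freq_offset=gz_amp * z,
        delay=GZ_RISE,
        shape=params.rf_shape,
        tbw=params.rf_tbw,
    )
    # gz is kept (zero-amplitude for single-slice) so timing is uniform
    gz = GradEvent(
        axis="z",
        amplitude=gz_amp,
        rise_time=GZ_RISE,
        flat_time=RF_DUR,
        fall_time=GZ_RISE,
    )
    return Block(rf=rf, gz=gz)


def _rf_block_halfspan() -> float:
    """Time from RF-block start (or end) to the pulse center."""
    return GZ_RISE + RF_DUR / 2.0


def _readout_block(params: ProtocolParams, echo_index: int) -> Block:
    n = params.matrix_n
    dwell = params.adc_dwell
    g_read = 1.0 / (params.fov * dwell)
    gx = GradEvent(
        axis="x",
        amplitude=g_read,
        rise_time=ADC_RISE,
        flat_time=n * dwell,
        fall_time=ADC_RISE,
    )
    adc = AdcEvent(
        num_samples=n, dwell_time=dwell, delay=ADC_RISE, echo_index=echo_index
    )
    return Block(gx=gx, adc=adc)


def _prephaser_area(params: ProtocolParams) -> float:
    g_read = 1.0 / (params.fov * params.adc_dwell)
    return g_read * (ADC_RISE / 2.0 + params.matrix_n * params.adc_dwell / 2.0)


def _pe_area(params: ProtocolParams, line: int) -> float:
    return (line - params.matrix_n // 2) / params.fov


def _enc_dur() -> float:
    return 2 * ENC_RISE + ENC_FLAT


def _spin_echo_readout_train(
    tl: _Timeline,
    params: ProtocolParams,
    z: float,
    exc_center_us: int,
    esp: float,
    lines_per_echo: list[int],
) -> None:
    """Emit a CPMG train: refocusing pulses every ``esp`` with one readout
    per echo; ``lines_per_echo[e]`` is the PE line of echo e+1."""
    half_rf = _rf_block_halfspan()
    n_read_half = ADC_RISE + params.matrix_n * params.adc_dwell / 2.0
    esp_us = round(esp * 1e6)
    for e, line in enumerate(lines_per_echo, start=1):
        ref_center_us = exc_center_us + round((e - 0.5) * esp * 1e6)
        tl.pad_to(ref_center_us - round(half_rf * 1e6), f"echo spacing (echo {e})")
        tl.add(
            _slice_rf_block(
                params,
                params.flip_refocus,
                np.pi / 2.0,
                RF_USE_REFOCUSING,
                z,
            )
        )
        tl.add(Block(gy=trap_for_area("y", _pe_area(params, line))))
        echo_center_us = exc_center_us + e * esp_us
        tl.pad_to(echo_center_us - round(n_read_half * 1e6), f"TE/2 (echo {e})")
        tl.add(_readout_block(params, echo_index=e))
        tl.add(Block(gy=trap_for_area("y", -_pe_area(params, line))))


def _se_segment(
    tl: _Timeline,
    params: ProtocolParams,
    z: float,
    pe_line: int,
    with_inversion: bool,
) -> None:
    """One single-echo (IR)SE slice segment appended to the timeline."""
    half_rf = _rf_block_halfspan()
    te, ti = params.te, params.ti
    if with_inversion:
        if ti is None:
            raise ConfigurationError("IRSE requires ti")
        tl.add(
            _slice_rf_block(
                params, params.flip_refocus, 0.0, RF_USE_INVERSION, z
            )
        )
        inv_center_us = tl.t_us - round(half_rf * 1e6)
        exc_center_us = inv_center_us + round(ti * 1e6)
        tl.pad_to(exc_center_us - round(half_rf * 1e6), "TI")
    tl.add(
        _slice_rf_block(
            params, params.flip_excitation, 0.0, RF_USE_EXCITATION, z
        )
    )
    exc_center_us = tl.t_us - round(half_rf * 1e6)
    # prephaser (+) and PE (-) together; refocusing conjugation flips both
    tl.add(
        Block(
            gx=trap_for_area("x", _prephaser_area(params)),
            gy=trap_for_area("y", -_pe_area(params, pe_line)),
        )
    )
    ref_center_us = exc_center_us + round(te / 2.0 * 1e6)
    tl.pad_to(ref_center_us - round(half_rf * 1e6), "TE/2 (exc->refocus)")
    tl.add(
        _slice_rf_block(
            params, params.flip_refocus, np.pi / 2.0, RF_USE_REFOCUSING, z
        )
    )
    echo_center_us = exc_center_us + round(te * 1e6)
    n_read_half = ADC_RISE + params.matrix_n * params.adc_dwell / 2.0
    tl.pad_to(echo_center_us - round(n_read_half * 1e6), "TE/2 (refocus->echo)")
    tl.add(_readout_block(params, echo_index=1))
    tl.add(Block(gy=trap_for_area("y", -_pe_area(params, pe_line))))


def _tr_slots(params: ProtocolParams) -> tuple[int, int]:
    tr_us = round(params.tr * 1e6)
    slot_us = (tr_us // params.n_slices) // 10 * 10
    return tr_us, slot_us


def _metadata(params: ProtocolParams, **extra) -> dict:
    md = {
        "name": params.name,
        "fov": params.fov,
        "matrix_n": params.matrix_n,
        "n_slices": params.n_slices,
        "slice_thickness": params.slice_thickness,
        "tr": params.tr,
        "te": params.te,
        "ti": params.ti,
        "quantitative": params.quantitative,
    }
    md.update(extra)
    return md


def make_irse(params: ProtocolParams) -> Sequence:
    """Multi-slice inversion-recovery spin echo, one PE line per TR."""
    if params.etl != 1:
        raise ConfigurationError("IRSE uses etl = 1")
    if params.ti is None:
        raise ConfigurationError("IRSE requires ti")
    tr_us, slot_us = _tr_slots(params)
    order = random_slice_order(params.n_slices, params.slice_order_seed)
    zpos = slice_positions(params.n_slices, params.slice_thickness)
    tl = _Timeline()
    for line in range(params.matrix_n):
        tr_start = tl.t_us
        for k, s in enumerate(order.permutation):
            seg_start = tr_start + k * slot_us
            tl.pad_to(seg_start, "slice slot")
            _se_segment(tl, params, float(zpos[s]), line, with_inversion=True)
            if tl.t_us > seg_start + slot_us:
                raise InfeasibleTimingError(
                    f"slice segment ({(tl.t_us - seg_start) / 1e3:.1f} ms) "
                    f"exceeds TR/n_slices slot ({slot_us / 1e3:.1f} ms); "
                    "TI + TE too long for TR"
                )
        tl.pad_to(tr_start + tr_us, "TR")
    seq = Sequence(blocks=tl.blocks, metadata=_metadata(params))
    return annotate_readouts(seq)


def make_tse(params: ProtocolParams) -> Sequence:
    """Multi-slice turbo spin echo with centric-banded phase encoding.

    With etl = 1 this degenerates to a conventional (non-inverted) spin
    echo with the same single-echo timing as :func:`make_irse`.
    """
    if params.matrix_n % params.etl != 0:
        raise ConfigurationError("matrix_n must be divisible by etl")
    esp = params.echo_spacing
    if esp is None:
        center = min(params.center_echo, params.etl)
        esp = params.te / center
    center = min(params.center_echo, params.etl)
    pe = tse_pe_order(params.matrix_n, params.etl, center)
    tr_us, slot_us = _tr_slots(params)
    order = random_slice_order(params.n_slices, params.slice_order_seed)
    zpos = slice_positions(params.n_slices, params.slice_thickness)
    half_rf = _rf_block_halfspan()
    tl = _Timeline()
    for exc in range(pe.n_excitations):
        tr_start = tl.t_us
        for k, s in enumerate(order.permutation):
            seg_start = tr_start + k * slot_us
            tl.pad_to(seg_start, "slice slot")
            tl.add(
                _slice_rf_block(
                    params,
                    params.flip_excitation,
                    0.0,
                    RF_USE_EXCITATION,
                    float(zpos[s]),
                )
            )
            exc_center_us = tl.t_us - round(half_rf * 1e6)
            tl.add(Block(gx=trap_for_area("x", _prephaser_area(params))))
            lines = [int(pe.table[e, exc]) for e in range(params.etl)]
            _spin_echo_readout_train(
                tl, params, float(zpos[s]), exc_center_us, esp, lines
            )
            if tl.t_us > seg_start + slot_us:
                raise InfeasibleTimingError(
                    "echo train exceeds the TR/n_slices slot"
                )
        tl.pad_to(tr_start + tr_us, "TR")
    seq = Sequence(
        blocks=tl.blocks,
        metadata=_metadata(params, echo_spacing=esp, etl=params.etl),
    )
    return annotate_readouts(seq)


def make_multiecho_tse(params: ProtocolParams) -> Sequence:
    """Variable-TE multi-echo TSE: each excitation acquires ONE PE line at
    every echo, so each echo index forms a complete k-space at its own TE."""
    if not params.te_list:
        raise ConfigurationError("multi-echo TSE requires te_list")
    te_list = list(params.te_list)
    esp = params.echo_spacing
    if esp is None:
        esp = te_list[0]
    expected = esp * np.arange(1, len(te_list) + 1)
    if not np.allclose(te_list, expected, atol=1e-9):
        raise ConfigurationError(
            "te_list must be n * echo_spacing for a CPMG train"
        )
    tr_us, slot_us = _tr_slots(params)
    order = random_slice_order(params.n_slices, params.slice_order_seed)
    zpos = slice_positions(params.n_slices, params.slice_thickness)
    half_rf = _rf_block_halfspan()
    tl = _Timeline()
    for line in range(params.matrix_n):
        tr_start = tl.t_us
        for k, s in enumerate(order.permutation):
            seg_start = tr_start + k * slot_us
            tl.pad_to(seg_start, "slice slot")
            tl.add(
                _slice_rf_block(
                    params,
                    params.flip_excitation,
                    0.0,
                    RF_USE_EXCITATION,
                    float(zpos[s]),
                )
            )
            exc_center_us = tl.t_us - round(half_rf * 1e6)
            tl.add(Block(gx=trap_for_area("x", _prephaser_area(params))))
            _spin_echo_readout_train(
                tl,
                params,
                float(zpos[s]),
                exc_center_us,
                esp,
                [line] * len(te_list),
            )
            if tl.t_us > seg_start + slot_us:
                raise InfeasibleTimingError(
                    "multi-echo train exceeds the TR/n_slices slot"
                )
        tl.pad_to(tr_start + tr_us, "TR")
    md = _metadata(
        params, te_list=te_list, echo_spacing=esp, etl=len(te_list)
    )
    md["te"] = te_list[-1]
    seq = Sequence(blocks=tl.blocks, metadata=md)
    return annotate_readouts(seq)


def make_t1_protocol(params: ProtocolParams) -> list[Sequence]:
    """One IRSE sequence per inversion time in ``params.ti_list``."""
    if not params.ti_list:
        raise ConfigurationError("T1 protocol requires a nonempty ti_list")
    seqs = []
    for ti in params.ti_list:
        p = replace(params, ti=float(ti), ti_list=None, kind="irse")
        p.name = f"{params.name}_TI{round(ti * 1000)}"
        try:
            seqs.append(make_irse(p))
        except InfeasibleTimingError as err:
            raise InfeasibleTimingError(
                f"TI = {ti * 1000:g} ms infeasible: {err}"
            ) from err
    return seqs


def make_protocol(params: ProtocolParams):
    """Dispatch on ``params.kind``; returns a Sequence or list of them."""
    kind = params.kind
    if kind == "irse":
        return make_irse(params)
    if kind == "tse":
        return make_tse(params)
    if kind == "multiecho_tse":
        return make_multiecho_tse(params)
    if kind == "irse_t1map":
        return make_t1_protocol(params)
    raise ConfigurationError(f"unknown protocol kind {kind!r}")


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = (
    "irse_acr",
    "tse_acr",
    "irse_t1map",
    "tse_t2map",
    "irse_sim",
    "tse_sim",
)


def load_preset(name: str, scale: int = 1) -> ProtocolParams:
    """Load a named preset, optionally downscaling the matrix by ``scale``
    (timing parameters are preserved; only the matrix shrinks)."""
    if name not in PRESET_NAMES:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    ref = importlib.resources.files("qmrisim.presets").joinpath(f"{name}.yaml")
    cfg = yaml.safe_load(ref.read_text())
    deg = np.pi / 180.0
    cfg["flip_excitation"] = cfg.pop("flip_excitation_deg", 90) * deg
    cfg["flip_refocus"] = cfg.pop("flip_refocus_deg", 180) * deg
    params = ProtocolParams(**cfg)
    if scale > 1:
        if params.matrix_n % scale != 0:
            raise ConfigurationError("matrix_n not divisible by scale")
        params = replace(params, matrix_n=params.matrix_n // scale)
    return params
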