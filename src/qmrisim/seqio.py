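"""Reader/writer for a Pulseq 1.2-dialect ``.seq`` text format.

Sections written: [VERSION], [DEFINITIONS], [BLOCKS], [RF], [TRAP], [ADC],
[DELAYS], [SHAPES].  Units per the Pulseq convention: RF amplitude in Hz,
gradients in Hz/m, RF/ADC/delay times in integer microseconds, ADC dwell in
integer nanoseconds.  Shapes are written uncompressed (explicit samples);
the reader additionally accepts Pulseq run-length-compressed derivative
shapes.  The reader accepts version 1.2.x and 1.3.x headers.

RF table rows carry a trailing ``use`` column (1 = excitation,
2 = refocusing, 3 = inversion); rows without it are classified from flip
angle and timeline order.
"""
from __future__ import annotations

import numpy as np

from .events import (
    AdcEvent,
    Block,
    GradEvent,
    RFEvent,
    RF_RASTER,
    RF_USE_EXCITATION,
    RF_USE_INVERSION,
    RF_USE_REFOCUSING,
    SequenceError,
)
from .sequence import Sequence, annotate_readouts

_USE_CODE = {RF_USE_EXCITATION: 1, RF_USE_REFOCUSING: 2, RF_USE_INVERSION: 3}
_CODE_USE = {v: k for k, v in _USE_CODE.items()}

_SECTIONS = (
    "[VERSION]",
    "[DEFINITIONS]",
    "[BLOCKS]",
    "[RF]",
    "[TRAP]",
    "[ADC]",
    "[DELAYS]",
    "[SHAPES]",
)


class ParseError(SequenceError):
    def __init__(self, msg: str, line_no: int | None = None):
        if line_no is not None:
            msg = f"line {line_no}: {msg}"
        super().__init__(msg)
        self.line_no = line_no


class VersionError(ParseError):
    pass


class FormatError(SequenceError):
    """Sequence cannot be expressed in the file format (e.g. off-raster)."""


def _fmt(x: float) -> str:
    return f"{float(x):.9g}"


def _time_us(t: float, what: str, where: str) -> int:
    n = int(np.floor(t * 1e6 + 0.5))
    if abs(t * 1e6 - n) > 1e-3:
        raise FormatError(f"{what} in {where} is not on the 1 us raster: {t!r} s")
    return n


class _Table:
    """Deduplicating id table keyed by formatted entries (first-use order)."""

    def __init__(self):
        self.entries: list[tuple] = []
        self._index: dict[tuple, int] = {}

    def add(self, key: tuple) -> int:
        if key not in self._index:
            self.entries.append(key)
            self._index[key] = len(self.entries)
        return self._index[key]


def write_seq(seq: Sequence, path) -> None:
    """Write a sequence to a ``.seq`` text file (re-readable by read_seq)."""
    shapes = _Table()
    rf_tab = _Table()
    trap_tab = _Table()
    adc_tab = _Table()
    delay_tab = _Table()
    block_rows = []

    for i, b in enumerate(seq.blocks):
        where = f"block {i + 1}"
        rf_id = gx_id = gy_id = gz_id = adc_id = d_id = 0
        if b.delay > 0:
            d_id = delay_tab.add((_time_us(b.delay, "delay", where),))
        if b.rf is not None:
            rf = b.rf
            amp = rf.peak_amplitude
            if amp <= 0:
                raise FormatError(f"zero-amplitude RF in {where}")
            mag = np.abs(rf.waveform) / amp
            ph = np.mod(np.angle(rf.waveform) / (2 * np.pi), 1.0)
            mag_id = shapes.add(tuple(_fmt(v) for v in mag))
            ph_id = shapes.add(tuple(_fmt(v) for v in ph))
            rf_id = rf_tab.add(
                (
                    _fmt(amp),
                    mag_id,
                    ph_id,
                    _time_us(rf.delay, "RF delay", where),
                    _fmt(rf.freq_offset),
                    _fmt(rf.phase_offset),
                    _USE_CODE[rf.use],
                )
            )
        grads = {}
        for name, g in (("gx", b.gx), ("gy", b.gy), ("gz", b.gz)):
            if g is None:
                continue
            grads[name] = trap_tab.add(
                (
                    _fmt(g.amplitude),
                    _time_us(g.rise_time, "rise", where),
                    _time_us(g.flat_time, "flat", where),
                    _time_us(g.fall_time, "fall", where),
                    _time_us(g.delay, "gradient delay", where),
                )
            )
        gx_id = grads.get("gx", 0)
        gy_id = grads.get("gy", 0)
        gz_id = grads.get("gz", 0)
        if b.adc is not None:
            a = b.adc
            dwell_ns = int(np.floor(a.dwell_time * 1e9 + 0.5))
            if abs(a.dwell_time * 1e9 - dwell_ns) > 1e-3:
                raise FormatError(f"ADC dwell in {where} not on 1 ns raster")
            adc_id = adc_tab.add(
                (
                    a.num_samples,
                    dwell_ns,
                    _time_us(a.delay, "ADC delay", where),
                    _fmt(a.freq),
                    _fmt(a.phase),
                )
            )
        block_rows.append((i + 1, d_id, rf_id, gx_id, gy_id, gz_id, adc_id))

    lines = ["# Pulseq sequence file", "# generated by qmrisim", ""]
    lines += ["[VERSION]", "major 1", "minor 2", "revision 1", ""]
    md = seq.metadata
    defs = []
    for key, name in (
        ("fov", "FOV"),
        ("matrix_n", "MatrixN"),
        ("n_slices", "NumSlices"),
        ("slice_thickness", "SliceThickness"),
        ("tr", "TR"),
        ("te", "TE"),
        ("ti", "TI"),
        ("echo_spacing", "EchoSpacing"),
    ):
        if md.get(key) is not None:
            defs.append(f"{name} {_fmt(md[key])}")
    if md.get("te_list"):
        defs.append("TEList " + " ".join(_fmt(v) for v in md["te_list"]))
    if md.get("name"):
        defs.append(f"Name {md['name']}")
    if defs:
        lines += ["[DEFINITIONS]"] + sorted(defs) + [""]

    lines.append("[BLOCKS]")
    for row in block_rows:
        lines.append(" ".join(str(v) for v in row))
    lines.append("")

    if rf_tab.entries:
        lines.append("[RF]")
        for i, e in enumerate(rf_tab.entries, 1):
            lines.append(f"{i} " + " ".join(str(v) for v in e))
        lines.append("")
    if trap_tab.entries:
        lines.append("[TRAP]")
        for i, e in enumerate(trap_tab.entries, 1):
            lines.append(f"{i} " + " ".join(str(v) for v in e))
        lines.append("")
    if adc_tab.entries:
        lines.append("[ADC]")
        for i, e in enumerate(adc_tab.entries, 1):
            lines.append(f"{i} " + " ".join(str(v) for v in e))
        lines.append("")
    if delay_tab.entries:
        lines.append("[DELAYS]")
        for i, e in enumerate(delay_tab.entries, 1):
            lines.append(f"{i} {e[0]}")
        lines.append("")
    if shapes.entries:
        lines.append("[SHAPES]")
        for i, samples in enumerate(shapes.entries, 1):
            lines.append("")
            lines.append(f"shape_id {i}")
            lines.append(f"num_samples {len(samples)}")
            lines.extend(samples)
        lines.append("")

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def decompress_shape(data: np.ndarray, num_samples: int) -> np.ndarray:
    """Decode a Pulseq shape record into ``num_samples`` samples.

    If the record already holds ``num_samples`` values it is returned as-is
    (uncompressed).  Otherwise it is the run-length-compressed derivative:
    two consecutive equal values are followed by a count of *additional*
    repeats, and the samples are the cumulative sum of the derivative.
    """
    data = np.asarray(data, dtype=float)
    if len(data) == num_samples:
        return data
    deriv = []
    i = 0
    while i < len(data):
        v = data[i]
        if i + 1 < len(data) and data[i + 1] == v:
            if i + 2 >= len(data):
                raise SequenceError("truncated compressed shape")
            rep = int(data[i + 2])
            deriv.extend([v] * (2 + rep))
            i += 3
        else:
            deriv.append(v)
            i += 1
    if len(deriv) != num_samples:
        raise SequenceError(
            f"compressed shape expands to {len(deriv)} samples, "
            f"expected {num_samples}"
        )
    return np.cumsum(deriv)


def _classify_rf(flip: float, seen_excitation: bool) -> str:
    if flip < 0.75 * np.pi:
        return RF_USE_EXCITATION
    return RF_USE_REFOCUSING if seen_excitation else RF_USE_INVERSION


def read_seq(path) -> Sequence:
    """Read a ``.seq`` file written by :func:`write_seq` (or a compatible
    Pulseq 1.2/1.3 subset) and return an annotated :class:`Sequence`."""
    with open(path) as fh:
        raw_lines = fh.read().splitlines()

    sections: dict[str, list[tuple[int, str]]] = {}
    current = None
    for no, line in enumerate(raw_lines, 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith("["):
            if s not in _SECTIONS:
                raise ParseError(f"unknown section header {s!r}", no)
            current = s
            sections[current] = []
            continue
        if current is None:
            raise ParseError(f"content outside any section: {s!r}", no)
        sections[current].append((no, s))

    if "[VERSION]" not in sections:
        raise ParseError("missing [VERSION] section")
    ver = {}
    for no, s in sections["[VERSION]"]:
        parts = s.split()
        if len(parts) != 2:
            raise ParseError(f"bad version line {s!r}", no)
        ver[parts[0]] = parts[1]
    major, minor = int(ver.get("major", 0)), int(ver.get("minor", 0))
    if major != 1 or minor not in (2, 3):
        raise VersionError(f"unsupported Pulseq version {major}.{minor}")

    defs: dict[str, object] = {}
    for no, s in sections.get("[DEFINITIONS]", []):
        parts = s.split()
        key, vals = parts[0], parts[1:]
        if key == "Name":
            defs[key] = " ".join(vals)
        elif len(vals) == 1:
            defs[key] = float(vals[0])
        else:
            defs[key] = [float(v) for v in vals]

    shapes: dict[int, np.ndarray] = {}
    shape_lines = sections.get("[SHAPES]", [])
    i = 0
    while i < len(shape_lines):
        no, s = shape_lines[i]
        parts = s.split()
        if parts[0] != "shape_id":
            raise ParseError(f"expected shape_id, got {s!r}", no)
        sid = int(parts[1])
        no2, s2 = shape_lines[i + 1]
        p2 = s2.split()
        if p2[0] != "num_samples":
            raise ParseError(f"expected num_samples, got {s2!r}", no2)
        n = int(p2[1])
        vals = []
        i += 2
        while i < len(shape_lines) and not shape_lines[i][1].startswith("shape_id"):
            vals.append(float(shape_lines[i][1]))
            i += 1
        shapes[sid] = decompress_shape(np.array(vals), n)

    rf_lib: dict[int, dict] = {}
    for no, s in sections.get("[RF]", []):
        p = s.split()
        if len(p) not in (7, 8):
            raise ParseError(f"bad RF row {s!r}", no)
        rf_lib[int(p[0])] = {
            "amp": float(p[1]),
            "mag_id": int(p[2]),
            "phase_id": int(p[3]),
            "delay_us": int(p[4]),
            "freq": float(p[5]),
            "phase": float(p[6]),
            "use": _CODE_USE[int(p[7])] if len(p) == 8 else None,
        }

    trap_lib: dict[int, tuple] = {}
    for no, s in sections.get("[TRAP]", []):
        p = s.split()
        if len(p) not in (5, 6):
            raise ParseError(f"bad TRAP row {s!r}", no)
        delay = int(p[5]) if len(p) == 6 else 0
        trap_lib[int(p[0])] = (float(p[1]), int(p[2]), int(p[3]), int(p[4]), delay)

    adc_lib: dict[int, tuple] = {}
    for no, s in sections.get("[ADC]", []):
        p = s.split()
        if len(p) != 6:
            raise ParseError(f"bad ADC row {s!r}", no)
        adc_lib[int(p[0])] = (int(p[1]), int(p[2]), int(p[3]), float(p[4]), float(p[5]))

    delay_lib: dict[int, int] = {}
    for no, s in sections.get("[DELAYS]", []):
        p = s.split()
        if len(p) != 2:
            raise ParseError(f"bad DELAYS row {s!r}", no)
        delay_lib[int(p[0])] = int(p[1])

    if "[BLOCKS]" not in sections:
        raise ParseError("missing [BLOCKS] section")

    def _trap(axis: str, tid: int) -> GradEvent | None:
        if tid == 0:
            return None
        amp, r, fl, f, d = trap_lib[tid]
        return GradEvent(
            axis=axis,
            amplitude=amp,
            rise_time=r * 1e-6,
            flat_time=fl * 1e-6,
            fall_time=f * 1e-6,
            delay=d * 1e-6,
        )

    blocks: list[Block] = []
    seen_excitation = False
    for no, s in sections["[BLOCKS]"]:
        p = s.split()
        if len(p) != 7:
            raise ParseError(f"bad BLOCKS row {s!r}", no)
        _, d_id, rf_id, gx_id, gy_id, gz_id, adc_id = (int(v) for v in p)
        rf = None
        if rf_id:
            e = rf_lib[rf_id]
            mag = shapes[e["mag_id"]]
            ph = shapes[e["phase_id"]]
            wf = e["amp"] * mag * np.exp(2j * np.pi * ph)
            duration = len(mag) * RF_RASTER
            flip = 2 * np.pi * float(np.sum(np.abs(wf))) * RF_RASTER
            use = e["use"] or _classify_rf(flip, seen_excitation)
            if use == RF_USE_EXCITATION:
                seen_excitation = True
            rf = RFEvent(
                waveform=wf,
                duration=duration,
                flip_angle=flip,
                phase_offset=e["phase"],
                use=use,
                freq_offset=e["freq"],
                delay=e["delay_us"] * 1e-6,
            )
        adc = None
        if adc_id:
            n_s, dwell_ns, delay_us, freq, phase = adc_lib[adc_id]
            adc = AdcEvent(
                num_samples=n_s,
                dwell_time=dwell_ns * 1e-9,
                delay=delay_us * 1e-6,
                freq=freq,
                phase=phase,
            )
        blocks.append(
            Block(
                rf=rf,
                gx=_trap("x", gx_id),
                gy=_trap("y", gy_id),
                gz=_trap("z", gz_id),
                adc=adc,
                delay=delay_lib[d_id] * 1e-6 if d_id else 0.0,
            )
        )

    metadata = {}
    for name, key in (
        ("FOV", "fov"),
        ("MatrixN", "matrix_n"),
        ("NumSlices", "n_slices"),
        ("SliceThickness", "slice_thickness"),
        ("TR", "tr"),
        ("TE", "te"),
        ("TI", "ti"),
        ("EchoSpacing", "echo_spacing"),
        ("TEList", "te_list"),
        ("Name", "name"),
    ):
        if name in defs:
            v = defs[name]
            if key in ("matrix_n", "n_slices"):
                v = int(v)
            metadata[key] = v

    seq = Sequence(blocks=blocks, metadata=metadata)
    if metadata.get("fov") and metadata.get("matrix_n") and seq.has_adc():
        annotate_readouts(seq)
    return seq
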