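"""Sequence container: an ordered list of blocks plus nominal metadata.

The metadata (nominal TR/TE/TI, matrix size, FOV, slice geometry) describes
the *intent* of the sequence; the timing auditor (:mod:`qmrisim.timing`)
measures the realized intervals purely from the event timeline and never
copies metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import (
    Block,
    RF_USE_EXCITATION,
    RF_USE_INVERSION,
    RF_USE_REFOCUSING,
    SequenceError,
)


@dataclass
class Sequence:
    blocks: list[Block] = field(default_factory=list)
    raster_time: float = 1e-6
    metadata: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        """Total duration: exact sum of block durations."""
        total_us = sum(round(b.duration * 1e6) for b in self.blocks)
        return total_us * 1e-6

    def block_starts(self) -> np.ndarray:
        durs = np.array([round(b.duration * 1e6) for b in self.blocks], dtype=np.int64)
        starts = np.concatenate([[0], np.cumsum(durs)[:-1]])
        return starts * 1e-6

    def rf_events(self):
        for t0, b in zip(self.block_starts(), self.blocks):
            if b.rf is not None:
                yield t0, b, b.rf

    def adc_events(self):
        for t0, b in zip(self.block_starts(), self.blocks):
            if b.adc is not None:
                yield t0, b, b.adc

    def has_adc(self) -> bool:
        return any(b.adc is not None for b in self.blocks)


def slice_positions(n_slices: int, thickness: float) -> np.ndarray:
    """Physical slice-center z positions for contiguous slices (m)."""
    return (np.arange(n_slices) - (n_slices - 1) / 2.0) * thickness


def annotate_readouts(seq: Sequence) -> Sequence:
    """(Re)derive acquisition annotations from the event timeline.

    Walks the blocks tracking the phase-encode k-space coordinate (reset by
    excitations, negated by refocusing/inversion pulses, advanced by y
    gradients) and the slice selected by the most recent excitation (from
    its frequency offset against the concurrent z gradient).  Sets
    ``slice_index``, ``pe_line`` and ``echo_index`` on every ADC event and
    ``slice_index`` on RF events.
    """
    md = seq.metadata
    fov = md.get("fov")
    matrix_n = md.get("matrix_n")
    n_slices = int(md.get("n_slices", 1))
    thickness = md.get("slice_thickness")
    if fov is None or matrix_n is None:
        raise SequenceError("annotation requires fov and matrix_n metadata")

    ky = 0.0
    current_slice = 0
    echo_counter = 0
    for b in seq.blocks:
        marks = []
        if b.rf is not None:
            marks.append((b.rf.center_time, "rf"))
        if b.adc is not None:
            marks.append((b.adc.center_time, "adc"))
        marks.sort()
        prev = 0.0
        for t, kind in marks:
            ky += float(b.grad_area_until("y", t) - b.grad_area_until("y", prev))
            prev = t
            if kind == "rf":
                rf = b.rf
                if n_slices > 1 and b.gz is not None and b.gz.amplitude != 0:
                    z = rf.freq_offset / b.gz.amplitude
                    rf.slice_index = int(
                        round(z / thickness + (n_slices - 1) / 2.0)
                    )
                else:
                    rf.slice_index = 0
                if rf.use == RF_USE_EXCITATION:
                    ky = 0.0
                    echo_counter = 0
                    current_slice = rf.slice_index
                else:
                    # any pi-type pulse conjugates the transverse phase
                    ky = -ky
            else:
                adc = b.adc
                echo_counter += 1
                adc.echo_index = echo_counter
                adc.slice_index = current_slice
                adc.pe_line = int(round(ky * fov)) + int(matrix_n) // 2
        ky += float(
            b.grad_area_until("y", b.duration) - b.grad_area_until("y", prev)
        )
    return seq
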