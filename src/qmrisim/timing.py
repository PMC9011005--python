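"""Timing auditor: measures TE/TI/TR/echo spacing from the event timeline.

Definitions: TE is the interval from an excitation RF center to the echo
(ADC temporal) center; TI from an inversion RF center to the next
excitation center of the same slice; TR between successive excitation
centers of the same slice.  For multi-echo trains the reported TE refers to
the echo that acquires the k-space center line when that echo index is
unique; when every echo revisits the center line (variable-TE mapping
trains) the tie is broken toward the ADC nearest after the last refocusing
pulse, i.e. the final echo.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import (
    RF_USE_EXCITATION,
    RF_USE_INVERSION,
    RF_USE_REFOCUSING,
    SequenceError,
)
from .sequence import Sequence, annotate_readouts


class AuditError(SequenceError):
    pass


@dataclass
class TimingReport:
    measured_TE: float
    measured_TI: float | None
    measured_TR: float | None
    echo_spacing: float | None
    echoes_per_excitation: int
    total_duration: float
    echo_times: list[float] = field(default_factory=list)
    n_slices_seen: int = 0


def timing_report(seq: Sequence) -> TimingReport:
    """Audit a sequence's realized intervals (never uses nominal metadata
    except for the FOV/matrix geometry needed to locate the center line)."""
    try:
        if seq.metadata.get("fov") and seq.metadata.get("matrix_n"):
            annotate_readouts(seq)
    except SequenceError:
        pass

    excitations = []  # (t_center, slice)
    inversions = []
    refocusings = []
    adcs = []  # (t_center, slice, echo, pe, excitation_idx)
    exc_idx = -1
    for t0, b, rf in _walk(seq):
        if rf is not None:
            t = t0 + rf.center_time
            s = rf.slice_index if rf.slice_index is not None else 0
            if rf.use == RF_USE_EXCITATION:
                exc_idx += 1
                excitations.append((t, s))
            elif rf.use == RF_USE_INVERSION:
                inversions.append((t, s))
            else:
                refocusings.append((t, s))
        adc = b.adc
        if adc is not None:
            adcs.append(
                (
                    t0 + adc.center_time,
                    adc.slice_index if adc.slice_index is not None else 0,
                    adc.echo_index,
                    adc.pe_line,
                    exc_idx,
                )
            )

    if not excitations:
        raise AuditError("no excitation RF found")
    if not adcs:
        raise AuditError("no ADC events found")

    slices = sorted({s for _, s in excitations})
    sampled_slices = sorted({s for _, s, *_ in adcs})
    ref_slice = sampled_slices[0]

    # group ADCs by excitation index
    trains: dict[int, list] = {}
    for rec in adcs:
        trains.setdefault(rec[4], []).append(rec)
    n_echoes = max(len({r[2] for r in recs}) for recs in trains.values())

    # echo spacing from the first multi-echo train
    echo_spacing = None
    for recs in trains.values():
        if len(recs) >= 2:
            ts = np.array(sorted(r[0] for r in recs))
            diffs = np.diff(ts)
            if not np.allclose(diffs, diffs[0], atol=2e-6):
                raise AuditError("non-uniform echo spacing within a train")
            echo_spacing = float(diffs[0])
            break

    exc_times = {i: t for i, (t, _) in enumerate(excitations)}

    # locate "the" echo: unique echo index acquiring the center PE line
    matrix_n = seq.metadata.get("matrix_n")
    te = None
    echo_times: list[float] = []
    if matrix_n is not None:
        center = int(matrix_n) // 2
        hits = [r for r in adcs if r[3] == center and r[1] == ref_slice]
        hit_echoes = {r[2] for r in hits}
        if len(hit_echoes) == 1 and hits:
            r = hits[0]
            te = r[0] - exc_times[r[4]]
    if te is None:
        # tie-break: nearest ADC after the last refocusing pulse of a train
        i0, recs = min(
            ((i, recs) for i, recs in trains.items() if recs),
            key=lambda kv: kv[0],
        )
        refs = [t for t, s in refocusings if exc_times[i0] < t]
        recs = sorted(recs)
        if refs:
            last_ref = max(t for t in refs if t < recs[-1][0] + 1e-12)
            later = [r for r in recs if r[0] > last_ref]
            te = (later[0][0] if later else recs[-1][0]) - exc_times[i0]
        else:
            te = recs[0][0] - exc_times[i0]

    first_train_idx = min(trains)
    echo_times = sorted(r[0] - exc_times[r[4]] for r in trains[first_train_idx])

    # TI: inversion -> next excitation of the same slice
    ti = None
    slice_exc = [(t, s) for t, s in excitations if s == ref_slice]
    for t_inv, s_inv in inversions:
        if s_inv != ref_slice:
            continue
        nxt = [t for t, _ in slice_exc if t > t_inv]
        if nxt:
            ti = min(nxt) - t_inv
            break

    # TR: successive excitations of the same slice
    tr = None
    if len(slice_exc) >= 2:
        ts = np.array([t for t, _ in slice_exc])
        diffs = np.diff(ts)
        tr = float(diffs[0])
        if not np.allclose(diffs, tr, atol=2e-6):
            raise AuditError("non-uniform repetition interval for a slice")

    return TimingReport(
        measured_TE=float(te),
        measured_TI=None if ti is None else float(ti),
        measured_TR=tr,
        echo_spacing=echo_spacing,
        echoes_per_excitation=int(n_echoes),
        total_duration=seq.duration,
        echo_times=[float(t) for t in echo_times],
        n_slices_seen=len(slices),
    )


def _walk(seq: Sequence):
    for t0, b in zip(seq.block_starts(), seq.blocks):
        yield t0, b, b.rf
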