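"""Voxel-wise T1/T2 relaxometry from multi-contrast magnitude images.

Signal models (magnitude data; A = signal scaling, B = signal offset):

    T1 (inversion recovery):  S(TI) = | A (1 - 2 e^{-TI/T1} + e^{-TR/T1}) + B |
    T2 (multi-echo decay):    S(TE) =   A e^{-TE/T2} + B

Both are fitted per voxel with bounded trust-region least squares.  The
magnitude form of the IR model accommodates magnitude images without
polarity restoration.  The mapping surface follows the statsmodels
Model/Results idiom (:class:`RelaxometryModel` / :class:`RelaxometryResults`)
with the functional entry points kept alongside.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .recon import ImageSet

T1_BOUNDS = (1e-3, 10.0)
T2_BOUNDS = (1e-3, 10.0)
_MAX_ITER = 200


class MappingError(ValueError):
    pass


@dataclass
class FitResult:
    value: float  # fitted T1 or T2, seconds
    a: float
    b: float
    residual_rms: float
    converged: bool


def _ir_model(ti, tr, t1, a, b):
    return np.abs(a * (1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr / t1)) + b)


def fit_t1_voxel(signal, ti_list, tr: float) -> FitResult:
    """Fit the magnitude IR model to one voxel's signal across TIs.

    Initializer: the magnitude minimum sits near the null TI = T1 ln 2
    when TR >> T1, so T1_0 = TI(argmin S)/ln 2, clipped to the bounds.
    """
    s = np.asarray(signal, dtype=float)
    ti = np.asarray(ti_list, dtype=float)
    if len(s) < 4:
        raise MappingError("T1 fit needs at least 4 points")
    if np.any(np.diff(ti) <= 0):
        raise MappingError("ti_list must be strictly increasing")
    if np.max(s) <= 0 or np.ptp(s) == 0:
        return FitResult(np.nan, 0.0, 0.0, float(np.std(s)), False)

    a0 = float(np.max(s))
    b0 = float(np.min(s))
    lo = [T1_BOUNDS[0], 0.0, -np.inf]
    hi = [T1_BOUNDS[1], np.inf, np.inf]

    def resid(p):
        return _ir_model(ti, tr, *p) - s

    # The magnitude model |.| has local minima when the null TI = T1 ln 2
    # falls between grid points; multi-start over every TI-implied null
    # (plus the argmin-based guess first) and keep the lowest cost.
    starts = [float(np.clip(ti[np.argmin(s)] / np.log(2.0), *T1_BOUNDS))]
    for t in ti:
        cand = float(np.clip(t / np.log(2.0), *T1_BOUNDS))
        if all(abs(cand - c) > 1e-6 for c in starts):
            starts.append(cand)

    res = None
    for t1_0 in starts:
        try:
            r = least_squares(
                resid,
                x0=[t1_0, a0, b0],
                bounds=(lo, hi),
                method="trf",
                max_nfev=_MAX_ITER * 4,
                ftol=1e-10,
                xtol=1e-12,
                gtol=1e-10,
            )
        except Exception:
            continue
        if res is None or r.cost < res.cost:
            res = r
    if res is None:
        return FitResult(np.nan, 0.0, 0.0, float(np.std(s)), False)
    t1_fit, a, b = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    at_bound = (
        t1_fit <= T1_BOUNDS[0] * (1 + 1e-6) or t1_fit >= T1_BOUNDS[1] * (1 - 1e-6)
    )
    ok = bool(res.success) and not at_bound and np.isfinite(t1_fit)
    return FitResult(float(t1_fit), float(a), float(b), rms, ok)


def fit_t2_voxel(signal, te_list) -> FitResult:
    """Fit A e^{-TE/T2} + B; initializer from a log-linear regression of
    S - min(S)."""
    s = np.asarray(signal, dtype=float)
    te = np.asarray(te_list, dtype=float)
    if len(s) < 3:
        raise MappingError("T2 fit needs at least 3 points")
    if np.any(np.diff(te) <= 0):
        raise MappingError("te_list must be strictly increasing")
    if np.max(s) <= 0 or np.ptp(s) == 0:
        return FitResult(np.nan, 0.0, 0.0, float(np.std(s)), False)

    shifted = s - np.min(s)
    pos = shifted > np.max(shifted) * 1e-6
    if np.count_nonzero(pos) >= 2:
        slope, icpt = np.polyfit(te[pos], np.log(shifted[pos]), 1)
        t2_0 = float(np.clip(-1.0 / slope if slope < 0 else T2_BOUNDS[1], *T2_BOUNDS))
        a0 = float(np.clip(np.exp(icpt), 1e-12, None))
    else:
        t2_0, a0 = 0.05, float(np.max(s))
    b0 = float(np.min(s))

    def resid(p):
        t2, a, b = p
        return a * np.exp(-te / t2) + b - s

    try:
        res = least_squares(
            resid,
            x0=[t2_0, a0, b0],
            bounds=([T2_BOUNDS[0], 0.0, -np.inf], [T2_BOUNDS[1], np.inf, np.inf]),
            method="trf",
            max_nfev=_MAX_ITER * 4,
            ftol=1e-10,
            xtol=1e-12,
            gtol=1e-10,
        )
    except Exception:
        return FitResult(np.nan, 0.0, 0.0, float(np.std(s)), False)
    t2_fit, a, b = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    at_bound = (
        t2_fit <= T2_BOUNDS[0] * (1 + 1e-6) or t2_fit >= T2_BOUNDS[1] * (1 - 1e-6)
    )
    ok = bool(res.success) and not at_bound and np.isfinite(t2_fit)
    return FitResult(float(t2_fit), float(a), float(b), rms, ok)


@dataclass
class ParameterMap:
    """Per-voxel fit over a region mask; values in seconds."""

    values: np.ndarray
    a: np.ndarray
    b: np.ndarray
    residual: np.ndarray
    converged: np.ndarray
    mask: np.ndarray
    kind: str  # 't1' | 't2'

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("map_seconds", data=self.values)
            f.create_dataset("a", data=self.a)
            f.create_dataset("b", data=self.b)
            f.create_dataset("residual", data=self.residual)
            f.create_dataset("converged", data=self.converged)
            f.create_dataset("mask", data=self.mask)
            f.attrs["kind"] = self.kind


def map_fit(
    images: ImageSet,
    kind: str,
    mask: np.ndarray,
    echo_subset: tuple[int, int] | None = None,
    tr: float | None = None,
) -> ParameterMap:
    """Voxel-by-voxel fit inside ``mask``.

    ``echo_subset`` is an inclusive 1-based (first, last) contrast range,
    e.g. (5, 23) to use only the 5th..23rd echoes.  For T1 fitting the
    contrast axis must carry TI values and ``tr`` must be given (or stored
    on the image set's acquisition metadata).
    """
    if kind not in ("t1", "t2"):
        raise MappingError(f"unknown map kind {kind!r}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MappingError("empty fitting mask")
    contrasts = images.contrast_values()
    if np.any(np.isnan(contrasts)):
        raise MappingError(
            "image set carries no contrast axis (TI/TE values) for mapping"
        )
    sel = slice(None)
    if echo_subset is not None:
        first, last = echo_subset
        if not (1 <= first <= last <= images.n_images):
            raise MappingError("echo_subset out of range")
        sel = slice(first - 1, last)
    contrasts = contrasts[sel]
    data = images.images[:, :, sel]
    if kind == "t1" and tr is None:
        raise MappingError("T1 mapping requires tr")

    shape = mask.shape
    values = np.full(shape, np.nan)
    a = np.full(shape, np.nan)
    b = np.full(shape, np.nan)
    residual = np.full(shape, np.nan)
    converged = np.zeros(shape, dtype=bool)
    for r, c in zip(*np.nonzero(mask)):
        sig = data[r, c, :]
        fr = (
            fit_t1_voxel(sig, contrasts, tr)
            if kind == "t1"
            else fit_t2_voxel(sig, contrasts)
        )
        values[r, c] = fr.value
        a[r, c] = fr.a
        b[r, c] = fr.b
        residual[r, c] = fr.residual_rms
        converged[r, c] = fr.converged
    return ParameterMap(
        values=values,
        a=a,
        b=b,
        residual=residual,
        converged=converged,
        mask=mask,
        kind=kind,
    )


def roi_stats(pmap: ParameterMap, rois: list[np.ndarray]) -> pd.DataFrame:
    """Mean/median/sd per ROI over converged voxels only."""
    rows = []
    for i, roi in enumerate(rois):
        roi = np.asarray(roi, dtype=bool)
        sel = roi & pmap.converged
        vals = pmap.values[sel]
        rows.append(
            {
                "roi": i,
                "n": int(vals.size),
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "median": float(np.median(vals)) if vals.size else np.nan,
                "sd": float(np.std(vals, ddof=0)) if vals.size else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("roi")


class RelaxometryModel:
    """statsmodels-style front end: model = RelaxometryModel(images, 't1',
    mask, tr=...); results = model.fit(); results.summary()."""

    def __init__(
        self,
        images: ImageSet,
        kind: str,
        mask: np.ndarray,
        echo_subset: tuple[int, int] | None = None,
        tr: float | None = None,
    ):
        self.images = images
        self.kind = kind
        self.mask = np.asarray(mask, dtype=bool)
        self.echo_subset = echo_subset
        self.tr = tr

    def fit(self) -> "RelaxometryResults":
        pmap = map_fit(
            self.images,
            self.kind,
            self.mask,
            echo_subset=self.echo_subset,
            tr=self.tr,
        )
        return RelaxometryResults(self, pmap)


class RelaxometryResults:
    def __init__(self, model: RelaxometryModel, pmap: ParameterMap):
        self.model = model
        self.parameter_map = pmap

    @property
    def values(self) -> np.ndarray:
        return self.parameter_map.values

    def roi_stats(self, rois: list[np.ndarray]) -> pd.DataFrame:
        return roi_stats(self.parameter_map, rois)

    def summary(self, rois: list[np.ndarray] | None = None) -> str:
        pm = self.parameter_map
        ok = pm.converged
        lines = [
            f"Relaxometry fit ({pm.kind.upper()})",
            "=" * 34,
            f"voxels fitted      : {int(pm.mask.sum())}",
            f"voxels converged   : {int(ok.sum())}",
            f"{pm.kind} median (s)      : "
            f"{np.nanmedian(pm.values[ok]) if ok.any() else float('nan'):.4f}",
            f"residual rms (med) : "
            f"{np.nanmedian(pm.residual[ok]) if ok.any() else float('nan'):.3e}",
        ]
        if rois is not None:
            lines.append("")
            lines.append(self.roi_stats(rois).to_string())
        return "\n".join(lines)
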