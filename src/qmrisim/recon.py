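"""Cartesian reconstruction: PE re-ordering, Hamming apodization, centered
2D inverse FFT, sum-of-squares channel combination, joint normalization.

FFT convention: the k-space grid is indexed [pe_line, kx_sample] with the
k-space center at index n/2 on both axes (even-n convention).  Image voxel
centers follow the phantom convention (FOV-centered, half-voxel offset,
row 0 at the top, y up), so a reconstructed image is directly comparable
with the phantom maps; the half-voxel offset is realized by linear phase
ramps applied in k-space before the transform.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .bloch import RawKSpace


class ReconError(ValueError):
    pass


@dataclass
class KSpaceGrid:
    """Fully-sampled k-space for one (slice, contrast/echo) image, all
    channels: data indexed (channel, pe_line, kx)."""

    data: np.ndarray
    slice_index: int = 0
    echo_index: int = 1
    contrast: float = float("nan")

    @property
    def n(self) -> int:
        return self.data.shape[1]


@dataclass
class ImageSet:
    """Magnitude images (x, y, contrast-or-slice) with joint normalization."""

    images: np.ndarray
    contrast_axis: list[dict]
    normalized: bool = False
    scale: float = 1.0  # global max divided out by normalize_set

    @property
    def n_images(self) -> int:
        return self.images.shape[2]

    def contrast_values(self) -> np.ndarray:
        return np.array([c.get("contrast", np.nan) for c in self.contrast_axis])

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images)
            f.create_dataset("contrast", data=self.contrast_values())
            f.create_dataset(
                "slice", data=np.array([c["slice"] for c in self.contrast_axis])
            )
            f.create_dataset(
                "echo", data=np.array([c["echo"] for c in self.contrast_axis])
            )
            f.attrs["normalized"] = self.normalized
            f.attrs["scale"] = self.scale

    @classmethod
    def load(cls, path) -> "ImageSet":
        with h5py.File(path, "r") as f:
            axis = [
                {
                    "slice": int(s),
                    "echo": int(e),
                    "contrast": float(c),
                }
                for s, e, c in zip(f["slice"][:], f["echo"][:], f["contrast"][:])
            ]
            return cls(
                images=f["images"][:],
                contrast_axis=axis,
                normalized=bool(f.attrs["normalized"]),
                scale=float(f.attrs["scale"]),
            )


def sort_kspace(raw: RawKSpace, matrix_n: int | None = None) -> list[KSpaceGrid]:
    """Correct the acquisition ordering into complete k-space grids.

    Readouts are grouped by (slice, contrast); if a group revisits PE lines
    (variable-TE trains) it is further split by echo index so each echo
    forms its own grid.  Errors on duplicated or missing PE lines.
    """
    n = matrix_n or raw.attrs.get("matrix_n")
    if n is None:
        raise ReconError("matrix size unknown; pass matrix_n")
    n = int(n)
    sl = np.asarray(raw.meta["slice"])
    pe = np.asarray(raw.meta["pe_line"])
    echo = np.asarray(raw.meta["echo"])
    contrast = np.asarray(raw.meta.get("contrast", np.full(sl.shape, np.nan)))

    def ckey(v):
        return None if np.isnan(v) else float(v)

    groups: dict[tuple, list[int]] = {}
    for i in range(len(sl)):
        groups.setdefault((int(sl[i]), ckey(contrast[i])), []).append(i)

    grids: list[KSpaceGrid] = []
    for (s, c), idxs in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1] or 0.0)
    ):
        lines = pe[idxs]
        if len(np.unique(lines)) < len(lines):
            # split by echo index: one grid per echo
            subgroups = {}
            for i in idxs:
                subgroups.setdefault(int(echo[i]), []).append(i)
        else:
            subgroups = {int(echo[idxs[0]]): idxs}
        for e, sub in sorted(subgroups.items()):
            lines = pe[sub]
            uniq, counts = np.unique(lines, return_counts=True)
            dup = uniq[counts > 1]
            if dup.size:
                raise ReconError(
                    f"duplicate PE line(s) {dup.tolist()} for slice {s}, "
                    f"echo {e}"
                )
            missing = sorted(set(range(n)) - set(uniq.tolist()))
            if missing:
                raise ReconError(
                    f"incomplete k-space for slice {s}, echo {e}: "
                    f"missing line(s) {missing}"
                )
            data = np.empty(
                (raw.n_channels, n, raw.samples.shape[0]), dtype=complex
            )
            for i in sub:
                data[:, pe[i], :] = raw.samples[:, :, i].T
            cval = c
            if cval is None and raw.attrs.get("te_list") is not None:
                cval = float(raw.attrs["te_list"][e - 1])
            grids.append(
                KSpaceGrid(
                    data=data,
                    slice_index=s,
                    echo_index=e,
                    contrast=float("nan") if cval is None else cval,
                )
            )
    return grids


def hamming_2d(n: int) -> np.ndarray:
    """Outer product of two n-point Hamming windows
    w(k) = 0.54 - 0.46 cos(2 pi k / (n-1))."""
    if n < 2:
        raise ReconError("window needs n >= 2")
    w = np.hamming(n)
    return np.outer(w, w)


def ifft2_image(grid: np.ndarray) -> np.ndarray:
    """Centered 2D inverse DFT of one k-space plane [pe(ky), kx] onto the
    phantom voxel grid (half-voxel offset; y decreasing with row)."""
    n0, n1 = grid.shape
    # half-voxel offset ramps; axis 0 (ky vs y-down rows) uses the
    # conjugate sense because y decreases with increasing row index
    r0 = np.exp(-1j * np.pi * (np.arange(n0) - n0 // 2) / n0)
    r1 = np.exp(+1j * np.pi * (np.arange(n1) - n1 // 2) / n1)
    g = grid * r0[:, None] * r1[None, :]
    # axis 1: centered inverse transform; axis 0: centered forward / n
    tmp = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(g, axes=1), axis=1), axes=1)
    img = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(tmp, axes=0), axis=0), axes=0)
    return img / n0


def sos_combine(channel_images: np.ndarray) -> np.ndarray:
    """Sum-of-squares combination of (channel, x, y) complex images."""
    imgs = np.asarray(channel_images)
    if imgs.ndim == 2:
        imgs = imgs[None]
    return np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))


def normalize_set(images: ImageSet) -> ImageSet:
    """Joint normalization: divide every image by the single global max."""
    peak = float(np.max(images.images))
    if peak <= 0:
        raise ReconError("cannot normalize an all-zero image set")
    return ImageSet(
        images=images.images / peak,
        contrast_axis=images.contrast_axis,
        normalized=True,
        scale=peak,
    )


def reconstruct(raw: RawKSpace, apodize: bool | None = None) -> ImageSet:
    """Full chain: sort -> (Hamming) -> IFFT per channel -> SoS -> joint
    normalization.  ``apodize`` defaults to the acquisition's character:
    on for quantitative mapping data, off for qualitative imaging."""
    if apodize is None:
        apodize = bool(raw.attrs.get("quantitative", False))
    grids = sort_kspace(raw)
    window = hamming_2d(grids[0].n) if apodize else None
    images = []
    axis = []
    for g in grids:
        data = g.data * window[None] if window is not None else g.data
        chans = np.stack([ifft2_image(data[c]) for c in range(data.shape[0])])
        images.append(sos_combine(chans))
        axis.append(
            {
                "slice": g.slice_index,
                "echo": g.echo_index,
                "contrast": g.contrast,
            }
        )
    stack = np.stack(images, axis=2)
    return normalize_set(
        ImageSet(images=stack, contrast_axis=axis, normalized=False)
    )
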