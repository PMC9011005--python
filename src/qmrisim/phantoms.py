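"""Numerical phantoms: resolution grid and NIST-like T1/T2 sphere planes.

A :class:`Phantom` holds per-voxel proton density, T1 and T2 maps on an
FOV-centered square grid.  The coordinate convention is fixed: voxel
(row 0, col 0) is the top-left corner; the voxel center maps to physical
coordinates x = -FOV/2 + (col + 1/2) * d (rightward) and
y = +FOV/2 - (row + 1/2) * d (upward), with d = FOV / n.

The sphere layouts are synthetic stand-ins for the calibrated sphere
arrays of the ISMRM/NIST system phantom: the real sphere values are not
published in text form, so the defaults here simply bracket the protocols'
TI/TE ranges and are sized to stay resolvable on the low-resolution
simulation grids.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np


class PhantomError(ValueError):
    pass


@dataclass
class Phantom:
    pd_map: np.ndarray
    t1_map: np.ndarray
    t2_map: np.ndarray
    fov: float

    def __post_init__(self) -> None:
        self.pd_map = np.asarray(self.pd_map, dtype=float)
        self.t1_map = np.asarray(self.t1_map, dtype=float)
        self.t2_map = np.asarray(self.t2_map, dtype=float)
        if not (self.pd_map.shape == self.t1_map.shape == self.t2_map.shape):
            raise PhantomError("pd/t1/t2 maps must share dimensions")
        sel = self.pd_map > 0
        if np.any(self.t2_map[sel] > self.t1_map[sel] + 1e-12):
            raise PhantomError("t2 must not exceed t1 where pd > 0")

    @property
    def n(self) -> int:
        return self.pd_map.shape[0]

    @property
    def voxel_size(self) -> float:
        return self.fov / self.n

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) physical coordinates of every voxel center."""
        d = self.voxel_size
        cols = np.arange(self.pd_map.shape[1])
        rows = np.arange(self.pd_map.shape[0])
        x = -self.fov / 2.0 + (cols + 0.5) * d
        y = +self.fov / 2.0 - (rows + 0.5) * d
        return np.meshgrid(x, y)


@dataclass
class Sphere:
    x: float
    y: float
    radius: float
    t1: float
    t2: float
    pd: float = 1.0


@dataclass
class SphereLayout:
    spheres: list[Sphere]
    disk_radius: float
    background_pd: float = 0.2
    background_t1: float = 3.0
    background_t2: float = 1.0

    def __post_init__(self) -> None:
        for i, a in enumerate(self.spheres):
            r = np.hypot(a.x, a.y)
            if r + a.radius > self.disk_radius + 1e-12:
                raise PhantomError(f"sphere {i} extends outside the disk")
            for j, b in enumerate(self.spheres[:i]):
                d = np.hypot(a.x - b.x, a.y - b.y)
                if d <= a.radius + b.radius:
                    raise PhantomError(f"spheres {j} and {i} overlap")


def _ring_layout(values: list[tuple[float, float]], disk_radius: float,
                 sphere_radius: float) -> SphereLayout:
    """1 center + 3 inner-ring + 6 outer-ring spheres carrying ``values``
    (list of (t1, t2) in ascending order)."""
    assert len(values) == 10
    centers = [(0.0, 0.0)]
    for k in range(3):
        a = 2 * np.pi * k / 3
        centers.append((0.052 * np.cos(a), 0.052 * np.sin(a)))
    for k in range(6):
        a = 2 * np.pi * (k + 0.5) / 6
        centers.append((0.092 * np.cos(a), 0.092 * np.sin(a)))
    spheres = [
        Sphere(x=cx, y=cy, radius=sphere_radius, t1=t1, t2=t2)
        for (cx, cy), (t1, t2) in zip(centers, values)
    ]
    return SphereLayout(spheres=spheres, disk_radius=disk_radius)


def default_t1_layout() -> SphereLayout:
    """Ten spheres with T1 from 50 ms to 2 s (T2 = T1/10, floored 20 ms)."""
    t1s = [0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 1.3, 1.6, 2.0]
    vals = [(t1, max(0.02, t1 / 10.0)) for t1 in t1s]
    return _ring_layout(vals, disk_radius=0.115, sphere_radius=0.020)


def default_t2_layout() -> SphereLayout:
    """Ten spheres with T2 from 20 ms to 300 ms (T1 = 10 * T2, capped 2.5 s)."""
    t2s = [0.02, 0.03, 0.045, 0.06, 0.08, 0.11, 0.15, 0.2, 0.25, 0.3]
    vals = [(min(2.5, 10.0 * t2), t2) for t2 in t2s]
    return _ring_layout(vals, disk_radius=0.115, sphere_radius=0.020)


def make_grid_phantom(
    n: int,
    period: int,
    fov: float = 0.25,
    t1: float = 0.5,
    t2: float = 0.1,
    disk_radius_frac: float = 0.46,
) -> Phantom:
    """Uniform disk crossed by zero-PD grid lines every ``period`` voxels.

    Grid lines sit at voxel indices congruent to period//2 (mod period);
    ``period = n`` yields a plain disk with no interior lines.
    """
    if not (n >= period >= 2):
        raise PhantomError("need n >= period >= 2")
    d = fov / n
    idx = np.arange(n)
    x = -fov / 2.0 + (idx + 0.5) * d
    xx, yy = np.meshgrid(x, -x)
    pd = (np.hypot(xx, yy) <= disk_radius_frac * fov).astype(float)
    if period < n:
        lines = (idx % period) == period // 2
        pd[lines, :] = 0.0
        pd[:, lines] = 0.0
    t1_map = np.where(pd > 0, t1, 0.0)
    t2_map = np.where(pd > 0, t2, 0.0)
    return Phantom(pd_map=pd, t1_map=t1_map, t2_map=t2_map, fov=fov)


def make_plane_phantom(
    kind: str,
    layout: SphereLayout | None = None,
    n: int = 128,
    fov: float = 0.25,
) -> Phantom:
    """Rasterize a sphere-plane phantom ('t1_plane' or 't2_plane')."""
    if kind not in ("t1_plane", "t2_plane"):
        raise PhantomError(f"unknown plane kind {kind!r}")
    if n < 32:
        raise PhantomError("plane phantom needs n >= 32")
    if layout is None:
        layout = default_t1_layout() if kind == "t1_plane" else default_t2_layout()
    d = fov / n
    idx = np.arange(n)
    x = -fov / 2.0 + (idx + 0.5) * d
    xx, yy = np.meshgrid(x, -x)
    inside = np.hypot(xx, yy) <= layout.disk_radius
    pd = np.where(inside, layout.background_pd, 0.0)
    t1 = np.where(inside, layout.background_t1, 0.0)
    t2 = np.where(inside, layout.background_t2, 0.0)
    for s in layout.spheres:
        m = np.hypot(xx - s.x, yy - s.y) <= s.radius
        pd[m] = s.pd
        t1[m] = s.t1
        t2[m] = s.t2
    return Phantom(pd_map=pd, t1_map=t1, t2_map=t2, fov=fov)


def sphere_masks(
    layout: SphereLayout, n: int, fov: float = 0.25, erode: float = 1.0
) -> list[np.ndarray]:
    """Interior ROI mask per sphere: voxels within radius - erode voxels."""
    d = fov / n
    idx = np.arange(n)
    x = -fov / 2.0 + (idx + 0.5) * d
    xx, yy = np.meshgrid(x, -x)
    masks = []
    for s in layout.spheres:
        masks.append(np.hypot(xx - s.x, yy - s.y) <= s.radius - erode * d)
    return masks


@dataclass
class Isochromat:
    pd: float
    t1: float
    t2: float
    x: float
    y: float
    row: int
    col: int


def to_isochromats(ph: Phantom) -> list[Isochromat]:
    """One isochromat per nonzero-PD voxel at the voxel center position."""
    xx, yy = ph.coordinates()
    rows, cols = np.nonzero(ph.pd_map > 0)
    return [
        Isochromat(
            pd=float(ph.pd_map[r, c]),
            t1=float(ph.t1_map[r, c]),
            t2=float(ph.t2_map[r, c]),
            x=float(xx[r, c]),
            y=float(yy[r, c]),
            row=int(r),
            col=int(c),
        )
        for r, c in zip(rows, cols)
    ]


def isochromat_arrays(ph: Phantom):
    """Vectorized view (pd, t1, t2, x, y) of the nonzero-PD voxels."""
    xx, yy = ph.coordinates()
    sel = ph.pd_map > 0
    return (
        ph.pd_map[sel],
        ph.t1_map[sel],
        ph.t2_map[sel],
        xx[sel],
        yy[sel],
    )


def add_noise(raw, sigma: float, seed: int = 0):
    """Add i.i.d. complex Gaussian noise (``sigma`` per real/imag part)."""
    from .bloch import RawKSpace

    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return raw
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=sigma, size=raw.samples.shape) + 1j * rng.normal(
        scale=sigma, size=raw.samples.shape
    )
    return RawKSpace(
        samples=raw.samples + noise,
        meta=dict(raw.meta),
        dwell_time=raw.dwell_time,
        attrs=dict(raw.attrs),
    )


def save_phantom(ph: Phantom, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("pd", data=ph.pd_map)
        f.create_dataset("t1", data=ph.t1_map)
        f.create_dataset("t2", data=ph.t2_map)
        f.attrs["fov"] = ph.fov


def load_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        return Phantom(
            pd_map=f["pd"][:],
            t1_map=f["t1"][:],
            t2_map=f["t2"][:],
            fov=float(f.attrs["fov"]),
        )
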