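"""Image-quality metrics (PSNR/SSIM on [0,1]-normalized images) and a
relative RF-power monitor.

SSIM uses the original publication's defaults (Gaussian window sigma 1.5,
C1 = (0.01 R)^2, C2 = (0.03 R)^2, R = 1), delegated to scikit-image.
PSNR of identical images is reported with a capped sentinel of
``PSNR_SENTINEL`` dB rather than infinity.

RF power is reported in relative units (time-averaged |B1|^2 in Hz^2);
absolute SAR in W/kg is deliberately out of scope -- only the reference
subject mass is book-kept (70 kg by convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .sequence import Sequence

PSNR_SENTINEL = 300.0  # dB, stands in for infinity on identical images


class MetricsError(ValueError):
    pass


def psnr(reference: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """10 log10(R^2 / MSE); identical images return the capped sentinel."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise MetricsError("images must have congruent dimensions")
    mse = float(np.mean((reference - test) ** 2))
    if mse <= (data_range**2) * 10 ** (-PSNR_SENTINEL / 10.0):
        return PSNR_SENTINEL
    return 10.0 * np.log10(data_range**2 / mse)


def ssim(reference: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Mean local SSIM, Gaussian-weighted window (sigma 1.5)."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise MetricsError("images must have congruent dimensions")
    return float(
        structural_similarity(
            reference,
            test,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


@dataclass
class QualityReport:
    psnr_per_slice: list[float]
    ssim_per_slice: list[float]
    psnr_mean: float
    ssim_mean: float
    note: str = "jointly normalized to [0,1] before comparison"

    def to_dict(self) -> dict:
        return {
            "psnr_per_slice": self.psnr_per_slice,
            "ssim_per_slice": self.ssim_per_slice,
            "psnr_mean": self.psnr_mean,
            "ssim_mean": self.ssim_mean,
            "note": self.note,
        }


def quality_report(reference: np.ndarray, test: np.ndarray) -> QualityReport:
    """Per-slice PSNR/SSIM between two (x, y, slice) image stacks."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise MetricsError("image stacks must have congruent dimensions")
    if reference.ndim == 2:
        reference = reference[:, :, None]
        test = test[:, :, None]
    ps = [psnr(reference[:, :, k], test[:, :, k]) for k in range(reference.shape[2])]
    ss = [ssim(reference[:, :, k], test[:, :, k]) for k in range(reference.shape[2])]
    return QualityReport(
        psnr_per_slice=ps,
        ssim_per_slice=ss,
        psnr_mean=float(np.mean(ps)),
        ssim_mean=float(np.mean(ss)),
    )


@dataclass
class RfPowerReport:
    time_averaged_b1sq: float  # Hz^2
    duty_cycle: float
    reference_mass: float  # kg
    total_duration: float  # s

    def to_dict(self) -> dict:
        return {
            "time_averaged_b1sq": self.time_averaged_b1sq,
            "duty_cycle": self.duty_cycle,
            "reference_mass": self.reference_mass,
            "total_duration": self.total_duration,
        }


def rf_power_summary(seq: Sequence, mass: float = 70.0) -> RfPowerReport:
    """Time-averaged |B1|^2 over the whole sequence (relative units) and
    the RF duty cycle; the subject mass is recorded, not used."""
    total = seq.duration
    if total <= 0:
        raise MetricsError("sequence has zero duration")
    power = 0.0
    on_time = 0.0
    for _, _, rf in seq.rf_events():
        power += rf.power_integral
        on_time += rf.duration
    return RfPowerReport(
        time_averaged_b1sq=power / total,
        duty_cycle=on_time / total,
        reference_mass=mass,
        total_duration=total,
    )
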