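"""Volumes, the contusion ratio with its 20% severity cutoff, and the P/F-based
respiratory-failure flag.

The severity rule is: ratio <= 20% is "moderate", ratio > 20% is "severe",
applied to the raw (unrounded) ratio.  Pneumothorax bookkeeping is
configurable: by default pleural air counts with functional (normal) lung —
collapsed lung re-expands after thoracostomy — but ``ptx_counts_as=
"contusion"`` folds it into the contusion bucket instead; both assignments
leave the total unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ct_io import MaskVolume
from .errors import DomainError, GeometryError

__all__ = [
    "LungPartition",
    "VolumeReport",
    "BloodGas",
    "mask_volume_ml",
    "contusion_ratio",
    "classify_severity",
    "ards_flag",
]

SEVERITY_CUTOFF_PERCENT = 20.0


@dataclass(frozen=True)
class LungPartition:
    """Disjoint lung masks (normal, contusion, pneumothorax) plus their union."""

    total: MaskVolume
    normal: MaskVolume
    contusion: MaskVolume
    pneumothorax: MaskVolume

    def __post_init__(self):
        for m in (self.normal, self.contusion, self.pneumothorax):
            m.check_grid(self.total)
        n, c, p = self.normal.voxels, self.contusion.voxels, self.pneumothorax.voxels
        if (n & c).any() or (n & p).any() or (c & p).any():
            raise GeometryError("partition masks are not pairwise disjoint")
        if not np.array_equal(n | c | p, self.total.voxels):
            raise GeometryError("partition masks do not union to the total mask")

    @property
    def spacing(self):
        return self.total.spacing


@dataclass(frozen=True)
class VolumeReport:
    """Per-CT volumetry: bucket volumes (mL), ratio (%), severity class."""

    v_total: float
    v_normal: float
    v_contusion: float
    v_ptx: float
    contusion_ratio: float
    severity: str
    ptx_counts_as: str

    @property
    def normal_percent(self) -> float:
        return 100.0 - self.contusion_ratio

    def to_dict(self) -> dict:
        return {
            "v_total_ml": round(self.v_total, 2),
            "v_normal_ml": round(self.v_normal, 2),
            "v_contusion_ml": round(self.v_contusion, 2),
            "v_pneumothorax_ml": round(self.v_ptx, 2),
            "contusion_ratio_percent": round(self.contusion_ratio, 2),
            "normal_percent": round(self.normal_percent, 2),
            "severity": self.severity,
            "ptx_counts_as": self.ptx_counts_as,
        }


def mask_volume_ml(mask: MaskVolume) -> float:
    """Volume of the true voxels in millilitres."""
    return float(mask.voxels.sum()) * mask.voxel_volume_ml


def classify_severity(ratio: float) -> str:
    """'moderate' iff ratio <= 20%, 'severe' iff ratio > 20% (raw, unrounded)."""
    if not 0.0 <= ratio <= 100.0:
        raise DomainError(f"contusion ratio {ratio} outside [0, 100]")
    return "moderate" if ratio <= SEVERITY_CUTOFF_PERCENT else "severe"


def contusion_ratio(part: LungPartition, ptx_counts_as: str = "normal") -> VolumeReport:
    """Contusion-to-total-lung volume ratio and severity class.

    Parameters
    ----------
    ptx_counts_as : {'normal', 'contusion'}
        Bucket to which pleural air is assigned.  Either way it stays inside
        the total, so the bucket volumes always sum to ``v_total``.
    """
    if ptx_counts_as not in ("normal", "contusion"):
        raise DomainError(f"ptx_counts_as must be 'normal' or 'contusion', got {ptx_counts_as!r}")
    v_total = mask_volume_ml(part.total)
    if v_total <= 0:
        raise DomainError("total lung volume is zero; contusion ratio undefined")
    v_ptx = mask_volume_ml(part.pneumothorax)
    v_normal = mask_volume_ml(part.normal)
    v_contusion = mask_volume_ml(part.contusion)
    if ptx_counts_as == "normal":
        v_normal += v_ptx
    else:
        v_contusion += v_ptx
    ratio = 100.0 * v_contusion / v_total
    return VolumeReport(
        v_total=v_total,
        v_normal=v_normal,
        v_contusion=v_contusion,
        v_ptx=v_ptx,
        contusion_ratio=ratio,
        severity=classify_severity(ratio),
        ptx_counts_as=ptx_counts_as,
    )


@dataclass(frozen=True)
class BloodGas:
    """Arterial oxygenation pair; FiO2 given as a fraction (percent inputs
    above 1.5 are auto-converted)."""

    pao2: float
    fio2: float

    def __post_init__(self):
        fio2 = float(self.fio2)
        if fio2 > 1.5:  # supplied as percent
            fio2 = fio2 / 100.0
        if not 0.21 <= fio2 <= 1.0:
            raise DomainError(f"FiO2 {self.fio2} outside (0.21..1.0] as a fraction")
        if not self.pao2 > 0:
            raise DomainError(f"PaO2 must be > 0 mmHg, got {self.pao2}")
        object.__setattr__(self, "fio2", fio2)
        object.__setattr__(self, "pao2", float(self.pao2))

    @property
    def pf_ratio(self) -> float:
        return self.pao2 / self.fio2


def ards_flag(bg: BloodGas, bilateral_infiltration: bool, chf: bool) -> bool:
    """True iff P/F <= 200 mmHg, bilateral diffuse infiltration, and no CHF."""
    return bool(bg.pf_ratio <= 200.0 and bilateral_infiltration and not chf)
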