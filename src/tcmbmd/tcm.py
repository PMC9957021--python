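"""Two-compartment model (TCM) for trabecular bone.

Trabecular bone is modelled as a volume-weighted mixture of two
compartments: cortical-bone-equivalent material (a K2HPO4 solution of
known concentration) and bone-marrow-equivalent material (water).  Under
a fixed X-ray spectrum the CT number of the mixture is linear in the
bone volume fraction (BVF), so two reference CT numbers — water and the
1.0 g/cm3 K2HPO4 solution — invert the mixing relation:

    BVF  = (CT_tra - CT_mar) / (CT_cor - CT_mar)
    vBMD = BVF * rho_cor

where CT_tra is the mean CT number of the trabecular ROI, CT_mar and
CT_cor are the marrow/cortical reference CT numbers, and rho_cor is the
density assigned to the cortical compartment (g/cm3).

Because both references are measured under the same spectrum as the
sample, the spectral weighting cancels exactly and the resulting vBMD is
independent of tube voltage — the property that makes the model usable
for opportunistic screening on CT scans acquired at different kVp.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

__all__ = [
    "ReferenceCalibration",
    "VBMDResult",
    "InvalidCalibrationError",
    "hu_from_attenuation",
    "mixture_attenuation",
    "volume_fraction",
    "vbmd_from_bvf",
    "measure_vbmd",
]


class InvalidCalibrationError(ValueError):
    """Raised when calibration references are degenerate or inverted."""


@dataclass(frozen=True)
class ReferenceCalibration:
    """Reference CT numbers that anchor the two compartments.

    Parameters
    ----------
    ct_marrow
        CT number (HU) of the bone-marrow equivalent (pure water).
    ct_cortical
        CT number (HU) of the cortical-bone equivalent
        (1.0 g/cm3 K2HPO4 solution) under the same spectrum.
    rho_cortical
        Density assigned to the cortical compartment, g/cm3.  The
        default 1.0 makes vBMD of a phantom compartment equal its
        K2HPO4 concentration; users preferring a physiological cortical
        density may set 0.884.
    kvp_label
        Free-text tag recording the tube voltage the references were
        measured at (informational only; vBMD does not depend on it).
    """

    ct_marrow: float
    ct_cortical: float
    rho_cortical: float = 1.0
    kvp_label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_marrow) and math.isfinite(self.ct_cortical)):
            raise InvalidCalibrationError("calibration CT numbers must be finite")
        if self.ct_cortical <= self.ct_marrow:
            raise InvalidCalibrationError(
                f"ct_cortical ({self.ct_cortical}) must exceed ct_marrow "
                f"({self.ct_marrow})"
            )
        if self.rho_cortical <= 0:
            raise InvalidCalibrationError("rho_cortical must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceCalibration":
        d = json.loads(Path(path).read_text())
        return cls(
            ct_marrow=float(d["ct_marrow"]),
            ct_cortical=float(d["ct_cortical"]),
            rho_cortical=float(d.get("rho_cortical", 1.0)),
            kvp_label=str(d.get("kvp_label", "")),
        )


@dataclass(frozen=True)
class VBMDResult:
    """Bone volume fraction and volumetric BMD for one ROI."""

    bvf: float
    vbmd: float  # g/cm3
    clamped: bool = False


def hu_from_attenuation(mu_mix: float, mu_water: float) -> float:
    """CT number (HU) of a material from linear attenuation coefficients.

    HU = 1000 * (mu_mix / mu_water - 1); water maps to 0 HU and vacuum
    to -1000 HU.  Both coefficients must be spectrum-weighted with the
    same spectrum.
    """
    if not mu_water > 0:
        raise InvalidCalibrationError("mu_water must be positive")
    if mu_mix < 0:
        raise ValueError("mu_mix must be non-negative")
    return 1000.0 * (mu_mix / mu_water - 1.0)


def mixture_attenuation(v_a: float, mu_a: float, mu_b: float) -> float:
    """Volume-weighted linear attenuation of a two-component mixture."""
    if not 0.0 <= v_a <= 1.0:
        raise ValueError(f"volume fraction {v_a} outside [0, 1]")
    return v_a * mu_a + (1.0 - v_a) * mu_b


def volume_fraction(ct_mix: float, ct_a: float, ct_b: float) -> float:
    """Volume fraction of component a from CT numbers.

    Exact inverse of :func:`mixture_attenuation` composed with
    :func:`hu_from_attenuation`: the 1000/mu_water scaling cancels.
    """
    if ct_a == ct_b:
        raise InvalidCalibrationError("degenerate calibration: ct_a == ct_b")
    return (ct_mix - ct_b) / (ct_a - ct_b)


def vbmd_from_bvf(bvf: float, rho_cortical: float) -> float:
    """Volumetric BMD (g/cm3) from bone volume fraction."""
    if not rho_cortical > 0:
        raise ValueError("rho_cortical must be positive")
    return bvf * rho_cortical


def measure_vbmd(
    ct_trabecular: float,
    calib: ReferenceCalibration,
    clamp: bool = False,
) -> VBMDResult:
    """Apply the two-compartment model to one trabecular CT number.

    BVF is not clamped to [0, 1] by default: image noise can push the
    ROI mean slightly outside the calibration span, and a small negative
    BVF is diagnostic information about calibration quality rather than
    an error.  Pass ``clamp=True`` to truncate; the result records
    whether truncation actually occurred.
    """
    bvf = volume_fraction(ct_trabecular, calib.ct_cortical, calib.ct_marrow)
    clamped = False
    if clamp and not 0.0 <= bvf <= 1.0:
        bvf = min(max(bvf, 0.0), 1.0)
        clamped = True
    return VBMDResult(bvf=bvf, vbmd=vbmd_from_bvf(bvf, calib.rho_cortical), clamped=clamped)
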