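"""Polyenergetic simulation of the K2HPO4 calibration phantom.

The physical phantom mimicked here is a plastic block whose
compartments (3 x 1.5 x 1.5 cm each) hold pure water and nine K2HPO4
solutions with concentrations from 0.02 to 1.5 g/cm3.  Scanned at a
given tube voltage, every compartment renders at the CT number of its
solution under that spectrum; the water and 1.0 g/cm3 compartments
provide the marrow/cortical references of the two-compartment model,
and the remaining compartments validate it: the measured vBMD of a
compartment should equal its concentration, independent of kVp.

The simulation is deliberately minimal: a Kramers bremsstrahlung
spectrum with aluminum filtration, spectrum-weighted attenuation per
material, one HU value per material, and i.i.d. Gaussian voxel noise.
No projection/reconstruction, scatter or beam hardening — ROI means
are the only statistic the validation consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import materials
from .materials import MaterialAttenuation, solution_attenuation
from .roi import CTVolume
from .tcm import ReferenceCalibration, hu_from_attenuation, measure_vbmd

__all__ = [
    "Spectrum",
    "PhantomSpec",
    "PhantomValidationRow",
    "DEFAULT_CONCENTRATIONS",
    "make_spectrum",
    "spectrum_weighted_attenuation",
    "solution_hu",
    "render_phantom",
    "compartment_means",
    "validate_phantom",
    "calibration_from_phantom",
]

#: Water plus nine K2HPO4 concentrations spanning 0.02-1.5 g/cm3.  The
#: set must contain 0.0 (marrow reference) and 1.0 (cortical reference).
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (
    0.0, 0.02, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.5,
)


@dataclass(frozen=True)
class Spectrum:
    """Normalized photon-fluence spectrum of an X-ray tube."""

    kvp: float
    energies: np.ndarray = field(repr=False)  # keV
    weights: np.ndarray = field(repr=False)  # sum to 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        if e.size == 0 or w.size != e.size:
            raise ValueError("energies/weights must be non-empty and matched")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        if e.max() > self.kvp + 1e-9:
            raise ValueError("photon energy cannot exceed the tube voltage")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / w.sum())

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.weights))


def make_spectrum(
    kvp: float,
    filtration_mm_al: float = 2.5,
    e_min: float = 10.0,
) -> Spectrum:
    """Kramers bremsstrahlung spectrum with aluminum filtration.

    Unfiltered fluence weights are proportional to (kVp - E) on a 1 keV
    grid from ``e_min`` to kVp; filtration multiplies by
    exp(-mu_Al(E) * t) with t in cm.  No characteristic lines.
    """
    if not 40.0 <= kvp <= 150.0:
        raise ValueError(f"kvp {kvp} outside supported range [40, 150]")
    if filtration_mm_al < 0:
        raise ValueError("filtration must be non-negative")
    e = np.arange(e_min, kvp + 0.5, 1.0)
    w = np.clip(kvp - e, 0.0, None)
    if filtration_mm_al > 0:
        w = w * np.exp(-materials.aluminum().mu(e) * filtration_mm_al / 10.0)
    return Spectrum(kvp=kvp, energies=e, weights=w)


def monoenergetic(energy_kev: float) -> Spectrum:
    """Single-line spectrum; useful as a degenerate check."""
    return Spectrum(kvp=energy_kev, energies=np.array([energy_kev]), weights=np.array([1.0]))


def spectrum_weighted_attenuation(material: MaterialAttenuation, spectrum: Spectrum) -> float:
    """Fluence-weighted mean linear attenuation, sum_E w(E) mu(E), 1/cm."""
    return float(np.sum(spectrum.weights * material.mu(spectrum.energies)))


def _solution_mu_bar(concentration: float, spectrum: Spectrum) -> float:
    return float(np.sum(spectrum.weights * solution_attenuation(concentration, spectrum.energies)))


def solution_hu(concentration: float, spectrum: Spectrum) -> float:
    """CT number of a K2HPO4 solution under the given spectrum."""
    mu_w = _solution_mu_bar(0.0, spectrum)
    return hu_from_attenuation(_solution_mu_bar(concentration, spectrum), mu_w)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the simulated phantom.

    All ten solutions are rendered side by side in one volume (the
    physical phantom fills five compartments twice; geometry does not
    enter the ROI-mean measurement).  Compartments are cuboids of
    ``compartment_mm`` laid out along the second axis with ``gap_mm``
    water-equivalent background between them.
    """

    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    compartment_mm: tuple[float, float, float] = (30.0, 15.0, 15.0)
    voxel_mm: float = 0.5
    gap_mm: float = 2.0
    background: str = "water"

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise ValueError("duplicate compartment concentrations")
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")


@dataclass(frozen=True)
class PhantomValidationRow:
    """Per-compartment comparison of measured vs theoretical vBMD."""

    concentration: float  # theoretical vBMD, g/cm3
    mean_hu: float
    n_voxels: int
    vbmd: float
    abs_diff: float
    rel_diff: float | None  # |measured-theoretical|/theoretical; None at c=0
    rel_diff_full_scale: float  # |measured-theoretical|/max concentration


def render_phantom(
    spec: PhantomSpec,
    spectrum: Spectrum,
    noise_sd_hu: float = 10.0,
    seed: int | None = None,
) -> tuple[CTVolume, np.ndarray]:
    """Render the phantom as an HU volume plus a ground-truth label map.

    Label map value k >= 1 marks compartment k-1 (in the order of
    ``spec.concentrations``); 0 is background.  Voxel HU is the
    spectrum-weighted CT number of the voxel's material plus i.i.d.
    Gaussian noise; fully reproducible for a fixed seed.
    """
    if noise_sd_hu < 0:
        raise ValueError("noise SD must be non-negative")
    vox = spec.voxel_mm
    cx, cy, cz = (int(round(d / vox)) for d in spec.compartment_mm)
    gap = int(round(spec.gap_mm / vox))
    margin = max(gap, 4)
    n = len(spec.concentrations)
    shape = (
        cx + 2 * margin,
        n * cy + (n - 1) * gap + 2 * margin,
        cz + 2 * margin,
    )
    hu_background = 0.0 if spec.background == "water" else -1000.0
    volume = np.full(shape, hu_background, dtype=float)
    labels = np.zeros(shape, dtype=np.int16)
    for k, c in enumerate(spec.concentrations):
        y0 = margin + k * (cy + gap)
        sl = (slice(margin, margin + cx), slice(y0, y0 + cy), slice(margin, margin + cz))
        if np.any(labels[sl] != 0):
            raise ValueError("overlapping compartments")
        volume[sl] = solution_hu(c, spectrum)
        labels[sl] = k + 1
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        volume = volume + rng.normal(0.0, noise_sd_hu, size=shape)
    ct = CTVolume(data=volume, spacing=(vox, vox, vox), orientation="phantom")
    return ct, labels


def compartment_means(
    volume: CTVolume, labels: np.ndarray, erode_voxels: int = 2
) -> list[tuple[float, int]]:
    """Mean HU and voxel count per compartment, eroding the box faces.

    Erosion keeps the ROI inside each compartment the way a manually
    drawn ROI avoids compartment walls.
    """
    out = []
    for k in range(1, int(labels.max()) + 1):
        idx = np.argwhere(labels == k)
        if idx.size == 0:
            raise ValueError(f"compartment {k} missing from label map")
        lo = idx.min(axis=0) + erode_voxels
        hi = idx.max(axis=0) - erode_voxels + 1
        if np.any(hi <= lo):
            raise ValueError("erosion removed an entire compartment")
        sub = volume.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        out.append((float(sub.mean()), int(sub.size)))
    return out


def calibration_from_phantom(
    volume: CTVolume,
    labels: np.ndarray,
    spec: PhantomSpec,
    rho_cortical: float = 1.0,
    kvp_label: str = "",
    erode_voxels: int = 2,
) -> ReferenceCalibration:
    """Measure CT_mar and CT_cor from the phantom's own compartments.

    The water compartment gives the marrow reference and the 1.0 g/cm3
    compartment the cortical reference, mirroring the clinical protocol
    where the phantom is scanned with the patient's technique.
    """
    concs = list(spec.concentrations)
    try:
        i_water = concs.index(0.0)
        i_cor = concs.index(1.0)
    except ValueError as err:
        raise ValueError("phantom must contain 0.0 and 1.0 g/cm3 compartments") from err
    means = compartment_means(volume, labels, erode_voxels=erode_voxels)
    return ReferenceCalibration(
        ct_marrow=means[i_water][0],
        ct_cortical=means[i_cor][0],
        rho_cortical=rho_cortical,
        kvp_label=kvp_label,
    )


def validate_phantom(
    volume: CTVolume,
    labels: np.ndarray,
    spec: PhantomSpec,
    calib: ReferenceCalibration | None = None,
    erode_voxels: int = 2,
) -> tuple[list[PhantomValidationRow], dict[str, float]]:
    """Compare TCM vBMD of every compartment with its concentration.

    Returns per-compartment rows plus an OLS fit summary (slope,
    intercept, r_squared) of measured vs theoretical vBMD over all
    compartments.  When ``calib`` is omitted it is measured from the
    same volume, the self-calibrating configuration in which the
    additive-salt model cancels exactly.
    """
    if calib is None:
        calib = calibration_from_phantom(volume, labels, spec, erode_voxels=erode_voxels)
    means = compartment_means(volume, labels, erode_voxels=erode_voxels)
    full_scale = max(spec.concentrations)
    rows = []
    for c, (mean_hu, nvox) in zip(spec.concentrations, means):
        vbmd = measure_vbmd(mean_hu, calib).vbmd
        diff = abs(vbmd - c)
        rows.append(
            PhantomValidationRow(
                concentration=c,
                mean_hu=mean_hu,
                n_voxels=nvox,
                vbmd=vbmd,
                abs_diff=diff,
                rel_diff=(diff / c) if c > 0 else None,
                rel_diff_full_scale=diff / full_scale,
            )
        )
    theo = np.array([r.concentration for r in rows])
    meas = np.array([r.vbmd for r in rows])
    fit = stats.linregress(theo, meas)
    summary = {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
    }
    return rows, summary


def validation_table(
    rows_by_kvp: dict[int, list[PhantomValidationRow]]
) -> pd.DataFrame:
    """Tidy CSV-ready table: one row per concentration, columns per kVp."""
    kvps = sorted(rows_by_kvp)
    concs = [r.concentration for r in rows_by_kvp[kvps[0]]]
    out = {"concentration": concs}
    for kvp in kvps:
        rows = rows_by_kvp[kvp]
        out[f"mean_hu_{kvp}"] = [r.mean_hu for r in rows]
        out[f"vbmd_{kvp}"] = [r.vbmd for r in rows]
        out[f"rel_diff_{kvp}"] = [r.rel_diff for r in rows]
    return pd.DataFrame(out)


def ground_truth_sidecar(
    spec: PhantomSpec, spectrum: Spectrum, noise_sd_hu: float, seed: int | None, path: str | Path
) -> None:
    """Write the JSON sidecar describing a rendered phantom."""
    doc = {
        "concentrations_g_cm3": list(spec.concentrations),
        "compartment_mm": list(spec.compartment_mm),
        "voxel_mm": spec.voxel_mm,
        "gap_mm": spec.gap_mm,
        "background": spec.background,
        "spectrum": {
            "kvp": spectrum.kvp,
            "mean_energy_kev": spectrum.mean_energy,
        },
        "noise_sd_hu": noise_sd_hu,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
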