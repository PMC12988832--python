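"""Laser fluence, dye dose, and renal-biomarker arithmetic.

Fluence assumes a uniform (top-hat) beam over the face of the delivery
fiber: pulse energy divided by the fiber cross-section in cm^2.  The
safety ratio divides that fluence by the ANSI maximum permissible
exposure for skin at 750 nm (25.2 mJ/cm^2), the conventional reference
for internal tissue in interventional guidance work.  Intraluminal
methylene blue concentration spreads the injected mass over an assumed
ureter lumen volume (22.2 mL) and converts by molar mass (319.85 g/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LaserExposure",
    "DyeDose",
    "BiomarkerPanel",
    "fluence",
    "mpe_ratio",
    "intraluminal_concentration",
    "systemic_concentration",
    "biomarker_flags",
]

MPE_SKIN_750NM_MJ_CM2 = 25.2
METHYLENE_BLUE_MOLAR_MASS_G_MOL = 319.85
URETER_LUMEN_VOLUME_ML = 22.2

BUN_RANGE_MG_DL = (2.0, 13.0)
SC_RANGE_MG_DL = (0.6, 1.8)
BUN_SC_RATIO_RANGE = (3.33, 7.22)


@dataclass(frozen=True)
class LaserExposure:
    pulse_energy_mj: float
    fiber_diameter_mm: float = 5.0
    wavelength_nm: float = 750.0
    pulse_duration_ns: float = 5.0
    repetition_rate_hz: float = 10.0
    mpe_limit_mj_cm2: float = MPE_SKIN_750NM_MJ_CM2

    def __post_init__(self) -> None:
        if self.pulse_energy_mj < 0:
            raise ValueError("pulse energy must be non-negative")
        if self.fiber_diameter_mm <= 0:
            raise ValueError("fiber diameter must be positive")
        if self.mpe_limit_mj_cm2 <= 0:
            raise ValueError("MPE limit must be positive")


@dataclass(frozen=True)
class DyeDose:
    injected_volume_ml: float
    vial_concentration_mg_ml: float = 5.0
    lumen_volume_ml: float = URETER_LUMEN_VOLUME_ML
    molar_mass_g_mol: float = METHYLENE_BLUE_MOLAR_MASS_G_MOL

    def __post_init__(self) -> None:
        if self.injected_volume_ml < 0:
            raise ValueError("injected volume must be non-negative")
        if min(self.vial_concentration_mg_ml, self.lumen_volume_ml, self.molar_mass_g_mol) <= 0:
            raise ValueError("concentration, volume, and molar mass must be positive")


@dataclass(frozen=True)
class BiomarkerPanel:
    bun_mg_dl: float
    sc_mg_dl: float

    def __post_init__(self) -> None:
        if self.bun_mg_dl < 0 or self.sc_mg_dl < 0:
            raise ValueError("biomarker values must be non-negative")


def fluence(exposure: LaserExposure) -> float:
    """Per-pulse fluence in mJ/cm^2 over the fiber face."""
    radius_cm = exposure.fiber_diameter_mm / 2.0 / 10.0
    return exposure.pulse_energy_mj / (math.pi * radius_cm**2)


def mpe_ratio(exposure: LaserExposure) -> float:
    """Fluence as a multiple of the MPE limit."""
    return fluence(exposure) / exposure.mpe_limit_mj_cm2


def intraluminal_concentration(dose: DyeDose) -> float:
    """Intraluminal dye concentration in micromolar.

    Injected mass (mg) diluted into the lumen volume, divided by the
    molar mass: ``(V_inj * c_vial) / V_lumen / M`` expressed in uM.
    """
    mg_per_ml = dose.injected_volume_ml * dose.vial_concentration_mg_ml / dose.lumen_volume_ml
    mol_per_l = mg_per_ml / dose.molar_mass_g_mol  # (g/L) / (g/mol)
    return mol_per_l * 1e6


def systemic_concentration(
    total_mass_mg: float,
    distribution_volume_ml: float,
    molar_mass_g_mol: float = METHYLENE_BLUE_MOLAR_MASS_G_MOL,
) -> float:
    """Helper for systemic (intravenous) concentration estimates, in uM.

    The distribution volume is supplied by the caller; no default is
    assumed because it depends on pharmacokinetic assumptions outside
    this package's scope.
    """
    if distribution_volume_ml <= 0 or molar_mass_g_mol <= 0:
        raise ValueError("volumes and molar mass must be positive")
    return total_mass_mg / distribution_volume_ml / molar_mass_g_mol * 1e6


def biomarker_flags(panel: BiomarkerPanel) -> dict:
    """Flag BUN, SC, and their ratio against reference ranges (inclusive
    bounds).  Raises when SC is zero (ratio undefined)."""
    if panel.sc_mg_dl == 0:
        raise ValueError("serum creatinine is zero: BUN/SC ratio undefined")
    ratio = panel.bun_mg_dl / panel.sc_mg_dl

    def in_range(v: float, lo_hi: tuple[float, float]) -> bool:
        return lo_hi[0] <= v <= lo_hi[1]

    return {
        "bun_mg_dl": panel.bun_mg_dl,
        "sc_mg_dl": panel.sc_mg_dl,
        "bun_sc_ratio": ratio,
        "bun_in_range": in_range(panel.bun_mg_dl, BUN_RANGE_MG_DL),
        "sc_in_range": in_range(panel.sc_mg_dl, SC_RANGE_MG_DL),
        "ratio_in_range": in_range(ratio, BUN_SC_RATIO_RANGE),
    }
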