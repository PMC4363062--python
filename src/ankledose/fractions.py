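"""Fractions irradiated (f_i): derivation helpers and the shipped default table.

f_i is the fraction of a whole-body organ (by mass for marrow, bone
surface and muscle; by area for skin; by node count for lymphatic
nodes) that lies in the exposed and dosimetrically evaluated region.
Derivation helpers speak percent, as the source literature does; the
:class:`~ankledose.phantom.FractionTable` stores dimensionless
fractions.

The shipped default encodes the ankle-region estimates: 1.1 % of
whole-body red-marrow mass (0.7 % calf + 0.4 % foot, from MRI and
cadaver volumetry), 4.9 % of the bone surface (ICRP 70 surface-to-volume
ratios with ICRP 89 skeletal mass fractions), 3.5 % of the skin area
(layer perimeters x 25 mm plus foot planimetry over a Du Bois whole-body
area), 0.9 % of a 28 kg whole-body muscle mass, and 1 % of the body's
lymphatic nodes per ankle.  Bone-surface 4.9 % and muscle 0.9 % rest on
external anatomical data and are shipped as cited constants, not
recomputed.
"""

from __future__ import annotations

import warnings
from typing import Optional

from pydantic import BaseModel, Field

from .phantom import FractionTable

__all__ = [
    "DU_BOIS_COEFFICIENTS",
    "BodyReference",
    "RegionAreaSpec",
    "du_bois_area",
    "skin_fraction",
    "marrow_region_fraction",
    "default_ankle_fractions",
    "BONE_SURFACE_FRACTION_PCT",
    "MUSCLE_FRACTION_PCT",
    "LYMPH_FRACTION_PCT",
    "SKIN_FRACTION_PCT",
]

#: (coefficient, weight exponent, height exponent) of the Du Bois-Du Bois
#: body-surface-area formula, BSA[m^2] = c * W[kg]^a * H[cm]^b, in its
#: standard published form.  Grouped so an alternate BSA model can be
#: swapped in one place.
DU_BOIS_COEFFICIENTS: tuple[float, float, float] = (0.007184, 0.425, 0.725)

# Region totals (percent of the whole-body organ) behind the default table.
BONE_SURFACE_FRACTION_PCT = 4.9   # per tuberosity site in the default table
MUSCLE_FRACTION_PCT = 0.9
LYMPH_FRACTION_PCT = 1.0
SKIN_FRACTION_PCT = 3.5           # whole region, split 0.9 + 2.6 across sites


class BodyReference(BaseModel):
    """Whole-body reference anatomy the fractions are normalized against."""

    height_cm: float = Field(gt=0.0)
    weight_kg: float = Field(gt=0.0)
    total_muscle_mass_g: float = Field(28000.0, gt=0.0)
    total_skin_area_m2: Optional[float] = Field(None, gt=0.0)

    def skin_area_m2(self) -> float:
        if self.total_skin_area_m2 is not None:
            return self.total_skin_area_m2
        return du_bois_area(self.height_cm, self.weight_kg)


class RegionAreaSpec(BaseModel):
    """Skin-area measurements of the scanned region.

    Calf/ankle layers contribute perimeter x slab thickness; foot layers
    are measured planimetrically.
    """

    layer_perimeters_mm: list[tuple[int, float]] = Field(default_factory=list)
    layer_thickness_mm: float = Field(25.0, gt=0.0)
    planimetric_areas_mm2: list[tuple[int, float]] = Field(default_factory=list)

    def area_m2(self) -> float:
        for _, p in self.layer_perimeters_mm:
            if p <= 0:
                raise ValueError("layer perimeter must be positive")
        for _, a in self.planimetric_areas_mm2:
            if a <= 0:
                raise ValueError("planimetric area must be positive")
        mm2 = sum(p * self.layer_thickness_mm for _, p in self.layer_perimeters_mm)
        mm2 += sum(a for _, a in self.planimetric_areas_mm2)
        return mm2 / 1e6


def du_bois_area(height_cm: float, weight_kg: float) -> float:
    """Whole-body surface area (m^2) from the Du Bois-Du Bois formula.

    Monotonically increasing in both arguments; raises ``ValueError`` on
    non-positive input.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    c, a, b = DU_BOIS_COEFFICIENTS
    return c * weight_kg**a * height_cm**b


def skin_fraction(
    region: RegionAreaSpec, total_area_m2: float, *, cap: bool = False
) -> float:
    """Fraction of the whole-body skin area contained in the region.

    Linear in the region areas, inversely proportional to the total.
    A region exceeding the total is an error unless ``cap=True``, in
    which case the fraction is clipped to 1 with a warning.
    """
    if total_area_m2 <= 0:
        raise ValueError("total skin area must be positive")
    frac = region.area_m2() / total_area_m2
    if frac > 1.0:
        if not cap:
            raise ValueError(
                f"region skin area exceeds total body area (fraction {frac:.3g})"
            )
        warnings.warn("region skin area exceeds total; capping fraction at 1")
        frac = 1.0
    return frac


def marrow_region_fraction(calf_pct: float, foot_pct: float) -> float:
    """Total percent of whole-body marrow mass in the region (calf + foot)."""
    if calf_pct < 0 or foot_pct < 0:
        raise ValueError("marrow percentages must be non-negative")
    return calf_pct + foot_pct


def default_ankle_fractions() -> FractionTable:
    """The shipped default fraction table for the ankle region."""
    from .datasets import default_fractions

    return default_fractions()
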