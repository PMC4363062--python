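"""Measurement-uncertainty budget: point, tissue and effective-dose level.

All uncertainties are relative (percent) standard uncertainties,
combined in quadrature ("weighted sum of variances") following the GUM
convention:

* point dose:   u_c = sqrt(typeA^2 + 10^2 + 10^2 + 5^2 + 1^2)
                (phantom positioning, dosimeter positioning, x-ray source
                variation, cable irradiation; defaults in
                :class:`SystematicComponents`)
* tissue dose:  each contribution c_i carries variance u_i^2 + u_f^2,
                with u_f = 25 % the uncertainty of the fraction
                irradiated; independent contributions combine as
                u_T = sqrt(sum (c_i * sqrt(u_i^2 + u_f^2))^2) / sum c_i
* effective dose: the same dose-weighted quadrature over tissue terms,
                expanded by a coverage factor (k = 2 ~ 95 %).

Contribution granularity matters: dosimeters enter the tissue
quadrature as independent terms, except tissues listed as *correlated*
(by default the bone surface, whose two dosimeters sit on the same
calcaneal tuberosity) whose members are merged into a single term — a
dose-weighted mean of their point uncertainties carrying one fraction
term.  See docs/methods.md for why this reading is adopted.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, Field

from .engine import (
    DoseEstimate,
    EffectiveDoseResult,
    MGY_TO_UGY,
    round_half_up,
)
from .phantom import Aggregation, Tissue, TissueGroupSet, TissueWeightTable

__all__ = [
    "SystematicComponents",
    "PointUncertainty",
    "UncertaintyBudget",
    "combine_point_uncertainty",
    "tissue_uncertainty",
    "expanded_effective_uncertainty",
    "build_budget",
    "DEFAULT_CORRELATED_TISSUES",
]


class SystematicComponents(BaseModel):
    """Systematic relative uncertainties (percent, 1SD) of a point dose."""

    phantom_positioning_pct: float = Field(10.0, ge=0.0)
    dosimeter_positioning_pct: float = Field(10.0, ge=0.0)
    source_variation_pct: float = Field(5.0, ge=0.0)
    cable_irradiation_pct: float = Field(1.0, ge=0.0)
    fraction_uncertainty_pct: float = Field(25.0, ge=0.0)

    def point_components(self) -> tuple[float, ...]:
        """The components entering the per-dosimeter quadrature (the
        fraction term belongs to the tissue level, not here)."""
        return (
            self.phantom_positioning_pct,
            self.dosimeter_positioning_pct,
            self.source_variation_pct,
            self.cable_irradiation_pct,
        )


def combine_point_uncertainty(
    type_a_pct: float, sys: Optional[SystematicComponents] = None
) -> float:
    """Combined point-dose uncertainty u_c (percent, unrounded).

    Quadrature of the type-A statistical uncertainty with the systematic
    components; reports round half-up to integer percent at display.
    """
    if type_a_pct < 0:
        raise ValueError("type-A uncertainty must be non-negative")
    sys = sys or SystematicComponents()
    return math.sqrt(type_a_pct**2 + sum(c**2 for c in sys.point_components()))


def tissue_uncertainty(
    contributions: Sequence[tuple[float, float]], fraction_u_pct: float
) -> float:
    """Relative uncertainty (percent) of a tissue dose.

    ``contributions`` is a list of (c_i, u_i): dose contributions (any
    common unit) with their relative point uncertainties in percent.
    Each term additionally carries the fraction-irradiated uncertainty;
    terms are independent:

        u_T = sqrt( sum (c_i * sqrt(u_i^2 + u_f^2))^2 ) / sum c_i
    """
    total = sum(c for c, _ in contributions)
    if total <= 0:
        raise ValueError("tissue contributions must sum to a positive dose")
    var = sum((c * math.sqrt(u**2 + fraction_u_pct**2)) ** 2 for c, u in contributions)
    return math.sqrt(var) / total


def expanded_effective_uncertainty(
    tissue_terms: Sequence[tuple[float, float]], k: float = 2.0
) -> float:
    """Expanded combined effective-dose uncertainty U_c (percent).

    ``tissue_terms`` is a list of (contribution uSv, tissue u %); the
    combined relative uncertainty is their dose-weighted quadrature,
    multiplied by the coverage factor ``k`` (k = 2 ~ 95 % by default).
    """
    if not tissue_terms:
        raise ValueError("no tissue terms supplied")
    if k <= 0:
        raise ValueError("coverage factor must be positive")
    total = sum(c for c, _ in tissue_terms)
    if total <= 0:
        raise ValueError("tissue contributions must sum to a positive dose")
    combined = math.sqrt(sum((c * u) ** 2 for c, u in tissue_terms)) / total
    return k * combined


class PointUncertainty(BaseModel):
    """Per-dosimeter uncertainty line of the budget report."""

    dosimeter_no: int
    mean_dose_mGy: float
    type_a_pct: Optional[float]
    combined_pct: float


class UncertaintyBudget(BaseModel):
    """Full study budget: per dosimeter, per tissue, and expanded E level."""

    points: list[PointUncertainty]
    tissue_u_pct: dict[Tissue, float]
    remainder_u_pct: Optional[float] = None
    combined_effective_pct: float
    expanded_effective_pct: float
    coverage_factor: float
    systematics: SystematicComponents

    def point_for(self, dosimeter_no: int) -> PointUncertainty:
        for p in self.points:
            if p.dosimeter_no == dosimeter_no:
                return p
        raise KeyError(f"no budget line for dosimeter {dosimeter_no}")

    def display_points(self) -> dict[int, int]:
        """Integer-percent point uncertainties, half-up."""
        return {p.dosimeter_no: int(round_half_up(p.combined_pct)) for p in self.points}


#: Tissues whose member dosimeters are treated as fully correlated in the
#: tissue-level quadrature (merged into a single contribution term).
DEFAULT_CORRELATED_TISSUES: frozenset[Tissue] = frozenset({Tissue.BONE_SURFACE})


def _per_dosimeter_contributions(
    group, estimates: Mapping[int, DoseEstimate], sys: SystematicComponents
) -> list[tuple[float, float]]:
    """(c_m uSv, u_c,m %) for every member dosimeter of a tissue group."""
    terms: list[tuple[float, float]] = []
    for entry in group.entries:
        n = len(entry.dosimeters)
        for no in entry.dosimeters:
            est = estimates[no]
            if est.rel_sd_pct is None:
                raise ValueError(
                    f"dosimeter {no}: type-A uncertainty undefined "
                    "(single exposure?); cannot build budget"
                )
            u = combine_point_uncertainty(est.rel_sd_pct, sys)
            if entry.aggregation is Aggregation.PER_SITE_FRACTION:
                c = entry.f_i * est.mean_dose_mGy * MGY_TO_UGY
            else:
                c = entry.f_i * est.mean_dose_mGy / n * MGY_TO_UGY
            terms.append((c, u))
    return terms


def build_budget(
    groups: TissueGroupSet,
    estimates: Mapping[int, DoseEstimate],
    result: EffectiveDoseResult,
    weights: TissueWeightTable,
    sys: Optional[SystematicComponents] = None,
    k: float = 2.0,
    correlated_tissues: Iterable[Tissue] = DEFAULT_CORRELATED_TISSUES,
) -> UncertaintyBudget:
    """Assemble the complete uncertainty budget of a study.

    Per-dosimeter combined uncertainties, per-tissue uncertainties (with
    the fraction-irradiated term), and the expanded effective-dose
    uncertainty weighted by the effective-dose contributions of
    ``result``.
    """
    sys = sys or SystematicComponents()
    correlated = set(correlated_tissues)

    points = [
        PointUncertainty(
            dosimeter_no=est.dosimeter_no,
            mean_dose_mGy=est.mean_dose_mGy,
            type_a_pct=est.rel_sd_pct,
            combined_pct=(
                combine_point_uncertainty(est.rel_sd_pct, sys)
                if est.rel_sd_pct is not None
                else float("nan")
            ),
        )
        for est in sorted(estimates.values(), key=lambda e: e.dosimeter_no)
    ]

    tissue_u: dict[Tissue, float] = {}
    remainder_terms: list[tuple[float, float]] = []
    for group in groups:
        terms = _per_dosimeter_contributions(group, estimates, sys)
        if group.tissue in correlated:
            # fully correlated members: dose-weighted mean point
            # uncertainty, a single fraction term
            total = sum(c for c, _ in terms)
            u_corr = sum(c * u for c, u in terms) / total
            terms = [(total, u_corr)]
        if group.tissue in weights.remainder_members:
            remainder_terms.extend(terms)
        tissue_u[group.tissue] = tissue_uncertainty(terms, sys.fraction_uncertainty_pct)

    remainder_u = (
        tissue_uncertainty(remainder_terms, sys.fraction_uncertainty_pct)
        if remainder_terms
        else None
    )

    tissue_terms = [
        (result.tissues[t], tissue_u[t]) for t in tissue_u if t in result.tissues
    ]
    expanded = expanded_effective_uncertainty(tissue_terms, k=k)
    return UncertaintyBudget(
        points=points,
        tissue_u_pct=tissue_u,
        remainder_u_pct=remainder_u,
        combined_effective_pct=expanded / k,
        expanded_effective_pct=expanded,
        coverage_factor=k,
        systematics=sys,
    )
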