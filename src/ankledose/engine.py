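"""Equivalent- and effective-dose computation.

The equivalent dose of tissue T is

    H_T = w_R * sum_i f_i * D_Ti

with w_R = 1 Sv/Gy for x-rays, f_i the fraction of the whole-body organ
in the evaluated region and D_Ti the (mean) absorbed dose of the
dosimeters representing sub-unit i.  The effective dose is

    E = sum_T w_T * H_T

with ICRP-103 tissue weighting factors; muscle and lymphatic nodes
enter as remainder tissues, each weighted w_remainder / 13.

Unit convention: absorbed-dose readings are mGy; H_T, contributions and
E are reported in uSv.  The mGy -> uSv conversion (x 1000, via w_R in
Sv/Gy) is applied exactly once, in :func:`equivalent_dose`.
"""

from __future__ import annotations

import math
import statistics
from typing import Iterable, Mapping, Optional

from pydantic import BaseModel, Field

from .phantom import (
    Aggregation,
    DosimeterRecord,
    Tissue,
    TissueGroup,
    TissueGroupSet,
    TissueWeightTable,
)

__all__ = [
    "DoseEstimate",
    "SubunitContribution",
    "EquivalentDoseResult",
    "EffectiveDoseResult",
    "DoseRatio",
    "estimate_from_readings",
    "mean_dose",
    "equivalent_dose",
    "effective_dose",
    "compute_effective_dose",
    "contribution_breakdown",
    "dose_ratio",
    "round_half_up",
]

MGY_TO_UGY = 1000.0


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero-half-up, as the printed reports do."""
    scale = 10.0**ndigits
    return math.floor(x * scale + 0.5) / scale


class DoseEstimate(BaseModel):
    """Mean absorbed dose of one dosimeter over repeated exposures.

    ``rel_sd_pct`` is the type-A (1SD, sample SD) uncertainty relative to
    the mean, in percent; it is ``None`` (flagged undefined) when only a
    single exposure exists or the mean is zero.
    """

    dosimeter_no: int
    mean_dose_mGy: float = Field(ge=0.0)
    rel_sd_pct: Optional[float] = None
    n_exposures: int = Field(ge=1)


def estimate_from_readings(dosimeter_no: int, readings: list[float]) -> DoseEstimate:
    """Build a :class:`DoseEstimate` from raw repeated readings (mGy).

    Uses the sample SD (n-1 denominator) for the relative spread; with a
    single reading the spread is undefined and left ``None``.
    """
    n = len(readings)
    if n == 0:
        raise ValueError(f"dosimeter {dosimeter_no} has no readings")
    mean = sum(readings) / n
    rel_sd: Optional[float] = None
    if n > 1:
        sd = statistics.stdev(readings)
        if mean > 0:
            rel_sd = 100.0 * sd / mean
        elif sd == 0.0:
            rel_sd = 0.0
        # mean 0 with nonzero spread: relative SD undefined, left None
    return DoseEstimate(
        dosimeter_no=dosimeter_no,
        mean_dose_mGy=mean,
        rel_sd_pct=rel_sd,
        n_exposures=n,
    )


def mean_dose(record: DosimeterRecord) -> DoseEstimate:
    """Average the repeated readings of one dosimeter record."""
    return estimate_from_readings(record.dosimeter_no, record.readings)


class SubunitContribution(BaseModel):
    """One sub-unit's equivalent-dose contribution c_i = f_i * D_i (uSv)."""

    subunit: str
    f_i: float
    dosimeters: list[int]
    mean_dose_mGy: float
    contribution_uSv: float


class EquivalentDoseResult(BaseModel):
    """H_T of one tissue with its per-subunit contributions (uSv)."""

    tissue: Tissue
    H_T_uSv: float
    subunits: list[SubunitContribution]


class EffectiveDoseResult(BaseModel):
    """E with per-tissue contributions w_T*H_T (uSv) and their percentages."""

    E_uSv: float
    tissues: dict[Tissue, float]          # contribution uSv (unrounded)
    H_T_uSv: dict[Tissue, float]
    percentages: dict[Tissue, float]      # unrounded percent of E
    protocol: Optional[str] = None

    def display_percentages(self) -> dict[Tissue, int]:
        """Integer percentages (half-up), computed from unrounded values."""
        return {t: int(round_half_up(p)) for t, p in self.percentages.items()}


def _lookup(estimates: Mapping[int, DoseEstimate], no: int, tissue: Tissue) -> DoseEstimate:
    try:
        return estimates[no]
    except KeyError:
        raise KeyError(
            f"no dose estimate for dosimeter {no} (tissue {tissue.value})"
        ) from None


def equivalent_dose(
    group: TissueGroup,
    estimates: Mapping[int, DoseEstimate],
    w_R: float = 1.0,
) -> EquivalentDoseResult:
    """Equivalent dose H_T (uSv) of one tissue group.

    Per-subunit contribution by aggregation mode:

    * ``mean_then_fraction`` / ``group_mean``: c = f * mean(member doses)
    * ``per_site_fraction``: c = f * dose for every member site

    Raises ``KeyError`` naming the dosimeter if an estimate is missing.
    """
    subs: list[SubunitContribution] = []
    for entry in group.entries:
        doses = [
            _lookup(estimates, no, group.tissue).mean_dose_mGy
            for no in entry.dosimeters
        ]
        if entry.aggregation is Aggregation.PER_SITE_FRACTION:
            c_mGy = entry.f_i * sum(doses)
            site_dose = sum(doses) / len(doses)
        else:  # mean_then_fraction, group_mean
            site_dose = sum(doses) / len(doses)
            c_mGy = entry.f_i * site_dose
        subs.append(
            SubunitContribution(
                subunit=entry.subunit,
                f_i=entry.f_i,
                dosimeters=list(entry.dosimeters),
                mean_dose_mGy=site_dose,
                contribution_uSv=w_R * c_mGy * MGY_TO_UGY,
            )
        )
    return EquivalentDoseResult(
        tissue=group.tissue,
        H_T_uSv=sum(s.contribution_uSv for s in subs),
        subunits=subs,
    )


def effective_dose(
    H_results: Iterable[EquivalentDoseResult],
    weights: TissueWeightTable,
    protocol: Optional[str] = None,
) -> EffectiveDoseResult:
    """Effective dose E = sum_T w_T * H_T (uSv).

    Named tissues contribute w_T * H_T; each remainder member contributes
    (w_remainder / remainder_count) * H_T.  Percentages are computed on
    the unrounded contributions.
    """
    contributions: dict[Tissue, float] = {}
    h_map: dict[Tissue, float] = {}
    for res in H_results:
        if res.tissue in contributions:
            raise ValueError(f"tissue {res.tissue.value} supplied twice")
        contributions[res.tissue] = weights.weight_for(res.tissue) * res.H_T_uSv
        h_map[res.tissue] = res.H_T_uSv
    E = sum(contributions.values())
    pct = {t: (100.0 * c / E if E > 0 else float("nan")) for t, c in contributions.items()}
    return EffectiveDoseResult(
        E_uSv=E, tissues=contributions, H_T_uSv=h_map, percentages=pct, protocol=protocol
    )


def compute_effective_dose(
    groups: TissueGroupSet,
    estimates: Mapping[int, DoseEstimate],
    weights: TissueWeightTable,
    protocol: Optional[str] = None,
) -> EffectiveDoseResult:
    """End-to-end: equivalent doses for every tissue group, then E."""
    results = [equivalent_dose(g, estimates, weights.w_R) for g in groups]
    return effective_dose(results, weights, protocol=protocol)


def contribution_breakdown(
    result: EffectiveDoseResult,
) -> list[tuple[Tissue, float, int]]:
    """Per-tissue (contribution uSv, integer percent of E), largest first.

    Raises ``ValueError`` when E = 0 (percentages undefined).
    """
    if result.E_uSv <= 0:
        raise ValueError("percent breakdown undefined for E = 0")
    rows = [
        (t, c, int(round_half_up(100.0 * c / result.E_uSv)))
        for t, c in result.tissues.items()
    ]
    rows.sort(key=lambda r: r[1], reverse=True)
    return rows


class DoseRatio(BaseModel):
    """Fold ratio of two effective doses with its display form."""

    raw: float
    display: str


def dose_ratio(E_a_uSv: float, E_b_uSv: float) -> DoseRatio:
    """E_a / E_b with a display rule: nearest-integer fold when >= 10,
    one decimal otherwise."""
    if E_b_uSv <= 0:
        raise ValueError("reference effective dose must be positive")
    raw = E_a_uSv / E_b_uSv
    if raw >= 10:
        display = f"{int(round_half_up(raw))}-fold"
    else:
        display = f"{round_half_up(raw, 1):.1f}-fold"
    return DoseRatio(raw=raw, display=display)
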