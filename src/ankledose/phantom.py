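"""Data model of the sliced ankle phantom and its dosimeter placements.

The phantom is an anthropomorphic leg sectioned into 25 mm layers
(numbered 23-28 for the ankle region in the shipped default) with
point dosimeters placed in bone marrow, on the bone surface, in the
skin, in muscle and in lymphatic tissue.  Tissue membership, the
fraction of each whole-body organ that lies in the scanned region
(f_i) and the ICRP-103 tissue weighting factors are configuration,
validated here and consumed by :mod:`ankledose.engine`.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Tissue",
    "Aggregation",
    "PhantomLayer",
    "DosimeterRecord",
    "FractionEntry",
    "FractionTable",
    "TissueWeightTable",
    "PhantomModel",
    "TissueGroup",
    "TissueGroupSet",
    "WeightValidationReport",
    "build_phantom",
    "resolve_groups",
    "validate_weights",
    "ICRP103_REFERENCE_WEIGHTS",
]


class Tissue(str, enum.Enum):
    """The five tissue classes instrumented in the ankle phantom."""

    BONE_MARROW = "bone_marrow"
    BONE_SURFACE = "bone_surface"
    SKIN = "skin"
    MUSCLE = "muscle"
    LYMPHATIC_NODES = "lymphatic_nodes"


class Aggregation(str, enum.Enum):
    """How member dosimeter doses combine into a sub-unit dose contribution.

    ``MEAN_THEN_FRACTION``
        c = f * mean(member doses); used per bone for marrow, where several
        dosimeters sample one bone at different depths/layers.
    ``PER_SITE_FRACTION``
        c = sum over members of f * dose; each member dosimeter is its own
        site carrying the full fraction (skin sites, bone-surface sites).
    ``GROUP_MEAN``
        c = f * mean(member doses) over the whole tissue group (muscle,
        lymphatic nodes); numerically identical to MEAN_THEN_FRACTION for a
        single-entry tissue but kept distinct because it declares intent.
    """

    MEAN_THEN_FRACTION = "mean_then_fraction"
    PER_SITE_FRACTION = "per_site_fraction"
    GROUP_MEAN = "group_mean"


class PhantomLayer(BaseModel):
    """One transverse slab of the phantom."""

    index: int
    thickness_mm: float = Field(25.0, gt=0.0)
    perimeter_mm: Optional[float] = Field(None, gt=0.0)
    description: str = ""


class DosimeterRecord(BaseModel):
    """One physical dosimeter: placement plus repeated absorbed-dose readings (mGy)."""

    dosimeter_no: int
    layer: int
    site: str
    tissue: Tissue
    subunit: str
    readings: list[float] = Field(default_factory=list)

    @field_validator("readings")
    @classmethod
    def _nonnegative(cls, v: list[float]) -> list[float]:
        for x in v:
            if x < 0:
                raise ValueError(f"negative absorbed-dose reading {x} mGy")
        return v


class FractionEntry(BaseModel):
    """One organ sub-unit: its fraction irradiated f_i and member dosimeters."""

    tissue: Tissue
    subunit: str
    f_i: float = Field(gt=0.0, le=1.0)
    dosimeters: list[int] = Field(min_length=1)
    aggregation: Aggregation

    @field_validator("dosimeters")
    @classmethod
    def _unique_members(cls, v: list[int]) -> list[int]:
        if len(set(v)) != len(v):
            raise ValueError("duplicate dosimeter in fraction entry")
        return v


class FractionTable(BaseModel):
    """All fraction entries of a study; a dosimeter may serve at most one entry."""

    entries: list[FractionEntry]

    @model_validator(mode="after")
    def _disjoint(self) -> "FractionTable":
        seen: dict[int, str] = {}
        for e in self.entries:
            for d in e.dosimeters:
                if d in seen:
                    raise ValueError(
                        f"dosimeter {d} appears in both {seen[d]!r} and {e.subunit!r}"
                    )
                seen[d] = e.subunit
        return self

    def claimed_dosimeters(self) -> set[int]:
        return {d for e in self.entries for d in e.dosimeters}

    def for_tissue(self, tissue: Tissue) -> list[FractionEntry]:
        return [e for e in self.entries if e.tissue == tissue]


#: ICRP-103 constants this study uses: named-tissue weights, the collective
#: remainder weight, and the x-ray radiation weighting factor.
ICRP103_REFERENCE_WEIGHTS: dict[str, float] = {
    "bone_marrow": 0.12,
    "bone_surface": 0.01,
    "skin": 0.01,
    "remainder": 0.12,
    "w_R": 1.0,
}


class TissueWeightTable(BaseModel):
    """ICRP-103 tissue weighting factors and remainder-tissue scheme.

    ``w_T`` maps the named tissues (and the key ``"remainder"``) to their
    weighting factors.  Remainder members each receive
    ``w_T["remainder"] / remainder_count`` where ``remainder_count`` is the
    size of the full ICRP-103 remainder set (13 tissues), of which only
    muscle and lymphatic nodes lie in the leg.
    """

    w_T: dict[str, float]
    remainder_members: set[Tissue] = Field(
        default_factory=lambda: {Tissue.MUSCLE, Tissue.LYMPHATIC_NODES}
    )
    remainder_count: int = Field(13, ge=1)
    w_R: float = Field(1.0, gt=0.0)

    @field_validator("w_T")
    @classmethod
    def _positive(cls, v: dict[str, float]) -> dict[str, float]:
        for k, w in v.items():
            if w <= 0:
                raise ValueError(f"non-positive weighting factor for {k}: {w}")
        return v

    def weight_for(self, tissue: Tissue) -> float:
        """Effective-dose weight applied to H_T of ``tissue``."""
        if tissue in self.remainder_members:
            return self.w_T["remainder"] / self.remainder_count
        try:
            return self.w_T[tissue.value]
        except KeyError:
            raise KeyError(f"no tissue weighting factor for {tissue.value}") from None


class PhantomModel(BaseModel):
    """A validated phantom: layers plus dosimeter placements."""

    layers: list[PhantomLayer]
    records: list[DosimeterRecord]

    @model_validator(mode="after")
    def _validate(self) -> "PhantomModel":
        idx = [l.index for l in self.layers]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate layer index in phantom")
        nos = [r.dosimeter_no for r in self.records]
        dup = {n for n in nos if nos.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate dosimeter_no: {sorted(dup)}")
        known = set(idx)
        for r in self.records:
            if r.layer not in known:
                raise ValueError(
                    f"dosimeter {r.dosimeter_no} references unknown layer {r.layer}"
                )
        return self

    def record(self, dosimeter_no: int) -> DosimeterRecord:
        for r in self.records:
            if r.dosimeter_no == dosimeter_no:
                return r
        raise KeyError(f"no dosimeter numbered {dosimeter_no}")

    def layer(self, index: int) -> PhantomLayer:
        for l in self.layers:
            if l.index == index:
                return l
        raise KeyError(f"no layer {index}")

    def by_tissue(self, tissue: Tissue) -> list[DosimeterRecord]:
        return [r for r in self.records if r.tissue == tissue]

    def by_site(self, tissue: Tissue, subunit: str) -> list[DosimeterRecord]:
        return [r for r in self.records if r.tissue == tissue and r.subunit == subunit]

    @property
    def dosimeter_numbers(self) -> set[int]:
        return {r.dosimeter_no for r in self.records}


class TissueGroup(BaseModel):
    """One tissue's resolved sub-units: (subunit, f_i, member records, mode)."""

    tissue: Tissue
    entries: list[FractionEntry]
    members: dict[str, list[DosimeterRecord]]  # subunit -> records

    def member_numbers(self) -> set[int]:
        return {r.dosimeter_no for recs in self.members.values() for r in recs}


class TissueGroupSet(BaseModel):
    """All tissue groups of a study plus the dosimeters no entry claimed."""

    groups: dict[Tissue, TissueGroup]
    unused_dosimeters: list[int]

    def __iter__(self):
        return iter(self.groups.values())


class WeightValidationReport(BaseModel):
    """Report-only check of a weight table against the ICRP-103 constants."""

    deviations: list[str]

    @property
    def ok(self) -> bool:
        return not self.deviations


def build_phantom(
    layers: list[PhantomLayer], records: list[DosimeterRecord]
) -> PhantomModel:
    """Assemble and validate a phantom model.

    Raises ``ValueError`` (via pydantic) on duplicate dosimeter numbers,
    duplicate layer indices, or records referencing unknown layers.
    """
    return PhantomModel(layers=layers, records=records)


def resolve_groups(model: PhantomModel, fractions: FractionTable) -> TissueGroupSet:
    """Attach dose records to fraction entries, grouped by tissue.

    Dosimeters not claimed by any entry are reported in
    ``unused_dosimeters`` (not an error — e.g. the talus marrow dosimeter
    in the shipped default).  An entry citing a dosimeter absent from the
    phantom raises ``KeyError`` naming the offending id.
    """
    groups: dict[Tissue, TissueGroup] = {}
    for tissue in Tissue:
        entries = fractions.for_tissue(tissue)
        if not entries:
            continue
        members: dict[str, list[DosimeterRecord]] = {}
        for e in entries:
            recs = []
            for no in e.dosimeters:
                try:
                    recs.append(model.record(no))
                except KeyError:
                    raise KeyError(
                        f"fraction entry {e.subunit!r} cites dosimeter {no}, "
                        f"which is not in the phantom"
                    ) from None
            members[e.subunit] = recs
        groups[tissue] = TissueGroup(tissue=tissue, entries=entries, members=members)
    unused = sorted(model.dosimeter_numbers - fractions.claimed_dosimeters())
    return TissueGroupSet(groups=groups, unused_dosimeters=unused)


def validate_weights(weights: TissueWeightTable) -> WeightValidationReport:
    """Compare a weight table against the ICRP-103 constants used here.

    Report-only: deviations are listed, never raised.
    """
    dev: list[str] = []
    for key in ("bone_marrow", "bone_surface", "skin", "remainder"):
        expected = ICRP103_REFERENCE_WEIGHTS[key]
        got = weights.w_T.get(key)
        if got is None:
            dev.append(f"missing w_T entry {key!r} (ICRP 103: {expected})")
        elif abs(got - expected) > 1e-12:
            dev.append(f"w_T[{key!r}] = {got}, ICRP 103 uses {expected}")
    if abs(weights.w_R - 1.0) > 1e-12:
        dev.append(f"w_R = {weights.w_R}, but w_R = 1 Sv/Gy for x-rays")
    extra = weights.remainder_members - {Tissue.MUSCLE, Tissue.LYMPHATIC_NODES}
    if extra:
        dev.append(
            "remainder members outside the leg's remainder tissues: "
            + ", ".join(sorted(t.value for t in extra))
        )
    return WeightValidationReport(deviations=dev)
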