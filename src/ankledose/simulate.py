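"""Synthetic studies: dose fields, noisy repeated readings, ground truth.

Real scanner dose fields in a layered extremity phantom are strongly
non-uniform along the scan axis: doses inside the field of view are an
order of magnitude (roughly 40x) above those just outside, where only
the scatter tail reaches.  The generator emulates this with a
phenomenological two-exponential model — depth attenuation inside the
FOV, an exponential scatter tail outside — not radiation transport.
Reading noise is multiplicative Gaussian with a dose-dependent relative
SD, large (tens of percent) at sub-mGy doses and a few percent above a
few mGy, matching the spread pattern of repeated point-dosimeter
measurements.  All randomness is seeded.
"""

from __future__ import annotations

import enum
import logging
import warnings
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .engine import DoseEstimate, EffectiveDoseResult, compute_effective_dose
from .phantom import (
    FractionTable,
    PhantomModel,
    Tissue,
    TissueWeightTable,
    resolve_groups,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Modality",
    "ProtocolSpec",
    "DoseFieldParams",
    "NoiseModel",
    "TYPICAL_DEPTH_MM",
    "generate_dose_field",
    "sample_readings",
    "ground_truth_effective_dose",
    "make_fixture",
    "FixtureBundle",
]


class Modality(str, enum.Enum):
    MSCT = "MSCT"
    CBCT = "CBCT"
    RADIOGRAPHY = "radiography"


class ProtocolSpec(BaseModel):
    """Exposure protocol of one device/mode."""

    name: str
    modality: Modality
    kVp: float = Field(gt=0.0)
    mAs: float = Field(gt=0.0)
    fov_length_mm: float = Field(gt=0.0)
    scan_angle_deg: float = 360.0
    projections: Optional[list[str]] = None


class DoseFieldParams(BaseModel):
    """Two-exponential phenomenological dose-field model.

    Inside the FOV: dose = peak * exp(-depth_mu * depth).  Outside: the
    in-field edge value times ``out_of_field_fraction``, decaying
    exponentially with distance from the FOV edge.  Defaults give an
    in-field : out-of-field ratio of roughly 40 across the default
    phantom, the spread observed between field-centre and field-edge
    dosimeters.
    """

    peak_dose_mGy: float = Field(10.0, gt=0.0)
    depth_mu_per_mm: float = Field(0.01, ge=0.0)
    out_of_field_fraction: float = Field(0.1, gt=0.0, lt=1.0)
    out_of_field_decay_per_mm: float = Field(0.09, ge=0.0)


class NoiseModel(BaseModel):
    """Dose-dependent multiplicative reading noise.

    Relative SD (percent): sigma_rel(D) = sigma_floor + sigma_scale / D^power,
    D in mGy.  Defaults (floor 4 %, scale 7.25 %*mGy, power 1) are
    calibrated so sigma_rel(0.25 mGy) = 33 % and sigma_rel drops to
    ~5 % above 4 mGy, the pattern of repeated readings at low and high
    dose.  ``power = 0.5`` selects an inverse-square-root law instead.
    A seed is mandatory: there is no unseeded randomness anywhere.
    """

    sigma_floor_pct: float = Field(4.0, ge=0.0)
    sigma_scale_pct: float = Field(7.25, ge=0.0)
    power: float = Field(1.0, gt=0.0)
    seed: int

    def rel_sd_pct(self, dose_mGy: float) -> float:
        if dose_mGy <= 0:
            return self.sigma_floor_pct
        return self.sigma_floor_pct + self.sigma_scale_pct / dose_mGy**self.power


#: Typical depth (mm) of each tissue class below the surface, used to
#: evaluate the depth-attenuation term of the field model.
TYPICAL_DEPTH_MM: dict[Tissue, float] = {
    Tissue.SKIN: 0.0,
    Tissue.BONE_SURFACE: 8.0,
    Tissue.LYMPHATIC_NODES: 15.0,
    Tissue.MUSCLE: 20.0,
    Tissue.BONE_MARROW: 30.0,
}


def _layer_positions(model: PhantomModel) -> dict[int, float]:
    """Axial centre (mm) of each layer, proximal end at 0."""
    layers = sorted(model.layers, key=lambda l: l.index)
    z = 0.0
    pos = {}
    for l in layers:
        pos[l.index] = z + l.thickness_mm / 2.0
        z += l.thickness_mm
    return pos


def generate_dose_field(
    protocol: ProtocolSpec,
    model: PhantomModel,
    params: Optional[DoseFieldParams] = None,
    fov_start_mm: float = 25.0,
    depths_mm: Optional[Mapping[Tissue, float]] = None,
) -> dict[int, float]:
    """True (noiseless) dose per dosimeter (mGy) under the field model.

    The FOV spans ``[fov_start_mm, fov_start_mm + protocol.fov_length_mm]``
    along the layer axis (default: from the second layer on, the beam
    aimed at the distal layers).  Doses are strictly positive everywhere;
    an FOV that misses the phantom entirely yields an all-scatter field
    with a warning.
    """
    params = params or DoseFieldParams()
    depths = dict(depths_mm or TYPICAL_DEPTH_MM)
    pos = _layer_positions(model)
    fov_lo = fov_start_mm
    fov_hi = fov_start_mm + protocol.fov_length_mm
    extent = sum(l.thickness_mm for l in model.layers)
    if fov_hi < 0 or fov_lo > extent:
        warnings.warn("FOV does not overlap the phantom; field is all scatter")
    doses: dict[int, float] = {}
    for rec in model.records:
        z = pos[rec.layer]
        depth = depths[rec.tissue]
        in_field = params.peak_dose_mGy * np.exp(-params.depth_mu_per_mm * depth)
        if fov_lo <= z <= fov_hi:
            dose = in_field
        else:
            dist = fov_lo - z if z < fov_lo else z - fov_hi
            dose = (
                in_field
                * params.out_of_field_fraction
                * np.exp(-params.out_of_field_decay_per_mm * dist)
            )
            # numerical floor: the scatter tail never underflows to zero
            dose = max(float(dose), params.peak_dose_mGy * 1e-15)
        doses[rec.dosimeter_no] = float(dose)
    return doses


def sample_readings(
    true_doses: Mapping[int, float],
    noise: NoiseModel,
    n_exposures: int = 6,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Draw repeated noisy readings for every dosimeter.

    Each reading is ``true * (1 + eps)`` with
    ``eps ~ Normal(0, sigma_rel(true))``; negative draws are truncated at
    zero and their count logged (and stored in ``df.attrs["n_truncated"]``).
    The same seed always yields the identical table.
    """
    if n_exposures < 1:
        raise ValueError("need at least one exposure")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    rows = []
    n_truncated = 0
    for no in sorted(true_doses):
        true = true_doses[no]
        sigma = noise.rel_sd_pct(true) / 100.0
        draws = true * (1.0 + rng.normal(0.0, sigma, size=n_exposures))
        neg = draws < 0
        n_truncated += int(neg.sum())
        draws[neg] = 0.0
        for i, d in enumerate(draws, start=1):
            rows.append({"dosimeter_no": no, "exposure_index": i, "dose_mGy": float(d)})
    if n_truncated:
        logger.info("truncated %d negative reading draws at zero", n_truncated)
    df = pd.DataFrame(rows, columns=["dosimeter_no", "exposure_index", "dose_mGy"])
    df.attrs["n_truncated"] = n_truncated
    return df


def ground_truth_effective_dose(
    true_doses: Mapping[int, float],
    model: PhantomModel,
    fractions: FractionTable,
    weights: TissueWeightTable,
) -> EffectiveDoseResult:
    """The dose-engine result on noiseless doses (one exact exposure each)."""
    groups = resolve_groups(model, fractions)
    estimates = {
        no: DoseEstimate(
            dosimeter_no=no, mean_dose_mGy=d, rel_sd_pct=0.0, n_exposures=1
        )
        for no, d in true_doses.items()
    }
    return compute_effective_dose(groups, estimates, weights)


class FixtureBundle(BaseModel):
    """Paths and ground truth of one generated study bundle."""

    directory: Path
    phantom: Path
    fractions: Path
    weights: Path
    readings: Path
    truth: Path
    E_true_uSv: float


def make_fixture(
    out_dir: Path | str,
    seed: int,
    protocol: Optional[ProtocolSpec] = None,
    field: Optional[DoseFieldParams] = None,
    noise: Optional[NoiseModel] = None,
    n_exposures: int = 6,
) -> FixtureBundle:
    """Generate a complete self-contained study bundle.

    Writes phantom/fraction/weight configs, a long-format readings CSV
    (20 dosimeters x ``n_exposures``) and a truth record with the
    noiseless E and per-tissue equivalent doses.  Identical seeds yield
    identical files.
    """
    from .datasets import default_fractions, default_phantom, default_weights
    from .io import save_fractions, save_phantom, save_weights

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = protocol or ProtocolSpec(
        name="synthetic_cbct", modality=Modality.CBCT, kVp=110, mAs=59,
        fov_length_mm=125.0,
    )
    noise = noise or NoiseModel(seed=seed)
    model = default_phantom()
    fractions = default_fractions()
    weights = default_weights()

    true_doses = generate_dose_field(protocol, model, field)
    readings = sample_readings(true_doses, noise, n_exposures=n_exposures, seed=seed)
    truth = ground_truth_effective_dose(true_doses, model, fractions, weights)

    paths = {
        "phantom": out / "phantom.yaml",
        "fractions": out / "fractions.yaml",
        "weights": out / "weights.yaml",
        "readings": out / "readings.csv",
        "truth": out / "truth.yaml",
    }
    save_phantom(model, paths["phantom"])
    save_fractions(fractions, paths["fractions"])
    save_weights(weights, paths["weights"])
    readings.to_csv(paths["readings"], index=False)
    truth_doc = {
        "schema": "ankledose/truth-v1",
        "seed": seed,
        "protocol": protocol.name,
        "E_true_uSv": truth.E_uSv,
        "H_T_uSv": {t.value: h for t, h in truth.H_T_uSv.items()},
        "true_doses_mGy": {int(k): v for k, v in true_doses.items()},
        "n_truncated": int(readings.attrs["n_truncated"]),
    }
    paths["truth"].write_text(yaml.safe_dump(truth_doc, sort_keys=False))
    return FixtureBundle(directory=out, E_true_uSv=truth.E_uSv, **paths)
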