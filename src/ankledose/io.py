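"""File I/O: config schemas (YAML), readings CSVs and study reports.

Config schemas (all versioned by a ``schema`` key):

* ``ankledose/phantom-v1``   — layers + dosimeter placements
* ``ankledose/fractions-v1`` — fraction-irradiated entries
* ``ankledose/weights-v1``   — tissue weighting factors
* ``ankledose/study-v1``     — paths + options tying a study together

Readings CSVs come in two dialects (comma-separated, dot decimal, units
in the header contract):

* long:          ``dosimeter_no,exposure_index,dose_mGy``
* pre-averaged:  ``dosimeter_no,mean_dose_mGy,rel_sd_pct,n``
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .engine import (
    DoseEstimate,
    EffectiveDoseResult,
    compute_effective_dose,
    contribution_breakdown,
    estimate_from_readings,
    round_half_up,
)
from .phantom import (
    Aggregation,
    DosimeterRecord,
    FractionEntry,
    FractionTable,
    PhantomLayer,
    PhantomModel,
    Tissue,
    TissueWeightTable,
    resolve_groups,
    validate_weights,
)
from .uncertainty import SystematicComponents, UncertaintyBudget, build_budget

__all__ = [
    "load_phantom",
    "save_phantom",
    "load_fractions",
    "save_fractions",
    "load_weights",
    "save_weights",
    "read_readings_csv",
    "StudyConfig",
    "StudyReport",
    "run_study",
]

LONG_COLUMNS = ["dosimeter_no", "exposure_index", "dose_mGy"]
AVERAGED_COLUMNS = ["dosimeter_no", "mean_dose_mGy", "rel_sd_pct", "n"]

PathLike = Union[str, Path]


def _check_schema(doc: dict, expected: str, path: PathLike) -> None:
    got = doc.get("schema")
    if got != expected:
        raise ValueError(f"{path}: expected schema {expected!r}, found {got!r}")


def load_phantom(path: PathLike) -> PhantomModel:
    doc = yaml.safe_load(Path(path).read_text())
    _check_schema(doc, "ankledose/phantom-v1", path)
    layers = [
        PhantomLayer(
            index=l["index"],
            thickness_mm=l.get("thickness_mm", 25.0),
            perimeter_mm=l.get("perimeter_mm"),
            description=l.get("description", ""),
        )
        for l in doc["layers"]
    ]
    records = [
        DosimeterRecord(
            dosimeter_no=d["dosimeter_no"],
            layer=d["layer"],
            site=d["site"],
            tissue=Tissue(d["tissue"]),
            subunit=d["subunit"],
            readings=d.get("readings", []),
        )
        for d in doc["dosimeters"]
    ]
    return PhantomModel(layers=layers, records=records)


def save_phantom(model: PhantomModel, path: PathLike) -> None:
    doc = {
        "schema": "ankledose/phantom-v1",
        "layers": [
            {
                "index": l.index,
                "thickness_mm": l.thickness_mm,
                **({"perimeter_mm": l.perimeter_mm} if l.perimeter_mm else {}),
                "description": l.description,
            }
            for l in model.layers
        ],
        "dosimeters": [
            {
                "dosimeter_no": r.dosimeter_no,
                "layer": r.layer,
                "site": r.site,
                "tissue": r.tissue.value,
                "subunit": r.subunit,
                **({"readings": r.readings} if r.readings else {}),
            }
            for r in model.records
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_fractions(path: PathLike) -> FractionTable:
    doc = yaml.safe_load(Path(path).read_text())
    _check_schema(doc, "ankledose/fractions-v1", path)
    entries = [
        FractionEntry(
            tissue=Tissue(e["tissue"]),
            subunit=e["subunit"],
            f_i=e["f_i"],
            dosimeters=e["dosimeters"],
            aggregation=Aggregation(e["aggregation"]),
        )
        for e in doc["entries"]
    ]
    return FractionTable(entries=entries)


def save_fractions(table: FractionTable, path: PathLike) -> None:
    doc = {
        "schema": "ankledose/fractions-v1",
        "entries": [
            {
                "tissue": e.tissue.value,
                "subunit": e.subunit,
                "f_i": e.f_i,
                "dosimeters": e.dosimeters,
                "aggregation": e.aggregation.value,
            }
            for e in table.entries
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_weights(path: PathLike) -> TissueWeightTable:
    doc = yaml.safe_load(Path(path).read_text())
    _check_schema(doc, "ankledose/weights-v1", path)
    return TissueWeightTable(
        w_T=doc["w_T"],
        remainder_members={Tissue(t) for t in doc["remainder_members"]},
        remainder_count=doc["remainder_count"],
        w_R=doc.get("w_R", 1.0),
    )


def save_weights(weights: TissueWeightTable, path: PathLike) -> None:
    doc = {
        "schema": "ankledose/weights-v1",
        "w_R": weights.w_R,
        "w_T": dict(weights.w_T),
        "remainder_members": sorted(t.value for t in weights.remainder_members),
        "remainder_count": weights.remainder_count,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_readings_csv(
    path: PathLike, model: Optional[PhantomModel] = None
) -> dict[int, DoseEstimate]:
    """Read a readings CSV (long or pre-averaged dialect) into estimates.

    With a phantom ``model`` supplied, every dosimeter number is checked
    against it.  Unknown column sets raise a format error; negative doses
    raise a validation error naming the row.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols == LONG_COLUMNS:
        neg = df[df["dose_mGy"] < 0]
        if not neg.empty:
            row = int(neg.index[0]) + 2  # header is line 1
            raise ValueError(f"{path}: negative dose on line {row}")
        estimates: dict[int, DoseEstimate] = {}
        for no, sub in df.groupby("dosimeter_no"):
            readings = list(sub.sort_values("exposure_index")["dose_mGy"])
            estimates[int(no)] = estimate_from_readings(int(no), readings)
    elif cols == AVERAGED_COLUMNS:
        neg = df[df["mean_dose_mGy"] < 0]
        if not neg.empty:
            row = int(neg.index[0]) + 2
            raise ValueError(f"{path}: negative dose on line {row}")
        estimates = {
            int(r.dosimeter_no): DoseEstimate(
                dosimeter_no=int(r.dosimeter_no),
                mean_dose_mGy=float(r.mean_dose_mGy),
                rel_sd_pct=float(r.rel_sd_pct),
                n_exposures=int(r.n),
            )
            for r in df.itertuples()
        }
    else:
        raise ValueError(
            f"{path}: unknown readings column set {cols}; expected "
            f"{LONG_COLUMNS} or {AVERAGED_COLUMNS} (units are part of the header)"
        )
    if model is not None:
        unknown = set(estimates) - model.dosimeter_numbers
        if unknown:
            raise ValueError(f"{path}: dosimeters not in phantom: {sorted(unknown)}")
    return estimates


class StudyConfig(BaseModel):
    """Everything needed to run one study end-to-end."""

    phantom: Path
    fractions: Path
    weights: Path
    readings: Path
    protocol: Optional[str] = None
    coverage_factor: float = Field(2.0, gt=0.0)
    systematics: SystematicComponents = Field(default_factory=SystematicComponents)
    timestamp_header: bool = True


class StudyReport(BaseModel):
    """The computed study: effective dose result plus uncertainty budget."""

    result: EffectiveDoseResult
    budget: UncertaintyBudget
    unused_dosimeters: list[int]
    options: dict[str, object]

    def dose_table(self) -> pd.DataFrame:
        rows = []
        for tissue, c, pct in contribution_breakdown(self.result):
            rows.append(
                {
                    "tissue": tissue.value,
                    "H_T_uSv": round_half_up(self.result.H_T_uSv[tissue], 1),
                    "contribution_uSv": round_half_up(c, 1),
                    "percent_of_E": pct,
                    "tissue_u_pct": int(
                        round_half_up(self.budget.tissue_u_pct[tissue])
                    ),
                }
            )
        return pd.DataFrame(rows)

    def budget_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dosimeter_no": p.dosimeter_no,
                    "mean_dose_mGy": p.mean_dose_mGy,
                    "type_a_pct": p.type_a_pct,
                    "point_u_pct": int(round_half_up(p.combined_pct)),
                }
                for p in self.budget.points
            ]
        )

    def summary_lines(self) -> list[str]:
        E = self.result.E_uSv
        return [
            f"effective dose E = {round_half_up(E, 1):.1f} uSv",
            f"expanded (k={self.budget.coverage_factor:g}) uncertainty U_c = "
            f"{int(round_half_up(self.budget.expanded_effective_pct))} %",
        ]

    def write(self, out_dir: PathLike, timestamp: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dose_table().to_csv(out / "dose_report.csv", index=False)
        self.budget_table().to_csv(out / "uncertainty_budget.csv", index=False)
        lines = []
        if timestamp:
            lines.append(f"# generated {_dt.datetime.now().isoformat(timespec='seconds')}")
        lines.append("# options: " + ", ".join(f"{k}={v}" for k, v in self.options.items()))
        if self.unused_dosimeters:
            lines.append(f"# unused dosimeters: {self.unused_dosimeters}")
        lines.append(self.dose_table().to_string(index=False))
        lines.extend(self.summary_lines())
        (out / "report.txt").write_text("\n".join(lines) + "\n")


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full analysis a config describes (deterministic)."""
    for p in (config.phantom, config.fractions, config.weights, config.readings):
        if not Path(p).exists():
            raise FileNotFoundError(f"study input not found: {p}")
    model = load_phantom(config.phantom)
    fractions = load_fractions(config.fractions)
    weights = load_weights(config.weights)
    report = validate_weights(weights)
    estimates = read_readings_csv(config.readings, model)
    groups = resolve_groups(model, fractions)
    result = compute_effective_dose(groups, estimates, weights, protocol=config.protocol)
    budget = build_budget(
        groups,
        estimates,
        result,
        weights,
        sys=config.systematics,
        k=config.coverage_factor,
    )
    options: dict[str, object] = {
        "aggregations": {
            e.subunit: e.aggregation.value for e in fractions.entries
        },
        "remainder_count": weights.remainder_count,
        "coverage_factor": config.coverage_factor,
        "weight_deviations": report.deviations,
    }
    return StudyReport(
        result=result,
        budget=budget,
        unused_dosimeters=groups.unused_dosimeters,
        options=options,
    )
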