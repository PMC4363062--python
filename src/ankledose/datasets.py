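"""Accessors for the packaged default study configuration and reference data."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .engine import DoseEstimate
from .io import load_fractions, load_phantom, load_weights, read_readings_csv
from .phantom import FractionTable, PhantomModel, TissueWeightTable

__all__ = [
    "data_path",
    "default_phantom",
    "default_fractions",
    "default_weights",
    "newtom_hires_readings",
    "published_dose_table",
    "protocol_specs",
]


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("ankledose.data") / name)


def default_phantom() -> PhantomModel:
    """The six-layer ankle phantom with its twenty dosimeter placements."""
    return load_phantom(data_path("phantom_ankle.yaml"))


def default_fractions() -> FractionTable:
    """The shipped ankle-region fraction-irradiated table."""
    return load_fractions(data_path("fractions_ankle.yaml"))


def default_weights() -> TissueWeightTable:
    """ICRP-103 tissue weights with the 13-tissue remainder scheme."""
    return load_weights(data_path("weights_icrp103.yaml"))


def newtom_hires_readings() -> dict[int, DoseEstimate]:
    """Measured mean doses and type-A spreads of the high-resolution
    small-FOV cone-beam protocol (six exposures per dosimeter)."""
    return read_readings_csv(data_path("readings_newtom_12x8.csv"))


def published_dose_table() -> pd.DataFrame:
    """Published per-tissue contributions and effective doses (uSv) of all
    six protocols, indexed by quantity."""
    return pd.read_csv(data_path("published_effective_doses.csv")).set_index("quantity")


def protocol_specs() -> list[dict]:
    """Exposure parameters of the compared devices (raw dicts)."""
    doc = yaml.safe_load(data_path("protocols.yaml").read_text())
    return doc["protocols"]
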