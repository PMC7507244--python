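"""Core corneal data containers.

The vertical corneal meridian is split into three imaging regions
(superior, central, inferior), each divided into 10 equal zones, giving
30 ordered zones per sublayer: z1..z10 superior, z11..z20 central,
z21..z30 inferior.  Zone index is the spatial unit throughout; all
thicknesses are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .registry import GROUPS, LAYERS, PENTACAM_FEATURES

N_ZONES = 30
REGIONS = ("superior", "central", "inferior")

GENDERS = ("female", "male")
#: Gender encoding used in the feature table.
GENDER_CODE = {"female": 0, "male": 1}


def zone_region(zone_index: int) -> str:
    """Region of a 1-based zone index."""
    if not 1 <= zone_index <= N_ZONES:
        raise ValueError(f"zone index {zone_index} outside 1..{N_ZONES}")
    return REGIONS[(zone_index - 1) // 10]


@dataclass(frozen=True)
class ZonalProfile:
    """Mean thickness of one sublayer over the 30 meridional zones."""

    eye_id: str
    layer: str
    zones: np.ndarray

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        zones = np.asarray(self.zones, dtype=float)
        if zones.shape != (N_ZONES,):
            raise ValueError(f"profile must have exactly {N_ZONES} zones, got shape {zones.shape}")
        if not np.all(np.isfinite(zones)) or np.any(zones <= 0):
            raise ValueError(f"all zone thicknesses must be finite and > 0 ({self.eye_id}/{self.layer})")
        zones.setflags(write=False)
        object.__setattr__(self, "zones", zones)


@dataclass(frozen=True)
class EyeRecord:
    """One eye: group label, gender, three sublayer profiles and the
    Scheimpflug-camera feature block."""

    eye_id: str
    group: str
    gender: str
    profiles: Mapping[str, ZonalProfile]
    scheimpflug: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        missing_layers = [l for l in LAYERS if l not in self.profiles]
        if missing_layers:
            raise ValueError(f"eye {self.eye_id} missing layers: {missing_layers}")
        missing = [f for f in PENTACAM_FEATURES if f not in self.scheimpflug]
        if missing:
            raise ValueError(f"eye {self.eye_id} missing Scheimpflug features: {missing}")
        object.__setattr__(self, "profiles", dict(self.profiles))
        object.__setattr__(self, "scheimpflug", {f: float(self.scheimpflug[f]) for f in PENTACAM_FEATURES})


@dataclass(frozen=True)
class NormativePattern:
    """Zonal mean thickness per layer over a reference cohort of normal
    eyes — the "pattern average" against which profile deviation (PSD)
    is measured."""

    zones: Mapping[str, np.ndarray]
    n_eyes: int = 0

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for layer in LAYERS:
            if layer not in self.zones:
                raise ValueError(f"pattern missing layer {layer!r}")
            z = np.asarray(self.zones[layer], dtype=float)
            if z.shape != (N_ZONES,):
                raise ValueError(f"pattern layer {layer!r} must have {N_ZONES} zones")
            z.setflags(write=False)
            clean[layer] = z
        object.__setattr__(self, "zones", clean)


def build_normative_pattern(cohort: Iterable[EyeRecord]) -> NormativePattern:
    """Arithmetic mean zonal thickness per layer over the normal eyes of
    a cohort.  Raises if the cohort contains no normal eye."""
    normals = [eye for eye in cohort if eye.group == "normal"]
    if not normals:
        raise ValueError("cannot build a normative pattern: no eyes labelled 'normal'")
    zones = {
        layer: np.mean([eye.profiles[layer].zones for eye in normals], axis=0)
        for layer in LAYERS
    }
    return NormativePattern(zones=zones, n_eyes=len(normals))


# ---------------------------------------------------------------------------
# Plain-text serialization


def profiles_to_frame(cohort: Iterable[EyeRecord]) -> pd.DataFrame:
    """Long-format table: one row per (eye, layer, zone)."""
    rows = []
    for eye in cohort:
        for layer in LAYERS:
            zones = eye.profiles[layer].zones
            for z in range(1, N_ZONES + 1):
                rows.append((eye.eye_id, eye.group, layer, zone_region(z), z, zones[z - 1]))
    return pd.DataFrame(
        rows, columns=["eye_id", "group", "layer", "region", "zone_index", "thickness_um"]
    )


def write_profiles(cohort: Iterable[EyeRecord], path: str | Path) -> None:
    # %.17g round-trips float64 exactly
    profiles_to_frame(cohort).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_profiles(path: str | Path) -> dict[str, dict]:
    """Read a profile TSV back into ``{eye_id: {"group": ..., "profiles": {...}}}``.

    Eye order follows first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out: dict[str, dict] = {}
    for (eye_id, group), sub in df.groupby(["eye_id", "group"], sort=False):
        profiles = {}
        for layer, lsub in sub.groupby("layer", sort=False):
            lsub = lsub.sort_values("zone_index")
            profiles[layer] = ZonalProfile(eye_id=str(eye_id), layer=str(layer),
                                           zones=lsub["thickness_um"].to_numpy())
        out[str(eye_id)] = {"group": str(group), "profiles": profiles}
    return out


def write_scheimpflug(cohort: Iterable[EyeRecord], path: str | Path) -> None:
    """One row per eye: id, group, gender, then the 21 Scheimpflug features."""
    rows = [
        {"eye_id": eye.eye_id, "group": eye.group, "gender": eye.gender, **eye.scheimpflug}
        for eye in cohort
    ]
    pd.DataFrame(rows, columns=["eye_id", "group", "gender", *PENTACAM_FEATURES]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_scheimpflug(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("eye_id", "group", "gender", *PENTACAM_FEATURES) if c not in df.columns]
    if missing:
        raise ValueError(f"Scheimpflug file {path} missing columns: {missing}")
    return df


def assemble_eyes(profiles: Mapping[str, dict], scheimpflug: pd.DataFrame) -> list[EyeRecord]:
    """Join profile and Scheimpflug tables (as read from disk) into EyeRecords."""
    eyes = []
    for _, rec in scheimpflug.iterrows():
        eye_id = str(rec["eye_id"])
        if eye_id not in profiles:
            raise ValueError(f"eye {eye_id} present in Scheimpflug file but has no profiles")
        eyes.append(
            EyeRecord(
                eye_id=eye_id,
                group=str(rec["group"]),
                gender=str(rec["gender"]),
                profiles=profiles[eye_id]["profiles"],
                scheimpflug={f: float(rec[f]) for f in PENTACAM_FEATURES},
            )
        )
    return eyes
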