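"""Sublayer thickness-profile indices.

Scoring functions computed per sublayer over the 30-zone vertical
meridian profile:

* ectasia index        EI     = 100 * min(inferior half) / mean(superior half)
* maximum ectasia idx  EI-MAX = 100 * min(inferior half) / max(superior half)
* profile variation    PV     = RMS deviation of the 30 zones from the
                                profile's own mean (within-eye irregularity)
* profile deviation    PSD    = RMS difference between the profile and a
                                normative zonal pattern average
* zonal statistics     mean (total / superior half / inferior half),
                       min over the inferior half, max over the superior half

Keratoconus thins the cornea inferior-paracentrally, so a low EI /
EI-MAX (marked inferior thinning relative to the superior half) and a
high PV / PSD (irregular profile) flag ectasia.

The "halves" split the meridian at the middle of the central region:
zones z1..z15 are superior, z16..z30 inferior.
"""

from __future__ import annotations

import numpy as np

from .cornea import N_ZONES, EyeRecord, NormativePattern, ZonalProfile
from .registry import LAYER_PREFIX, LAYERS

#: Number of zones in each half of the meridian.
HALF = N_ZONES // 2


def half_split(profile: ZonalProfile) -> tuple[np.ndarray, np.ndarray]:
    """Split a profile's zones into (superior half, inferior half).

    Superior half = superior region plus the upper half of the central
    region (z1..z15); inferior half = z16..z30.
    """
    return profile.zones[:HALF], profile.zones[HALF:]


def ectasia_index(profile: ZonalProfile) -> float:
    """100 x minimum inferior-half thickness / mean superior-half thickness."""
    superior, inferior = half_split(profile)
    mean_sup = superior.mean()
    if mean_sup <= 0:
        raise ValueError("superior-half mean thickness must be positive")
    return 100.0 * inferior.min() / mean_sup


def ectasia_index_max(profile: ZonalProfile) -> float:
    """100 x minimum inferior-half thickness / maximum superior-half thickness.

    Never exceeds :func:`ectasia_index` since max >= mean.
    """
    superior, inferior = half_split(profile)
    max_sup = superior.max()
    if max_sup <= 0:
        raise ValueError("superior-half maximum thickness must be positive")
    return 100.0 * inferior.min() / max_sup


def profile_variation(profile: ZonalProfile) -> float:
    """Within-eye RMS deviation of zonal thickness from the profile mean.

    Population RMS (divisor N = 30), in micrometres.
    """
    z = profile.zones
    return float(np.sqrt(np.mean((z - z.mean()) ** 2)))


def profile_deviation(profile: ZonalProfile, pattern: NormativePattern) -> float:
    """RMS difference between a profile and the normative pattern average
    for the same layer, in micrometres."""
    if profile.layer not in pattern.zones:
        raise ValueError(f"pattern has no layer {profile.layer!r}")
    p = pattern.zones[profile.layer]
    if p.shape != profile.zones.shape:
        raise ValueError("profile/pattern zone count mismatch")
    return float(np.sqrt(np.mean((profile.zones - p) ** 2)))


def zonal_statistics(profile: ZonalProfile) -> tuple[float, float, float, float, float]:
    """(mean total, mean superior half, mean inferior half,
    min inferior half, max superior half), all in micrometres."""
    superior, inferior = half_split(profile)
    return (
        float(profile.zones.mean()),
        float(superior.mean()),
        float(inferior.mean()),
        float(inferior.min()),
        float(superior.max()),
    )


def extract_oct_features(eye: EyeRecord, pattern: NormativePattern) -> dict[str, float]:
    """All 27 OCT-derived features of one eye, keyed by registry name.

    9 features per sublayer: PSD, PV, EI, EI-MAX, and the five zonal
    statistics.
    """
    out: dict[str, float] = {}
    for layer in LAYERS:
        if layer not in eye.profiles:
            raise ValueError(f"eye {eye.eye_id} missing layer {layer!r}")
        prof = eye.profiles[layer]
        p = LAYER_PREFIX[layer]
        mean_total, mean_s, mean_i, min_i, max_s = zonal_statistics(prof)
        out[f"{p}PSD"] = profile_deviation(prof, pattern)
        out[f"{p}PV"] = profile_variation(prof)
        out[f"{p}EI (I/S)"] = ectasia_index(prof)
        out[f"{p}EI-MAX (I/S)"] = ectasia_index_max(prof)
        out[f"{p}Mean (total)"] = mean_total
        out[f"{p}mean (I)"] = mean_i
        out[f"{p}mean (S)"] = mean_s
        out[f"{p}min (I)"] = min_i
        out[f"{p}max (S)"] = max_s
    return out
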