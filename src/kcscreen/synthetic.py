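"""Synthetic cornea cohort generator.

Generates eyes whose sublayer thickness profiles and Scheimpflug-style
features reproduce, at the group level, the printed cohort statistics
the generator defaults are calibrated to.

Model per eye
-------------
A latent severity scalar ``zeta ~ N(0, 1)`` couples the two instruments:
it scales the ectatic cone (lognormally, ``S = exp(tau*zeta - tau^2/2)``,
so E[S] = 1), inflates the smooth profile irregularity, and shifts every
Scheimpflug feature along its disease direction.  Each sublayer profile
is

    thickness(z) = base(z) + offset + irregularity(z) - cone(z) + noise(z)

* ``base`` — fixed smooth meridional curve per layer (level + unit-RMS
  shape scaled in micrometres);
* ``offset`` — per-eye Gaussian thickness offset (between-eye biometry);
* ``irregularity`` — per-eye smooth random curve in two bands of
  meridional harmonics orthogonal to the fixed shape: a macro band
  (long-wavelength, strongly spatially correlated) and a micro band
  (short-wavelength), each with a lognormal amplitude.  Disease scales
  the macro band only (epithelial remodelling raises profile
  irregularity diffusely — driving EPV — while long-wavelength
  undulation moves zonal extremes far less than rough noise would), and
  the macro innovation is correlated with the latent severity;
* ``cone`` — Gaussian-in-zone-index thinning bump centred uniformly in
  the inferior paracentral zones (width 3-5 zones), depth saturating at
  85 % of the local baseline thickness so thinning can never exceed the
  layer itself; amplitude mean is 0 for the normal group, and each
  layer's amplitude carries an extra mean-one lognormal dispersion
  factor (Bowman involvement in particular is heterogeneous);
* ``noise`` — per-zone measurement noise averaged over ``repeats``
  (default 3) independent acquisitions.

Scheimpflug features are drawn per group as Gaussians with the
calibrated means/SDs, with an equicorrelated block (rho) realized
through the shared severity factor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from ._calibration import (
    CONE_AMPLITUDE,
    CONE_DISPERSION,
    IRREGULARITY_MULT,
    IRREGULARITY_SPREAD_MULT,
    LAYER_PARAMS,
    SCHEIMPFLUG_STATS,
)
from .cornea import GENDERS, N_ZONES, EyeRecord, ZonalProfile
from .registry import GROUPS, LAYERS, PENTACAM_FEATURES

__all__ = [
    "GeneratorError",
    "LayerModel",
    "GeneratorConfig",
    "default_config",
    "load_config",
    "save_config",
    "generate_eye",
    "generate_cohort",
]


class GeneratorError(ValueError):
    """Raised when a generated thickness is non-positive, signalling a
    miscalibrated configuration (silent clamping would bias calibration)."""


def _zone_x() -> np.ndarray:
    """Zone index mapped to [-1, 1]; -1 superior edge, +1 inferior edge."""
    z = np.arange(1, N_ZONES + 1, dtype=float)
    return (z - 15.5) / 14.5


# Fixed meridional shape of each layer (before unit-RMS normalisation):
# epithelium thickens slightly towards the inferior periphery, Bowman's
# layer thins superior-to-inferior, the stroma thickens peripherally.
_SHAPE_FORMS = {
    "epithelium": lambda x: x + 0.4 * x**2,
    "bowman": lambda x: -x + 0.15 * x**2,
    "stroma": lambda x: (x**2 - 1.0 / 3.0) + 0.15 * x,
}

_N_HARMONICS = 8        # harmonics k = 2..9; first 4 macro, last 4 micro
_N_MACRO = 4

#: SD of a standard normal clipped to [-2, 2] (unit-variance rescaling).
_ZETA_SCALE = 0.9594461556733254


def _unit_rms(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    return v / np.sqrt(np.mean(v**2))


def _layer_geometry(layer: str) -> tuple[np.ndarray, np.ndarray]:
    """(fixed unit-RMS shape, orthonormal irregularity basis) for a layer.

    The basis spans four smooth cosine harmonics orthogonalised against
    the constant and the fixed shape, so irregularity amplitude adds to
    profile variation independently of the fixed curve.
    """
    x = _zone_x()
    shape = _unit_rms(_SHAPE_FORMS[layer](x))
    raw = [np.cos(k * np.pi * (x + 1) / 2) for k in range(2, 2 + _N_HARMONICS)]
    ortho: list[np.ndarray] = []
    anchors = [np.ones(N_ZONES), shape]
    for v in raw:
        v = v.copy()
        for b in anchors + ortho:
            v -= np.mean(v * b) / np.mean(b * b) * b
        ortho.append(v / np.sqrt(np.mean(v**2)))
    return shape, np.array(ortho)


@dataclass(frozen=True)
class LayerModel:
    """Structural parameters of one sublayer (micrometres)."""

    layer: str
    base_level: float
    shape_scale: float
    irregularity_median: float
    irregularity_gsd: float
    offset_sd: float
    noise_sd: float
    micro_fraction: float = 0.8  # micro-band amplitude relative to macro
    shape: np.ndarray = field(init=False, repr=False, compare=False)
    basis: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.base_level <= 0:
            raise ValueError(f"{self.layer}: base_level must be > 0")
        for name in ("shape_scale", "offset_sd", "noise_sd", "irregularity_median",
                     "micro_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.layer}: {name} must be >= 0")
        if self.irregularity_gsd < 1.0:
            raise ValueError(f"{self.layer}: irregularity_gsd must be >= 1")
        shape, basis = _layer_geometry(self.layer)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "basis", basis)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full generator configuration; ``default_config()`` yields the
    calibrated defaults."""

    layers: Mapping[str, LayerModel]
    cone_amplitude: Mapping[str, Mapping[str, float]]  # group -> layer -> mean um
    scheimpflug: Mapping[str, Mapping[str, tuple[float, float]]]
    irregularity_mult: Mapping[str, Mapping[str, float]] | None = None  # group -> layer
    irregularity_spread_mult: Mapping[str, Mapping[str, float]] | None = None  # group -> layer
    cone_dispersion: Mapping[str, float] | None = None  # layer -> lognormal sigma
    severity_sigma: float = 0.32       # lognormal sigma of the cone-amplitude factor
    scheimpflug_rho: float = 0.70      # equicorrelation within the Scheimpflug block
    irregularity_rho: float = 0.00     # corr(irregularity innovation, severity)
    cone_width_range: tuple[float, float] = (3.0, 5.0)   # zones
    cone_center_range: tuple[int, int] = (17, 27)        # inferior paracentral zones
    max_thinning_fraction: float = 0.85
    repeats: int = 3

    def __post_init__(self) -> None:
        if self.irregularity_mult is None:
            object.__setattr__(self, "irregularity_mult",
                               {g: {l: 1.0 for l in LAYERS} for g in GROUPS})
        if self.irregularity_spread_mult is None:
            object.__setattr__(self, "irregularity_spread_mult",
                               {g: {l: 1.0 for l in LAYERS} for g in GROUPS})
        if self.cone_dispersion is None:
            object.__setattr__(self, "cone_dispersion", {l: 0.0 for l in LAYERS})
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        for rho in (self.scheimpflug_rho, self.irregularity_rho):
            if not 0 <= rho < 1:
                raise ValueError("correlation shares must be in [0, 1)")
        if self.severity_sigma < 0:
            raise ValueError("severity_sigma must be >= 0")
        if not 0 < self.max_thinning_fraction < 1:
            raise ValueError("max_thinning_fraction must be in (0, 1)")
        for layer in LAYERS:
            if layer not in self.layers:
                raise ValueError(f"missing layer model {layer!r}")
        for group in GROUPS:
            if group not in self.cone_amplitude:
                raise ValueError(f"missing cone amplitudes for group {group!r}")
            for layer in LAYERS:
                if self.cone_amplitude[group].get(layer, None) is None:
                    raise ValueError(f"missing cone amplitude {group}/{layer}")
                if self.cone_amplitude[group][layer] < 0:
                    raise ValueError("cone amplitudes must be >= 0")
        if any(self.cone_amplitude["normal"][layer] != 0.0 for layer in LAYERS):
            raise ValueError("normal-group cone amplitude must have mean 0")
        for group in GROUPS:
            for layer in LAYERS:
                if self.irregularity_mult[group][layer] <= 0:
                    raise ValueError("irregularity multipliers must be > 0")
                if self.irregularity_spread_mult[group][layer] <= 0:
                    raise ValueError("irregularity spread multipliers must be > 0")
        for layer in LAYERS:
            if (self.irregularity_mult["normal"][layer] != 1.0
                    or self.irregularity_spread_mult["normal"][layer] != 1.0):
                raise ValueError("normal-group irregularity multipliers must be 1")
        for layer in LAYERS:
            if self.cone_dispersion[layer] < 0:
                raise ValueError("cone dispersion sigmas must be >= 0")
        for feat in PENTACAM_FEATURES:
            if feat not in self.scheimpflug:
                raise ValueError(f"missing Scheimpflug statistics for {feat!r}")
            for group in GROUPS:
                mean, sd = self.scheimpflug[feat][group]
                if sd < 0:
                    raise ValueError(f"{feat}/{group}: SD must be >= 0")
        lo, hi = self.cone_center_range
        if not (16 <= lo <= hi <= 30):
            raise ValueError("cone centre range must lie in the inferior half (zones 16..30)")

    @property
    def severity_sign(self) -> dict[str, float]:
        """Disease direction of each Scheimpflug feature: +1 if the KC
        mean exceeds the normal mean, else -1."""
        return {
            f: 1.0 if self.scheimpflug[f]["KC"][0] >= self.scheimpflug[f]["normal"][0] else -1.0
            for f in PENTACAM_FEATURES
        }


def default_config(**overrides) -> GeneratorConfig:
    """The calibrated default configuration (see ``_calibration``)."""
    layers = {
        layer: LayerModel(layer=layer, **LAYER_PARAMS[layer]) for layer in LAYERS
    }
    params = dict(
        layers=layers,
        cone_amplitude={g: dict(CONE_AMPLITUDE[g]) for g in GROUPS},
        scheimpflug={f: dict(SCHEIMPFLUG_STATS[f]) for f in PENTACAM_FEATURES},
        irregularity_mult={g: dict(IRREGULARITY_MULT[g]) for g in GROUPS},
        irregularity_spread_mult={g: dict(IRREGULARITY_SPREAD_MULT[g]) for g in GROUPS},
        cone_dispersion=dict(CONE_DISPERSION),
    )
    params.update(overrides)
    return GeneratorConfig(**params)


# ---------------------------------------------------------------------------
# Configuration file round-trip (nested key/value text, YAML)


def config_to_dict(config: GeneratorConfig) -> dict:
    return {
        "repeats": config.repeats,
        "severity_sigma": config.severity_sigma,
        "scheimpflug_rho": config.scheimpflug_rho,
        "irregularity_rho": config.irregularity_rho,
        "irregularity_mult": {g: dict(config.irregularity_mult[g]) for g in GROUPS},
        "irregularity_spread_mult": {g: dict(config.irregularity_spread_mult[g]) for g in GROUPS},
        "cone_dispersion": dict(config.cone_dispersion),
        "cone_width_range": list(config.cone_width_range),
        "cone_center_range": list(config.cone_center_range),
        "max_thinning_fraction": config.max_thinning_fraction,
        "layers": {
            layer: {
                k: getattr(m, k)
                for k in ("base_level", "shape_scale", "irregularity_median",
                          "irregularity_gsd", "offset_sd", "noise_sd", "micro_fraction")
            }
            for layer, m in config.layers.items()
        },
        "cone_amplitude": {g: dict(config.cone_amplitude[g]) for g in GROUPS},
        "scheimpflug": {
            f: {g: list(config.scheimpflug[f][g]) for g in GROUPS}
            for f in PENTACAM_FEATURES
        },
    }


def config_from_dict(data: Mapping) -> GeneratorConfig:
    """Build a config from a (possibly partial) nested mapping; unset
    values fall back to the calibrated defaults."""
    base = config_to_dict(default_config())

    def merge(dst: dict, src: Mapping) -> dict:
        for k, v in src.items():
            if isinstance(v, Mapping) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v
        return dst

    merged = merge(base, dict(data))
    layers = {
        layer: LayerModel(layer=layer, **merged["layers"][layer]) for layer in LAYERS
    }
    return GeneratorConfig(
        layers=layers,
        cone_amplitude=merged["cone_amplitude"],
        scheimpflug={
            f: {g: tuple(merged["scheimpflug"][f][g]) for g in GROUPS}
            for f in PENTACAM_FEATURES
        },
        irregularity_mult=merged["irregularity_mult"],
        irregularity_spread_mult=merged["irregularity_spread_mult"],
        cone_dispersion=merged["cone_dispersion"],
        severity_sigma=merged["severity_sigma"],
        scheimpflug_rho=merged["scheimpflug_rho"],
        irregularity_rho=merged["irregularity_rho"],
        cone_width_range=tuple(merged["cone_width_range"]),
        cone_center_range=tuple(merged["cone_center_range"]),
        max_thinning_fraction=merged["max_thinning_fraction"],
        repeats=merged["repeats"],
    )


def load_config(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: GeneratorConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Generation


def generate_eye(group: str, config: GeneratorConfig, rng: np.random.Generator,
                 eye_id: str = "eye") -> EyeRecord:
    """Generate one synthetic eye of the given group from an rng stream.

    Raises :class:`GeneratorError` if any generated thickness is
    non-positive.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")

    # latent severity, clipped at +/-2 sigma and rescaled to unit
    # variance: keeps every marginal mean/SD while bounding the common
    # factor (an unbounded draw would let single eyes cross the whole
    # group separation)
    zeta = float(np.clip(rng.standard_normal(), -2.0, 2.0)) / _ZETA_SCALE
    gender = GENDERS[int(rng.random() < 0.5)]
    tau = config.severity_sigma
    severity = float(np.exp(tau * zeta - 0.5 * tau**2))

    center = int(rng.integers(config.cone_center_range[0], config.cone_center_range[1] + 1))
    width = float(rng.uniform(*config.cone_width_range))
    z = np.arange(1, N_ZONES + 1, dtype=float)
    bump = np.exp(-((z - center) ** 2) / (2.0 * width**2))

    rho_irr = config.irregularity_rho
    profiles: dict[str, ZonalProfile] = {}
    for layer in LAYERS:
        m = config.layers[layer]
        offset = rng.normal(0.0, m.offset_sd)
        innovation = np.sqrt(rho_irr) * zeta + np.sqrt(1.0 - rho_irr) * rng.standard_normal()
        log_spread = np.log(m.irregularity_gsd) * config.irregularity_spread_mult[group][layer]
        amp_macro = (m.irregularity_median * config.irregularity_mult[group][layer]
                     * float(np.exp(log_spread * innovation)))
        amp_micro = (m.irregularity_median * m.micro_fraction
                     * float(np.exp(np.log(m.irregularity_gsd) * rng.standard_normal())))
        # random direction within each band, normalised so the drawn
        # amplitude is exactly the band's RMS contribution
        coef = rng.standard_normal(_N_HARMONICS)
        u, v = coef[:_N_MACRO], coef[_N_MACRO:]
        irregularity = (
            amp_macro * (u @ m.basis[:_N_MACRO]) / np.linalg.norm(u)
            + amp_micro * (v @ m.basis[_N_MACRO:]) / np.linalg.norm(v)
        )
        base = m.base_level + m.shape_scale * m.shape + offset + irregularity

        disp = config.cone_dispersion[layer]
        layer_factor = float(np.exp(disp * rng.standard_normal() - 0.5 * disp**2))
        cone_amp = config.cone_amplitude[group][layer] * severity * layer_factor
        depth_cap = config.max_thinning_fraction * base
        cone = depth_cap * -np.expm1(-cone_amp * bump / depth_cap)

        noise = rng.normal(0.0, m.noise_sd, size=(config.repeats, N_ZONES)).mean(axis=0)
        thickness = base - cone + noise
        if np.any(thickness <= 0):
            raise GeneratorError(
                f"non-positive {layer} thickness generated for a {group} eye; "
                "the generator configuration is miscalibrated"
            )
        profiles[layer] = ZonalProfile(eye_id=eye_id, layer=layer, zones=thickness)

    rho = config.scheimpflug_rho
    signs = config.severity_sign
    eps = rng.standard_normal(len(PENTACAM_FEATURES))
    scheimpflug = {}
    for j, feat in enumerate(PENTACAM_FEATURES):
        mean, sd = config.scheimpflug[feat][group]
        u = signs[feat] * np.sqrt(rho) * zeta + np.sqrt(1.0 - rho) * eps[j]
        scheimpflug[feat] = mean + sd * u

    return EyeRecord(eye_id=eye_id, group=group, gender=gender,
                     profiles=profiles, scheimpflug=scheimpflug)


def generate_cohort(config: GeneratorConfig, n_normal: int, n_subkc: int,
                    n_kc: int, seed: int) -> list[EyeRecord]:
    """Generate a reproducible cohort (normal eyes first, then subKC,
    then KC).  Identical (config, seed) yield bitwise-identical cohorts."""
    for n in (n_normal, n_subkc, n_kc):
        if n < 0:
            raise ValueError("group counts must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cohort: list[EyeRecord] = []
    plan = [("normal", "N", n_normal), ("subKC", "S", n_subkc), ("KC", "K", n_kc)]
    for group, prefix, count in plan:
        for i in range(1, count + 1):
            cohort.append(generate_eye(group, config, rng, eye_id=f"{prefix}{i:04d}"))
    return cohort
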