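"""Shared feature-name registry.

All modules refer to features through this registry so the 49-column
contract (21 Scheimpflug-camera features + 27 UHR-OCT sublayer features
+ gender) cannot drift between the generator, the index extractor, the
ranking and the classifier harness.
"""

from __future__ import annotations

#: Corneal sublayers resolved by ultra-high-resolution OCT, in canonical order.
LAYERS = ("epithelium", "bowman", "stroma")

#: Single-letter prefix used in the published feature names.
LAYER_PREFIX = {"epithelium": "E", "bowman": "B", "stroma": "S"}

#: Diagnostic group labels.
GROUPS = ("normal", "subKC", "KC")

#: 21 Scheimpflug-camera (Pentacam-style) features: anterior/posterior
#: keratometry, best-fit-sphere elevations, pachymetry and the built-in
#: topographic indices.
PENTACAM_FEATURES = (
    "K1 (Front)",
    "K2 (Front)",
    "Km (Front)",
    "Kmax (Front)",
    "K1 (Back)",
    "K2 (Back)",
    "Km (Back)",
    "Kmax (Back)",
    "Emax (Front)",
    "Ecenter (Front)",
    "Emax (Back)",
    "Ecenter (Back)",
    "Thinnest point",
    "Corneal Volume",
    "ISV",
    "IHA",
    "IVA",
    "IHD",
    "KI",
    "Rmin",
    "CKI",
)


def _oct_names() -> tuple[str, ...]:
    names: list[str] = []
    for layer in LAYERS:
        p = LAYER_PREFIX[layer]
        names += [
            f"{p}PSD",
            f"{p}PV",
            f"{p}EI (I/S)",
            f"{p}EI-MAX (I/S)",
            f"{p}Mean (total)",
            f"{p}mean (I)",
            f"{p}mean (S)",
            f"{p}min (I)",
            f"{p}max (S)",
        ]
    return tuple(names)


#: 27 UHR-OCT sublayer thickness-profile features (9 per layer).
OCT_FEATURES = _oct_names()

GENDER_FEATURE = "Gender"

#: The full 49-feature contract, in canonical column order.
ALL_FEATURES = PENTACAM_FEATURES + OCT_FEATURES + (GENDER_FEATURE,)

#: Named feature subsets selectable in the classifier harness.
FEATURE_SUBSETS = {
    "pentacam_only": PENTACAM_FEATURES,
    "oct_only": OCT_FEATURES,
    "combined": ALL_FEATURES,
}

assert len(ALL_FEATURES) == 49


def feature_order(name: str) -> int:
    """Registry position of a feature (used as the deterministic tie-break)."""
    return ALL_FEATURES.index(name)


def resolve_subset(subset: str) -> tuple[str, ...]:
    try:
        return FEATURE_SUBSETS[subset]
    except KeyError:
        raise ValueError(
            f"unknown feature subset {subset!r}; expected one of {sorted(FEATURE_SUBSETS)}"
        ) from None
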