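"""Frozen default-generator calibration constants.

Group-level targets for the Scheimpflug block are the printed cohort
statistics where available (keratometry, posterior elevations, ISV, IVA,
KI); the remaining Pentacam-style features carry literature-plausible
means/SDs for normal, subclinical-KC and KC corneas.  The structural
(profile) constants were fitted once by stochastic root-finding so that
OCT indices extracted from generated profiles reproduce the reference
group means (EPV, BPV, EPSD, Bmin(I), BEI-MAX); see docs/methods.md.

Values are (mean, SD) per group, in the units the instrument prints.
"""

# feature -> {group: (mean, sd)}
SCHEIMPFLUG_STATS = {
    "K1 (Front)":      {"normal": (43.0, 1.3),   "subKC": (43.1, 1.9),   "KC": (46.3, 3.3)},
    "K2 (Front)":      {"normal": (44.3, 1.6),   "subKC": (44.7, 1.3),   "KC": (51.2, 4.7)},
    "Km (Front)":      {"normal": (43.7, 1.4),   "subKC": (43.9, 2.0),   "KC": (48.8, 3.6)},
    "Kmax (Front)":    {"normal": (44.8, 1.6),   "subKC": (45.6, 2.2),   "KC": (55.0, 5.5)},
    "K1 (Back)":       {"normal": (-6.2, 0.25),  "subKC": (-6.2, 0.30),  "KC": (-7.0, 0.60)},
    "K2 (Back)":       {"normal": (-6.5, 0.30),  "subKC": (-6.6, 0.35),  "KC": (-7.8, 0.80)},
    "Km (Back)":       {"normal": (-6.35, 0.27), "subKC": (-6.4, 0.30),  "KC": (-7.4, 0.70)},
    "Kmax (Back)":     {"normal": (-6.7, 0.35),  "subKC": (-6.9, 0.45),  "KC": (-8.5, 1.00)},
    "Emax (Front)":    {"normal": (3.5, 1.8),    "subKC": (5.5, 3.0),    "KC": (18.0, 8.0)},
    "Ecenter (Front)": {"normal": (1.0, 1.5),    "subKC": (1.8, 2.5),    "KC": (8.0, 5.0)},
    "Emax (Back)":     {"normal": (4.8, 2.5),    "subKC": (11.1, 7.4),   "KC": (28.5, 10.3)},
    "Ecenter (Back)":  {"normal": (-0.6, 2.2),   "subKC": (1.9, 5.0),    "KC": (14.7, 10.6)},
    "Thinnest point":  {"normal": (540.0, 30.0), "subKC": (520.0, 35.0), "KC": (465.0, 40.0)},
    "Corneal Volume":  {"normal": (60.5, 3.5),   "subKC": (59.0, 3.8),   "KC": (56.5, 4.2)},
    "ISV":             {"normal": (17.2, 5.9),   "subKC": (24.5, 8.3),   "KC": (91.0, 37.2)},
    "IHA":             {"normal": (5.0, 4.0),    "subKC": (8.0, 6.5),    "KC": (21.0, 15.0)},
    "IVA":             {"normal": (0.1, 0.1),    "subKC": (0.2, 0.1),    "KC": (0.8, 0.4)},
    "IHD":             {"normal": (0.009, 0.006),"subKC": (0.016, 0.010),"KC": (0.090, 0.045)},
    "KI":              {"normal": (1.02, 0.03),  "subKC": (1.05, 0.03),  "KC": (1.21, 0.12)},
    "Rmin":            {"normal": (7.75, 0.25),  "subKC": (7.55, 0.30),  "KC": (6.40, 0.60)},
    "CKI":             {"normal": (1.003, 0.005),"subKC": (1.007, 0.008),"KC": (1.035, 0.025)},
}

# layer -> structural parameters (micrometres)
LAYER_PARAMS = {
    "epithelium": dict(base_level=52.5, shape_scale=1.5, irregularity_median=1.4247,
                       irregularity_gsd=1.6273, offset_sd=2.529, noise_sd=1.5),
    "bowman":     dict(base_level=17.3929, shape_scale=0.05, irregularity_median=0.856,
                       irregularity_gsd=1.4045, offset_sd=1.2826, noise_sd=0.9),
    "stroma":     dict(base_level=480.0, shape_scale=12.0, irregularity_median=3.8,
                       irregularity_gsd=1.35, offset_sd=25.0, noise_sd=3.0),
}

# group -> layer -> mean cone thinning amplitude (micrometres).  The
# epithelial cone is kept shallow (epithelial remodelling smooths focal
# thinning); the disease signal in the epithelium comes mostly through
# the irregularity multipliers below.
CONE_AMPLITUDE = {
    "normal": {"epithelium": 0.0, "bowman": 0.0, "stroma": 0.0},
    "subKC":  {"epithelium": 1.5, "bowman": 3.1814, "stroma": 16.0},
    "KC":     {"epithelium": 25.6736, "bowman": 9.5686, "stroma": 45.0},
}

# group -> layer -> multiplier on the irregularity amplitude median
IRREGULARITY_MULT = {
    "normal": {"epithelium": 1.0, "bowman": 1.0, "stroma": 1.0},
    "subKC":  {"epithelium": 2.3319, "bowman": 1.0, "stroma": 1.0},
    "KC":     {"epithelium": 1.60, "bowman": 1.0, "stroma": 1.0},
}

# group -> layer -> multiplier on the irregularity lognormal log-spread
# (relative spread of disease-group EPV narrows toward the reference SDs)
IRREGULARITY_SPREAD_MULT = {
    "normal": {"epithelium": 1.0, "bowman": 1.0, "stroma": 1.0},
    "subKC":  {"epithelium": 0.616, "bowman": 1.0, "stroma": 1.0},
    "KC":     {"epithelium": 0.8, "bowman": 1.0, "stroma": 1.0},
}

# layer -> extra mean-one lognormal dispersion of the cone amplitude
# (Bowman involvement is the most heterogeneous across eyes)
CONE_DISPERSION = {"epithelium": 0.5, "bowman": 0.8, "stroma": 0.3}
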