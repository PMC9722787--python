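"""Default scenario constants: station layout, seasonal water-quality
location/scale parameters, community compositions and genus inventories.

These are the package's built-in reference scenario; every value is
overridable through :class:`brackish.synthetic.ScenarioSpec`.
"""
from __future__ import annotations

# Stations ordered landward -> seaward; axis_km is distance from the estuary head.
STATIONS: tuple[tuple[str, float], ...] = (
    ("UE", 0.0),
    ("ME", 30.0),
    ("LE", 60.0),
    ("CK", 95.0),
    ("HI", 100.0),
)

# 12 sampling sites total: 2 each in the river/estuary sections, 3 each seaward.
SITES_PER_STATION: dict[str, int] = {"UE": 2, "ME": 2, "LE": 2, "CK": 3, "HI": 3}

DRY_MONTHS: tuple[int, ...] = (12, 1, 2, 3)
WET_MONTHS: tuple[int, ...] = (7, 8, 9, 10)

# Seasonal per-station (location, standard error) for the ten-parameter panel.
# Units: temperature degC, salinity PSU, do mg/L, ph units, nutrients mg/L, chla ug/L.
WATER_PANEL: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "temperature": {
        "dry": {"UE": (22.0, 0.4), "ME": (22.7, 0.3), "LE": (22.0, 0.3), "CK": (22.9, 0.5), "HI": (23.1, 0.3)},
        "wet": {"UE": (31.2, 0.4), "ME": (30.4, 0.5), "LE": (30.5, 1.1), "CK": (29.8, 0.7), "HI": (30.1, 0.3)},
    },
    "salinity": {
        "dry": {"UE": (0.50, 0.2), "ME": (6.5, 2.0), "LE": (7.0, 1.2), "CK": (12.2, 2.2), "HI": (12.4, 1.8)},
        "wet": {"UE": (0.22, 0.10), "ME": (0.22, 0.06), "LE": (0.08, 0.01), "CK": (0.09, 0.01), "HI": (0.48, 0.06)},
    },
    "do": {
        "dry": {"UE": (8.4, 0.06), "ME": (8.3, 0.07), "LE": (8.2, 0.01), "CK": (8.3, 0.03), "HI": (8.3, 0.04)},
        "wet": {"UE": (6.9, 0.2), "ME": (6.8, 0.1), "LE": (6.9, 0.1), "CK": (6.9, 0.0), "HI": (6.7, 0.2)},
    },
    "ph": {
        "dry": {"UE": (7.1, 0.27), "ME": (7.3, 0.14), "LE": (7.2, 0.23), "CK": (6.5, 0.70), "HI": (7.2, 0.01)},
        "wet": {"UE": (6.8, 0.6), "ME": (7.4, 0.5), "LE": (7.3, 0.7), "CK": (7.6, 0.5), "HI": (8.6, 0.1)},
    },
    "no3_n": {
        "dry": {"UE": (0.05, 0.01), "ME": (0.05, 0.01), "LE": (0.07, 0.02), "CK": (0.03, 0.02), "HI": (0.06, 0.03)},
        "wet": {"UE": (0.07, 0.04), "ME": (0.04, 0.01), "LE": (0.04, 0.02), "CK": (0.04, 0.01), "HI": (0.07, 0.01)},
    },
    "no2_n": {
        "dry": {"UE": (0.008, 0.002), "ME": (0.01, 0.002), "LE": (0.013, 0.002), "CK": (0.007, 0.001), "HI": (0.005, 0.001)},
        "wet": {"UE": (0.008, 0.002), "ME": (0.012, 0.005), "LE": (0.007, 0.001), "CK": (0.01, 0.004), "HI": (0.005, 0.001)},
    },
    "nh4": {
        "dry": {"UE": (0.06, 0.02), "ME": (0.10, 0.02), "LE": (0.33, 0.14), "CK": (0.16, 0.15), "HI": (0.14, 0.04)},
        "wet": {"UE": (0.37, 0.15), "ME": (0.23, 0.09), "LE": (0.08, 0.03), "CK": (0.27, 0.12), "HI": (0.22, 0.07)},
    },
    "po4_p": {
        "dry": {"UE": (0.34, 0.11), "ME": (0.49, 0.27), "LE": (1.39, 0.73), "CK": (0.31, 0.13), "HI": (0.33, 0.12)},
        "wet": {"UE": (0.13, 0.04), "ME": (0.59, 0.34), "LE": (0.23, 0.11), "CK": (0.89, 0.71), "HI": (0.46, 0.23)},
    },
    "dsi": {
        "dry": {"UE": (5.19, 0.51), "ME": (4.53, 0.27), "LE": (5.75, 1.52), "CK": (2.71, 1.09), "HI": (4.46, 0.33)},
        "wet": {"UE": (8.3, 1.8), "ME": (5.0, 1.0), "LE": (6.9, 3.2), "CK": (3.2, 0.7), "HI": (7.1, 2.0)},
    },
    "chla": {
        "dry": {"UE": (4.46, 0.77), "ME": (2.54, 0.47), "LE": (3.24, 1.60), "CK": (4.15, 1.35), "HI": (1.11, 0.07)},
        "wet": {"UE": (3.4, 0.6), "ME": (3.0, 0.4), "LE": (4.9, 0.3), "CK": (5.9, 1.0), "HI": (4.0, 0.8)},
    },
}

# Seasonal percent contribution of each phylum, by sample source. The per-season
# percents do not sum to 100 (the balance is unresolved material); generators
# renormalise and record the factor.
WATER_COMPOSITION: dict[str, dict[str, float]] = {
    "dry": {
        "Bacillariophyta": 32.0,
        "Chlorophyta": 26.0,
        "Cyanobacteria": 16.0,
        "Xanthophyta": 6.0,
        "Euglenophyta": 3.0,
        "Miozoa": 9.0,
    },
    "wet": {
        "Bacillariophyta": 27.0,
        "Chlorophyta": 36.0,
        "Cyanobacteria": 14.0,
        "Euglenophyta": 4.0,
        "Miozoa": 4.0,
    },
}

GUT_COMPOSITION: dict[str, dict[str, float]] = {
    "dry": {
        "Bacillariophyta": 21.6,
        "Chlorophyta": 45.8,
        "Cyanobacteria": 14.08,
        "Xanthophyta": 2.6,
    },
    "wet": {
        "Bacillariophyta": 23.5,
        "Chlorophyta": 61.5,
        "Cyanobacteria": 12.0,
        "Euglenophyta": 1.0,
    },
}

# Genus inventories per (source, season, phylum); used to split phylum-level
# simulated counts. Genus identity carries no signal downstream.
GENUS_LISTS: dict[tuple[str, str, str], tuple[str, ...]] = {
    ("gut", "dry", "Bacillariophyta"): (
        "Synedra", "Coscinodiscus", "Pleorosigma", "Triceratium", "Navicula",
        "Fragilaria", "Lioloma", "Ditylum", "Odontella", "Gomphonema"),
    ("water", "dry", "Bacillariophyta"): (
        "Coscinodiscus", "Lioloma", "Asterionella", "Pleorosigma", "Chaetoceros",
        "Proboscia", "Ditylum", "Cerataulina", "Fragilaria", "Melosira",
        "Asteromphalus", "Triceratium", "Nitzchia"),
    ("gut", "wet", "Bacillariophyta"): (
        "Coscinodiscus", "Melosira", "Synedra", "Fragilaria", "Asterionella",
        "Odontella", "Diatoma", "Navicula", "Surirella", "Nitzchia", "Lioloma"),
    ("water", "wet", "Bacillariophyta"): (
        "Coscinodiscus", "Lioloma", "Pleorosigma", "Cyclotella", "Fragilaria",
        "Asterionella", "Odontella", "Licmophora", "Synedra", "Thalassonema",
        "Surirella", "Triceratium", "Melosira", "Nitzchia"),
    ("gut", "dry", "Chlorophyta"): (
        "Oedogonium", "Spirogyra", "Pediastrum", "Muogeotia", "Ulothrix",
        "Microspora", "Volvox", "Tetraedron", "Chlorella", "Zygnema",
        "Closterium", "Stichococcus"),
    ("water", "dry", "Chlorophyta"): (
        "Hydrodictyon", "Muogeotia", "Microspora", "Chlorella", "Volvox",
        "Ulothrix", "Merismopedium", "Uroglena", "Closterium", "Pediastrum",
        "Oedogonium", "Spirogyra", "Tetraedron"),
    ("gut", "wet", "Chlorophyta"): (
        "Muogeotia", "Spirogyra", "Zygnema", "Ulothrix", "Pediastrum",
        "Phytocoris", "Cladophora", "Arthrospira"),
    ("water", "wet", "Chlorophyta"): (
        "Hydrodictyon", "Pediastrum", "Oedogonium", "Muogeotia", "Phytoconis",
        "Microspora", "Volvox", "Arthrospira", "Zygnema", "Spirogyra",
        "Tetraedron"),
    ("gut", "dry", "Cyanobacteria"): (
        "Oscillatoria", "Chroococcus", "Microcystis", "Aphanizomenon",
        "Gomphosphaeria", "Anabaena", "Merismopedium"),
    ("water", "dry", "Cyanobacteria"): (
        "Microcystis", "Gomphosphaeria", "Oscillatoria", "Aphanizomenon",
        "Lyngbya", "Rivularia"),
    ("gut", "wet", "Cyanobacteria"): (
        "Gomphosphaeria", "Microcystis", "Oscillatoria", "Gleocapsa", "Anabena"),
    ("water", "wet", "Cyanobacteria"): (
        "Microcystis", "Anabaena", "Gomphosphaeria", "Oscillatoria"),
    ("gut", "dry", "Xanthophyta"): ("Botrydium",),
    ("water", "dry", "Euglenophyta"): ("Euglena",),
    ("gut", "wet", "Euglenophyta"): ("Euglena",),
    ("water", "wet", "Euglenophyta"): ("Euglena",),
    ("water", "dry", "Miozoa"): ("Ceratium",),
    ("water", "wet", "Miozoa"): ("Ceratium", "Detonula"),
}

# Seasonal whole-community cell-density ranges (cells/L of original water).
DENSITY_RANGE: dict[str, tuple[int, int]] = {
    "dry": (16_200, 94_100),
    "wet": (10_300, 215_100),
}

GUT_TOTAL_RANGE: tuple[int, int] = (50, 500)
N_FISH: int = 90
FISH_LENGTH_RANGE: tuple[float, float] = (18.0, 35.0)

# Literature PUFA share (% of total fatty acids) per annotated phylum.
PUFA_PERCENT: dict[str, float] = {
    "Chlorophyta": 60.0,
    "Bacillariophyta": 28.0,
    "Cyanobacteria": 26.0,
}

VENICE_BOUNDARIES: tuple[float, float, float, float] = (0.5, 5.0, 18.0, 30.0)
MIXING_THRESHOLDS: tuple[float, float] = (0.1, 1.0)
CORRELATION_STAR_LEVELS: tuple[float, float, float] = (0.05, 0.01, 0.001)
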