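"""Reference values for the Gulf of Cadiz bottlenose dolphin population.

Published summary tables for *Tursiops truncatus* in the Gulf of Cadiz
(North Atlantic): diet composition reconstructed from 13 stomachs of
stranded animals (1001 prey items, 143,842.21 g reconstructed weight),
and delta13C/delta15N summaries for 51 biopsied free-ranging dolphins and
their 12 main prey species, grouped into four isotopic source groups.

These constants are inputs for worked examples and cross-checks; the
per-stomach raw data behind them were never released, so they support
aggregate-level computations only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_STOMACHS = 13
TOTAL_PREY = 1001
TOTAL_WEIGHT_G = 143842.21

N_CONSUMERS = 51

#: Consumer (dolphin skin) isotope summary: per-isotope mean, sd, min, max.
CONSUMER_SUMMARY = {
    "d13C": {"n": 51, "mean": -16.13, "sd": 0.57, "min": -17.55, "max": -15.30},
    "d15N": {"n": 51, "mean": 14.30, "sd": 0.76, "min": 12.80, "max": 15.94},
}

# Aggregate diet-composition rows that are arithmetically self-consistent
# with the printed totals (family / class level; W blank where no weight
# could be reconstructed).
_DIET_ROWS = [
    # taxon, level, N, O, W (g)
    ("Congridae", "family", 215, 8, 50603.24),
    ("Merluciidae", "family", 137, 5, 23768.36),
    ("Cepolidae", "family", 256, 2, 7007.84),
    ("Mugilidae", "family", 32, 3, 50948.96),
    ("Sparidae", "family", 49, 9, 2133.01),
    ("Teleostei", "class", 983, 13, 140929.18),
    ("Cephalopoda", "class", 15, 5, 2913.03),
    ("Crustacea", "class", 3, 3, np.nan),
]


def diet_composition() -> pd.DataFrame:
    """Aggregate diet table (raw N, O, W) for the Gulf of Cadiz dolphins."""
    return pd.DataFrame(_DIET_ROWS, columns=["taxon", "level", "N", "O", "W"])


# Per-species isotope summaries (per mil; mean +/- sd over n samples) and the
# four-group partition used as mixing-model sources.
_ISOTOPE_ROWS = [
    # taxon, group, n, mean13, sd13, min13, max13, mean15, sd15, min15, max15
    ("Diplodus annularis", 1, 31, -16.58, 0.42, -17.37, -15.56, 14.43, 0.85, 12.60, 15.92),
    ("Diplodus bellottii", 1, 9, -16.42, 0.22, -16.73, -16.05, 15.14, 0.20, 14.74, 15.37),
    ("Plectorhinchus mediterraneus", 1, 2, -16.64, 0.23, -16.80, -16.47, 15.00, 0.04, 14.97, 15.02),
    ("Pagellus erythrinus", 1, 10, -15.84, 0.25, -16.38, -15.55, 13.79, 0.50, 13.24, 14.73),
    ("Merluccius merluccius", 2, 31, -18.23, 0.66, -19.44, -16.56, 10.86, 0.89, 9.66, 13.21),
    ("Scomber colias", 2, 20, -18.41, 0.43, -19.25, -17.63, 10.99, 0.45, 10.30, 11.74),
    ("Scomber scombrus", 2, 10, -18.26, 0.18, -18.47, -18.02, 11.13, 0.57, 10.31, 12.04),
    ("Cepola macrophthalma", 2, 9, -17.53, 0.27, -18.02, -17.17, 10.05, 0.40, 9.50, 10.69),
    ("Conger conger", 2, 10, -17.26, 0.18, -17.56, -17.00, 10.91, 0.33, 10.15, 11.32),
    ("Sardina pilchardus", 2, 40, -18.04, 0.77, -19.64, -16.99, 10.38, 1.27, 8.36, 13.07),
    ("Octopus vulgaris", 3, 11, -16.10, 0.73, -16.96, -14.36, 11.49, 0.98, 10.02, 13.14),
    ("Liza ramada", 4, 5, -20.77, 4.58, -27.15, -15.28, 15.21, 0.71, 14.00, 15.79),
]

_ISOTOPE_COLS = [
    "taxon", "group", "n",
    "mean_d13C", "sd_d13C", "min_d13C", "max_d13C",
    "mean_d15N", "sd_d15N", "min_d15N", "max_d15N",
]


def prey_isotope_summaries() -> pd.DataFrame:
    """Per-species isotope summaries for the 12 main prey species."""
    return pd.DataFrame(_ISOTOPE_ROWS, columns=_ISOTOPE_COLS)


# Printed pooled summaries for the two multi-species groups.
_GROUP_ROWS = [
    ("Group 1", 52, -16.41, 0.45, 14.45, 0.81),
    ("Group 2", 120, -18.07, 0.67, 10.69, 0.96),
    ("Group 3", 11, -16.10, 0.73, 11.49, 0.98),
    ("Group 4", 5, -20.77, 4.58, 15.21, 0.71),
]


def group_summaries() -> pd.DataFrame:
    """Published group-level source summaries (Groups 1-4)."""
    return pd.DataFrame(
        _GROUP_ROWS,
        columns=["group_id", "n", "mean_d13C", "sd_d13C", "mean_d15N", "sd_d15N"],
    )
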