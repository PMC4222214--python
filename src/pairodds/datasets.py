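"""Reference prevalence data from a longitudinal woodland bird study.

A decade-long survey program of birds on farms in the temperate eucalypt
woodlands of the south-western slopes of New South Wales, Australia,
recorded species presence in 795 surveys of remnant native woodland and
345 surveys of revegetated woodland ("plantings") across 199 sites
surveyed repeatedly. The table below lists the 38 species recorded in at
least 10% of remnant surveys, with their percent presence in each
habitat. These published prevalences are the standard inputs for
structural checks (filter counts, pair combinatorics) and for null
simulations matched to the study's design; the underlying survey-level
records are not public.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import SurveyTable

__all__ = [
    "woodland_bird_prevalences",
    "prevalence_profile",
    "survey_table_from_percents",
    "REMNANT_N_SURVEYS",
    "PLANTING_N_SURVEYS",
    "N_STUDY_SITES",
]

REMNANT_N_SURVEYS = 795
PLANTING_N_SURVEYS = 345
N_STUDY_SITES = 199

# (ref number, common name, % presence in remnants, % presence in plantings)
_BIRDS = [
    (1, "Australian magpie", 84, 74),
    (2, "Australian raven", 16, 14),
    (3, "Black-faced cuckoo-shrike", 30, 24),
    (4, "Brown treecreeper", 29, 3),
    (5, "Cockatiel", 12, 3),
    (6, "Common bronzewing", 12, 9),
    (7, "Common starling", 48, 37),
    (8, "Crested pigeon", 43, 44),
    (9, "Crested shrike-tit", 13, 12),
    (10, "Crimson rosella", 12, 11),
    (11, "Dusky woodswallow", 18, 4),
    (12, "Eastern rosella", 79, 59),
    (13, "Galah", 59, 33),
    (14, "Grey butcher-bird", 12, 5),
    (15, "Grey shrikethrush", 34, 43),
    (16, "Jacky winter", 12, 2),
    (17, "Laughing kookaburra", 21, 6),
    (18, "Little friarbird", 15, 8),
    (19, "Magpie-lark", 45, 33),
    (20, "Noisy miner", 66, 27),
    (21, "Peaceful dove", 12, 8),
    (22, "Pied butcher-bird", 16, 3),
    (23, "Red wattlebird", 19, 44),
    (24, "Red-rumped parrot", 58, 54),
    (25, "Restless flycatcher", 11, 3),
    (26, "Rufous songlark", 41, 49),
    (27, "Rufous whistler", 14, 35),
    (28, "Sacred kingfisher", 11, 3),
    (29, "Striated pardalote", 68, 48),
    (30, "Superb fairy-wren", 13, 61),
    (31, "Superb parrot", 14, 8),
    (32, "Welcome swallow", 12, 13),
    (33, "White-browed woodswallow", 18, 15),
    (34, "White-plumed honeyeater", 57, 75),
    (35, "White-winged chough", 29, 20),
    (36, "White-winged triller", 16, 12),
    (37, "Willie wagtail", 61, 79),
    (38, "Yellow-rumped thornbill", 12, 34),
]


def woodland_bird_prevalences() -> pd.DataFrame:
    """The published species prevalence table.

    Columns: ``ref`` (species reference number), ``species`` (common
    name), ``remnants`` and ``plantings`` (percent presence in each
    habitat's surveys).
    """
    return pd.DataFrame(_BIRDS, columns=["ref", "species", "remnants", "plantings"])


def prevalence_profile(habitat: str = "remnants") -> pd.Series:
    """Per-species presence proportions (0-1) for one habitat.

    Indexed by common name, ordered by reference number.
    """
    tab = woodland_bird_prevalences()
    if habitat not in ("remnants", "plantings"):
        raise ValueError(f"habitat must be 'remnants' or 'plantings', got {habitat!r}")
    return pd.Series(tab[habitat].to_numpy() / 100.0, index=tab["species"], name=habitat)


def survey_table_from_percents(
    percents: pd.Series | dict[str, float], n_surveys: int = 100
) -> SurveyTable:
    """Deterministic survey table realising given percent prevalences.

    Species s is marked present in the first ``round(pct * n_surveys /
    100)`` surveys — a minimal presence matrix whose per-species
    prevalences equal the stated percentages exactly (when they divide
    ``n_surveys`` evenly). Association structure is meaningless by
    construction; the table exists to drive prevalence filtering and
    combinatorics on published marginal data.
    """
    percents = pd.Series(percents)
    mat = np.zeros((n_surveys, len(percents)), dtype=np.int8)
    for k, pct in enumerate(percents.to_numpy()):
        mat[: int(round(pct * n_surveys / 100.0)), k] = 1
    return SurveyTable(pd.DataFrame(mat, columns=list(percents.index)))
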