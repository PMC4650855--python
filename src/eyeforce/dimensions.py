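"""Shared axis definitions for the population and care grids.

Every array in the package is laid out on these axes, in this order:

* age — 1-year cohorts 0..99 plus an absorbing 100+ bin (index 100);
* gender — female, male (demography only; marginalized out before prevalence);
* ethnicity — Chinese, Malay, Indian, Other;
* education — none, primary, secondary, tertiary;
* condition — the nine tracked eye conditions.

Care-side arrays use the adult sub-grid (ages 40..100+).
"""

from __future__ import annotations

import numpy as np

N_AGES = 101          # 0..99 and the absorbing 100+ bin
OPEN_AGE = 100        # index of the 100+ bin
ADULT_MIN_AGE = 40    # prevalence and care apply to the 40+ population
N_ADULT_AGES = N_AGES - ADULT_MIN_AGE

GENDERS = ("female", "male")
ETHNICITIES = ("chinese", "malay", "indian", "other")
EDUCATIONS = ("none", "primary", "secondary", "tertiary")

#: The nine conditions, in the package's canonical order.
CONDITIONS = (
    "cataract",
    "dr",                 # diabetic retinopathy
    "glaucoma",
    "amd",                # age-related macular degeneration
    "myopia",
    "refractive_error",   # under-corrected refractive error other than myopia
    "erm",                # epiretinal membrane
    "rvo",                # retinal vein occlusion
    "other",
)

#: Conditions with a finite course of specialist treatment and their average
#: duration in care (years).  All other conditions require lifelong care.
CURABLE_DURATIONS = {"cataract": 3.0, "myopia": 1.0, "refractive_error": 2.0}

N_GENDERS = len(GENDERS)
N_ETHNICITIES = len(ETHNICITIES)
N_EDUCATIONS = len(EDUCATIONS)
N_CONDITIONS = len(CONDITIONS)

GENDER_INDEX = {g: i for i, g in enumerate(GENDERS)}
ETHNICITY_INDEX = {e: i for i, e in enumerate(ETHNICITIES)}
EDUCATION_INDEX = {e: i for i, e in enumerate(EDUCATIONS)}
CONDITION_INDEX = {c: i for i, c in enumerate(CONDITIONS)}

CURABLE_INDICES = tuple(CONDITION_INDEX[c] for c in CURABLE_DURATIONS)

#: Population grid shape (age, gender, ethnicity, education).
POP_SHAPE = (N_AGES, N_GENDERS, N_ETHNICITIES, N_EDUCATIONS)
#: Care grid shape (condition, adult age, education).
CARE_SHAPE = (N_CONDITIONS, N_ADULT_AGES, N_EDUCATIONS)

AGES = np.arange(N_AGES)
ADULT_AGES = np.arange(ADULT_MIN_AGE, N_AGES)


def is_whole_year(t: float, tol: float = 1e-9) -> bool:
    """True if ``t`` sits on a whole-year boundary (cohort-shift instant)."""
    return abs(t - round(t)) < tol
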