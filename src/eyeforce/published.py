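"""Published reference projections for Singapore public-sector eye care.

Central projection figures (prevalent cases by condition; visit demand
and required ophthalmologists by scenario, 2010-2040 at 5-year steps) as
published for the Singapore public eye-care system.  They are reference
*inputs* for worked examples and summary arithmetic — the model does not
produce them, and nothing here feeds back into any computation.

Case counts and visit volumes are printed rounded to the nearest 100;
ophthalmologist head counts are integers.
"""

from __future__ import annotations

import pandas as pd

_YEARS = [2010, 2015, 2020, 2025, 2030, 2035, 2040]

#: Prevalent cases of each condition among residents aged 40+, by year.
PREVALENCE_CASES = pd.DataFrame.from_dict(
    {
        "cataract": [590_000, 739_400, 900_200, 1_054_800, 1_186_100, 1_283_500, 1_345_300],
        "dr": [92_000, 116_500, 144_100, 172_700, 200_300, 225_800, 248_600],
        "glaucoma": [59_200, 75_300, 93_800, 112_600, 129_800, 143_300, 152_100],
        "amd": [106_500, 125_700, 145_700, 164_600, 180_300, 190_700, 194_900],
        "myopia": [957_000, 1_148_100, 1_317_900, 1_483_700, 1_654_800, 1_818_600, 1_954_900],
        "refractive_error": [323_600, 359_400, 385_500, 403_500, 416_900, 428_300, 438_600],
        "erm": [217_100, 276_100, 340_900, 405_000, 461_600, 508_200, 544_800],
        "rvo": [12_600, 14_300, 15_900, 17_300, 18_700, 20_000, 21_000],
        "other": [73_500, 90_500, 109_900, 131_400, 153_900, 174_600, 190_400],
    },
    orient="index",
    columns=_YEARS,
)

#: Annual visit demand (visits/year) by scenario and year.
DEMAND_VISITS = pd.DataFrame.from_dict(
    {
        "business_as_usual": [568_200, 718_500, 887_200, 1_069_700, 1_251_800, 1_418_600, 1_557_900],
        "current_policy": [568_200, 733_200, 997_500, 1_296_000, 1_582_500, 1_828_500, 2_019_000],
        "new_model_of_care": [568_200, 733_200, 965_400, 1_229_000, 1_477_200, 1_682_100, 1_830_600],
        "moderated_workload": [568_200, 733_200, 965_400, 1_229_000, 1_477_200, 1_682_100, 1_830_600],
    },
    orient="index",
    columns=_YEARS,
)

#: Required ophthalmologists by scenario and year.
REQUIRED_OPHTHALMOLOGISTS = pd.DataFrame.from_dict(
    {
        "business_as_usual": [104, 141, 174, 210, 245, 278, 305],
        "current_policy": [104, 144, 196, 254, 310, 359, 396],
        "new_model_of_care": [104, 144, 189, 241, 290, 330, 359],
        "moderated_workload": [104, 145, 196, 257, 319, 375, 422],
    },
    orient="index",
    columns=_YEARS,
)

#: Published per-scenario adequate residency-intake ranges (residents/year).
INTAKE_RANGES = {
    "business_as_usual": (8, 22),
    "current_policy": (17, 21),
    "new_model_of_care": (14, 18),
    "moderated_workload": (18, 23),
}
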