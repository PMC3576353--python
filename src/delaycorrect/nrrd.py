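"""Published summary figures of the NRRD ALS extract (Italy, 1993-2009).

The microdata of Italy's National Registry of Rare Diseases are not public;
what is public are the summary figures of its ALS extract as of the archive
closure of 21 December 2009. They are collected here because they are the
inputs for worked examples and consistency checks: the registered-case
series by onset year, the person-years denominator for the 2007-09 target
cohort, the published delay quartiles the synthetic generator is calibrated
to, and the published delay-corrected counts.

These are published registry summaries, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "T_END",
    "REGISTERED_BY_ONSET_YEAR",
    "PERSON_YEARS_2007_09",
    "DELAY_QUARTILES_DAYS",
    "MEDIAN_DELAY_CI_DAYS",
    "N_REGISTERED_1993_2009",
    "N_DUPLICATE_REGISTRATIONS",
    "CORRECTED_COUNT_2007_09",
    "observed_cohort_count",
]

#: Archive closure date of the extract.
T_END = pd.Timestamp("2009-12-21")

#: Registered ALS cases by year of suspected onset (truncated at T_END).
REGISTERED_BY_ONSET_YEAR = {
    1994: 6, 1995: 8, 1996: 9, 1997: 14, 1998: 17, 1999: 33, 2000: 38,
    2001: 49, 2002: 75, 2003: 109, 2004: 142, 2005: 212, 2006: 347,
    2007: 378, 2008: 282, 2009: 73,
}

#: Person-years at risk, 2007-2009, over the 11 regions with usable dates.
PERSON_YEARS_2007_09 = 124_842_678

#: Published 25th/50th/75th percentiles of the delay to diagnosis (days).
DELAY_QUARTILES_DAYS = (183, 316, 519)

#: Published 95% CI of the median delay (days).
MEDIAN_DELAY_CI_DAYS = (304, 334)

#: Cases with an ALS diagnosis registered between 1993 and 2009.
N_REGISTERED_1993_2009 = 1799

#: Units registered twice (first diagnosis retained on deduplication).
N_DUPLICATE_REGISTRATIONS = 26

#: Published HT-corrected incident counts for the 2007-09 onset cohort,
#: keyed by the reference cohort whose cdf supplied the weights.
CORRECTED_COUNT_2007_09 = {"2001-03": 1344, "2004-06": 1206}


def observed_cohort_count(start_year: int, end_year: int) -> int:
    """Registered cases with onset in the closed year range."""
    return sum(
        v for y, v in REGISTERED_BY_ONSET_YEAR.items() if start_year <= y <= end_year
    )
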