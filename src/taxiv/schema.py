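"""Canonical variable schema shared by the synthetic generator and the loaders.

The analysis dataset is organised around one row per survey respondent
(state of residence, survey year, edentulism outcome, drinks per day, and
the confounder set: age, sex, race/ethnicity, educational attainment and
smoking status) linked to a state-year table of beverage excise taxes.
"""

from __future__ import annotations

#: Survey years pooled in the study design (repeated cross-sections).
STUDY_YEARS = (2003, 2004, 2005, 2006, 2008, 2010, 2012)

SEX_LEVELS = ("male", "female")
RACE_LEVELS = ("White", "Black", "Hispanic", "Other")
EDUCATION_LEVELS = (
    "no_certificate",
    "elementary",
    "some_high_school",
    "high_school_graduate",
    "some_college",
    "college_graduate",
)
SMOKING_LEVELS = ("never", "current", "former")

#: Reference level per categorical (largest cell; affects intercepts only).
REFERENCE_LEVELS = {
    "sex": "male",
    "race_ethnicity": "White",
    "education": "college_graduate",
    "smoking": "never",
}

#: Mandatory individual-level columns (canonical names).
INDIVIDUAL_REQUIRED = (
    "state_code",
    "year",
    "edentulous",
    "drinks_per_day",
    "age",
    "sex",
    "race_ethnicity",
    "education",
    "smoking",
)

#: Optional individual-level columns.
INDIVIDUAL_OPTIONAL = ("bmi", "dental_visit", "chd", "negative_control")

TAX_COLUMNS = ("beer_tax", "wine_tax", "spirits_tax")
TAX_OPTIONAL = ("cigarette_tax",)

#: Names of the covariate design columns, in order (intercept first).
#: Categoricals are reference-coded against REFERENCE_LEVELS.
DESIGN_COLUMNS = (
    "const",
    "age",
    "female",
    "race_black",
    "race_hispanic",
    "race_other",
    "edu_no_certificate",
    "edu_elementary",
    "edu_some_high_school",
    "edu_high_school_graduate",
    "edu_some_college",
    "smoke_current",
    "smoke_former",
)

#: Exposure categories as printed in descriptive tables: (0,2], (2,5), [5,inf).
DRINK_CATEGORIES = (">0-2", ">2-<5", ">=5")
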