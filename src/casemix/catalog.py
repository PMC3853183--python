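"""Default ACG morbidity catalog.

Adjusted Clinical Groups (ACG) assign every attended patient to exactly one
mutually exclusive morbidity-burden category based on age, sex and the
diagnoses recorded over a year. The catalog below describes the case mix of a
2008 Catalan adult primary-care population (196,593 attended patients aged
>14 in 13 centres): the 17 most prevalent ACG categories individually, and
the remaining rarer categories pooled into a single ``OTHER`` entry. For each
category it records the attended-patient count and the per-patient mean/SD of
care episodes, total direct cost (EUR) and visits over the year.

These are the default targets of the synthetic-cohort generator and the
default external reference profile for planted-effect recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["AcgCatalogEntry", "default_acg_catalog", "catalog_dataframe", "OTHER_CODE"]

#: code used for the pooled remainder of rare ACG categories
OTHER_CODE = "OTHER"


@dataclass(frozen=True)
class AcgCatalogEntry:
    """One ACG category with its population share and utilization moments."""

    acg_code: str
    description: str
    n_patients: int
    share: float  # proportion of the attended population, renormalized
    episodes_mean: float
    episodes_sd: float
    cost_mean: float  # EUR per patient-year
    cost_sd: float
    visits_mean: float
    visits_sd: float

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError(f"{self.acg_code}: n_patients must be positive")
        for name in ("episodes_mean", "episodes_sd", "cost_mean", "cost_sd",
                     "visits_mean", "visits_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.acg_code}: {name} must be >= 0")


# (code, description, n, ep_mean, ep_sd, cost_mean, cost_sd, v_mean, v_sd)
_CATALOG_ROWS = [
    ("4100", "2-3 other ADG combinations, age 35+",
     28864, 3.9, 1.3, 776.3, 828.2, 7.0, 5.2),
    ("300", "Acute minor, age 6+",
     23095, 1.7, 0.9, 173.2, 249.8, 2.9, 2.6),
    ("4910", "6-9 other ADG combinations, age 35+, 0-1 major ADGs",
     14876, 10.2, 2.4, 1624.4, 1092.9, 17.4, 10.3),
    ("4410", "4-5 other ADG combinations, age 45+, no major ADGs",
     10551, 6.6, 1.6, 1025.4, 755.9, 10.8, 6.2),
    ("4420", "4-5 other ADG combinations, age 45+, 1 major ADGs",
     10137, 6.7, 1.6, 1336.2, 1061.6, 12.2, 8.7),
    ("2100", "Acute minor/likely to recur, age 6+, w/o allergy",
     9689, 3.4, 1.4, 310.3, 296.3, 5.3, 3.8),
    ("500", "Likely to recur, w/o allergies",
     8815, 1.6, 0.8, 192.6, 274.4, 2.6, 2.3),
    ("400", "Acute major",
     7511, 1.6, 0.8, 243.2, 388.8, 3.0, 2.6),
    ("1800", "Acute minor/acute major",
     6993, 3.4, 1.3, 355.9, 393.2, 5.7, 4.0),
    ("1600", "Preventive/administrative",
     6937, 1.1, 0.3, 259.7, 540.2, 2.0, 2.2),
    ("900", "Chronic medical: stable",
     6175, 2.0, 0.7, 512.8, 580.5, 4.1, 3.3),
    ("3900", "2-3 other ADG combinations, males age 18 to 34",
     5877, 3.4, 1.0, 341.7, 399.1, 5.6, 4.1),
    ("3200", "Acute minor/acute major/likely to recur, age 12+, w/o allergy",
     5535, 5.4, 1.8, 529.0, 477.1, 8.1, 5.2),
    ("2300", "Acute minor/chronic medical: stable",
     5345, 3.7, 1.3, 634.8, 594.8, 6.8, 5.0),
    ("3600", "Acute minor/acute major/likely to recur/chronic medical: stable",
     5300, 7.8, 2.3, 1043.4, 742.9, 12.4, 7.2),
    ("4310", "4-5 other ADG combinations, age 18 to 44, no major ADGs",
     4168, 5.9, 1.3, 554.8, 474.6, 9.3, 5.1),
    ("4920", "6-9 other ADG combinations, age 35+, 2 major ADGs",
     4089, 10.6, 2.5, 2102.5, 1407.8, 20.7, 13.9),
    (OTHER_CODE, "Other ACG codes (pooled rare categories)",
     32636, 5.0, 4.0, 747.8, 1045.4, 9.0, 10.0),
]


def default_acg_catalog() -> list[AcgCatalogEntry]:
    """Return the default 18-entry catalog, shares renormalized to sum to 1."""
    total = sum(row[2] for row in _CATALOG_ROWS)
    return [
        AcgCatalogEntry(
            acg_code=code,
            description=desc,
            n_patients=n,
            share=n / total,
            episodes_mean=em, episodes_sd=es,
            cost_mean=cm, cost_sd=cs,
            visits_mean=vm, visits_sd=vs,
        )
        for code, desc, n, em, es, cm, cs, vm, vs in _CATALOG_ROWS
    ]


def catalog_dataframe(catalog: list[AcgCatalogEntry] | None = None) -> pd.DataFrame:
    """Catalog as a DataFrame (one row per ACG), convenient for I/O and joins."""
    catalog = default_acg_catalog() if catalog is None else catalog
    return pd.DataFrame([vars(e) for e in catalog])
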