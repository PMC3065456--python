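"""Diet classification and its association with gene status.

Species are binned by the Van Valkenburgh system on percent animal matter in
the natural diet: hypercarnivore (>70%), mesocarnivore (50–70%, both ends
inclusive), hypocarnivore (<50%). The association with pseudogene status is
reported as a contingency table plus the qualitative check of whether every
pseudogene carrier is a hypercarnivore; a formal 2x2 exact test is available
behind a flag as an extension beyond the descriptive comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact

from .lesionscan import GeneStatus

__all__ = [
    "DietRecord",
    "classify_diet",
    "crosstab",
    "CrosstabReport",
    "HYPER",
    "MESO",
    "HYPO",
]

log = logging.getLogger(__name__)

HYPER = "hypercarnivore"
MESO = "mesocarnivore"
HYPO = "hypocarnivore"
CATEGORIES = (HYPER, MESO, HYPO)


@dataclass(frozen=True)
class DietRecord:
    species: str
    category: str
    percent_animal_matter: float | None = None
    evidence: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown diet category {self.category!r}")
        if self.percent_animal_matter is not None:
            expected = classify_diet(self.percent_animal_matter)
            if expected != self.category:
                raise ValueError(
                    f"{self.species}: category {self.category!r} inconsistent "
                    f"with {self.percent_animal_matter}% animal matter "
                    f"(expected {expected!r})"
                )


def classify_diet(percent_animal_matter: float) -> str:
    """Diet category from percent animal matter (boundaries: 70% and 50%
    are mesocarnivore — 'more than 70%' and 'less than 50%' read strictly)."""
    p = float(percent_animal_matter)
    if not 0 <= p <= 100:
        raise ValueError(f"percent animal matter out of range: {p}")
    if p > 70:
        return HYPER
    if p >= 50:
        return MESO
    return HYPO


@dataclass
class CrosstabReport:
    table: pd.DataFrame  # diet category x gene status counts
    unclassified: list[str]  # statuses lacking a diet record
    all_pseudogenes_hypercarnivore: bool
    constraint_table: pd.DataFrame | None = None
    fisher_p: float | None = None


def crosstab(statuses, diets, constraint=None, exact_test: bool = False,
             relaxed_threshold: float = 0.5) -> CrosstabReport:
    """Tabulate gene status against diet category.

    ``statuses``: GeneStatus list. ``diets``: DietRecord list. When a
    per-lineage dN/dS table ``constraint`` ({species: omega}) is supplied, a
    second table of diet x relaxed-constraint (omega above
    ``relaxed_threshold``) is added. ``exact_test=True`` additionally runs a
    Fisher exact test on the 2x2 pseudogene x hypercarnivore table — an
    extension; the primary output is the qualitative concordance check.
    """
    diet_of = {d.species: d.category for d in diets}
    rows = []
    unclassified = []
    for st in statuses:
        cat = diet_of.get(st.species)
        if cat is None:
            unclassified.append(st.species)
            continue
        rows.append({"species": st.species, "diet": cat, "status": st.status})
    if unclassified:
        log.warning("species without diet records (reported, not dropped): %s",
                    ", ".join(sorted(unclassified)))
    df = pd.DataFrame(rows)
    if df.empty:
        log.warning("no species shared between status and diet tables")
        table = pd.DataFrame(
            0, index=list(CATEGORIES), columns=["intact", "pseudogene"]
        )
        return CrosstabReport(table, sorted(unclassified), True)
    table = (
        df.pivot_table(index="diet", columns="status", values="species",
                       aggfunc="count", fill_value=0)
        .reindex(index=list(CATEGORIES), columns=["intact", "pseudogene"],
                 fill_value=0)
    )
    pseudo = df[df.status == "pseudogene"]
    concordant = bool((pseudo.diet == HYPER).all())

    constraint_table = None
    if constraint is not None:
        crows = []
        for sp, omega in constraint.items():
            cat = diet_of.get(sp)
            if cat is None:
                continue
            crows.append(
                {"diet": cat,
                 "relaxed": bool(omega > relaxed_threshold), "species": sp}
            )
        constraint_table = (
            pd.DataFrame(crows)
            .pivot_table(index="diet", columns="relaxed", values="species",
                         aggfunc="count", fill_value=0)
            .reindex(index=list(CATEGORIES), fill_value=0)
        )

    fisher_p = None
    if exact_test:
        a = int(((df.status == "pseudogene") & (df.diet == HYPER)).sum())
        b = int(((df.status == "pseudogene") & (df.diet != HYPER)).sum())
        c = int(((df.status == "intact") & (df.diet == HYPER)).sum())
        d = int(((df.status == "intact") & (df.diet != HYPER)).sum())
        fisher_p = float(fisher_exact([[a, b], [c, d]])[1])

    return CrosstabReport(table, sorted(unclassified), concordant,
                          constraint_table, fisher_p)
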