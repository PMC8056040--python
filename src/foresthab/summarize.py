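"""Headline summaries of an association table.

Collapses a per-(species, habitat) association table into the counts and
percentages conventionally reported for torus-translation studies: how many
species were tested, how many species-habitat pairs came out positive or
negative, how many species carry at least one (or simultaneous) association,
and the same split by life form.  Percentages are rounded half-up to two
decimals to match conventional table formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

__all__ = ["AssociationSummary", "summarize_associations"]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (66.665 -> 66.67)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class AssociationSummary:
    """Counts over an association table; see :func:`summarize_associations`."""

    n_species_tested: int = 0
    n_pairs_significant: int = 0
    n_pairs_positive: int = 0
    n_pairs_negative: int = 0
    n_species_with_any: int = 0
    n_species_positive: int = 0
    n_species_negative: int = 0
    n_species_dual: int = 0
    pct_pairs_over_species: float = 0.0
    pct_species_with_any: float = 0.0
    by_life_form: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "by_life_form"}
        for lf, sub in self.by_life_form.items():
            for k, v in sub.to_dict().items():
                out[f"{lf}_{k}"] = v
        return out


def _summary_core(at: pd.DataFrame) -> AssociationSummary:
    species = at["species"].unique()
    n_tested = len(species)
    sig = at[at["class"].isin(["positive", "negative"])]
    per_sp = sig.groupby("species")["class"]
    n_any = per_sp.count()
    s = AssociationSummary(
        n_species_tested=n_tested,
        n_pairs_significant=len(sig),
        n_pairs_positive=int((sig["class"] == "positive").sum()),
        n_pairs_negative=int((sig["class"] == "negative").sum()),
        n_species_with_any=int((n_any > 0).sum()),
        n_species_positive=int(per_sp.apply(lambda c: (c == "positive").any()).sum()),
        n_species_negative=int(per_sp.apply(lambda c: (c == "negative").any()).sum()),
        n_species_dual=int((n_any >= 2).sum()),
    )
    if n_tested:
        s.pct_pairs_over_species = round2(100.0 * s.n_pairs_significant / n_tested)
        s.pct_species_with_any = round2(100.0 * s.n_species_with_any / n_tested)
    return s


def summarize_associations(at: pd.DataFrame) -> AssociationSummary:
    """Summarize an association table (one row per species x habitat).

    ``at`` needs columns ``species, life_form, class`` with class in
    ``{"positive", "negative", "none"}``; rows of class ``none`` count a
    species as tested but contribute no pairs.  Pair counts treat each
    species-habitat association separately; species-level counts collapse
    per species (a species is "dual" when it carries two or more significant
    associations, e.g. positive with one community and negative with
    another).  ``pct_pairs_over_species`` is the conventional headline
    fraction 100 * significant pairs / species tested.  ``by_life_form``
    replicates every count per life form.
    """
    required = {"species", "life_form", "class"}
    missing = required - set(at.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    s = _summary_core(at)
    for lf, sub in at.groupby("life_form"):
        s.by_life_form[lf] = _summary_core(sub)
    return s
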