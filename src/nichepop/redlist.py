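"""IUCN Red List screening under the small-population criteria (C and D).

Encodes the mature-individual thresholds of the IUCN Red List categories and
criteria (version 3.1) that can be evaluated from census data alone:

* Criterion C — small population size and decline: CR < 250, EN < 2500,
  VU < 10000 mature individuals, qualified by continuing decline (subcriterion
  2) with conditions a(i) (largest subpopulation below a per-category cap),
  a(ii) (≥ 90/95/100 % of mature individuals in one subpopulation) and
  b (extreme fluctuation in mature numbers).
* Criterion D — very small population: CR < 50, EN < 250, VU (D1) < 1000.

Extreme fluctuation is an asserted input, not computed: census series short
enough to need this screen rarely support the order-of-magnitude test.

A PSESP screen (Plant Species with Extremely Small Populations, the Chinese
conservation designation) is included with policy-configurable cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, ValidationError

NOT_LISTED = "not listed"

# criterion C mature-individual ceilings and C2a(i)/(ii) conditions per category
_C_THRESHOLDS = (("CR", 250, 50, 90.0), ("EN", 2500, 250, 95.0), ("VU", 10000, 1000, 100.0))
# criterion D ceilings; VU under D is coded D1 (count-based)
_D_THRESHOLDS = (("CR", 50, "D"), ("EN", 250, "D"), ("VU", 1000, "D1"))


@dataclass(frozen=True)
class AssessmentInput:
    """Census-derived inputs to the criterion-C assessment."""

    mature_individuals: int
    continuing_decline: bool = False
    extreme_fluctuation: bool = False
    largest_subpop_mature: int | None = None
    n_locations: int | None = None

    def validate(self) -> None:
        if self.mature_individuals < 0:
            raise ValidationError("mature_individuals must be non-negative")
        if (
            self.largest_subpop_mature is not None
            and self.largest_subpop_mature > self.mature_individuals
        ):
            raise ValidationError(
                "largest subpopulation cannot exceed the total mature count"
            )


@dataclass(frozen=True)
class RedListAssessment:
    category: str  # CR | EN | VU | "not listed"
    criteria_code: str
    rationale: tuple[str, ...] = field(default_factory=tuple)

    @property
    def listed(self) -> bool:
        return self.category in {"CR", "EN", "VU"}


def assess_criterion_c(inp: AssessmentInput) -> RedListAssessment:
    """Assess under criterion C (small population size and decline)."""
    inp.validate()
    rationale: list[str] = []
    for category, ceiling, subpop_cap, one_pop_pct in _C_THRESHOLDS:
        if inp.mature_individuals < ceiling:
            rationale.append(
                f"mature individuals {inp.mature_individuals} < {ceiling} ({category} under C)"
            )
            code = "C"
            if inp.continuing_decline:
                code += "2"
                rationale.append("continuing decline observed (subcriterion 2)")
                conditions = ""
                if (
                    inp.largest_subpop_mature is not None
                    and inp.largest_subpop_mature <= subpop_cap
                ):
                    conditions += "a(i)"
                    rationale.append(
                        f"largest subpopulation {inp.largest_subpop_mature} ≤ {subpop_cap} (a(i))"
                    )
                if (
                    inp.largest_subpop_mature is not None
                    and inp.mature_individuals > 0
                    and 100.0 * inp.largest_subpop_mature / inp.mature_individuals
                    >= one_pop_pct
                ):
                    conditions += "a(ii)"
                    rationale.append(
                        f"≥ {one_pop_pct:g}% of mature individuals in one subpopulation (a(ii))"
                    )
                if inp.extreme_fluctuation:
                    conditions += "b"
                    rationale.append("extreme fluctuation in mature numbers (b)")
                code += conditions
            return RedListAssessment(category, code, tuple(rationale))
    rationale.append(
        f"mature individuals {inp.mature_individuals} ≥ 10000: criterion C thresholds not met"
    )
    return RedListAssessment(NOT_LISTED, "", tuple(rationale))


def assess_criterion_d(mature_individuals: int) -> RedListAssessment:
    """Assess under criterion D (very small or restricted population)."""
    if mature_individuals < 0:
        raise ValidationError("mature_individuals must be non-negative")
    for category, ceiling, code in _D_THRESHOLDS:
        if mature_individuals < ceiling:
            return RedListAssessment(
                category,
                code,
                (f"mature individuals {mature_individuals} < {ceiling} ({category} under {code})",),
            )
    return RedListAssessment(
        NOT_LISTED,
        "",
        (f"mature individuals {mature_individuals} ≥ 1000: criterion D thresholds not met",),
    )


def psesp_screen(
    mature_individuals: int,
    n_populations: int,
    mature_cutoff: int | None = 5000,
    population_cutoff: int | None = 5,
) -> tuple[bool, tuple[str, ...]]:
    """Screen against PSESP listing cutoffs (policy-configurable).

    Returns (qualifies, rationale). Defaults — fewer than 5000 mature
    individuals restricted to fewer than 5 populations — follow the common
    operational reading of the designation; both cutoffs are policy numbers,
    not biological constants, and should be set from the applicable list.
    """
    if mature_cutoff is None or population_cutoff is None:
        raise ConfigurationError("PSESP screen requires both cutoffs")
    hit_mature = mature_individuals < mature_cutoff
    hit_pops = n_populations < population_cutoff
    rationale = (
        f"mature individuals {mature_individuals} "
        f"{'<' if hit_mature else '≥'} cutoff {mature_cutoff}",
        f"populations {n_populations} "
        f"{'<' if hit_pops else '≥'} cutoff {population_cutoff}",
    )
    return hit_mature and hit_pops, rationale
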