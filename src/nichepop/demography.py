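"""Census aggregation, life-stage structure and decline flags.

Censuses record, per site and survey year, the total number of plants and
the split into adults (reproductive), juveniles and seedlings. A juvenile-
dominated structure with few seedlings signals recruitment limitation; a
drop in totals between consecutive surveys is the "continuing decline"
input to red-list screening.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import EmptySelectionError, InsufficientHistoryError, ValidationError
from .survey_io import CensusRecord, round_half_up

STAGES = ("adult", "juvenile", "seedling")


@dataclass(frozen=True)
class StagePercentages:
    adult: float
    juvenile: float
    seedling: float


@dataclass
class DemographySummary:
    """Aggregate of one survey year across sites, with stage structure."""

    year: int
    total: int
    adult: int
    juvenile: int
    seedling: int
    percentages: StagePercentages
    per_site: pd.DataFrame  # site-indexed counts and stage percents


@dataclass
class DeclineFlags:
    per_site: dict[str, bool]
    overall: bool
    compared_years: tuple[int, int] | None = None
    excluded_sites: tuple[str, ...] = ()


def stage_percentages(record: CensusRecord) -> StagePercentages:
    """Per-stage percents of one census row, rounded half-up to 2 dp."""
    if record.total is None or record.total <= 0:
        raise ValidationError(
            f"stage percentages undefined for total {record.total} "
            f"({record.site}/{record.year})"
        )
    if not record.stages_complete:
        raise ValidationError(
            f"stage counts incomplete for {record.site}/{record.year}"
        )
    return StagePercentages(
        *(round_half_up(100.0 * getattr(record, s) / record.total) for s in STAGES)
    )


def census_totals(records: list[CensusRecord], year: int) -> DemographySummary:
    """Sum one year's censuses across sites and derive the stage structure."""
    sel = [r for r in records if r.year == year and r.total is not None]
    if not sel:
        raise EmptySelectionError(f"no census records for year {year}")
    total = sum(r.total for r in sel)  # type: ignore[misc]
    counts = {s: sum(getattr(r, s) or 0 for r in sel) for s in STAGES}
    if total <= 0:
        raise ValidationError(f"aggregate total for {year} is zero")
    pct = StagePercentages(
        *(round_half_up(100.0 * counts[s] / total) for s in STAGES)
    )
    per_site_rows = {}
    for r in sel:
        row: dict[str, float | int | None] = {"total": r.total}
        for s in STAGES:
            row[s] = getattr(r, s)
            row[f"{s}_pct"] = (
                round_half_up(100.0 * getattr(r, s) / r.total)
                if r.stages_complete and r.total
                else None
            )
        per_site_rows[r.site] = row
    return DemographySummary(
        year=year,
        total=total,
        adult=counts["adult"],
        juvenile=counts["juvenile"],
        seedling=counts["seedling"],
        percentages=pct,
        per_site=pd.DataFrame.from_dict(per_site_rows, orient="index"),
    )


def _comparable(record: CensusRecord) -> int | None:
    """Value a record contributes to a trend comparison (bound or count)."""
    return record.total if record.total is not None else record.upper_bound


def decline_flags(
    records: list[CensusRecord], censored_policy: str = "pessimistic"
) -> DeclineFlags:
    """Flag per-site and overall decline between the two most recent surveys.

    A site's flag is true when its latest total is below the previous one.
    When the previous survey recorded only a bound ("<N"), the comparison is
    policy-driven: "pessimistic" flags decline whenever the latest count is
    below the bound (treating the bound as the plausible historical size);
    "optimistic" never flags against a bound, since the true historical
    count could have been arbitrarily small.

    The overall flag compares aggregate totals of the two most recent survey
    years over the sites present in both years; sites first surveyed in the
    latest year are excluded from the trend.
    """
    if censored_policy not in {"pessimistic", "optimistic"}:
        raise ValidationError(f"unknown censored_policy {censored_policy!r}")
    by_site: dict[str, list[CensusRecord]] = {}
    for r in sorted(records, key=lambda r: (r.site, r.year)):
        by_site.setdefault(r.site, []).append(r)
    if not any(len(v) >= 2 for v in by_site.values()):
        raise InsufficientHistoryError(
            "decline flags require at least two survey years for some site"
        )

    per_site: dict[str, bool] = {}
    for site, recs in by_site.items():
        if len(recs) < 2:
            per_site[site] = False
            continue
        prev, last = recs[-2], recs[-1]
        latest = _comparable(last)
        if prev.total is not None:
            per_site[site] = bool(latest is not None and latest < prev.total)
        else:  # previous survey recorded a bound "<N"
            if censored_policy == "pessimistic":
                per_site[site] = bool(
                    latest is not None
                    and prev.upper_bound is not None
                    and latest < prev.upper_bound
                )
            else:
                per_site[site] = False

    years = sorted({r.year for r in records})
    overall = False
    compared = None
    excluded: tuple[str, ...] = ()
    if len(years) >= 2:
        y_prev, y_last = years[-2], years[-1]
        prev_sites = {r.site for r in records if r.year == y_prev}
        last_sites = {r.site for r in records if r.year == y_last}
        common = prev_sites & last_sites
        excluded = tuple(sorted(last_sites - prev_sites))
        if common:
            def year_sum(year: int) -> int:
                return sum(
                    _comparable(r) or 0
                    for r in records
                    if r.year == year and r.site in common
                )

            overall = year_sum(y_last) < year_sum(y_prev)
            compared = (y_prev, y_last)
    return DeclineFlags(
        per_site=per_site,
        overall=overall,
        compared_years=compared,
        excluded_sites=excluded,
    )
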