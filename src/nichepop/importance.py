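"""Importance values from quadrat surveys.

The importance value (IV) of a species in a plot is the equal-weight mean of
its relative abundance (RA), relative height (RH) and relative cover (RC):

    IV = (RA + RH + RC) / 3

with each relative component expressed in percent of the plot total, so
within a plot the IVs of all species sum to 100. Per-species cross-plot
summaries report mean IV with a standard error; species absent from a plot
contribute an IV of 0 to their summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegeneratePlotError, ValidationError
from .survey_io import PlotSurveyTable


@dataclass
class ImportanceTable:
    """Species × plot importance values in percent.

    ``iv`` is indexed by species (rows) with one column per plot; absent
    species hold 0. ``components`` optionally keeps the per-plot RA/RH/RC
    breakdown.
    """

    iv: pd.DataFrame
    components: dict[str, pd.DataFrame] | None = None

    @property
    def species(self) -> list[str]:
        return list(self.iv.index)

    @property
    def plots(self) -> list[str]:
        return list(self.iv.columns)

    @classmethod
    def from_iv_frame(cls, frame: pd.DataFrame) -> "ImportanceTable":
        """Wrap an already-computed species × plot IV matrix (e.g. a published table)."""
        iv = frame.astype(float)
        if (iv.to_numpy() < 0).any():
            raise ValidationError("importance values must be non-negative")
        return cls(iv=iv)

    def filter_min_iv(self, min_mean_pct: float) -> "ImportanceTable":
        """Display filter: keep species whose cross-plot mean IV is ≥ a cutoff.

        This is a reporting option only; niche metrics must be computed on
        the unfiltered table.
        """
        keep = self.iv.mean(axis=1) >= min_mean_pct
        return ImportanceTable(iv=self.iv.loc[keep])


@dataclass(frozen=True)
class ImportanceSummary:
    species: str
    mean_iv: float
    se_iv: float
    n_plots: int


def relative_components(survey: PlotSurveyTable, plot_id: str) -> pd.DataFrame:
    """Per-species RA, RH, RC (percent) within one plot.

    RA_i = 100·count_i/Σcount, RH_i = 100·height_i/Σheight,
    RC_i = 100·cover_i/Σcover; each column sums to 100.
    """
    obs = survey.plot_observations(plot_id)
    if not obs:
        raise ValidationError(f"plot {plot_id!r} has no observations")
    counts = np.array([o.count for o in obs], dtype=float)
    heights = np.array([o.mean_height for o in obs], dtype=float)
    covers = np.array([o.cover for o in obs], dtype=float)
    if counts.sum() <= 0:
        raise DegeneratePlotError(f"plot {plot_id!r} has all-zero counts")
    if covers.sum() <= 0:
        raise DegeneratePlotError(f"plot {plot_id!r} has all-zero cover")
    out = pd.DataFrame(
        {
            "RA": 100.0 * counts / counts.sum(),
            "RH": 100.0 * heights / heights.sum(),
            "RC": 100.0 * covers / covers.sum(),
        },
        index=pd.Index([o.species for o in obs], name="species"),
    )
    return out


def importance_values(survey: PlotSurveyTable) -> ImportanceTable:
    """IV matrix over the union of species; absent species get IV 0."""
    species = survey.species
    plots = survey.plot_ids
    iv = pd.DataFrame(0.0, index=pd.Index(species, name="species"), columns=plots)
    components: dict[str, pd.DataFrame] = {}
    for plot in plots:
        comp = relative_components(survey, plot)
        components[plot] = comp
        iv.loc[comp.index, plot] = comp.mean(axis=1)  # (RA+RH+RC)/3
    return ImportanceTable(iv=iv, components=components)


def iv_summary(
    table: ImportanceTable, species: str, se_convention: str = "population"
) -> ImportanceSummary:
    """Cross-plot mean ± SE of one species' IVs (absent plots count as 0).

    ``se_convention`` selects the standard-deviation estimator feeding the
    standard error: "population" (divide by n; the convention of the printed
    tables this package replicates) or "sample" (divide by n−1).
    """
    if species not in table.iv.index:
        raise KeyError(f"species {species!r} not in importance table")
    x = table.iv.loc[species].to_numpy(dtype=float)
    n = len(x)
    mean = float(x.mean())
    ddof = 0 if se_convention == "population" else 1
    if se_convention not in {"population", "sample"}:
        raise ValueError(f"unknown SE convention {se_convention!r}")
    se = float(x.std(ddof=ddof) / math.sqrt(n)) if n > ddof else float("nan")
    return ImportanceSummary(species=species, mean_iv=mean, se_iv=se, n_plots=n)


def summaries(
    table: ImportanceTable, se_convention: str = "population"
) -> pd.DataFrame:
    """Mean ± SE summary rows for every species, in table order."""
    rows = [iv_summary(table, sp, se_convention) for sp in table.species]
    return pd.DataFrame(
        {
            "species": [r.species for r in rows],
            "mean_iv": [r.mean_iv for r in rows],
            "se_iv": [r.se_iv for r in rows],
            "n_plots": [r.n_plots for r in rows],
        }
    ).set_index("species")
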