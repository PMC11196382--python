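"""Seeded generators of community, census and soil–trait data.

These produce tables with the statistical structure the downstream analyses
assume, so every stage is testable without field data:

* :func:`gen_community` — a multi-plot herb community with per-species plot
  occupancy, heavy-tailed (rounded-lognormal) abundances, positive heights
  and per-plot cover fractions; defaults emulate a 62-species, 4-plot
  quadrat survey with many site-restricted species.
* :func:`gen_census_series` — multi-year stage-structured censuses in which
  totals decline by binomial thinning at a fixed expected rate and stages
  are multinomial given the total.
* :func:`gen_soil_traits` — paired soil-chemistry and trait tables in which
  organic matter has a dominant positive effect and pH a negative effect on
  a shared growth/flowering axis, plus weak nuisance effects and noise.

Each generator consumes a single integer seed driving one explicit
pseudo-random stream; identical parameters and seed give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .survey_io import (
    SOIL_VARS,
    TRAIT_VARS,
    CensusRecord,
    PlotDescriptor,
    PlotObservation,
    PlotSurveyTable,
    SoilTraitTable,
)


@dataclass
class CommunitySimParams:
    """Parameters of the quadrat-community generator.

    Defaults emulate a four-plot herbaceous community of 62 species in which
    roughly half the species occur at any one plot, abundances are heavy-
    tailed and cover fractions within a plot are Dirichlet-distributed
    (gamma draws scaled to percent).
    """

    n_species: int = 62
    n_plots: int = 4
    occupancy: float | np.ndarray = 0.5
    abundance_logmean: float = 1.0
    abundance_logsd: float = 1.0
    height_mean: float = 30.0
    height_sd: float = 12.0
    cover_concentration: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ParameterError("n_species must be ≥ 2")
        if self.n_plots < 2:
            raise ParameterError("n_plots must be ≥ 2")
        occ = np.broadcast_to(np.asarray(self.occupancy, dtype=float), (self.n_species,))
        if ((occ <= 0) | (occ > 1)).any():
            raise ParameterError("occupancy probabilities must lie in (0, 1]")
        if self.cover_concentration <= 0:
            raise ParameterError("cover_concentration must be positive")


def gen_community(params: CommunitySimParams) -> PlotSurveyTable:
    """Simulate a plot survey; validated against all plot-survey invariants."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    occ = np.broadcast_to(
        np.asarray(params.occupancy, dtype=float), (params.n_species,)
    )
    plot_ids = [f"P{i + 1}" for i in range(params.n_plots)]
    species = [f"sp{i + 1:03d}" for i in range(params.n_species)]

    present = rng.random((params.n_species, params.n_plots)) < occ[:, None]
    for i in range(params.n_species):  # condition on ≥1 plot occupied
        if not present[i].any():
            present[i, rng.integers(params.n_plots)] = True
    for j in range(params.n_plots):  # a plot must host ≥1 species
        if not present[:, j].any():
            present[rng.integers(params.n_species), j] = True

    observations: list[PlotObservation] = []
    for j, plot in enumerate(plot_ids):
        idx = np.flatnonzero(present[:, j])
        counts = np.maximum(
            1,
            np.rint(
                rng.lognormal(params.abundance_logmean, params.abundance_logsd, idx.size)
            ).astype(int),
        )
        heights = np.maximum(
            1.0, rng.normal(params.height_mean, params.height_sd, idx.size)
        )
        covers = 100.0 * rng.dirichlet(
            np.full(idx.size, params.cover_concentration)
        )
        covers = np.maximum(covers, 1e-6)
        for i, c, h, cv in zip(idx, counts, heights, covers):
            observations.append(
                PlotObservation(
                    plot_id=plot,
                    species=species[i],
                    count=int(c),
                    mean_height=float(np.round(h, 1)),
                    cover=float(min(cv, 100.0)),
                )
            )
    plots = [
        PlotDescriptor(plot_id=p, site=f"SITE{j // 2 + 1}", width_m=5.0, length_m=10.0)
        for j, p in enumerate(plot_ids)
    ]
    return PlotSurveyTable(plots=plots, observations=observations)


def gen_census_series(
    n_sites: int,
    years: list[int],
    initial_total: int,
    decline_rate: float,
    stage_probs: tuple[float, float, float] = (0.23, 0.72, 0.05),
    seed: int = 0,
) -> list[CensusRecord]:
    """Simulate per-site census series with expected geometric decline.

    Totals follow binomial thinning: N_{t+1} ~ Binomial(N_t, 1 − decline_rate),
    so the expected total shrinks by ``decline_rate`` per survey interval.
    Stage counts are multinomial given the total, with default stage
    fractions shaped like a juvenile-dominated, recruitment-limited
    population (adult/juvenile/seedling ≈ 23/72/5 %).
    """
    if not years:
        raise ParameterError("years must be non-empty")
    if n_sites < 1:
        raise ParameterError("n_sites must be ≥ 1")
    if not 0.0 <= decline_rate < 1.0:
        raise ParameterError("decline_rate must lie in [0, 1)")
    probs = np.asarray(stage_probs, dtype=float)
    if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ParameterError("stage_probs must be a 3-simplex")
    rng = np.random.default_rng(seed)
    records: list[CensusRecord] = []
    for s in range(n_sites):
        total = int(initial_total)
        for t, year in enumerate(sorted(years)):
            if t > 0:
                total = int(rng.binomial(total, 1.0 - decline_rate))
            adult, juvenile, seedling = rng.multinomial(total, probs)
            records.append(
                CensusRecord(
                    site=f"SITE{s + 1}",
                    year=int(year),
                    total=total,
                    adult=int(adult),
                    juvenile=int(juvenile),
                    seedling=int(seedling),
                )
            )
    return sorted(records, key=lambda r: (r.site, r.year))


#: Baseline (mean, sd) per soil variable, shaped on site-level summaries of
#: a subtropical cliff-herb habitat: OM spans a wide 44–118 g/kg range, pH a
#: narrow slightly-alkaline band, the rest realistic nuisance chemistry.
SOIL_BASELINES: dict[str, tuple[float, float]] = {
    "pH": (7.9, 0.15),
    "EC": (0.17, 0.06),
    "OM": (81.0, 22.0),
    "N": (4.9, 1.1),
    "P": (1.5, 1.2),
    "K": (21.0, 9.0),
    "AN": (296.0, 50.0),
    "AP": (134.0, 120.0),
    "AK": (127.0, 25.0),
    "CEC": (13.2, 3.0),
    "B": (1.84, 0.1),
    "S": (33.6, 12.0),
    "SM": (69.0, 12.0),
}

#: Baseline (mean, sd) per trait, pooled across wild and ex-situ plants.
TRAIT_BASELINES: dict[str, tuple[float, float]] = {
    "PHE": (19.7, 7.0),
    "CD": (19.5, 7.5),
    "NT": (5.6, 5.0),
    "NL": (29.3, 18.0),
    "NI": (5.2, 4.0),
    "NB": (4.2, 2.0),
    "NV": (9.2, 1.2),
    "NF": (6.3, 1.3),
    "NBF": (3.2, 0.8),
    "NBFPI": (75.6, 70.0),
    "NFP": (583.8, 500.0),
}


@dataclass
class SoilTraitSimParams:
    """Parameters of the paired soil–trait generator.

    Effects act on the standardized scale: ``om_effect`` is the shift, in
    trait standard deviations, produced by one standard deviation of organic
    matter (positive), ``ph_effect`` likewise for pH (negative in the
    emulated system). ``nuisance_sd`` scales random weak effects of the
    remaining soil variables and ``noise_sd`` the residual trait noise.
    """

    n_samples: int = 60
    om_effect: float = 1.0
    ph_effect: float = -0.4
    nuisance_sd: float = 0.05
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if self.n_samples < len(SOIL_VARS) + 2:
            raise ParameterError(
                f"n_samples must be ≥ {len(SOIL_VARS) + 2} "
                "(ordination would be rank-deficient)"
            )


def gen_soil_traits(params: SoilTraitSimParams) -> SoilTraitTable:
    """Simulate paired soil and trait tables with an OM-dominant growth axis.

    Every trait loads positively (loadings in [0.6, 1.4], drawn once from the
    seeded stream) on a latent growth axis driven by standardized OM and pH,
    so ``om_effect`` dominant makes OM the first-selected variable in a
    constrained ordination, while pH pushes traits in the opposite direction.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_samples

    soil = {}
    for var, (mu, sd) in SOIL_BASELINES.items():
        if var == "OM":
            soil[var] = rng.uniform(mu - 1.7 * sd, mu + 1.7 * sd, n)
        else:
            soil[var] = np.maximum(rng.normal(mu, sd, n), 0.01)
    soil_df = pd.DataFrame(soil)

    def z(col: np.ndarray) -> np.ndarray:
        return (col - col.mean()) / col.std(ddof=1)

    om_z = z(soil_df["OM"].to_numpy())
    ph_z = z(soil_df["pH"].to_numpy())
    nuisance_vars = [v for v in SOIL_VARS if v not in ("OM", "pH")]
    nuisance_z = np.column_stack([z(soil_df[v].to_numpy()) for v in nuisance_vars])

    loadings = rng.uniform(0.6, 1.4, len(TRAIT_VARS))
    nuisance_coef = rng.normal(0.0, params.nuisance_sd, (len(nuisance_vars), len(TRAIT_VARS)))

    traits = {}
    for t, trait in enumerate(TRAIT_VARS):
        mu, sd = TRAIT_BASELINES[trait]
        latent = (
            loadings[t] * (params.om_effect * om_z + params.ph_effect * ph_z)
            + nuisance_z @ nuisance_coef[:, t]
            + rng.normal(0.0, params.noise_sd, n)
        )
        traits[trait] = np.maximum(mu + sd * latent, 0.0)
    frame = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:03d}" for i in range(n)],
            "site": [f"SITE{i % 3 + 1}" for i in range(n)],
            **{v: np.round(soil_df[v], 4) for v in SOIL_VARS},
            **{t: np.round(traits[t], 4) for t in TRAIT_VARS},
        }
    )
    return SoilTraitTable(frame=frame, soil_vars=SOIL_VARS, trait_vars=TRAIT_VARS)
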