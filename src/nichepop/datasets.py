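"""Bundled fixtures: published summary tables of a *Salvia daiguii* survey.

Raw per-quadrat observations were never deposited for this system; what the
study published are derived tables, and those printed tables are themselves
the inputs to the niche, demography and red-list stages:

* :func:`load_dominant_importance` — the 13 species with importance values
  above 1 % in the four survey quadrats (two each at the ZEFR and TNFP
  sites), as a species × plot IV matrix in percent.
* :func:`load_census` — the 2019–2022 stage-structured censuses of the five
  known sites, including censored historical totals ("<200") and rows with
  unrecorded stages.
* :func:`load_printed_overlap` — the published 13 × 13 pairwise Pianka
  overlap matrix (lower triangle as printed, rounded to 2 decimals),
  mirrored to a symmetric matrix with a unit diagonal.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .importance import ImportanceTable
from .niche import OverlapMatrix
from .survey_io import CensusRecord, read_census

_DATA = resources.files("nichepop") / "data"


def _path(name: str):
    return _DATA / name


def load_dominant_importance() -> ImportanceTable:
    """Species × plot importance values (percent) of the 13 dominant herbs."""
    with resources.as_file(_path("dominant_iv.csv")) as p:
        df = pd.read_csv(p).set_index("species")
    return ImportanceTable.from_iv_frame(df)


def load_census() -> list[CensusRecord]:
    """Five-site, 2019–2022 stage-structured census records."""
    with resources.as_file(_path("census.csv")) as p:
        return read_census(p)


def load_printed_overlap() -> OverlapMatrix:
    """The published pairwise overlap matrix (2-decimal, symmetric, unit diagonal)."""
    species = list(load_dominant_importance().species)
    with resources.as_file(_path("overlap_printed.csv")) as p:
        long = pd.read_csv(p)
    o = pd.DataFrame(1.0, index=species, columns=species)
    for _, row in long.iterrows():
        a, b = species[int(row["i"]) - 1], species[int(row["j"]) - 1]
        o.loc[a, b] = o.loc[b, a] = float(row["overlap"])
    return OverlapMatrix(o=o)


def default_config_path():
    """Filesystem path of the packaged default pipeline configuration."""
    return _path("default_config.yaml")
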