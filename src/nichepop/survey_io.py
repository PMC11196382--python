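"""Typed readers, writers and validation for the tabular inputs and outputs.

The package exchanges four kinds of tables as delimited text (UTF-8, header
row mandatory, comma default with tab accepted, "." decimal separator):

* plot-survey tables — one row per (plot, species) with count, mean height
  in cm and percent cover;
* demographic census tables — one row per (site, year) with total and
  per-life-stage counts, where historical cells may be missing ("—") or
  bounded ("<200");
* paired soil-chemistry / plant-trait tables — one row per sample;
* result tables (importance values, niche breadths, overlap matrices),
  written bit-stably so identical inputs yield byte-identical files.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

#: Declared vocabulary of soil physicochemical variables.
SOIL_VARS = ("pH", "EC", "OM", "N", "P", "K", "AN", "AP", "AK", "CEC", "B", "S", "SM")

#: Declared vocabulary of growth and flowering traits.
TRAIT_VARS = ("PHE", "CD", "NT", "NL", "NI", "NB", "NV", "NF", "NBF", "NBFPI", "NFP")

#: Canonical plot-survey column names (schema maps may rename them).
SURVEY_COLUMNS = ("plot_id", "species", "count", "mean_height_cm", "cover_pct")

CENSUS_COLUMNS = ("site", "year", "total", "adult", "juvenile", "seedling")

#: Cell markers parsed as "not recorded".
MISSING_TOKENS = {"", "—", "-", "na", "NA", "NaN", "nan"}


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as printed survey tables are rounded."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PlotDescriptor:
    plot_id: str
    site: str | None = None
    width_m: float | None = None
    length_m: float | None = None


@dataclass(frozen=True)
class PlotObservation:
    """One species in one quadrat: abundance, mean height (cm), percent cover."""

    plot_id: str
    species: str
    count: int
    mean_height: float
    cover: float

    def validate(self, row: int | None = None) -> None:
        where = f" (row {row})" if row is not None else ""
        if self.count < 0:
            raise ValidationError(f"negative count for {self.species!r}{where}")
        if self.count > 0 and not self.mean_height > 0:
            raise ValidationError(
                f"mean height must be positive when count > 0 for {self.species!r}{where}"
            )
        if not 0.0 <= self.cover <= 100.0:
            raise ValidationError(
                f"cover {self.cover} outside [0, 100] for {self.species!r}{where}"
            )


@dataclass
class PlotSurveyTable:
    """A validated quadrat survey: plot descriptors plus per-plot observations."""

    plots: list[PlotDescriptor]
    observations: list[PlotObservation]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        known = {p.plot_id for p in self.plots}
        seen: set[tuple[str, str]] = set()
        covered: set[str] = set()
        for i, obs in enumerate(self.observations):
            obs.validate(row=i + 1)
            if obs.plot_id not in known:
                raise ValidationError(
                    f"observation row {i + 1} references unknown plot {obs.plot_id!r}"
                )
            key = (obs.plot_id, obs.species)
            if key in seen:
                raise ValidationError(
                    f"duplicate (plot, species) pair {key} at row {i + 1}"
                )
            seen.add(key)
            covered.add(obs.plot_id)
        empty = known - covered
        if empty:
            raise ValidationError(f"plot(s) without observations: {sorted(empty)}")

    @property
    def plot_ids(self) -> list[str]:
        return [p.plot_id for p in self.plots]

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for obs in self.observations:
            if obs.species not in out:
                out.append(obs.species)
        return out

    def plot_observations(self, plot_id: str) -> list[PlotObservation]:
        return [o for o in self.observations if o.plot_id == plot_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "plot_id": o.plot_id,
                    "species": o.species,
                    "count": o.count,
                    "mean_height_cm": o.mean_height,
                    "cover_pct": o.cover,
                }
                for o in self.observations
            ]
        )


@dataclass(frozen=True)
class CensusRecord:
    """One site-year census row.

    Stage counts may be missing (historical rows record only totals); a
    bounded historical total like "<200" is stored in ``upper_bound`` with
    ``total`` left as None.
    """

    site: str
    year: int
    total: int | None
    adult: int | None = None
    juvenile: int | None = None
    seedling: int | None = None
    upper_bound: int | None = None

    def validate(self) -> None:
        for name in ("total", "adult", "juvenile", "seedling"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"negative {name} for {self.site}/{self.year}")
        stages = (self.adult, self.juvenile, self.seedling)
        if self.total is not None and all(s is not None for s in stages):
            if sum(stages) != self.total:  # type: ignore[arg-type]
                raise ValidationError(
                    f"stage counts {stages} do not sum to total {self.total} "
                    f"for {self.site}/{self.year}"
                )
        if self.total is None and self.upper_bound is None:
            raise ValidationError(f"no total recorded for {self.site}/{self.year}")

    @property
    def stages_complete(self) -> bool:
        return all(
            getattr(self, s) is not None for s in ("adult", "juvenile", "seedling")
        )


@dataclass
class SoilTraitTable:
    """Paired soil-chemistry and plant-trait measurements, one row per sample."""

    frame: pd.DataFrame
    soil_vars: tuple[str, ...] = SOIL_VARS
    trait_vars: tuple[str, ...] = TRAIT_VARS

    def __post_init__(self) -> None:
        missing = [
            c for c in ("sample_id", "site", *self.soil_vars, *self.trait_vars)
            if c not in self.frame.columns
        ]
        if missing:
            raise SchemaError(f"soil-trait table missing column(s): {missing}")
        unknown = [
            c
            for c in self.frame.columns
            if c not in ("sample_id", "site", *self.soil_vars, *self.trait_vars)
        ]
        if unknown:
            raise SchemaError(f"undeclared soil/trait column(s): {unknown}")
        block = self.frame[list(self.soil_vars) + list(self.trait_vars)]
        if block.isna().any().any():
            bad = block.columns[block.isna().any()].tolist()
            raise ValidationError(f"missing values in column(s): {bad}")
        if self.frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id values")

    @property
    def soil(self) -> pd.DataFrame:
        return self.frame.set_index("sample_id")[list(self.soil_vars)]

    @property
    def traits(self) -> pd.DataFrame:
        return self.frame.set_index("sample_id")[list(self.trait_vars)]


# ---------------------------------------------------------------------------
# readers


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_plot_survey(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    plots: Sequence[PlotDescriptor] | None = None,
) -> PlotSurveyTable:
    """Read and validate a plot-survey table.

    ``schema`` maps canonical column names (:data:`SURVEY_COLUMNS`) to the
    file's actual headers; canonical headers are assumed when omitted.
    Plot descriptors default to bare identifiers inferred from the data.
    """
    df = _read_delimited(path)
    schema = dict(schema or {})
    colmap = {canon: schema.get(canon, canon) for canon in SURVEY_COLUMNS}
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"plot-survey file missing column(s): {missing}")

    observations = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            obs = PlotObservation(
                plot_id=str(rec[colmap["plot_id"]]),
                species=str(rec[colmap["species"]]),
                count=int(rec[colmap["count"]]),
                mean_height=float(rec[colmap["mean_height_cm"]]),
                cover=float(rec[colmap["cover_pct"]]),
            )
        except ValueError as exc:
            raise ValidationError(f"unparseable value at file line {i}: {exc}") from exc
        observations.append(obs)

    if plots is None:
        ids: list[str] = []
        for o in observations:
            if o.plot_id not in ids:
                ids.append(o.plot_id)
        plots = [PlotDescriptor(plot_id=p) for p in ids]
    return PlotSurveyTable(plots=list(plots), observations=observations)


def _parse_count_cell(cell: str) -> tuple[int | None, int | None]:
    """Parse a census cell into (count, upper_bound)."""
    cell = cell.strip()
    if cell in MISSING_TOKENS:
        return None, None
    if cell.startswith("<"):
        return None, int(cell[1:])
    return int(cell), None


def read_census(path: str | Path) -> list[CensusRecord]:
    """Read a census table into records sorted by (site, year).

    The stage-sum invariant (adult + juvenile + seedling = total) is enforced
    whenever all three stages are recorded; "—" and empty cells are missing;
    "<N" totals become censored upper bounds.
    """
    df = _read_delimited(path)
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"census file missing column(s): {missing}")
    records = []
    for i, row in df.iterrows():
        total, bound = _parse_count_cell(row["total"])
        stages = {}
        for s in ("adult", "juvenile", "seedling"):
            v, _ = _parse_count_cell(row[s])
            stages[s] = v
        rec = CensusRecord(
            site=str(row["site"]),
            year=int(row["year"]),
            total=total,
            upper_bound=bound,
            **stages,
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise ValidationError(f"census file line {i + 2}: {exc}") from exc
        records.append(rec)
    return sorted(records, key=lambda r: (r.site, r.year))


def read_soil_traits(
    path: str | Path,
    soil_vars: Sequence[str] = SOIL_VARS,
    trait_vars: Sequence[str] = TRAIT_VARS,
) -> SoilTraitTable:
    df = _read_delimited(path)
    numeric = [c for c in df.columns if c not in ("sample_id", "site")]
    for c in numeric:
        df[c] = pd.to_numeric(df[c].replace(sorted(MISSING_TOKENS), pd.NA))
    return SoilTraitTable(
        frame=df, soil_vars=tuple(soil_vars), trait_vars=tuple(trait_vars)
    )


# ---------------------------------------------------------------------------
# writers


def _format_value(v, decimals: int) -> str:
    if v is None:
        return "—"
    if isinstance(v, float):
        return f"{round_half_up(v, decimals):.{decimals}f}"
    return str(v)


def write_table(
    rows: pd.DataFrame,
    path: str | Path,
    format: str = "tsv",
    decimals: int = 2,
    allow_empty: bool = False,
    index: bool = False,
) -> None:
    """Write a result table bit-stably.

    Floats are rendered with a fixed number of decimals (half-up, default 2,
    the convention of printed survey tables), so the same table and format
    always produce byte-identical files.
    """
    if rows.empty and not allow_empty:
        raise ValidationError("refusing to write an empty table (allow_empty=False)")
    if format not in {"tsv", "csv", "markdown"}:
        raise ValidationError(f"unknown output format {format!r}")

    df = rows.copy()
    if index:
        df = df.reset_index()
    cells = [
        [_format_value(v, decimals) for v in df.iloc[i]] for i in range(len(df))
    ]
    header = [str(c) for c in df.columns]

    buf = _stdio.StringIO()
    if format == "markdown":
        buf.write("| " + " | ".join(header) + " |\n")
        buf.write("|" + "|".join("---" for _ in header) + "|\n")
        for r in cells:
            buf.write("| " + " | ".join(r) + " |\n")
    else:
        sep = "\t" if format == "tsv" else ","
        buf.write(sep.join(header) + "\n")
        for r in cells:
            buf.write(sep.join(r) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def overlap_to_markdown(matrix: pd.DataFrame, decimals: int = 2) -> str:
    """Render a symmetric overlap matrix as a lower-triangular markdown table.

    The diagonal and upper triangle are printed as em-dashes, the layout used
    for pairwise niche-overlap tables in community-ecology reports.
    """
    names = list(matrix.index)
    header = ["No."] + [str(i + 1) for i in range(len(names))]
    lines = ["| " + " | ".join(header) + " |", "|" + "|".join("---" for _ in header) + "|"]
    for i in range(len(names)):
        row = [str(i + 1)]
        for j in range(len(names)):
            if j >= i:
                row.append("—" if j == i else "")
            else:
                row.append(_format_value(float(matrix.iloc[i, j]), decimals))
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines) + "\n"
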