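"""Niche breadth and overlap from importance values.

Plots (quadrats) act as the resource states. For a species with importance
values IV_k over plots k:

* Levins breadth  B = 1 / Σ p_k², with p_k the species' IV proportion
  across plots (p_k = IV_k / Σ IV). B ranges from 1 (single-plot
  specialist) to the number of plots (uniform use).
* Shannon breadth B_s = −Σ p_k ln p_k with 0·ln 0 := 0. Two proportion
  conventions are supported: "iv-fraction" takes p_k = IV_k/100 without
  renormalisation (the convention that reproduces published quadrat tables,
  where IVs are percents of the plot total); "normalized" takes
  p_k = IV_k / Σ IV, whose maximum is ln(number of plots).
* Pianka overlap  O_ij = Σ p_ik p_jk / sqrt(Σ p_ik² · Σ p_jk²) — a cosine
  similarity of the two species' plot-use vectors, in [0, 1], invariant to
  rescaling either species' vector, so raw IVs may be used directly.

The default "paper-replication" breadth mode pairs the normalized Levins
form with the iv-fraction Shannon form, the combination under which both
printed columns of the replicated survey table are recovered;
"consistent-normalized" applies the normalized convention to both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedBreadthError, ValidationError
from .importance import ImportanceTable

#: |O| below this is an exact zero (disjoint plot support).
ZERO_TOL = 1e-12


def _as_vector(iv_row) -> np.ndarray:
    x = np.asarray(iv_row, dtype=float).ravel()
    if (x < 0).any():
        raise ValidationError("importance values must be non-negative")
    return x


def levins_breadth(iv_row) -> float:
    """Levins niche breadth 1/Σp² with proportions normalized within the species."""
    x = _as_vector(iv_row)
    s = x.sum()
    if s <= 0:
        raise UndefinedBreadthError("niche breadth undefined for an all-zero IV row")
    p = x / s
    return float(1.0 / np.sum(p**2))


def shannon_breadth(iv_row, convention: str = "iv-fraction") -> float:
    """Shannon–Wiener niche breadth −Σ p ln p (0·ln 0 := 0)."""
    x = _as_vector(iv_row)
    if x.sum() <= 0:
        raise UndefinedBreadthError("niche breadth undefined for an all-zero IV row")
    if convention == "iv-fraction":
        p = x / 100.0
    elif convention == "normalized":
        p = x / x.sum()
    else:
        raise ValueError(f"unknown Shannon convention {convention!r}")
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def breadth_table(table: ImportanceTable, mode: str = "paper-replication") -> pd.DataFrame:
    """Levins and Shannon breadths for every species of an importance table."""
    if mode == "paper-replication":
        conv = "iv-fraction"
    elif mode == "consistent-normalized":
        conv = "normalized"
    else:
        raise ValueError(f"unknown breadth mode {mode!r}")
    rows = {
        sp: (levins_breadth(table.iv.loc[sp]), shannon_breadth(table.iv.loc[sp], conv))
        for sp in table.species
    }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["b_levins", "b_shannon"])
    out.index.name = "species"
    return out


def pianka_overlap(iv_i, iv_j) -> float:
    """Pianka overlap of two species' plot-IV vectors."""
    a = _as_vector(iv_i)
    b = _as_vector(iv_j)
    if a.shape != b.shape:
        raise ValidationError(f"IV vectors differ in length: {a.size} vs {b.size}")
    na = np.sum(a**2)
    nb = np.sum(b**2)
    if na <= 0 or nb <= 0:
        raise UndefinedBreadthError("overlap undefined for an all-zero IV row")
    return float(np.dot(a, b) / math.sqrt(na * nb))


@dataclass
class OverlapMatrix:
    """Symmetric species × species Pianka overlaps with a unit diagonal."""

    o: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.o.index)

    def lower_triangle(self) -> list[tuple[str, str, float]]:
        """Strict lower-triangle pairs in row-major order."""
        names = self.species
        return [
            (names[i], names[j], float(self.o.iloc[i, j]))
            for i in range(len(names))
            for j in range(i)
        ]


def overlap_matrix(table: ImportanceTable) -> OverlapMatrix:
    """All pairwise Pianka overlaps of an importance table (≥2 species)."""
    if len(table.species) < 2:
        raise ValidationError("overlap matrix requires at least two species")
    x = table.iv.to_numpy(dtype=float)
    norms = np.sqrt(np.sum(x**2, axis=1))
    if (norms <= 0).any():
        bad = [s for s, n in zip(table.species, norms) if n <= 0]
        raise UndefinedBreadthError(f"all-zero IV row(s): {bad}")
    o = (x @ x.T) / np.outer(norms, norms)
    np.fill_diagonal(o, 1.0)
    o = np.clip(o, 0.0, 1.0)
    return OverlapMatrix(o=pd.DataFrame(o, index=table.iv.index, columns=table.iv.index))


@dataclass(frozen=True)
class OverlapCensus:
    """Counts over the strict lower triangle of an overlap matrix."""

    n_pairs: int
    n_at_or_above: int
    fraction_pct: float
    n_zero: int
    zero_fraction_pct: float
    threshold: float


def overlap_census(
    matrix: OverlapMatrix | pd.DataFrame,
    threshold: float = 0.5,
    inclusive: bool = True,
) -> OverlapCensus:
    """Census of pairwise overlaps: how many reach a threshold, how many are zero.

    The threshold is applied inclusively (≥) by default; zeros are detected
    as |O| < 1e-12, i.e. genuinely disjoint plot support rather than values
    that merely round to 0.00.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    om = matrix if isinstance(matrix, OverlapMatrix) else OverlapMatrix(o=matrix)
    vals = np.array([v for _, _, v in om.lower_triangle()])
    n_pairs = vals.size
    n_at = int(np.sum(vals >= threshold) if inclusive else np.sum(vals > threshold))
    n_zero = int(np.sum(np.abs(vals) < ZERO_TOL))
    return OverlapCensus(
        n_pairs=int(n_pairs),
        n_at_or_above=n_at,
        fraction_pct=100.0 * n_at / n_pairs if n_pairs else float("nan"),
        n_zero=n_zero,
        zero_fraction_pct=100.0 * n_zero / n_pairs if n_pairs else float("nan"),
        threshold=threshold,
    )
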