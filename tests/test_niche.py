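"""Niche breadth and Pianka overlap: published examples, algebra, properties."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichepop.errors import UndefinedBreadthError, ValidationError
from nichepop.importance import ImportanceTable
from nichepop.niche import (
    breadth_table,
    levins_breadth,
    overlap_census,
    overlap_matrix,
    pianka_overlap,
    shannon_breadth,
)

import pandas as pd

positive_vectors = st.lists(
    st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=8
)


@pytest.mark.parametrize(
    "species, b_levins, b_shannon",
    [
        ("Salvia daiguii", 3.36, 0.84),
        ("Pilea notata", 3.05, 1.03),
        ("Strobilanthes pentstemonoides", 2.99, 1.07),
        ("Lycianthes lysimachioides", 1.99, 0.71),
    ],
)
def test_breadths_reproduce_published_rows(dominant_iv, species, b_levins, b_shannon):
    """Dominant-herb breadth values recomputed from the published IV matrix."""
    row = dominant_iv.iv.loc[species]
    assert levins_breadth(row) == pytest.approx(b_levins, abs=0.005)
    assert shannon_breadth(row, "iv-fraction") == pytest.approx(b_shannon, abs=0.005)


def test_levins_extremes():
    assert levins_breadth([5, 5, 5, 5]) == pytest.approx(4.0)
    assert levins_breadth([7, 0, 0, 0]) == pytest.approx(1.0)


def test_shannon_normalized_uniform_is_log_nplots():
    assert shannon_breadth([5, 5, 5, 5], "normalized") == pytest.approx(math.log(4))


def test_breadth_errors():
    with pytest.raises(UndefinedBreadthError):
        levins_breadth([0, 0, 0])
    with pytest.raises(UndefinedBreadthError):
        shannon_breadth([0.0, 0.0])
    with pytest.raises(ValueError):
        shannon_breadth([1, 2], convention="bogus")


def test_levins_maximized_by_uniform_vector_brute_force():
    """Grid search over the 3-plot simplex: no allocation beats the uniform one."""
    best, argbest = -1.0, None
    for i in range(1, 20):
        for j in range(1, 20 - i):
            k = 20 - i - j
            b = levins_breadth([i, j, k])
            if b > best:
                best, argbest = b, (i, j, k)
    assert best <= levins_breadth([1, 1, 1]) + 1e-12
    assert argbest is not None and len(set(argbest)) <= 2  # near-uniform wins


def test_pianka_published_pairs(dominant_iv):
    sd = dominant_iv.iv.loc["Salvia daiguii"]
    hc = dominant_iv.iv.loc["Houttuynia cordata"]
    assert pianka_overlap(sd, hc) == pytest.approx(0.94, abs=0.005)


def test_pianka_identities():
    assert pianka_overlap([3, 1, 4], [3, 1, 4]) == pytest.approx(1.0)
    assert pianka_overlap([1, 0], [0, 1]) == 0.0
    with pytest.raises(ValidationError):
        pianka_overlap([1, 2], [1, 2, 3])


@settings(deadline=None, derandomize=True)
@given(v=positive_vectors, c=st.floats(min_value=0.01, max_value=100))
def test_pianka_scale_invariance_and_bounds(v, c):
    w = [x * 1.7 + 0.3 for x in v]  # second, non-proportional-in-general vector
    o = pianka_overlap(v, w)
    assert 0.0 <= o <= 1.0 + 1e-12
    assert pianka_overlap([c * x for x in v], w) == pytest.approx(o, rel=1e-9)
    assert pianka_overlap(v, [c * x for x in v]) == pytest.approx(1.0)


def test_overlap_matrix_structure(dominant_iv):
    om = overlap_matrix(dominant_iv)
    o = om.o.to_numpy()
    assert np.allclose(o, o.T)
    assert np.allclose(np.diag(o), 1.0)
    assert ((o >= 0) & (o <= 1)).all()
    # zero exactly when plot supports are disjoint
    iv = dominant_iv.iv.to_numpy()
    for i, j in itertools.combinations(range(len(o)), 2):
        disjoint = not ((iv[i] > 0) & (iv[j] > 0)).any()
        assert (abs(o[i, j]) < 1e-12) == disjoint


def test_overlap_matrix_requires_two_species():
    single = ImportanceTable.from_iv_frame(
        pd.DataFrame({"p1": [10.0], "p2": [5.0]}, index=["only"])
    )
    with pytest.raises(ValidationError):
        overlap_matrix(single)


def test_proportional_rows_overlap_fully():
    t = ImportanceTable.from_iv_frame(
        pd.DataFrame({"p1": [10.0, 20.0], "p2": [5.0, 10.0]}, index=["a", "b"])
    )
    assert overlap_matrix(t).o.loc["a", "b"] == pytest.approx(1.0)


def test_overlap_census_on_printed_matrix(printed_overlap):
    """The published matrix censuses to 78 pairs, 43 at/above 0.50, 13 zeros."""
    c = overlap_census(printed_overlap, threshold=0.50)
    assert (c.n_pairs, c.n_at_or_above, c.n_zero) == (78, 43, 13)
    assert c.fraction_pct == pytest.approx(55.1, abs=0.1)
    # the inclusive threshold matters: one printed cell equals 0.50 exactly
    strict = overlap_census(printed_overlap, threshold=0.50, inclusive=False)
    assert strict.n_at_or_above == 42


def test_overlap_census_trivial_cases():
    ones = pd.DataFrame(1.0, index=list("abc"), columns=list("abc"))
    c = overlap_census(ones, threshold=0.5)
    assert (c.n_pairs, c.n_at_or_above, c.n_zero) == (3, 3, 0)
    assert overlap_census(ones, threshold=0.0).n_at_or_above == 3
    with pytest.raises(ValidationError):
        overlap_census(ones, threshold=1.5)


def test_breadth_table_modes(dominant_iv):
    paper = breadth_table(dominant_iv, "paper-replication")
    norm = breadth_table(dominant_iv, "consistent-normalized")
    assert (paper["b_levins"] == norm["b_levins"]).all()
    # normalized Shannon is bounded by ln(n_plots); iv-fraction is not comparable
    assert (norm["b_shannon"] <= math.log(4) + 1e-12).all()
    with pytest.raises(ValueError):
        breadth_table(dominant_iv, "bogus")
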