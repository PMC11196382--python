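"""Redundancy analysis: algebraic oracles, permutation tests, cross-checks."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from nichepop.errors import CollinearityError, ParameterError
from nichepop.ordination import RDA, forward_select, standardize
from nichepop.simulate import SoilTraitSimParams, gen_soil_traits


def _random_matrices(seed, n=30, p_y=5, p_x=3):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p_x)), columns=[f"x{i}" for i in range(p_x)])
    Y = pd.DataFrame(rng.normal(size=(n, p_y)), columns=[f"y{i}" for i in range(p_y)])
    return Y, X


def test_standardize_center_and_zscore():
    Y, _ = _random_matrices(0)
    c = standardize(Y, "center")
    assert np.allclose(c.mean(axis=0), 0, atol=1e-12)
    z = standardize(Y, "zscore")
    assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)
    # idempotence: re-standardizing changes nothing
    assert np.allclose(standardize(z, "zscore"), z, atol=1e-12)
    with pytest.raises(ParameterError):
        standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0]}), "zscore")
    with pytest.raises(ParameterError):
        standardize(Y, "bogus")


def test_noiseless_linear_response_is_fully_constrained():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 3))
    Y = X @ rng.normal(size=(3, 4))
    res = RDA(Y, X).fit()
    assert res.total_constrained_pct == pytest.approx(100.0, abs=1e-9)


def test_variance_conservation_on_noisy_data():
    Y, X = _random_matrices(2)
    res = RDA(Y, X).fit()
    total = res.eigenvalues.sum() + res.residual_eigenvalues.sum()
    assert total == pytest.approx(res.total_variance, abs=1e-9)
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)  # non-increasing


def test_full_rank_orthonormal_constraints_recover_pca():
    """X spanning the centred sample space makes RDA a plain PCA of Y."""
    rng = np.random.default_rng(3)
    n, p = 5, 4
    Y = rng.normal(size=(n, p))
    centering = np.eye(n) - np.ones((n, n)) / n
    u, s, _ = np.linalg.svd(centering)
    X = u[:, : n - 1]  # orthonormal basis of the centred space
    res = RDA(Y, X, scale_response="center", scale_explanatory="center").fit()
    Yc = Y - Y.mean(axis=0)
    oracle = np.sort(np.linalg.eigvalsh(Yc.T @ Yc / (n - 1)))[::-1]
    assert np.allclose(res.eigenvalues, oracle[: len(res.eigenvalues)], atol=1e-9)
    assert res.total_constrained_pct == pytest.approx(100.0, abs=1e-9)


def test_constrained_variance_monotone_in_added_variables():
    Y, X = _random_matrices(4, p_x=4)
    prev = 0.0
    for k in range(1, 5):
        res = RDA(Y, X.iloc[:, :k]).fit()
        assert res.eigenvalues.sum() >= prev - 1e-12
        prev = res.eigenvalues.sum()


def test_collinear_columns_are_named():
    Y, X = _random_matrices(5)
    X["dup"] = X["x0"] * 2.0
    with pytest.raises(CollinearityError) as err:
        RDA(Y, X)
    assert "dup" in str(err.value)


def test_forward_select_contract_and_reproducibility():
    Y, X = _random_matrices(6)
    a = forward_select(Y, X, n_perm=99, seed=42)
    b = forward_select(Y, X, n_perm=99, seed=42)
    pd.testing.assert_frame_equal(a, b)
    assert a["contribution_pct"].sum() == pytest.approx(100.0, abs=1e-6)
    assert (a["p_value"] >= 1 / 100).all()
    with pytest.raises(ParameterError):
        forward_select(Y, X, n_perm=50)
    with pytest.raises(ParameterError):
        forward_select(Y, X.iloc[:, :0], n_perm=99)


def test_single_strong_predictor_hits_permutation_floor():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(40, 1))
    Y = x @ np.ones((1, 3)) * 2.0 + rng.normal(scale=0.1, size=(40, 3))
    sel = forward_select(Y, pd.DataFrame(x, columns=["x"]), n_perm=999, seed=0)
    assert sel.loc[0, "p_value"] == pytest.approx(1 / 1000)


def test_om_first_then_ph_on_simulated_soil():
    table = gen_soil_traits(SoilTraitSimParams(seed=7))
    sel = forward_select(table.traits, table.soil, n_perm=99, seed=7, max_steps=2)
    assert list(sel["variable"]) == ["OM", "pH"]
    assert sel.loc[0, "contribution_pct"] > sel.loc[1, "contribution_pct"]
    res = RDA.from_soil_traits(table).fit()
    # axis 1 dominates and OM has the largest axis-1 biplot magnitude
    assert res.explained_pct[0] > res.explained_pct[1]
    assert res.biplot_scores["RDA1"].abs().idxmax() == "OM"


def test_eigenvalues_match_vegan_rda():
    """Independent cross-check against the vegan implementation in R."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the cross-check oracle")
    Y, X = _random_matrices(8, n=25, p_y=4, p_x=3)
    script = textwrap.dedent(
        """
        suppressMessages(library(vegan))
        y <- as.matrix(read.csv("y.csv"))
        x <- read.csv("x.csv")
        m <- rda(y ~ ., data = x, scale = TRUE)
        cat(format(c(m$CCA$eig, m$tot.chi), digits = 15), sep = "\\n")
        """
    )
    import tempfile, os

    with tempfile.TemporaryDirectory() as d:
        Y.to_csv(os.path.join(d, "y.csv"), index=False)
        X.to_csv(os.path.join(d, "x.csv"), index=False)
        out = subprocess.run(
            ["Rscript", "-e", script], cwd=d, capture_output=True, text=True, check=True
        )
    values = [float(v) for v in out.stdout.split()]
    vegan_eig, vegan_total = np.array(values[:-1]), values[-1]
    res = RDA(Y, X, scale_response="zscore", scale_explanatory="zscore").fit()
    assert res.total_variance == pytest.approx(vegan_total, rel=1e-10)
    assert np.allclose(res.eigenvalues, vegan_eig, rtol=1e-8)
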