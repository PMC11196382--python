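"""Redundancy analysis (RDA) with forward selection and permutation tests.

RDA is the constrained ordination in which principal axes are extracted from
the portion of a multivariate response Y (here, growth and flowering traits)
explained by least-squares regression on explanatory variables X (here, soil
physicochemistry). After column standardisation:

1. regress Y on X (with intercept, via centring) to obtain fitted values Ŷ;
2. the constrained axes are the principal axes of Ŷ; their eigenvalues
   partition the variance of Ŷ;
3. per-axis explained percentages are taken relative to the total variance
   of Y, so constrained + residual variance = total variance exactly.

Forward selection adds, at each step, the explanatory variable contributing
the most additional explained variance; significance of each addition is a
permutation test of the pseudo-F statistic

    F = (added variance / 1) / (residual variance / (n − k − 1)),

where k counts explanatory variables in the model after the addition, with
residuals of the reduced model permuted (a conditional test). Contribution
percentages are relative to the variance explainable by the full explanatory
matrix, so a complete selection sums to 100.

Implemented as a model/results pair: ``RDA(Y, X).fit()`` returns an
:class:`RDAResults` with eigenvalues, scores and a ``summary()`` table;
``forward_select`` is available both module-level and as a model method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CollinearityError, ParameterError
from .survey_io import SoilTraitTable


def standardize(matrix, mode: str = "zscore") -> pd.DataFrame:
    """Column-standardize a samples × variables matrix.

    "center" subtracts column means; "zscore" additionally divides by the
    sample standard deviation (n−1). Constant columns are rejected under
    zscore because they carry no variance to ordinate.
    """
    df = pd.DataFrame(matrix).astype(float)
    if len(df) < 2:
        raise ParameterError("standardization requires at least 2 samples")
    if df.isna().any().any():
        raise ParameterError("matrix contains missing values")
    out = df - df.mean(axis=0)
    if mode == "zscore":
        sd = df.std(axis=0, ddof=1)
        constant = sd.index[sd <= 0].tolist()
        if constant:
            raise ParameterError(f"constant column(s) under zscore: {constant}")
        out = out / sd
    elif mode != "center":
        raise ParameterError(f"unknown standardization mode {mode!r}")
    return out


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name dependent columns via pivoted QR on the transposed matrix
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        tol = max(arr.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        dependent = [X.columns[i] for i, d in enumerate(diag) if d <= tol]
        if not dependent:
            dependent = list(X.columns[rank:])
        raise CollinearityError(dependent)


def _fitted(Yc: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    return Xc @ beta


def _trace_var(M: np.ndarray, n: int) -> float:
    return float(np.sum(M**2) / (n - 1))


@dataclass
class RDAResults:
    """Fitted redundancy analysis.

    Eigenvalues are in variance units of the standardized response; explained
    percentages are relative to the total response variance.
    """

    eigenvalues: np.ndarray
    residual_eigenvalues: np.ndarray
    total_variance: float
    site_scores: pd.DataFrame
    response_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    nobs: int
    n_constraints: int

    @property
    def explained_pct(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.total_variance

    @property
    def total_constrained_pct(self) -> float:
        return float(100.0 * self.eigenvalues.sum() / self.total_variance)

    def summary(self) -> str:
        lines = [
            "Redundancy analysis",
            f"  samples: {self.nobs}   responses: {self.response_scores.shape[0]}"
            f"   constraints: {self.n_constraints}",
            f"  total variance: {self.total_variance:.4f}",
            f"  constrained: {self.total_constrained_pct:.2f}%",
            "",
            "  axis        eigenvalue   explained%",
        ]
        for i, (ev, pct) in enumerate(zip(self.eigenvalues, self.explained_pct), 1):
            lines.append(f"  RDA{i:<9} {ev:10.4f} {pct:11.2f}")
        return "\n".join(lines)


class RDA:
    """Redundancy analysis model of a response matrix on explanatory variables.

    Parameters
    ----------
    Y, X : DataFrame or array
        Samples × responses and samples × explanatory variables, row-aligned.
    scale_response, scale_explanatory : str
        "zscore" (default; the matrices mix units) or "center".
    """

    def __init__(self, Y, X, scale_response="zscore", scale_explanatory="zscore"):
        Y = pd.DataFrame(Y)
        X = pd.DataFrame(X)
        if len(Y) != len(X):
            raise ParameterError("Y and X must have the same number of samples")
        if len(Y) <= X.shape[1]:
            raise ParameterError(
                f"need n_samples > n_explanatory (got {len(Y)} ≤ {X.shape[1]})"
            )
        self.Y = standardize(Y, scale_response)
        self.X = standardize(X, scale_explanatory)
        _check_rank(self.X)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, response: list, explanatory: list, **kw):
        return cls(frame[list(response)], frame[list(explanatory)], **kw)

    @classmethod
    def from_soil_traits(cls, table: SoilTraitTable, **kw):
        """Traits as the response, soil variables as the constraints."""
        return cls(table.traits, table.soil, **kw)

    def fit(self) -> RDAResults:
        Yc = self.Y.to_numpy()
        Xc = self.X.to_numpy()
        n = Yc.shape[0]
        Yhat = _fitted(Yc, Xc)
        resid = Yc - Yhat

        rank = min(np.linalg.matrix_rank(Xc), Yc.shape[1], n - 1)
        u, s, vt = np.linalg.svd(Yhat, full_matrices=False)
        eig = (s**2) / (n - 1)
        u, s, vt, eig = u[:, :rank], s[:rank], vt[:rank], eig[:rank]

        _, s_r, _ = np.linalg.svd(resid, full_matrices=False)
        resid_eig = (s_r**2) / (n - 1)
        resid_eig = resid_eig[resid_eig > 1e-12]

        axes = [f"RDA{i + 1}" for i in range(rank)]
        site = pd.DataFrame(u * s, index=self.Y.index, columns=axes)
        resp = pd.DataFrame(vt.T, index=self.Y.columns, columns=axes)
        # biplot scores: correlations of constraints with the site scores
        bip = np.zeros((Xc.shape[1], rank))
        for k in range(rank):
            ax = site.iloc[:, k].to_numpy()
            sd_ax = ax.std(ddof=1)
            for j in range(Xc.shape[1]):
                sd_x = Xc[:, j].std(ddof=1)
                bip[j, k] = (
                    np.cov(Xc[:, j], ax, ddof=1)[0, 1] / (sd_x * sd_ax)
                    if sd_ax > 0 and sd_x > 0
                    else 0.0
                )
        biplot = pd.DataFrame(bip, index=self.X.columns, columns=axes)

        return RDAResults(
            eigenvalues=eig,
            residual_eigenvalues=resid_eig,
            total_variance=_trace_var(Yc, n),
            site_scores=site,
            response_scores=resp,
            biplot_scores=biplot,
            nobs=n,
            n_constraints=Xc.shape[1],
        )

    def forward_select(self, n_perm: int = 999, seed: int | None = None,
                       max_steps: int | None = None) -> pd.DataFrame:
        return forward_select(self.Y, self.X, n_perm=n_perm, seed=seed,
                              max_steps=max_steps, _prestandardized=True)


def forward_select(
    Y,
    X,
    n_perm: int = 999,
    seed: int | None = None,
    max_steps: int | None = None,
    scale_response: str = "zscore",
    scale_explanatory: str = "zscore",
    _prestandardized: bool = False,
) -> pd.DataFrame:
    """Greedy forward selection of explanatory variables with permutation tests.

    Returns one row per selected variable, in selection order, with the
    variance contribution (percent of the variance explainable by the full
    X), the pseudo-F of the addition and its permutation p-value
    ``(1 + #{F* ≥ F}) / (n_perm + 1)``. Ties in added variance break
    lexicographically by variable name. All variables are selected (no
    stopping rule), matching the full explanation-rate tables of constrained
    ordinations.
    """
    if n_perm < 99:
        raise ParameterError("n_perm must be at least 99")
    Y = pd.DataFrame(Y)
    X = pd.DataFrame(X)
    if X.shape[1] == 0:
        raise ParameterError("explanatory matrix has no columns")
    if not _prestandardized:
        Y = standardize(Y, scale_response)
        X = standardize(X, scale_explanatory)
        _check_rank(X)
    rng = np.random.default_rng(seed)
    Yc = Y.to_numpy()
    n = Yc.shape[0]
    total = _trace_var(Yc, n)
    explainable = _trace_var(_fitted(Yc, X.to_numpy()), n)

    def constrained_var(cols: list, Ymat: np.ndarray) -> float:
        if not cols:
            return 0.0
        return _trace_var(_fitted(Ymat, X[cols].to_numpy()), n)

    selected: list = []
    rows = []
    remaining = sorted(X.columns)
    base = 0.0
    steps = len(remaining) if max_steps is None else min(max_steps, len(remaining))
    for _ in range(steps):
        best, best_added = None, -np.inf
        for v in remaining:  # lexicographic order; strict > breaks ties
            added = constrained_var(selected + [v], Yc) - base
            if added > best_added + 1e-15:
                best, best_added = v, added
        assert best is not None
        k = len(selected) + 1
        df_resid = n - k - 1
        new_constrained = base + best_added
        f_obs = (best_added / 1.0) / ((total - new_constrained) / df_resid)

        # conditional permutation test: permute reduced-model residuals
        if selected:
            fit_reduced = _fitted(Yc, X[selected].to_numpy())
        else:
            fit_reduced = np.zeros_like(Yc)
        resid_reduced = Yc - fit_reduced
        exceed = 0
        for _p in range(n_perm):
            perm = rng.permutation(n)
            Ystar = fit_reduced + resid_reduced[perm]
            total_star = _trace_var(Ystar, n)
            base_star = constrained_var(selected, Ystar)
            new_star = constrained_var(selected + [best], Ystar)
            added_star = new_star - base_star
            f_star = (added_star / 1.0) / ((total_star - new_star) / df_resid)
            if f_star >= f_obs:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)

        rows.append(
            {
                "variable": best,
                "contribution_pct": 100.0 * best_added / explainable if explainable > 0 else 0.0,
                "added_variance": best_added,
                "pseudo_f": f_obs,
                "p_value": p,
            }
        )
        selected.append(best)
        remaining.remove(best)
        base = new_constrained
    return pd.DataFrame(rows)
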