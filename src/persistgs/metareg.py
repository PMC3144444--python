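"""Linear model for accuracy as a function of heritability, pi and generation.

The full regressor set is intercept + h2 + pi + generation + generation^2 +
h2*generation + pi*generation (seven coefficients).  A reduced variant
drops every term involving pi (equivalent to fitting the average pi), which
is the form applicable when pedigree-based methods are included, since
their accuracy is not expected to depend on pi.  Least-squares means are
model predictions on a user grid with the remaining regressors held at
their data means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["AccuracyModelSpec", "MetaFit", "fit_accuracy_model", "ls_means"]

_FULL_TERMS = ("h2", "pi", "generation", "generation_squared",
               "h2_x_generation", "pi_x_generation")


@dataclass
class AccuracyModelSpec:
    include_pi_terms: bool = True
    include_method_factor: bool = False
    response: str = "accuracy"

    @property
    def terms(self) -> tuple[str, ...]:
        if self.include_pi_terms:
            return _FULL_TERMS
        return tuple(t for t in _FULL_TERMS if "pi" not in t)


@dataclass
class MetaFit:
    spec: AccuracyModelSpec
    coefficients: pd.DataFrame  # estimate, se, t, p per regressor
    result: object = field(repr=False)  # statsmodels RegressionResults
    means: pd.Series = field(repr=False, default=None)  # regressor data means


def _design(records: pd.DataFrame, spec: AccuracyModelSpec) -> pd.DataFrame:
    need = {"h2", "generation"} | ({"pi"} if spec.include_pi_terms else set())
    missing = need - set(records.columns)
    if missing:
        raise KeyError(f"records lack required columns: {sorted(missing)}")
    X = pd.DataFrame(index=records.index)
    g = records["generation"].astype(float)
    h2 = records["h2"].astype(float)
    for t in spec.terms:
        if t == "h2":
            X[t] = h2
        elif t == "pi":
            X[t] = records["pi"].astype(float)
        elif t == "generation":
            X[t] = g
        elif t == "generation_squared":
            X[t] = g**2
        elif t == "h2_x_generation":
            X[t] = h2 * g
        elif t == "pi_x_generation":
            X[t] = records["pi"].astype(float) * g
    if spec.include_method_factor:
        dummies = pd.get_dummies(records["method"], prefix="method", drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    return X


def fit_accuracy_model(
    records: pd.DataFrame, spec: AccuracyModelSpec = AccuracyModelSpec()
) -> MetaFit:
    """Ordinary least squares of accuracy on the model terms, with t-based
    standard errors and p-values."""
    rec = records.dropna(subset=[spec.response]).copy()
    X = _design(rec, spec)
    y = rec[spec.response].astype(float)
    if len(rec) < X.shape[1] + 3:
        raise ValueError("too few accuracy records for the requested model")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ValueError(
            "collinear design: at least one regressor among "
            f"{list(Xc.columns)} is linearly dependent"
        )
    res = sm.OLS(y, Xc).fit()
    coef = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    return MetaFit(spec=spec, coefficients=coef, result=res, means=X.mean())


def ls_means(
    fit: MetaFit,
    grid: pd.DataFrame,
) -> pd.DataFrame:
    """Predicted accuracy at the grid points (columns from {pi, h2,
    generation}), other regressors held at their data means.

    Warns when a grid value lies outside the observed range of its variable.
    """
    import warnings

    spec = fit.spec
    rows = []
    for _, point in grid.iterrows():
        vals = {}
        h2 = point.get("h2", np.nan)
        pi = point.get("pi", np.nan)
        g = point.get("generation", np.nan)
        for t in spec.terms:
            if t == "h2":
                vals[t] = h2 if not np.isnan(h2) else fit.means[t]
            elif t == "pi":
                vals[t] = pi if not np.isnan(pi) else fit.means[t]
            elif t == "generation":
                vals[t] = g if not np.isnan(g) else fit.means[t]
            elif t == "generation_squared":
                vals[t] = vals["generation"] ** 2
            elif t == "h2_x_generation":
                vals[t] = vals["h2"] * vals["generation"]
            elif t == "pi_x_generation":
                vals[t] = vals["pi"] * vals["generation"]
        for extra in fit.means.index:
            if extra not in vals:
                vals[extra] = fit.means[extra]
        rows.append(vals)
    X = pd.DataFrame(rows)[fit.means.index]
    for col in ("h2", "pi", "generation"):
        if col in grid.columns and col in fit.means.index:
            data_col = fit.result.model.exog[
                :, list(fit.result.model.exog_names).index(col)
            ]
            lo, hi = data_col.min(), data_col.max()
            out = grid[col].dropna()
            if ((out < lo) | (out > hi)).any():
                warnings.warn(
                    f"grid values for {col} outside observed range [{lo}, {hi}]",
                    UserWarning,
                )
    Xc = sm.add_constant(X, has_constant="add")
    pred = fit.result.predict(Xc)
    out = grid.copy().reset_index(drop=True)
    out["accuracy"] = np.asarray(pred)
    return out
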