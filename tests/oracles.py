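"""Independent oracles used by the test suite.

These deliberately avoid the package's per-cluster likelihood code path:
the dense oracle materialises the full marginal covariance of a (small)
dataset and evaluates the restricted likelihood directly; the moment
oracle computes the expected response analytically from covariate moments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FIXED_COLUMNS = (
    "intercept",
    "time",
    "time2",
    "influence",
    "gender",
    "classtype",
    "classtype_x_time",
    "gender_x_time",
    "influence_x_classtype",
)


def dense_design(df: pd.DataFrame, terms=FIXED_COLUMNS) -> np.ndarray:
    t = df["time"].to_numpy(dtype=float)
    cols = {
        "intercept": np.ones(len(df)),
        "time": t,
        "time2": t * t,
        "influence": df.get("influence", pd.Series(np.zeros(len(df)))).to_numpy(float),
        "gender": df.get("gender", pd.Series(np.zeros(len(df)))).to_numpy(float),
        "classtype": df.get("classtype", pd.Series(np.zeros(len(df)))).to_numpy(float),
    }
    cols["classtype_x_time"] = cols["classtype"] * t
    cols["gender_x_time"] = cols["gender"] * t
    cols["influence_x_classtype"] = cols["influence"] * cols["classtype"]
    return np.column_stack([cols[c] for c in terms])


def dense_marginal_covariance(
    df: pd.DataFrame,
    resid: float,
    l2_intercept: float,
    l2_slope: float,
    l3_intercept: float,
    l3_slope: float,
    random_slopes: bool = True,
) -> np.ndarray:
    """Full n x n covariance of the response, built cluster by cluster."""
    n = len(df)
    V = np.eye(n) * resid
    df = df.reset_index(drop=True)
    for _, g in df.groupby("class_id"):
        idx = g.index.to_numpy()
        Z = np.column_stack([np.ones(len(g)), g["time"].to_numpy(float)])
        G = np.diag([l3_intercept, l3_slope if random_slopes else 0.0])
        if not random_slopes:
            Z, G = Z[:, :1], G[:1, :1]
        V[np.ix_(idx, idx)] += Z @ G @ Z.T
    for _, g in df.groupby(["class_id", "student_id"]):
        idx = g.index.to_numpy()
        Z = np.column_stack([np.ones(len(g)), g["time"].to_numpy(float)])
        G = np.diag([l2_intercept, l2_slope if random_slopes else 0.0])
        if not random_slopes:
            Z, G = Z[:, :1], G[:1, :1]
        V[np.ix_(idx, idx)] += Z @ G @ Z.T
    return V


def dense_restricted_deviance(
    df: pd.DataFrame, terms, V: np.ndarray, method: str = "REML"
) -> float:
    """-2 log (restricted) likelihood from the dense covariance matrix."""
    df = df.sort_values(["class_id", "student_id", "time"]).reset_index(drop=True)
    X = dense_design(df, terms)
    y = df["motivation"].to_numpy(float)
    n, p = X.shape
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    logdetV = np.linalg.slogdet(V)[1]
    if method == "REML":
        return (
            (n - p) * np.log(2 * np.pi)
            + logdetV
            + np.linalg.slogdet(A)[1]
            + quad
        )
    return n * np.log(2 * np.pi) + logdetV + quad


def expected_response_mean(params) -> float:
    """Analytic expectation of the response under the generating model.

    Uses independence of the covariates and the moments of the occasion
    grid: E[t], E[t^2], the covariate mean, and the two Bernoulli rates.
    """
    t = np.asarray(params.time_points, dtype=float)
    Et, Et2 = t.mean(), (t**2).mean()
    mi, pg, ph = params.influence_mean, params.p_girl, params.p_heterogeneous
    return (
        params.intercept
        + params.beta_time * Et
        + params.beta_time2 * Et2
        + params.beta_influence * mi
        + params.beta_gender * pg
        + params.beta_classtype * ph
        + params.beta_classtype_x_time * ph * Et
        + params.beta_gender_x_time * pg * Et
        + params.beta_influence_x_classtype * mi * ph
    )
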