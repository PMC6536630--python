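"""Three-level linear mixed model engine (REML/ML).

Fits the longitudinal growth model with random intercepts and linear-time
slopes for classrooms (level 3) and students within classrooms (level 2),
assuming zero covariance between intercepts and slopes at both levels
(diagonal random-effects covariance).

The marginal covariance of the response within one classroom k is

    V_k = Z3_k G3 Z3_k' + blockdiag_j(Z2_jk G2 Z2_jk') + sigma2_e I,

with G3 = diag(sigma2_v0, sigma2_v1) and G2 = diag(tau2_u0, tau2_u1).
Classrooms are independent, so the restricted likelihood factors over
classes; fixed effects are profiled out by generalized least squares and
the residual variance is profiled analytically.  The optimizer works on
the non-negative relative standard deviations theta_i = sd_i / sigma_e
(the zero boundary is reachable and flags a singular fit).

Classes sharing the same per-student occasion structure share a marginal
covariance matrix; its Cholesky factor is computed once per unique
structure, which makes complete-data fits on very large populations cheap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cholesky, solve_triangular
from scipy.stats import norm

__all__ = [
    "FULL_FIXED_TERMS",
    "ModelSpec",
    "FULL_MODEL",
    "EMPTY_MODEL",
    "VarianceComponents",
    "FitResult",
    "IntervalSet",
    "DesignBundle",
    "build_design",
    "reml_deviance",
    "fit_lmm",
    "fit_empty_model",
    "wald_ci",
]

FULL_FIXED_TERMS = (
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

_RANDOM_TERMS = ("intercept", "time")


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed terms and which random intercepts/slopes to fit."""

    fixed_terms: tuple[str, ...] = FULL_FIXED_TERMS
    random_l2: tuple[str, ...] = ("intercept", "time")
    random_l3: tuple[str, ...] = ("intercept", "time")
    method: str = "REML"

    def __post_init__(self) -> None:
        if "intercept" not in self.fixed_terms:
            raise ValueError("fixed_terms must include the intercept")
        unknown = set(self.fixed_terms) - set(FULL_FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed terms: {sorted(unknown)}")
        for side in (self.random_l2, self.random_l3):
            if tuple(side) not in ((), ("intercept",), ("intercept", "time")):
                raise ValueError(
                    "random terms must be ('intercept',) or ('intercept','time')"
                )
        if self.method not in ("REML", "ML"):
            raise ValueError("method must be 'REML' or 'ML'")


FULL_MODEL = ModelSpec()
EMPTY_MODEL = ModelSpec(
    fixed_terms=("intercept",),
    random_l2=("intercept",),
    random_l3=("intercept",),
)


@dataclass(frozen=True)
class VarianceComponents:
    """Estimated (or candidate) variance components; slopes may be absent."""

    resid: float
    l2_intercept: float
    l2_slope: float | None = None
    l3_intercept: float = 0.0
    l3_slope: float | None = None

    def __post_init__(self) -> None:
        for name in ("resid", "l2_intercept", "l2_slope", "l3_intercept", "l3_slope"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        out = {"resid": self.resid, "l2_intercept": self.l2_intercept}
        if self.l2_slope is not None:
            out["l2_slope"] = self.l2_slope
        out["l3_intercept"] = self.l3_intercept
        if self.l3_slope is not None:
            out["l3_slope"] = self.l3_slope
        return out


@dataclass
class FitResult:
    """Result of one mixed-model fit."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    varcomps: VarianceComponents
    log_restricted_likelihood: float
    converged: bool
    singular: bool
    n_obs: int
    n_students: int
    n_classes: int
    method: str = "REML"

    def to_json(self, path=None) -> str:
        payload = {
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "varcomps": self.varcomps.as_dict(),
            "log_restricted_likelihood": self.log_restricted_likelihood,
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": self.n_obs,
            "n_students": self.n_students,
            "n_classes": self.n_classes,
            "method": self.method,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class IntervalSet:
    """Per-term symmetric confidence intervals."""

    alpha: float
    intervals: dict[str, tuple[float, float]]

    def __getitem__(self, term: str) -> tuple[float, float]:
        return self.intervals[term]


# ---------------------------------------------------------------------------
# design construction


def _term_column(term: str, df: pd.DataFrame) -> np.ndarray:
    t = df["time"].to_numpy(dtype=float)
    if term == "intercept":
        return np.ones(len(df))
    if term == "time":
        return t
    if term == "time2":
        return t * t
    if term == "influence":
        return df["influence"].to_numpy(dtype=float)
    if term == "gender":
        return df["gender"].to_numpy(dtype=float)
    if term == "classtype":
        return df["classtype"].to_numpy(dtype=float)
    if term == "classtype_x_time":
        return df["classtype"].to_numpy(dtype=float) * t
    if term == "gender_x_time":
        return df["gender"].to_numpy(dtype=float) * t
    if term == "influence_x_classtype":
        return df["influence"].to_numpy(dtype=float) * df["classtype"].to_numpy(
            dtype=float
        )
    raise ValueError(f"unknown term {term!r}")


@dataclass
class _ClassBlock:
    X: np.ndarray  # n_k x p fixed design
    y: np.ndarray  # n_k
    signature: tuple  # per-student tuples of times, in row order


@dataclass
class DesignBundle:
    """Per-classroom design blocks plus bookkeeping for the fit."""

    spec: ModelSpec
    blocks: list[_ClassBlock]
    n_obs: int
    n_students: int
    n_classes: int
    y_sd: float
    # classes grouped by shared covariance structure
    groups: dict[tuple, list[int]]


def build_design(dataset: pd.DataFrame, spec: ModelSpec) -> DesignBundle:
    """Assemble per-class fixed and random design blocks.

    Rows are ordered by (class, student, occasion); classes that share a
    per-student time structure are grouped so the fit can reuse Cholesky
    factors of the marginal covariance.
    """
    needed = {"class_id", "student_id", "time", "motivation"}
    for term in spec.fixed_terms:
        if term in ("influence", "influence_x_classtype"):
            needed.add("influence")
        if term in ("gender", "gender_x_time"):
            needed.add("gender")
        if term in ("classtype", "classtype_x_time", "influence_x_classtype"):
            needed.add("classtype")
    missing = sorted(needed - set(dataset.columns))
    if missing:
        raise ValueError(f"dataset missing required columns: {missing}")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")

    df = dataset.sort_values(
        ["class_id", "student_id", "time"], kind="mergesort"
    ).reset_index(drop=True)
    y_all = df["motivation"].to_numpy(dtype=float)
    X_all = np.column_stack([_term_column(t, df) for t in spec.fixed_terms])

    class_codes, class_starts = _run_bounds(df["class_id"].to_numpy())
    stu_key = (
        df["class_id"].to_numpy().astype(np.int64) * np.int64(1_000_000)
        + df["student_id"].to_numpy().astype(np.int64)
    )
    _, stu_starts = _run_bounds(stu_key)
    n_students = len(stu_starts) - 1

    times = df["time"].to_numpy(dtype=float)
    blocks: list[_ClassBlock] = []
    groups: dict[tuple, list[int]] = {}
    si = 0
    for ci in range(len(class_starts) - 1):
        a, b = class_starts[ci], class_starts[ci + 1]
        sig_parts = []
        while si < len(stu_starts) - 1 and stu_starts[si] < b:
            s0, s1 = stu_starts[si], stu_starts[si + 1]
            sig_parts.append(tuple(times[s0:s1]))
            si += 1
        sig = tuple(sig_parts)
        blocks.append(_ClassBlock(X=X_all[a:b], y=y_all[a:b], signature=sig))
        groups.setdefault(sig, []).append(ci)

    return DesignBundle(
        spec=spec,
        blocks=blocks,
        n_obs=len(df),
        n_students=n_students,
        n_classes=len(blocks),
        y_sd=float(np.std(y_all)),
        groups=groups,
    )


def _run_bounds(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices of runs of equal consecutive values (plus end)."""
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change, [len(values)]))
    return values[starts[:-1]], starts


def _random_cols(terms: Sequence[str], t: np.ndarray) -> np.ndarray:
    cols = []
    for term in terms:
        cols.append(np.ones_like(t) if term == "intercept" else t)
    return np.column_stack(cols) if cols else np.empty((t.size, 0))


def _make_W(signature: tuple, spec: ModelSpec, g3: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Marginal covariance (unit residual scale) for one class structure.

    ``g3``/``g2`` are variance-to-residual ratios for the level-3/level-2
    random terms in spec order.
    """
    t = np.concatenate([np.asarray(s, dtype=float) for s in signature])
    n = t.size
    W = np.eye(n)
    if g3.size:
        Z3 = _random_cols(spec.random_l3, t)
        W += (Z3 * g3) @ Z3.T
    if g2.size:
        pos = 0
        for stu in signature:
            m = len(stu)
            Z2 = _random_cols(spec.random_l2, t[pos : pos + m])
            W[pos : pos + m, pos : pos + m] += (Z2 * g2) @ Z2.T
            pos += m
    return W


# ---------------------------------------------------------------------------
# likelihood evaluation


def _gls_pieces(
    bundle: DesignBundle, g3: np.ndarray, g2: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Accumulate GLS cross-products over classes at unit residual scale.

    Returns (sum log|W_k|, X'W^-1X, X'W^-1y, y'W^-1y).
    """
    p = bundle.blocks[0].X.shape[1]
    logdet = 0.0
    crossprod = np.zeros((p + 1, p + 1))
    for sig, class_ids in bundle.groups.items():
        W = _make_W(sig, bundle.spec, g3, g2)
        L = cholesky(W, lower=True, check_finite=False)
        logdet += 2.0 * float(np.sum(np.log(np.diag(L)))) * len(class_ids)
        r = W.shape[0]
        M = np.empty((r, len(class_ids) * (p + 1)))
        for i, ci in enumerate(class_ids):
            blk = bundle.blocks[ci]
            M[:, i * (p + 1) : i * (p + 1) + p] = blk.X
            M[:, i * (p + 1) + p] = blk.y
        U = solve_triangular(L, M, lower=True, check_finite=False)
        U = U.reshape(r, len(class_ids), p + 1)
        crossprod += np.einsum("rmi,rmj->ij", U, U)
    A = crossprod[:p, :p]
    b = crossprod[:p, p]
    c = float(crossprod[p, p])
    return logdet, A, b, c


def _profiled_deviance(
    bundle: DesignBundle, theta: np.ndarray, method: str
) -> tuple[float, dict]:
    """-2 log (restricted) likelihood profiled over beta and sigma2_e.

    ``theta`` holds relative standard deviations (level-3 terms first,
    then level-2 terms, each in spec order).
    """
    q3 = len(bundle.spec.random_l3)
    g = np.asarray(theta, dtype=float) ** 2
    g3, g2 = g[:q3], g[q3:]
    logdetW, A, b, c = _gls_pieces(bundle, g3, g2)
    n, p = bundle.n_obs, A.shape[0]
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return math.inf, {}
    beta = np.linalg.solve(A, b)
    q = max(c - float(b @ beta), 1e-300)
    if method == "REML":
        dof = n - p
        sigma2 = q / dof
        dev = dof * (math.log(2 * math.pi) + math.log(sigma2) + 1.0) + logdetW + logdetA
    else:
        sigma2 = q / n
        dev = n * (math.log(2 * math.pi) + math.log(sigma2) + 1.0) + logdetW
    info = {
        "beta": beta,
        "sigma2": sigma2,
        "A": A,
        "logdetW": logdetW,
        "logdetA": logdetA,
    }
    return dev, info


def reml_deviance(
    varcomps: VarianceComponents,
    bundle: DesignBundle,
    method: str = "REML",
) -> float:
    """-2 x (restricted) log-likelihood at a given variance candidate.

    Fixed effects are profiled out by GLS; the residual variance is taken
    from the candidate, not profiled.  Exploits independence across
    classes (the full-population covariance is never materialised).
    """
    if varcomps.resid <= 0:
        raise ValueError("resid variance must be strictly positive")
    spec = bundle.spec
    g3 = np.array(
        [
            {"intercept": varcomps.l3_intercept, "time": varcomps.l3_slope or 0.0}[t]
            for t in spec.random_l3
        ],
        dtype=float,
    ) / varcomps.resid
    g2 = np.array(
        [
            {"intercept": varcomps.l2_intercept, "time": varcomps.l2_slope or 0.0}[t]
            for t in spec.random_l2
        ],
        dtype=float,
    ) / varcomps.resid
    logdetW, A, b, c = _gls_pieces(bundle, g3, g2)
    n, p = bundle.n_obs, A.shape[0]
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1 X is not positive definite")
    beta = np.linalg.solve(A, b)
    q = c - float(b @ beta)
    s2 = varcomps.resid
    if method == "REML":
        return (
            (n - p) * math.log(2 * math.pi)
            + (n - p) * math.log(s2)
            + logdetW
            + logdetA
            + q / s2
        )
    return n * math.log(2 * math.pi) + n * math.log(s2) + logdetW + q / s2


# ---------------------------------------------------------------------------
# fitting


def _moment_start(bundle: DesignBundle) -> np.ndarray:
    """Crude variance-decomposition starting values on the theta scale."""
    X = np.vstack([blk.X for blk in bundle.blocks])
    y = np.concatenate([blk.y for blk in bundle.blocks])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta

    class_means = []
    stu_dev = []
    within = []
    pos = 0
    for blk in bundle.blocks:
        n_k = blk.y.size
        ek = e[pos : pos + n_k]
        cm = ek.mean()
        class_means.append(cm)
        s0 = 0
        for stu in blk.signature:
            m = len(stu)
            sm = ek[s0 : s0 + m].mean()
            stu_dev.append(sm - cm)
            within.append(ek[s0 : s0 + m] - sm)
            s0 += m
        pos += n_k
    s2 = max(float(np.var(np.concatenate(within))), 1e-8 * bundle.y_sd**2 + 1e-12)
    v0 = max(float(np.var(class_means)), 0.0)
    u0 = max(float(np.var(stu_dev)), 0.0)

    start = []
    for term in bundle.spec.random_l3:
        start.append(math.sqrt(v0 / s2) if term == "intercept" else 0.05)
    for term in bundle.spec.random_l2:
        start.append(math.sqrt(u0 / s2) if term == "intercept" else 0.05)
    return np.clip(np.asarray(start), 0.02, 50.0)


def fit_lmm(
    dataset: pd.DataFrame | DesignBundle,
    spec: ModelSpec = FULL_MODEL,
    method: str | None = None,
    boundary_tol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """Fit the three-level model by REML (default) or ML.

    Variance components are optimised on the non-negative relative
    standard-deviation scale with a reachable zero boundary; fixed effects
    and their standard errors come from GLS at the optimum,
    ``cov(beta) = sigma2_e (X'W^-1X)^-1``.  Non-convergence is reported via
    ``converged=False``, never raised.
    """
    bundle = dataset if isinstance(dataset, DesignBundle) else build_design(dataset, spec)
    spec = bundle.spec
    method = method or spec.method
    d = len(spec.random_l3) + len(spec.random_l2)
    p = bundle.blocks[0].X.shape[1]
    if bundle.n_obs <= p:
        raise ValueError(
            f"model with {p} fixed effects needs more than {bundle.n_obs} rows"
        )
    X_stack = np.vstack([blk.X for blk in bundle.blocks])
    if np.linalg.matrix_rank(X_stack) < p:
        # e.g. every sampled class shares one classtype value
        raise np.linalg.LinAlgError("fixed-effect design is rank deficient")

    def objective(theta: np.ndarray) -> float:
        dev, _ = _profiled_deviance(bundle, theta, method)
        return dev

    converged = True
    if d == 0:
        theta_hat = np.empty(0)
    else:
        # two deterministic starts guard against the rare local optimum in
        # boundary-heavy problems (tiny cluster-level variances)
        starts = [_moment_start(bundle), np.full(d, 1.0)]
        best = None
        for k, x0 in enumerate(starts):
            res = optimize.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=[(0.0, 1e3)] * d,
                options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        if not best.success or not np.isfinite(best.fun):
            # line searches can fail on flat boundary regions; polish from
            # the best point and declare convergence if the simplex cannot
            # improve the criterion materially
            res2 = optimize.minimize(
                objective,
                np.clip(best.x, 0.0, 1e3),
                method="Nelder-Mead",
                options={"maxiter": 1000, "xatol": 1e-8, "fatol": 1e-10},
            )
            res2.x = np.clip(res2.x, 0.0, 1e3)
            improvement = best.fun - res2.fun
            if res2.fun <= best.fun:
                best = res2
            converged = bool(np.isfinite(best.fun)) and (
                bool(res2.success) or improvement < 1e-3
            )
        theta_hat = np.clip(best.x, 0.0, None)

    dev, info = _profiled_deviance(bundle, theta_hat, method)
    if not info:
        raise np.linalg.LinAlgError("likelihood evaluation failed at the optimum")
    sigma2 = info["sigma2"]
    beta = info["beta"]
    cov = sigma2 * np.linalg.inv(info["A"])
    se = np.sqrt(np.diag(cov))

    sd_floor = boundary_tol * max(bundle.y_sd, 1e-12)
    sds = theta_hat * math.sqrt(sigma2)
    singular = bool(np.any(sds < sd_floor)) if d else False

    q3 = len(spec.random_l3)
    vc3 = {t: float(theta_hat[i] ** 2 * sigma2) for i, t in enumerate(spec.random_l3)}
    vc2 = {
        t: float(theta_hat[q3 + i] ** 2 * sigma2)
        for i, t in enumerate(spec.random_l2)
    }
    varcomps = VarianceComponents(
        resid=float(sigma2),
        l2_intercept=vc2.get("intercept", 0.0),
        l2_slope=vc2.get("time") if "time" in spec.random_l2 else None,
        l3_intercept=vc3.get("intercept", 0.0),
        l3_slope=vc3.get("time") if "time" in spec.random_l3 else None,
    )
    return FitResult(
        coefficients={t: float(b) for t, b in zip(spec.fixed_terms, beta)},
        std_errors={t: float(s) for t, s in zip(spec.fixed_terms, se)},
        varcomps=varcomps,
        log_restricted_likelihood=-0.5 * dev,
        converged=converged,
        singular=singular,
        n_obs=bundle.n_obs,
        n_students=bundle.n_students,
        n_classes=bundle.n_classes,
        method=method,
    )


def fit_empty_model(dataset: pd.DataFrame, method: str = "REML") -> FitResult:
    """Intercept-only model with random intercepts at levels 2 and 3."""
    return fit_lmm(dataset, EMPTY_MODEL, method=method)


def wald_ci(fit: FitResult, alpha: float = 0.05) -> IntervalSet:
    """Symmetric standard-normal (Wald) confidence intervals per fixed term."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    z = float(norm.ppf(1.0 - alpha / 2.0))
    intervals = {
        term: (est - z * fit.std_errors[term], est + z * fit.std_errors[term])
        for term, est in fit.coefficients.items()
    }
    return IntervalSet(alpha=alpha, intervals=intervals)
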