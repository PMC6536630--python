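"""Shared fixtures.

The expensive objects (full population, truth, condition runs, the R
reference fits) are session-scoped so the acceptance tests and unit tests
share one computation.
"""

from __future__ import annotations

import json
import subprocess
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

import trilevel as tl

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

MASTER_SEED = 1


@pytest.fixture(scope="session")
def small_population():
    """40 classes (20 of 5 students, 20 of 15), complete data."""
    structure = tl.PopulationStructure(classes_per_stratum=20, strata_sizes=(5, 15))
    return tl.generate_population(tl.PopulationParams(), structure, seed=7)


@pytest.fixture(scope="session")
def population():
    """The full synthetic population: 3000 classes, 55000 students."""
    return tl.generate_population(seed=tl.population_seed(MASTER_SEED, "COM"))


@pytest.fixture(scope="session")
def truth(population):
    return tl.derive_true_values(population)


def _run(population, truth, n2, n3, replicates):
    cond = tl.Condition(n2=n2, n3=n3, pattern="COM", replicates=replicates)
    return tl.run_condition(population, truth, cond, master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def cond_15_35(population, truth):
    return _run(population, truth, 15, 35, 200)


@pytest.fixture(scope="session")
def cond_5_15(population, truth):
    return _run(population, truth, 5, 15, 300)


@pytest.fixture(scope="session")
def cond_15_15(population, truth):
    return _run(population, truth, 15, 15, 300)


@pytest.fixture(scope="session")
def cond_35_15(population, truth):
    return _run(population, truth, 35, 15, 300)


# ---------------------------------------------------------------------------
# reference mixed-model implementation (lme4 via Rscript)

N_REFERENCE_DATASETS = 50
N_REFERENCE_EMPTY = 20

#: generating values with clearly interior variance components, so both
#: optimisers converge away from the zero boundary and are comparable.
REFERENCE_PARAMS = tl.PopulationParams().with_(
    var_l3_intercept=0.05, var_l3_slope=0.0015, var_l2_slope=0.004
)

_R_SCRIPT = r"""
suppressMessages(library(lme4))
suppressMessages(library(jsonlite))
args <- commandArgs(trailingOnly = TRUE)
dir <- args[1]
n_full <- as.integer(args[2])
n_empty <- as.integer(args[3])
out <- list()
vc_map <- function(m) {
  vc <- as.data.frame(VarCorr(m))
  res <- list()
  for (i in seq_len(nrow(vc))) {
    grp <- vc$grp[i]; v1 <- vc$var1[i]
    key <- if (grp == "Residual") "resid"
      else if (startsWith(grp, "stu") && v1 == "(Intercept)") "l2_intercept"
      else if (startsWith(grp, "stu")) "l2_slope"
      else if (startsWith(grp, "cls") && v1 == "(Intercept)") "l3_intercept"
      else "l3_slope"
    res[[key]] <- vc$vcov[i]
  }
  res
}
# default optimizer for basin selection, then a tightly converged BOBYQA
# polish from its optimum (the default stopping tolerances are ~1e-6, too
# loose to compare coefficients at 1e-4 relative)
ctrl0 <- lmerControl(check.conv.grad = .makeCC("ignore", tol = 1e-3))
ctrl_tight <- function() lmerControl(
  optimizer = "bobyqa",
  optCtrl = list(rhobeg = 2e-3, rhoend = 1e-10),
  check.conv.grad = .makeCC("ignore", tol = 1e-3))
fit_tight <- function(form, d) {
  m0 <- lmer(form, data = d, REML = TRUE, control = ctrl0)
  m1 <- update(m0, start = getME(m0, "theta"), control = ctrl_tight())
  if (REMLcrit(m1) <= REMLcrit(m0)) m1 else m0
}
for (i in seq_len(n_full)) {
  d <- read.csv(file.path(dir, sprintf("ds_%03d.csv", i)))
  d$time2 <- d$time^2
  d$cls <- factor(d$class_id)
  d$stu <- interaction(d$class_id, d$student_id)
  m <- fit_tight(motivation ~ time + time2 + influence + gender + classtype +
                   classtype:time + gender:time + influence:classtype +
                   (1 + time || cls) + (1 + time || stu), d)
  entry <- list(
    coef = as.list(fixef(m)),
    se = as.list(sqrt(diag(as.matrix(vcov(m))))),
    vc = vc_map(m),
    remlcrit = REMLcrit(m)
  )
  if (i <= n_empty) {
    me <- fit_tight(motivation ~ 1 + (1 | cls) + (1 | stu), d)
    entry$empty <- list(vc = vc_map(me), remlcrit = REMLcrit(me))
  }
  out[[i]] <- entry
}
writeLines(toJSON(out, auto_unbox = TRUE, digits = 12), file.path(dir, "ref.json"))
"""

_COEF_MAP = {
    "(Intercept)": "intercept",
    "time": "time",
    "time2": "time2",
    "influence": "influence",
    "gender": "gender",
    "classtype": "classtype",
    "time:classtype": "classtype_x_time",
    "classtype:time": "classtype_x_time",
    "time:gender": "gender_x_time",
    "gender:time": "gender_x_time",
    "influence:classtype": "influence_x_classtype",
}


def reference_dataset(i: int):
    structure = tl.PopulationStructure(classes_per_stratum=25, strata_sizes=(8,))
    return tl.generate_population(REFERENCE_PARAMS, structure, seed=1000 + i)


@pytest.fixture(scope="session")
def engine_reference_fits():
    """Our engine's fits of the reference datasets."""
    return [
        tl.fit_lmm(reference_dataset(i)) for i in range(1, N_REFERENCE_DATASETS + 1)
    ]


@pytest.fixture(scope="session")
def lme4_reference(tmp_path_factory):
    """Fits of the reference datasets by lme4, parsed into our naming."""
    workdir = tmp_path_factory.mktemp("lme4")
    for i in range(1, N_REFERENCE_DATASETS + 1):
        reference_dataset(i).to_csv(workdir / f"ds_{i:03d}.csv", index=False)
    script = workdir / "fit.R"
    script.write_text(_R_SCRIPT, encoding="utf-8")
    subprocess.run(
        [
            "Rscript",
            str(script),
            str(workdir),
            str(N_REFERENCE_DATASETS),
            str(N_REFERENCE_EMPTY),
        ],
        check=True,
        capture_output=True,
        text=True,
    )
    raw = json.loads((workdir / "ref.json").read_text(encoding="utf-8"))
    parsed = []
    for entry in raw:
        coef = {_COEF_MAP[k]: v for k, v in entry["coef"].items()}
        se = {_COEF_MAP[k]: v for k, v in entry["se"].items()}
        parsed.append(
            {
                "coef": coef,
                "se": se,
                "vc": entry["vc"],
                "remlcrit": entry["remlcrit"],
                "empty": entry.get("empty"),
            }
        )
    return parsed
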