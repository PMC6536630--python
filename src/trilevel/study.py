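"""Study orchestration: truth derivation, condition runs, aggregation.

The study pipeline regenerates the synthetic population, derives "true"
parameter values by fitting the full and empty models to it, then for each
design condition repeatedly samples classes, imposes missingness, fits the
growth model and aggregates peb, coverage, power and estimate spread.

Reproducibility contract: every random draw descends from the master seed
through ``numpy.random.SeedSequence`` spawn keys, so any condition or
replicate can be recomputed independently and results are identical for
any execution order or subset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import (
    DEFAULT_N2_LEVELS,
    DEFAULT_N3_LEVELS,
    DEFAULT_PATTERN_NAMES,
    PATTERNS,
    Condition,
    MissingnessPattern,
    draw_sample,
    enumerate_conditions,
    impose_missingness,
)
from .lmm import EMPTY_MODEL, FULL_MODEL, FitResult, ModelSpec, fit_lmm, wald_ci
from .metrics import (
    ICCValues,
    PEB_BIAS_THRESHOLD,
    compute_coverage,
    compute_icc,
    compute_peb,
    compute_power,
)
from .params import PopulationParams, PopulationStructure
from .population import generate_population

__all__ = [
    "TrueValues",
    "ConditionSummary",
    "StudyConfig",
    "StudySummary",
    "population_seed",
    "replicate_rng",
    "derive_true_values",
    "run_condition",
    "run_study",
    "summarize_population",
]


# ---------------------------------------------------------------------------
# seed management


def population_seed(master_seed: int, pattern: str) -> np.random.SeedSequence:
    """Seed for the population generated for one missingness pattern."""
    idx = list(PATTERNS).index(pattern)
    return np.random.SeedSequence(master_seed, spawn_key=(0, idx))


def replicate_rng(
    master_seed: int, condition: Condition, replicate: int
) -> np.random.Generator:
    """Independent generator for one replicate of one condition.

    Keyed by the condition's identity (n2, n3, pattern), not its position
    in the grid, so running any subset of conditions in any order gives
    bit-identical per-condition results.
    """
    pattern_idx = list(PATTERNS).index(condition.pattern)
    ss = np.random.SeedSequence(
        master_seed, spawn_key=(1, condition.n2, condition.n3, pattern_idx, replicate)
    )
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# truth derivation


@dataclass(frozen=True)
class TrueValues:
    """Population-fit parameters used as truth for peb and coverage."""

    fixed: dict[str, float]
    varcomps: dict[str, float]
    empty_varcomps: dict[str, float]
    icc: ICCValues

    def to_json(self, path) -> None:
        payload = {
            "fixed": self.fixed,
            "varcomps": self.varcomps,
            "empty_varcomps": self.empty_varcomps,
            "icc": dataclasses.asdict(self.icc),
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "TrueValues":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            fixed=payload["fixed"],
            varcomps=payload["varcomps"],
            empty_varcomps=payload["empty_varcomps"],
            icc=ICCValues(**payload["icc"]),
        )


def derive_true_values(
    population: pd.DataFrame, spec: ModelSpec = FULL_MODEL
) -> TrueValues:
    """Fit the full and empty models to the population.

    The resulting estimates (not the generating parameters) serve as true
    values for all bias/coverage computations.  Non-convergence on the
    population is a hard failure: the study cannot proceed without truth.
    """
    full = fit_lmm(population, spec)
    if not full.converged:
        raise RuntimeError("full model did not converge on the population")
    empty = fit_lmm(population, EMPTY_MODEL)
    if not empty.converged:
        raise RuntimeError("empty model did not converge on the population")
    return TrueValues(
        fixed=dict(full.coefficients),
        varcomps=full.varcomps.as_dict(),
        empty_varcomps=empty.varcomps.as_dict(),
        icc=compute_icc(empty.varcomps),
    )


# ---------------------------------------------------------------------------
# condition execution


@dataclass
class ConditionSummary:
    condition: Condition
    fixed: dict[str, dict[str, float]]
    varcomps: dict[str, dict[str, float]]
    n_replicates_used: int
    n_excluded: int
    n_singular: int
    quality_warning: bool

    def to_dict(self) -> dict:
        return {
            "condition": dataclasses.asdict(self.condition),
            "fixed": self.fixed,
            "varcomps": self.varcomps,
            "n_replicates_used": self.n_replicates_used,
            "n_excluded": self.n_excluded,
            "n_singular": self.n_singular,
            "quality_warning": self.quality_warning,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ConditionSummary":
        return cls(
            condition=Condition(**payload["condition"]),
            fixed=payload["fixed"],
            varcomps=payload["varcomps"],
            n_replicates_used=payload["n_replicates_used"],
            n_excluded=payload["n_excluded"],
            n_singular=payload["n_singular"],
            quality_warning=payload["quality_warning"],
        )


def run_condition(
    population: pd.DataFrame,
    truth: TrueValues,
    condition: Condition,
    master_seed: int,
    spec: ModelSpec = FULL_MODEL,
    alpha: float = 0.05,
    mcar_student_level: bool = False,
    dump_dir=None,
) -> ConditionSummary:
    """Run all replicates of one condition and aggregate the metrics.

    Each replicate draws its classes, deletes rows per the missingness
    pattern, fits the growth model and forms Wald intervals.  Replicates
    whose fit does not converge are excluded from all metrics (their count
    is reported); singular but converged fits are kept.
    """
    pattern = PATTERNS[condition.pattern]
    if mcar_student_level and condition.pattern == "MCAR":
        pattern = dataclasses.replace(pattern, student_level=True)

    terms = list(spec.fixed_terms)
    estimates: dict[str, list[float]] = {t: [] for t in terms}
    intervals: dict[str, list[tuple[float, float]]] = {t: [] for t in terms}
    vc_estimates: dict[str, list[float]] = {k: [] for k in truth.varcomps}
    n_excluded = 0
    n_singular = 0

    for rep in range(condition.replicates):
        rng = replicate_rng(master_seed, condition, rep)
        sample = draw_sample(population, condition, rng)
        sample = impose_missingness(sample, pattern, rng)
        if dump_dir is not None:
            Path(dump_dir).mkdir(parents=True, exist_ok=True)
            sample.to_csv(
                Path(dump_dir) / f"{condition.n2}_{condition.n3}_"
                f"{condition.pattern}_rep{rep}.csv",
                index=False,
            )
        try:
            fit = fit_lmm(sample, spec)
        except np.linalg.LinAlgError:
            n_excluded += 1
            continue
        if not fit.converged:
            n_excluded += 1
            continue
        if fit.singular:
            n_singular += 1
        ci = wald_ci(fit, alpha)
        for t in terms:
            estimates[t].append(fit.coefficients[t])
            intervals[t].append(ci[t])
        vc = fit.varcomps.as_dict()
        for k in vc_estimates:
            if k in vc:
                vc_estimates[k].append(vc[k])

    n_used = condition.replicates - n_excluded
    if n_used == 0:
        raise RuntimeError(f"no replicate converged in condition {condition.label}")

    fixed_summary: dict[str, dict[str, float]] = {}
    for t in terms:
        est = np.asarray(estimates[t])
        true_val = truth.fixed[t]
        cov, in_band = compute_coverage(intervals[t], true_val)
        fixed_summary[t] = {
            "truth": true_val,
            "mean_estimate": float(est.mean()),
            "peb": compute_peb(est, true_val),
            "coverage": cov,
            "coverage_in_band": bool(in_band),
            "power": compute_power(intervals[t]),
            "sd": float(est.std(ddof=1)) if est.size > 1 else 0.0,
        }

    vc_summary: dict[str, dict[str, float]] = {}
    for k, vals in vc_estimates.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        true_val = truth.varcomps[k]
        vc_summary[k] = {
            "truth": true_val,
            "mean_estimate": float(arr.mean()),
            "peb": compute_peb(arr, true_val) if true_val != 0 else float("nan"),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        }

    return ConditionSummary(
        condition=condition,
        fixed=fixed_summary,
        varcomps=vc_summary,
        n_replicates_used=n_used,
        n_excluded=n_excluded,
        n_singular=n_singular,
        quality_warning=n_excluded > 0.20 * condition.replicates,
    )


# ---------------------------------------------------------------------------
# whole-study driver


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study run.

    Defaults reproduce the published design: the 3x3x4 condition grid with
    1000 replicates per condition and per-pattern population regeneration.
    """

    params: PopulationParams = field(default_factory=PopulationParams)
    structure: PopulationStructure = field(default_factory=PopulationStructure)
    n2_levels: tuple[int, ...] = DEFAULT_N2_LEVELS
    n3_levels: tuple[int, ...] = DEFAULT_N3_LEVELS
    patterns: tuple[str, ...] = DEFAULT_PATTERN_NAMES
    replicates: int = 1000
    master_seed: int = 1
    regenerate_per_pattern: bool = True
    mcar_student_level: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.patterns) - set(PATTERNS)
        if unknown:
            raise ValueError(f"unknown patterns: {sorted(unknown)}")

    def conditions(self) -> list[Condition]:
        return enumerate_conditions(
            self.n2_levels, self.n3_levels, self.patterns, self.replicates
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "StudyConfig":
        payload = dict(payload)
        if "params" in payload and isinstance(payload["params"], dict):
            payload["params"] = PopulationParams(**payload["params"])
        if "structure" in payload and isinstance(payload["structure"], dict):
            payload["structure"] = PopulationStructure(**payload["structure"])
        for key in ("n2_levels", "n3_levels", "patterns"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=False),
            encoding="utf-8",
        )

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class StudySummary:
    config: StudyConfig
    population_descriptives: pd.DataFrame
    truths: dict[str, TrueValues]
    conditions: list[ConditionSummary]


def summarize_population(population: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics of a generated population.

    Means and SDs of the time-varying covariate and the response, and the
    composition fractions of the binary covariates (girls among students,
    heterogeneous-ability among classes).
    """
    students = population.drop_duplicates(["class_id", "student_id"])
    classes = population.drop_duplicates("class_id")

    def _sd(x):
        x = np.asarray(x, dtype=float)
        return float(x.std(ddof=1)) if x.size > 1 else float("nan")

    rows = [
        {
            "variable": "influence",
            "mean": float(population["influence"].mean()),
            "sd": _sd(population["influence"]),
            "fraction_pct": float("nan"),
        },
        {
            "variable": "motivation",
            "mean": float(population["motivation"].mean()),
            "sd": _sd(population["motivation"]),
            "fraction_pct": float("nan"),
        },
        {
            "variable": "girls",
            "mean": float("nan"),
            "sd": float("nan"),
            "fraction_pct": 100.0 * float(students["gender"].mean()),
        },
        {
            "variable": "heterogeneous_classes",
            "mean": float("nan"),
            "sd": float("nan"),
            "fraction_pct": 100.0 * float(classes["classtype"].mean()),
        },
    ]
    return pd.DataFrame(rows)


def run_study(config: StudyConfig, out_dir=None, log=print) -> StudySummary:
    """Run the whole condition grid and write summary tables.

    With ``regenerate_per_pattern`` (default) each missingness pattern gets
    its own freshly generated population and truth, as the study design
    prescribes; otherwise one shared population is used for all patterns.
    Per-condition results are cached as JSON under ``out_dir/conditions``
    so an interrupted study resumes where it stopped.
    """
    t0 = time.time()
    out = Path(out_dir) if out_dir is not None else None
    log_lines: list[str] = []

    def _log(msg):
        log_lines.append(str(msg))
        log(msg)

    log = log or (lambda *_: None)
    if out is not None:
        (out / "conditions").mkdir(parents=True, exist_ok=True)

    populations: dict[str, pd.DataFrame] = {}
    truths: dict[str, TrueValues] = {}
    base_patterns = (
        list(config.patterns) if config.regenerate_per_pattern else ["COM"]
    )
    for pat in base_patterns:
        seed = population_seed(config.master_seed, pat)
        _log(f"generating population for pattern {pat} ...")
        populations[pat] = generate_population(config.params, config.structure, seed)
        cache = out / f"truth_{pat}.json" if out is not None else None
        if cache is not None and cache.exists():
            truths[pat] = TrueValues.from_json(cache)
        else:
            _log(f"deriving true values for pattern {pat} ...")
            truths[pat] = derive_true_values(populations[pat])
            if cache is not None:
                truths[pat].to_json(cache)

    def _for(pattern: str) -> str:
        return pattern if config.regenerate_per_pattern else "COM"

    summaries: list[ConditionSummary] = []
    conditions = config.conditions()
    for idx, cond in enumerate(conditions):
        cache = (
            out / "conditions" / f"{cond.n2}_{cond.n3}_{cond.pattern}.json"
            if out is not None
            else None
        )
        if cache is not None and cache.exists():
            summaries.append(
                ConditionSummary.from_dict(
                    json.loads(cache.read_text(encoding="utf-8"))
                )
            )
            continue
        _log(f"[{idx + 1}/{len(conditions)}] condition {cond.label}")
        summary = run_condition(
            populations[_for(cond.pattern)],
            truths[_for(cond.pattern)],
            cond,
            config.master_seed,
            alpha=config.alpha,
            mcar_student_level=config.mcar_student_level,
        )
        summaries.append(summary)
        if cache is not None:
            cache.write_text(
                json.dumps(_jsonable(summary.to_dict()), indent=2),
                encoding="utf-8",
            )

    descriptives = summarize_population(populations[base_patterns[0]])
    result = StudySummary(
        config=config,
        population_descriptives=descriptives,
        truths=truths,
        conditions=summaries,
    )
    if out is not None:
        _write_tables(result, out)
        import numpy, pandas, scipy  # versions recorded for the manifest
        from . import __version__

        manifest = {
            "versions": {
                "trilevel": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
            },
            "config": _jsonable(config.to_dict()),
            "config_hash": config.config_hash(),
            "master_seed": config.master_seed,
            "n_conditions": len(summaries),
            "elapsed_seconds": round(time.time() - t0, 2),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8"
        )
        (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return result


def _write_tables(result: StudySummary, out: Path) -> None:
    result.population_descriptives.to_csv(
        out / "population_descriptives.csv", index=False
    )

    def rows(metric_of):
        for s in result.conditions:
            row = {
                "n2": s.condition.n2,
                "n3": s.condition.n3,
                "pattern": s.condition.pattern,
                "n_replicates_used": s.n_replicates_used,
                "n_excluded": s.n_excluded,
                "n_singular": s.n_singular,
            }
            row.update(metric_of(s))
            yield row

    def fixed_metric(name):
        def _get(s: ConditionSummary):
            return {t: v[name] for t, v in s.fixed.items()}

        return _get

    def fixed_peb_with_flags(s: ConditionSummary):
        row = {}
        for t, v in s.fixed.items():
            row[t] = v["peb"]
            row[f"{t}_biased"] = abs(v["peb"]) > PEB_BIAS_THRESHOLD
        return row

    pd.DataFrame(rows(fixed_peb_with_flags)).to_csv(
        out / "fixed_peb.csv", index=False
    )
    pd.DataFrame(rows(fixed_metric("coverage"))).to_csv(
        out / "coverage.csv", index=False
    )
    pd.DataFrame(rows(fixed_metric("power"))).to_csv(out / "power.csv", index=False)
    pd.DataFrame(rows(fixed_metric("sd"))).to_csv(
        out / "fixed_estimate_sd.csv", index=False
    )

    def vc_metric(s: ConditionSummary):
        out_row = {}
        for k, v in s.varcomps.items():
            out_row[k] = v["peb"]
            out_row[f"{k}_biased"] = (
                abs(v["peb"]) > PEB_BIAS_THRESHOLD
                if np.isfinite(v["peb"])
                else True
            )
        return out_row

    pd.DataFrame(rows(vc_metric)).to_csv(out / "varcomp_peb.csv", index=False)
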