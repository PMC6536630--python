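"""Generating parameters of the synthetic three-level population.

The population emulates a longitudinal school study: students (level 2)
nested in classrooms (level 3), each measured on five occasions (level 1).
The response ("motivation") follows a quadratic growth curve with a
time-varying covariate ("influence", perceived teacher influence), a
student-level covariate (gender) and a classroom-level covariate
(classtype, heterogeneous- vs. homogeneous-ability class), plus random
intercepts and linear-time slopes at both grouping levels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "PopulationParams",
    "PopulationStructure",
    "default_population_params",
    "default_population_structure",
]

DEFAULT_TIME_POINTS: tuple[float, ...] = (0.0, 1.5, 4.0, 7.0, 10.0)


@dataclass(frozen=True)
class PopulationParams:
    """Fixed effects, variance components and covariate distributions.

    Defaults are the published multilevel growth-curve estimates the
    simulation study treats as generating values: coefficients in response
    units (per month for time terms), variances in squared response units.
    """

    intercept: float = 3.2032
    beta_time: float = 0.0547
    beta_time2: float = -0.0039
    beta_influence: float = 0.1493
    beta_gender: float = 0.0072
    beta_classtype: float = 0.2946
    beta_classtype_x_time: float = 0.0092
    beta_gender_x_time: float = 0.0056
    beta_influence_x_classtype: float = -0.1514

    var_resid: float = 0.2622
    var_l2_intercept: float = 0.1950
    var_l2_slope: float = 0.0009
    var_l3_intercept: float = 0.0041
    var_l3_slope: float = 0.0002

    p_girl: float = 0.56
    p_heterogeneous: float = 0.52
    influence_mean: float = 0.42
    influence_sd: float = 0.36
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS

    def __post_init__(self) -> None:
        for name in (
            "var_resid",
            "var_l2_intercept",
            "var_l2_slope",
            "var_l3_intercept",
            "var_l3_slope",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("p_girl", "p_heterogeneous"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.influence_sd <= 0:
            raise ValueError("influence_sd must be strictly positive")
        tp = tuple(float(t) for t in self.time_points)
        if len(tp) < 1 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points must be strictly increasing")
        object.__setattr__(self, "time_points", tp)

    @property
    def fixed_effects(self) -> dict[str, float]:
        """Generating fixed effects keyed by model term name."""
        return {
            "intercept": self.intercept,
            "time": self.beta_time,
            "time2": self.beta_time2,
            "influence": self.beta_influence,
            "gender": self.beta_gender,
            "classtype": self.beta_classtype,
            "classtype_x_time": self.beta_classtype_x_time,
            "gender_x_time": self.beta_gender_x_time,
            "influence_x_classtype": self.beta_influence_x_classtype,
        }

    @property
    def variance_components(self) -> dict[str, float]:
        return {
            "resid": self.var_resid,
            "l2_intercept": self.var_l2_intercept,
            "l2_slope": self.var_l2_slope,
            "l3_intercept": self.var_l3_intercept,
            "l3_slope": self.var_l3_slope,
        }

    def with_(self, **changes) -> "PopulationParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class PopulationStructure:
    """How many classrooms of each size the population contains.

    The population is stratified by class size: ``classes_per_stratum``
    classrooms for each entry of ``strata_sizes`` (students per class).
    Defaults give 3000 classrooms and 55000 students.
    """

    classes_per_stratum: int = 1000
    strata_sizes: tuple[int, ...] = (5, 15, 35)

    def __post_init__(self) -> None:
        if self.classes_per_stratum < 1:
            raise ValueError("classes_per_stratum must be a positive integer")
        sizes = tuple(int(s) for s in self.strata_sizes)
        if len(sizes) != len(set(sizes)) or any(s < 1 for s in sizes):
            raise ValueError("strata_sizes must be distinct positive integers")
        object.__setattr__(self, "strata_sizes", sizes)

    @property
    def n_classes(self) -> int:
        return self.classes_per_stratum * len(self.strata_sizes)

    @property
    def n_students(self) -> int:
        return self.classes_per_stratum * sum(self.strata_sizes)


def default_population_params() -> PopulationParams:
    return PopulationParams()


def default_population_structure() -> PopulationStructure:
    return PopulationStructure()
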