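"""Synthetic population generation for the three-level growth model.

Each classroom draws a class type and level-3 random intercept/slope; each
student draws a gender and level-2 random intercept/slope; each occasion
draws the time-varying covariate and a residual.  The response is the fixed
linear predictor plus (class + student) intercept deviations, (class +
student) slope deviations times months since baseline, and the residual.
Random intercepts and slopes are generated uncorrelated at both levels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import PopulationParams, PopulationStructure

__all__ = [
    "LONG_COLUMNS",
    "generate_population",
    "linear_predictor",
    "read_long_csv",
    "write_long_csv",
]

#: Canonical column order of a long-format dataset.
LONG_COLUMNS = [
    "class_id",
    "stratum",
    "student_id",
    "occasion_index",
    "time",
    "influence",
    "gender",
    "classtype",
    "motivation",
]


def linear_predictor(
    params: PopulationParams,
    time,
    influence,
    gender,
    classtype,
):
    """Fixed part of the growth model (no random effects, no residual).

    Accepts scalars or broadcastable arrays; returns response units.
    """
    t = np.asarray(time, dtype=float)
    infl = np.asarray(influence, dtype=float)
    g = np.asarray(gender, dtype=float)
    c = np.asarray(classtype, dtype=float)
    out = (
        params.intercept
        + params.beta_time * t
        + params.beta_time2 * t * t
        + params.beta_influence * infl
        + params.beta_gender * g
        + params.beta_classtype * c
        + params.beta_classtype_x_time * c * t
        + params.beta_gender_x_time * g * t
        + params.beta_influence_x_classtype * infl * c
    )
    return out if out.ndim else float(out)


def generate_population(
    params: PopulationParams | None = None,
    structure: PopulationStructure | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate a complete long-format population dataset.

    Parameters
    ----------
    params
        Generating fixed effects, variance components and covariate
        distributions; defaults to the published study values.
    structure
        Classrooms per stratum and students per class for each stratum.
    seed
        Any integer, ``SeedSequence`` or ``Generator``; the output is
        bit-reproducible given the same seed.

    Returns
    -------
    pandas.DataFrame
        One row per (class, student, occasion) with columns
        ``LONG_COLUMNS``.  ``class_id`` and ``student_id`` are consecutive
        integers assigned in generation order.
    """
    params = params or PopulationParams()
    structure = structure or PopulationStructure()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    times = np.asarray(params.time_points, dtype=float)
    n_occ = times.size
    frames = []
    class_offset = 0
    for size in structure.strata_sizes:
        m = structure.classes_per_stratum  # classes in this stratum
        n_stu = m * size
        n_rows = n_stu * n_occ

        classtype = (rng.random(m) < params.p_heterogeneous).astype(np.int8)
        v0 = rng.normal(0.0, np.sqrt(params.var_l3_intercept), m)
        v1 = rng.normal(0.0, np.sqrt(params.var_l3_slope), m)

        gender = (rng.random(n_stu) < params.p_girl).astype(np.int8)
        u0 = rng.normal(0.0, np.sqrt(params.var_l2_intercept), n_stu)
        u1 = rng.normal(0.0, np.sqrt(params.var_l2_slope), n_stu)

        influence = rng.normal(params.influence_mean, params.influence_sd, n_rows)
        resid = rng.normal(0.0, np.sqrt(params.var_resid), n_rows)

        stu_class = np.repeat(np.arange(m), size)  # class index per student
        row_stu = np.repeat(np.arange(n_stu), n_occ)  # student index per row
        row_class = stu_class[row_stu]
        row_time = np.tile(times, n_stu)

        fixed = linear_predictor(
            params,
            row_time,
            influence,
            gender[row_stu],
            classtype[row_class],
        )
        motivation = (
            fixed
            + v0[row_class]
            + u0[row_stu]
            + (v1[row_class] + u1[row_stu]) * row_time
            + resid
        )

        frames.append(
            pd.DataFrame(
                {
                    "class_id": class_offset + row_class,
                    "stratum": np.int64(size),
                    "student_id": row_stu % size,  # index within class
                    "occasion_index": np.tile(
                        np.arange(n_occ, dtype=np.int64), n_stu
                    ),
                    "time": row_time,
                    "influence": influence,
                    "gender": gender[row_stu].astype(np.int64),
                    "classtype": classtype[row_class].astype(np.int64),
                    "motivation": motivation,
                }
            )
        )
        class_offset += m

    out = pd.concat(frames, ignore_index=True)
    out["class_id"] = out["class_id"].astype(np.int64)
    out["student_id"] = out["student_id"].astype(np.int64)
    return out


def write_long_csv(dataset: pd.DataFrame, path) -> None:
    """Write a long-format dataset as UTF-8 CSV with a header row."""
    dataset.loc[:, LONG_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_long_csv(path) -> pd.DataFrame:
    """Read a long-format dataset written by :func:`write_long_csv`."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long-format CSV missing columns: {missing}")
    return df[LONG_COLUMNS]
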