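"""Synthetic covariate tables emulating the motivating trial structure.

The motivating study is a three-arm parallel nutrition trial in 162 healthy
volunteers with covariates gender (104 F / 58 M), age, BMI, an initial
composite health score, and a 17-level "first-visit group" factor (subjects
whose intake visit fell on the same day).  No subject-level data are
deposited, so the generator reproduces the published marginal structure:
exact gender and group counts, and continuous covariates drawn from normal
distributions at the published pooled means/SDs (age and BMI truncated to
physiologically plausible ranges, which perturbs the moments negligibly).

``generate_toy`` produces tiny instances whose allocation spaces are small
enough to enumerate, for oracle testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignSpec, SubjectTable, ValidationError

__all__ = ["ReplicaParams", "generate_trial_replica", "generate_toy", "TRIAL_GROUP_SIZES"]

#: first-visit group sizes of the motivating trial (17 groups, total 162)
TRIAL_GROUP_SIZES: tuple[int, ...] = (10, 10, 11, 7, 11, 10, 7, 11, 8, 9, 9, 11, 10, 10, 12, 6, 10)


@dataclass(frozen=True)
class ReplicaParams:
    """Parameters of the trial-replica generator.

    Defaults reproduce the motivating trial: 162 subjects, 104 female and
    58 male, 17 first-visit groups, age in years ~ N(42.6, 12.3^2) truncated
    to [18, 70], BMI in kg/m^2 ~ N(25.3, 3.6^2) truncated to [18, 40], and a
    dimensionless composite health score ~ N(1.476, 0.13^2).  An optional
    correlation matrix over (age, bmi, score) supports sensitivity studies;
    by default the three are independent.
    """

    n_subjects: int = 162
    n_female: int = 104
    n_male: int = 58
    group_sizes: tuple[int, ...] = TRIAL_GROUP_SIZES
    age_mean: float = 42.6
    age_sd: float = 12.3
    age_range: tuple[float, float] = (18.0, 70.0)
    bmi_mean: float = 25.3
    bmi_sd: float = 3.6
    bmi_range: tuple[float, float] = (18.0, 40.0)
    score_mean: float = 1.476
    score_sd: float = 0.13
    correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_sizes", tuple(int(g) for g in self.group_sizes))
        if self.n_female + self.n_male != self.n_subjects:
            raise ValidationError(
                f"n_female + n_male = {self.n_female + self.n_male} "
                f"!= n_subjects = {self.n_subjects}"
            )
        if sum(self.group_sizes) != self.n_subjects:
            raise ValidationError(
                f"group sizes sum to {sum(self.group_sizes)} != {self.n_subjects}"
            )
        if any(g < 1 for g in self.group_sizes):
            raise ValidationError("every group size must be >= 1")
        for sd in (self.age_sd, self.bmi_sd, self.score_sd):
            if sd <= 0:
                raise ValidationError("standard deviations must be > 0")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (3, 3) or not np.allclose(C, C.T):
                raise ValidationError("correlation must be a symmetric 3x3 matrix")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_trial_replica(params: ReplicaParams | None = None) -> SubjectTable:
    """Generate a subject table with the motivating trial's structure.

    Gender counts and first-visit group sizes are exact in every replica
    (they are design facts, not random); gender is randomly interleaved
    across groups.  Continuous covariates are random draws, so only their
    population moments match the published values.  Deterministic given
    ``params.seed``.
    """
    p = params if params is not None else ReplicaParams()
    rng = np.random.default_rng(p.seed)
    n = p.n_subjects

    gender = np.array(["F"] * p.n_female + ["M"] * p.n_male)
    rng.shuffle(gender)
    groups = np.repeat(
        [str(g + 1) for g in range(len(p.group_sizes))], p.group_sizes
    )

    if p.correlation is None:
        age = _truncated_normal(rng, p.age_mean, p.age_sd, *p.age_range, size=n)
        bmi = _truncated_normal(rng, p.bmi_mean, p.bmi_sd, *p.bmi_range, size=n)
        score = rng.normal(p.score_mean, p.score_sd, size=n)
    else:
        # correlated draws via a Gaussian copula, then marginal truncation
        L = np.linalg.cholesky(np.asarray(p.correlation, dtype=float))
        z = rng.standard_normal((n, 3)) @ L.T
        u = stats.norm.cdf(z)
        a_age = tuple((x - p.age_mean) / p.age_sd for x in p.age_range)
        a_bmi = tuple((x - p.bmi_mean) / p.bmi_sd for x in p.bmi_range)
        age = stats.truncnorm.ppf(u[:, 0], *a_age, loc=p.age_mean, scale=p.age_sd)
        bmi = stats.truncnorm.ppf(u[:, 1], *a_bmi, loc=p.bmi_mean, scale=p.bmi_sd)
        score = stats.norm.ppf(u[:, 2], loc=p.score_mean, scale=p.score_sd)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{idx + 1:03d}" for idx in range(n)],
            "gender": gender,
            "visit_group": groups,
            "age": np.round(age, 2),
            "bmi": np.round(bmi, 2),
            "score": np.round(score, 4),
        }
    )
    return SubjectTable(
        data=df,
        categorical=("gender", "visit_group"),
        continuous=("age", "bmi", "score"),
    )


def generate_toy(
    seed: int,
    N: int,
    t: int,
    n_continuous: int = 1,
    n_categorical_levels: tuple[int, ...] = (),
) -> tuple[SubjectTable, DesignSpec]:
    """Small random instance for oracle-scale testing.

    Continuous columns are standard normal; categorical levels are assigned
    round-robin then shuffled; arm sizes are as equal as possible (differing
    by at most 1).  Deterministic given ``seed``.
    """
    if t > N:
        raise ValidationError(f"cannot split N={N} subjects into t={t} arms")
    if t < 2 or N < 2:
        raise ValidationError("need t >= 2 and N >= 2")
    rng = np.random.default_rng(seed)
    data: dict[str, object] = {"subject_id": [f"s{idx}" for idx in range(N)]}
    continuous = tuple(f"x{j + 1}" for j in range(n_continuous))
    for name in continuous:
        data[name] = rng.standard_normal(N)
    categorical = tuple(f"c{j + 1}" for j in range(len(n_categorical_levels)))
    for name, n_levels in zip(categorical, n_categorical_levels):
        labels = np.array([str(i % n_levels + 1) for i in range(N)])
        rng.shuffle(labels)
        data[name] = labels
    table = SubjectTable(
        data=pd.DataFrame(data), categorical=categorical, continuous=continuous
    )
    base, extra = divmod(N, t)
    sizes = tuple(base + (1 if k < extra else 0) for k in range(t))
    return table, DesignSpec(arm_sizes=sizes)
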