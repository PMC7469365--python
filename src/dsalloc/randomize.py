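"""Randomization baselines and Monte-Carlo D_s-efficiency distributions.

Two reference allocation schemes are provided for comparison with the
optimizer: *complete* randomization (a uniform draw over all allocations
with the prescribed arm sizes) and *stratified* randomization (independent
uniform draws within each stratum, achieving prescribed stratum-by-arm
counts exactly).  ``monte_carlo`` draws many such allocations against a
fixed covariate matrix and summarizes the distribution of D_s-efficiencies
by its empirical middle-95% interval and extremes.

"Completely random" here means uniform over allocations with the *fixed*
arm sizes (e.g. 54/54/54), not per-subject coin flips: the efficiency
normalization presupposes fixed T'T, which only holds at fixed arm counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import (
    Allocation,
    CovariateMatrix,
    DesignSpec,
    ValidationError,
    helmert_contrasts,
)
from .optimize import initial_allocation

__all__ = [
    "MonteCarloSummary",
    "complete_randomization",
    "stratified_randomization",
    "even_stratum_arm_counts",
    "monte_carlo",
]


@dataclass(frozen=True)
class MonteCarloSummary:
    """Distribution of D_s-efficiencies over random allocations."""

    n_draws: int
    efficiencies: np.ndarray
    interval_95: tuple[float, float]
    maximum: float
    minimum: float
    method_label: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """One-column frame (header ``ds_efficiency``) for CSV export."""
        return pd.DataFrame({"ds_efficiency": self.efficiencies})


def complete_randomization(spec: DesignSpec, seed: int | np.random.Generator) -> Allocation:
    """Uniform draw over allocations with the prescribed arm sizes.

    Identical contract to the optimizer's ``initial_allocation``; exposed
    separately so reports can name the baseline unambiguously.
    """
    return initial_allocation(spec, seed)


def even_stratum_arm_counts(
    stratum_sizes: dict[str, int] | pd.Series,
    spec: DesignSpec,
) -> pd.DataFrame:
    """Prescribe per-stratum arm counts as even as possible within each
    stratum, with column totals equal to the arm sizes.

    Each stratum of size m gives floor(m/t) subjects to every arm; the
    leftover units go, stratum by stratum, to the arms with the largest
    remaining deficit (ties to the earlier arm label).  Deterministic.
    """
    sizes = pd.Series(stratum_sizes).astype(int)
    if int(sizes.sum()) != spec.n_subjects:
        raise ValidationError(
            f"stratum sizes sum to {int(sizes.sum())} but spec has "
            f"{spec.n_subjects} subjects"
        )
    t = spec.n_arms
    counts = pd.DataFrame(0, index=sizes.index, columns=list(spec.arm_labels), dtype=int)
    assigned = np.zeros(t, dtype=int)
    for level, m in sizes.items():
        base = m // t
        counts.loc[level] = base
        assigned += base
        deficit = np.asarray(spec.arm_sizes) - assigned
        for _ in range(m % t):
            k = int(np.argmax(deficit))
            counts.loc[level, spec.arm_labels[k]] += 1
            deficit[k] -= 1
            assigned[k] += 1
    if not np.array_equal(counts.to_numpy().sum(axis=0), np.asarray(spec.arm_sizes)):
        raise ValidationError(
            "cannot achieve the arm sizes with per-stratum counts this even; "
            "check stratum sizes against arm sizes"
        )
    return counts


def stratified_randomization(
    spec: DesignSpec,
    strata: Sequence[str] | np.ndarray | pd.Series,
    seed: int | np.random.Generator,
) -> Allocation:
    """Random allocation achieving the prescribed stratum-by-arm counts.

    Within each stratum the prescribed multiset of arm labels is uniformly
    shuffled; strata are drawn independently.  Requires
    ``spec.stratum_arm_counts``.
    """
    if spec.stratum_arm_counts is None:
        raise ValidationError("spec.stratum_arm_counts is required for stratified randomization")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = pd.Series(list(strata)).astype(str)
    if len(labels) != spec.n_subjects:
        raise ValidationError("strata length must equal the number of subjects")
    counts = spec.stratum_arm_counts
    observed = set(labels.unique())
    prescribed = set(str(x) for x in counts.index)
    if observed != prescribed:
        missing = sorted(observed ^ prescribed)
        raise ValidationError(
            f"stratum levels in data and stratum_arm_counts differ: {missing}"
        )
    arm_of = np.empty(len(labels), dtype=np.int64)
    counts = counts.copy()
    counts.index = counts.index.astype(str)
    for level in sorted(observed):
        members = np.flatnonzero((labels == level).to_numpy())
        row = counts.loc[level].to_numpy()
        if int(row.sum()) != members.size:
            raise ValidationError(
                f"stratum {level!r} has {members.size} subjects but "
                f"stratum_arm_counts prescribes {int(row.sum())}"
            )
        arms = np.repeat(np.arange(spec.n_arms), row)
        arm_of[members] = rng.permutation(arms)
    alloc = Allocation(arm_of)
    alloc.check(spec)
    return alloc


def _efficiencies_for_draws(
    X: CovariateMatrix, spec: DesignSpec, draws: np.ndarray
) -> np.ndarray:
    """D_s-efficiency for a batch of allocations (draws: n x N arm indices)."""
    t = spec.n_arms
    n = spec.n_subjects
    H = np.sqrt(t) * helmert_contrasts(t)          # t x (t-1)
    # T'T depends only on arm counts, identical across draws (H already
    # carries the sqrt(t) scale, so no extra factor of t here)
    counts = np.asarray(spec.arm_sizes, dtype=float)
    TtT = (H.T * counts) @ H                        # (t-1) x (t-1)
    B = X.basis
    effs = np.empty(draws.shape[0])
    chunk = 512
    for start in range(0, draws.shape[0], chunk):
        block = draws[start : start + chunk]
        T = H[block]                                # m x N x (t-1)
        P = np.einsum("nr,mnk->mrk", B, T)          # m x r x (t-1)
        G = TtT[None] - np.einsum("mrk,mrl->mkl", P, P)
        det = np.linalg.det(G)
        det = np.clip(det, 0.0, None)
        effs[start : start + block.shape[0]] = det ** (1.0 / (t - 1)) / n
    return effs


def monte_carlo(
    X: CovariateMatrix,
    spec: DesignSpec,
    method: str = "complete",
    strata: Sequence[str] | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
) -> MonteCarloSummary:
    """Monte-Carlo distribution of D_s-efficiencies over random allocations.

    Draws ``n_draws`` independent allocations by the chosen method, computes
    each allocation's D_s-efficiency against the fixed covariate matrix, and
    summarizes by the empirical 2.5th/97.5th percentiles (linear
    interpolation between order statistics) and the extremes.  Deterministic
    given ``seed``.
    """
    if n_draws < 100:
        raise ValidationError("n_draws must be >= 100")
    if method not in ("complete", "stratified"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "stratified" and strata is None:
        raise ValidationError("stratified method requires per-subject strata")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_draws, spec.n_subjects), dtype=np.int64)
    for m in range(n_draws):
        if method == "complete":
            draws[m] = complete_randomization(spec, rng).arm_of
        else:
            draws[m] = stratified_randomization(spec, strata, rng).arm_of
    effs = _efficiencies_for_draws(X, spec, draws)
    lo, hi = np.percentile(effs, [2.5, 97.5])
    return MonteCarloSummary(
        n_draws=n_draws,
        efficiencies=effs,
        interval_95=(float(lo), float(hi)),
        maximum=float(effs.max()),
        minimum=float(effs.min()),
        method_label=method,
        seed=seed if isinstance(seed, int) else -1,
    )
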