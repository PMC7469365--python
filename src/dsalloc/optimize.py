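"""Exchange algorithm maximizing the D_s criterion over fixed-size arms.

Because the arm sizes are fixed, T'T is constant and the search only moves
probability mass between arms by *pairwise swaps* of subjects — the natural
exchange neighborhood that preserves arm counts by construction.  Each
restart starts from a uniformly random size-respecting allocation, then
performs steepest-ascent passes: every cross-arm pair is scored and the best
improving swap (relative improvement > 1e-10) is applied, until a pass
improves nothing.  The best local optimum over restarts is returned.

Swap deltas are evaluated without refitting: swapping subjects i and j
changes T by the rank-one update (e_i - e_j) d' with d = h_j - h_i the
difference of their scaled Helmert rows, which leaves T'T unchanged and
perturbs the residual Gram G = T'T - P'P (P = B'T) by a rank-two symmetric
term.  The matrix determinant lemma then gives the determinant ratio

    det(G') / det(G) = 1 - 2*beta - c*alpha + beta^2 - alpha*gamma,

with alpha = d'G^-1 d, beta = d'G^-1 v, gamma = v'G^-1 v, v = P'(b_i - b_j),
c = ||b_i - b_j||^2 (b_i = row i of the covariate basis B).  All cross-arm
pairs are scored vectorized per arm pair, so a pass costs O(N^2) small
array operations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .design import (
    Allocation,
    ContrastMatrix,
    CovariateMatrix,
    DesignSpec,
    DsEvaluation,
    ValidationError,
    contrast_gram,
    ds_criterion,
    ds_efficiency,
    helmert_contrasts,
    treatment_contrasts,
)

__all__ = [
    "OptimizerState",
    "OptimizerResult",
    "initial_allocation",
    "swap_delta",
    "exchange_optimize",
    "brute_force_optimize",
]

logger = logging.getLogger(__name__)

#: relative improvement below this is floating-point noise, not progress
_IMPROVE_TOL = 1e-10
#: hard cap on steepest-ascent passes per restart (never reached in practice)
_MAX_PASSES = 10_000
#: brute-force enumeration guard
_BRUTE_FORCE_LIMIT = 200_000


@dataclass
class OptimizerState:
    """Bookkeeping for one local search: allocation plus derived matrices.

    ``projected_contrasts`` is P = B'T (r x (t-1)); ``gram`` is the residual
    matrix G = T'T - P'P whose determinant is the D_s criterion value.
    """

    allocation: Allocation
    spec: DesignSpec
    X: CovariateMatrix
    projected_contrasts: np.ndarray
    gram: np.ndarray
    current_ds: float

    @classmethod
    def from_allocation(
        cls, allocation: Allocation, spec: DesignSpec, X: CovariateMatrix
    ) -> "OptimizerState":
        T = treatment_contrasts(allocation, spec)
        P = X.basis.T @ T.matrix
        G = T.matrix.T @ T.matrix - P.T @ P
        ev = ds_criterion(X, T)
        return cls(
            allocation=allocation,
            spec=spec,
            X=X,
            projected_contrasts=P,
            gram=G,
            current_ds=ev.ds_value,
        )


@dataclass(frozen=True)
class OptimizerResult:
    best_allocation: Allocation
    evaluation: DsEvaluation
    n_restarts_run: int
    n_swaps_accepted: int
    seed: int | None


def initial_allocation(spec: DesignSpec, seed: int | np.random.Generator) -> Allocation:
    """Uniformly random allocation with the prescribed arm sizes.

    A random shuffle of the fixed multiset of arm indices; deterministic
    given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arms = np.repeat(np.arange(spec.n_arms), spec.arm_sizes)
    return Allocation(arm_of=rng.permutation(arms))


def swap_delta(state: OptimizerState, i: int, j: int) -> float:
    """Change in ds_value from swapping subjects ``i`` and ``j``.

    Uses the rank-two update of the residual Gram (see module docstring);
    does not mutate ``state``.
    """
    a = state.allocation.arm_of
    if a[i] == a[j]:
        raise ValidationError(f"subjects {i} and {j} are in the same arm")
    t = state.spec.n_arms
    H = np.sqrt(t) * helmert_contrasts(t)
    d = H[a[j]] - H[a[i]]
    B = state.X.basis
    u = B[i] - B[j]
    v = state.projected_contrasts.T @ u
    c = float(u @ u)
    G = state.gram
    det_g = state.current_ds
    if det_g == 0.0:
        # degenerate current point: fall back to direct evaluation
        return _ds_after_swap(state, i, j) - det_g
    Gi = np.linalg.inv(G)
    gid = Gi @ d
    alpha = float(d @ gid)
    beta = float(gid @ v)
    gamma = float(v @ Gi @ v)
    ratio = 1.0 - 2.0 * beta - c * alpha + beta * beta - alpha * gamma
    return det_g * (ratio - 1.0)


def _ds_after_swap(state: OptimizerState, i: int, j: int) -> float:
    a = state.allocation.arm_of.copy()
    a[i], a[j] = a[j], a[i]
    T = treatment_contrasts(Allocation(a), state.spec)
    return ds_criterion(state.X, T).ds_value


def _pass_best_swap(
    state: OptimizerState,
    BBt_diag: np.ndarray,
    BBt: np.ndarray,
    arm_members: list[np.ndarray],
) -> tuple[float, int, int]:
    """Score every cross-arm pair; return (best delta, i, j) with ties broken
    toward the lexicographically smallest (i, j)."""
    t = state.spec.n_arms
    H = np.sqrt(t) * helmert_contrasts(t)
    G = state.gram
    det_g = state.current_ds
    Gi = np.linalg.inv(G)
    B = state.X.basis
    P = state.projected_contrasts
    Q = B @ P                      # N x (t-1), row i = P' b_i
    R = Q @ Gi                     # N x (t-1)
    s_diag = np.einsum("ij,ij->i", Q, R)

    best = (-np.inf, -1, -1)
    for arm_a, arm_b in itertools.combinations(range(t), 2):
        ia = arm_members[arm_a]
        jb = arm_members[arm_b]
        d = H[arm_b] - H[arm_a]
        gid = Gi @ d
        alpha = float(d @ gid)
        # beta_ij = gid . (q_i - q_j)
        beta = (Q[ia] @ gid)[:, None] - (Q[jb] @ gid)[None, :]
        # gamma_ij = (q_i - q_j) . Gi (q_i - q_j)
        cross = Q[ia] @ R[jb].T
        gamma = s_diag[ia][:, None] + s_diag[jb][None, :] - cross - (R[ia] @ Q[jb].T)
        # c_ij = |b_i - b_j|^2
        c = BBt_diag[ia][:, None] + BBt_diag[jb][None, :] - 2.0 * BBt[np.ix_(ia, jb)]
        ratio = 1.0 - 2.0 * beta - c * alpha + beta * beta - alpha * gamma
        delta = det_g * (ratio - 1.0)
        k = int(np.argmax(delta))
        r, cidx = divmod(k, delta.shape[1])
        cand = (float(delta[r, cidx]), int(ia[r]), int(jb[cidx]))
        # ties toward lexicographically smallest (i, j); argmax already
        # returns the first (smallest flat index) maximum within an arm pair,
        # and members are sorted, so only compare across arm pairs
        if cand[0] > best[0] + 0.0 or (
            cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2])
        ):
            best = cand
    return best


def _apply_swap(state: OptimizerState, i: int, j: int) -> None:
    """Swap i and j and recompute the derived matrices exactly."""
    a = state.allocation.arm_of.copy()
    a[i], a[j] = a[j], a[i]
    alloc = Allocation(a)
    T = treatment_contrasts(alloc, state.spec)
    P = state.X.basis.T @ T.matrix
    state.allocation = alloc
    state.projected_contrasts = P
    state.gram = T.matrix.T @ T.matrix - P.T @ P
    state.current_ds = ds_criterion(state.X, T).ds_value


def _local_search(
    state: OptimizerState,
    BBt_diag: np.ndarray,
    BBt: np.ndarray,
) -> int:
    """Steepest-ascent passes until no improving swap remains; returns the
    number of accepted swaps."""
    accepted = 0
    for _ in range(_MAX_PASSES):
        a = state.allocation.arm_of
        arm_members = [np.flatnonzero(a == k) for k in range(state.spec.n_arms)]
        delta, i, j = _pass_best_swap(state, BBt_diag, BBt, arm_members)
        scale = max(state.current_ds, 1.0)
        if delta <= _IMPROVE_TOL * scale:
            break
        _apply_swap(state, i, j)
        accepted += 1
    return accepted


def exchange_optimize(
    X: CovariateMatrix,
    spec: DesignSpec,
    n_restarts: int = 50,
    seed: int | None = 0,
) -> OptimizerResult:
    """Maximize the D_s criterion over allocations with fixed arm sizes.

    Runs ``n_restarts`` independent steepest-ascent exchange searches from
    random starting allocations and returns the best local optimum.
    Deterministic given ``seed``: one master seed spawns per-restart seeds by
    a fixed counter scheme.
    """
    if X.n_subjects != spec.n_subjects:
        raise ValidationError(
            f"X has {X.n_subjects} rows but spec allocates {spec.n_subjects}"
        )
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    B = X.basis
    BBt = B @ B.T
    BBt_diag = np.einsum("ij,ij->i", B, B)

    best_state: OptimizerState | None = None
    total_accepted = 0
    for r in range(n_restarts):
        restart_rng = np.random.default_rng(np.random.SeedSequence([seed or 0, r]))
        alloc = initial_allocation(spec, restart_rng)
        state = OptimizerState.from_allocation(alloc, spec, X)
        total_accepted += _local_search(state, BBt_diag, BBt)
        if best_state is None or state.current_ds > best_state.current_ds:
            best_state = state
        logger.info(
            "restart %d/%d: ds=%.6g best_eff=%.5f",
            r + 1,
            n_restarts,
            state.current_ds,
            ds_efficiency(best_state.current_ds, spec.n_subjects, spec.n_arms),
        )
    assert best_state is not None
    T = treatment_contrasts(best_state.allocation, spec)
    return OptimizerResult(
        best_allocation=best_state.allocation,
        evaluation=ds_criterion(X, T),
        n_restarts_run=n_restarts,
        n_swaps_accepted=total_accepted,
        seed=seed,
    )


def _count_assignments(arm_sizes: tuple[int, ...]) -> int:
    n = sum(arm_sizes)
    count = 1
    rem = n
    for k in arm_sizes:
        count *= math.comb(rem, k)
        rem -= k
    return count


def brute_force_optimize(X: CovariateMatrix, spec: DesignSpec) -> OptimizerResult:
    """Exact D_s maximizer by enumeration of every size-respecting assignment.

    Arms are distinguishable; ties return the first maximizer in
    lexicographic order of the assignment vector.  Guarded to at most
    200,000 assignments.
    """
    if X.n_subjects != spec.n_subjects:
        raise ValidationError("X row count does not match spec")
    count = _count_assignments(spec.arm_sizes)
    if count > _BRUTE_FORCE_LIMIT:
        raise ValidationError(
            f"{count} assignments exceed the brute-force guard of {_BRUTE_FORCE_LIMIT}"
        )
    n = spec.n_subjects
    t = spec.n_arms
    best_ds = -np.inf
    best_a: np.ndarray | None = None

    def assign(remaining: list[int], arm: int, a: np.ndarray):
        nonlocal best_ds, best_a
        if arm == t - 1:
            a = a.copy()
            a[remaining] = arm
            T = treatment_contrasts(Allocation(a), spec)
            ds = ds_criterion(X, T).ds_value
            if ds > best_ds:
                best_ds = ds
                best_a = a
            return
        for chosen in itertools.combinations(remaining, spec.arm_sizes[arm]):
            a2 = a.copy()
            a2[list(chosen)] = arm
            rest = [x for x in remaining if x not in set(chosen)]
            assign(rest, arm + 1, a2)

    assign(list(range(n)), 0, np.full(n, -1, dtype=np.int64))
    assert best_a is not None
    alloc = Allocation(best_a)
    T = treatment_contrasts(alloc, spec)
    return OptimizerResult(
        best_allocation=alloc,
        evaluation=ds_criterion(X, T),
        n_restarts_run=0,
        n_swaps_accepted=0,
        seed=None,
    )
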