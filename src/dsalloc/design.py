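"""Design-matrix encoding, treatment contrasts and the D_s criterion.

The allocation problem is posed on the linear model

    y = X beta + T gamma + eps,

where ``X`` (N x p) collects an intercept plus the subject covariates and
``T`` (N x (t-1)) holds normalized treatment contrasts encoding the
differences between the ``t`` study arms.  At allocation time no outcomes
exist; the only quantity under the experimenter's control is the row
permutation of ``T``, i.e. which subject goes to which arm.  The precision of
the covariate-adjusted arm-effect estimators is maximized by maximizing the
D_s criterion

    Ds = | T' (I - X (X'X)^-1 X') T |,

the determinant of the residual SSP matrix of the contrasts after projecting
out the covariate column space.  We compute the projection through an
orthonormal basis of col(X) so the criterion is well defined even when X is
rank deficient (as it is under full-dummy coding, where each indicator set
sums to the intercept).  The scale-free D_s-efficiency is

    eff = Ds^(1/(t-1)) / N,

equal to 1 when the contrasts are orthogonal to the covariates and 0 when a
contrast is completely aliased with them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "SubjectTable",
    "DesignSpec",
    "CovariateMatrix",
    "Allocation",
    "ContrastMatrix",
    "DsEvaluation",
    "encode_covariates",
    "helmert_contrasts",
    "treatment_contrasts",
    "contrast_gram",
    "ds_criterion",
    "ds_efficiency",
    "ds_via_ratio",
]

#: values within this distance below zero are treated as rounded-off zeros
_DET_CLAMP = 1e-10


class ValidationError(ValueError):
    """Raised when input data violate a declared contract."""


@dataclass(frozen=True)
class SubjectTable:
    """Immutable per-subject covariate table.

    Parameters
    ----------
    data
        One row per subject, in enrollment order (row order defines the
        subject index).  Must contain a ``subject_id`` column plus every
        declared covariate column.
    categorical
        Names of categorical covariate columns (level labels compared as
        exact strings).
    continuous
        Names of continuous covariate columns (finite reals).
    """

    data: pd.DataFrame
    categorical: tuple[str, ...] = ()
    continuous: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "categorical", tuple(self.categorical))
        object.__setattr__(self, "continuous", tuple(self.continuous))
        df = self.data
        if "subject_id" not in df.columns:
            raise ValidationError("table must contain a 'subject_id' column")
        if len(df) < 2:
            raise ValidationError(f"need at least 2 subjects, got {len(df)}")
        if df["subject_id"].duplicated().any():
            dup = df["subject_id"][df["subject_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate subject_id {dup!r}")
        for col in (*self.categorical, *self.continuous):
            if col not in df.columns:
                raise ValidationError(f"declared covariate column {col!r} missing")
            na = df[col].isna()
            if na.any():
                row = int(np.flatnonzero(na.to_numpy())[0])
                raise ValidationError(
                    f"missing value in column {col!r} at row {row} "
                    f"(subject_id={df['subject_id'].iloc[row]!r})"
                )
        for col in self.continuous:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = int(np.flatnonzero(vals.isna().to_numpy())[0])
                raise ValidationError(
                    f"non-numeric entry in continuous column {col!r} at row {row}"
                )
            if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
                raise ValidationError(f"non-finite value in continuous column {col!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def levels(self, column: str) -> list[str]:
        """Observed levels of a categorical column, in sorted label order."""
        return sorted(self.data[column].astype(str).unique())


@dataclass(frozen=True)
class DesignSpec:
    """Number of arms, their labels and their fixed sizes.

    ``stratum_arm_counts`` (optional) prescribes, for each stratum level, how
    many of its subjects go to each arm; it is consulted only by stratified
    randomization.  Rows are stratum levels, columns are arm labels.
    """

    arm_sizes: tuple[int, ...]
    arm_labels: tuple[str, ...] = ()
    stratum_arm_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "arm_sizes", tuple(int(n) for n in self.arm_sizes))
        if self.n_arms < 2:
            raise ValidationError(f"need at least 2 arms, got {self.n_arms}")
        if any(n < 1 for n in self.arm_sizes):
            raise ValidationError(f"every arm size must be >= 1, got {self.arm_sizes}")
        if not self.arm_labels:
            labels = tuple(_default_arm_label(k) for k in range(self.n_arms))
            object.__setattr__(self, "arm_labels", labels)
        else:
            object.__setattr__(self, "arm_labels", tuple(str(a) for a in self.arm_labels))
        if len(self.arm_labels) != self.n_arms:
            raise ValidationError("arm_labels length must equal number of arms")
        if len(set(self.arm_labels)) != self.n_arms:
            raise ValidationError("arm_labels must be distinct")
        if any(not lab for lab in self.arm_labels):
            raise ValidationError("arm labels must be non-empty")
        sac = self.stratum_arm_counts
        if sac is not None:
            if list(sac.columns) != list(self.arm_labels):
                raise ValidationError(
                    "stratum_arm_counts columns must equal arm_labels in order"
                )
            col_tot = sac.to_numpy().sum(axis=0)
            if not np.array_equal(col_tot, np.asarray(self.arm_sizes)):
                raise ValidationError(
                    f"stratum_arm_counts column totals {col_tot.tolist()} "
                    f"!= arm sizes {list(self.arm_sizes)}"
                )

    @property
    def n_arms(self) -> int:
        return len(self.arm_sizes)

    @property
    def n_subjects(self) -> int:
        return int(sum(self.arm_sizes))


def _default_arm_label(k: int) -> str:
    # A, B, ..., Z, AA, AB, ... (spreadsheet-style)
    label = ""
    k += 1
    while k:
        k, rem = divmod(k - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


@dataclass(frozen=True)
class CovariateMatrix:
    """Encoded numeric design matrix X with its column-space basis.

    ``basis`` is an N x r matrix with orthonormal columns spanning col(X);
    ``rank`` is r as detected with ``rank_tolerance``.  Only the column space
    enters the D_s criterion, so linear dependence among the encoded columns
    (full-dummy coding) is harmless.
    """

    matrix: np.ndarray
    column_names: tuple[str, ...]
    basis: np.ndarray
    rank: int
    rank_tolerance: float
    warnings_: tuple[str, ...] = ()

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class Allocation:
    """Assignment of each subject (by row index) to an arm index in 0..t-1."""

    arm_of: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "arm_of", np.ascontiguousarray(self.arm_of, dtype=np.int64)
        )

    @property
    def n_subjects(self) -> int:
        return self.arm_of.shape[0]

    def arm_counts(self, n_arms: int) -> np.ndarray:
        return np.bincount(self.arm_of, minlength=n_arms)

    def check(self, spec: DesignSpec) -> None:
        counts = self.arm_counts(spec.n_arms)
        if not np.array_equal(counts, np.asarray(spec.arm_sizes)):
            raise ValidationError(
                f"allocation arm counts {counts.tolist()} != "
                f"spec arm sizes {list(spec.arm_sizes)}"
            )


@dataclass(frozen=True)
class ContrastMatrix:
    """N x (t-1) matrix T of scaled Helmert treatment contrasts.

    Row i depends only on the arm of subject i.  For equal arm sizes the
    columns are mutually orthogonal with squared norm N, hence
    |T'T| = N^(t-1).
    """

    matrix: np.ndarray
    n_arms: int

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class DsEvaluation:
    """D_s criterion value and the derived efficiency for one allocation."""

    ds_value: float
    log_ds: float
    ds_efficiency: float
    t: int
    n_subjects: int


def helmert_contrasts(t: int) -> np.ndarray:
    """Orthonormal Helmert matrix: t x (t-1), columns unit-norm, mutually
    orthogonal and orthogonal to the all-ones vector.

    Column k (1-based) contrasts level k+1 against the mean of levels 1..k.
    """
    if t < 2:
        raise ValidationError("need t >= 2")
    H = np.zeros((t, t - 1))
    for k in range(1, t):
        scale = 1.0 / np.sqrt(k * (k + 1))
        H[:k, k - 1] = scale
        H[k, k - 1] = -k * scale
    return H


def encode_covariates(
    table: SubjectTable,
    categorical: Sequence[str] | None = None,
    continuous: Sequence[str] | None = None,
) -> CovariateMatrix:
    """Encode a subject table into the numeric design matrix X.

    X carries the intercept, one column per continuous covariate, and a full
    set of 0/1 indicator columns per categorical covariate (no reference
    level dropped, so each indicator set sums to the intercept and the
    encoding is deliberately rank deficient).  The returned object carries an
    orthonormal basis of col(X) with SVD-based rank detection at tolerance
    ``sigma_1 * max(N, p) * eps``.
    """
    if categorical is None:
        categorical = table.categorical
    if continuous is None:
        continuous = table.continuous
    df = table.data
    for col in (*categorical, *continuous):
        if col not in df.columns:
            raise ValidationError(f"column {col!r} not in table")
    n = table.n_subjects

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    notes: list[str] = []
    for col in continuous:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValidationError(
                f"non-numeric entry in continuous column {col!r} at row {row}"
            )
        arr = vals.to_numpy(dtype=float)
        if np.ptp(arr) == 0.0:
            msg = f"continuous column {col!r} is constant (aliased with intercept)"
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
        cols.append(arr)
        names.append(col)
    for col in categorical:
        labels = df[col].astype(str).to_numpy()
        for level in sorted(set(labels)):
            cols.append((labels == level).astype(float))
            names.append(f"{col}={level}")

    X = np.column_stack(cols)
    U, s, _ = linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    basis = np.ascontiguousarray(U[:, :rank])
    return CovariateMatrix(
        matrix=X,
        column_names=tuple(names),
        basis=basis,
        rank=rank,
        rank_tolerance=float(tol),
        warnings_=tuple(notes),
    )


def covariate_matrix_from_array(X: np.ndarray, names: Sequence[str] | None = None) -> CovariateMatrix:
    """Wrap an explicit design matrix (first column must be the intercept)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-d matrix")
    if not np.allclose(X[:, 0], 1.0):
        raise ValidationError("first column of X must be the all-ones intercept")
    U, s, _ = linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if names is None:
        names = ["intercept"] + [f"x{j}" for j in range(1, X.shape[1])]
    return CovariateMatrix(
        matrix=X,
        column_names=tuple(names),
        basis=np.ascontiguousarray(U[:, :rank]),
        rank=rank,
        rank_tolerance=float(tol),
    )


def treatment_contrasts(allocation: Allocation, spec: DesignSpec) -> ContrastMatrix:
    """Build the N x (t-1) contrast matrix T for an allocation.

    Row i equals sqrt(t) times row ``arm_of[i]`` of the orthonormal Helmert
    matrix, so that for equal arm sizes T'T = N * I (each contrast has
    length sqrt(N)).
    """
    allocation.check(spec)
    t = spec.n_arms
    H = helmert_contrasts(t)
    T = np.sqrt(t) * H[allocation.arm_of]
    return ContrastMatrix(matrix=T, n_arms=t)


def contrast_gram(spec: DesignSpec) -> np.ndarray:
    """T'T for any allocation respecting ``spec`` (depends only on arm counts):
    T'T = t * H' diag(n_1..n_t) H."""
    t = spec.n_arms
    H = helmert_contrasts(t)
    n = np.asarray(spec.arm_sizes, dtype=float)
    return t * (H.T * n) @ H


def _det_psd(M: np.ndarray) -> tuple[float, float]:
    """Determinant of a symmetric PSD-up-to-roundoff matrix.

    Returns ``(det, logdet)``; values in [-1e-10 * scale, 0] clamp to 0 and
    genuinely negative values raise (internal-error signal).
    """
    M = np.asarray(M, dtype=float)
    sign, logdet = np.linalg.slogdet(M)
    if sign > 0:
        return float(np.exp(logdet)), float(logdet)
    # zero or negative determinant: decide via eigenvalues
    eigs = np.linalg.eigvalsh((M + M.T) / 2.0)
    scale = max(1.0, float(np.max(np.abs(eigs), initial=0.0)) ** M.shape[0])
    det = float(np.prod(eigs))
    if det < -_DET_CLAMP * scale:
        raise FloatingPointError(
            f"residual contrast Gram has significantly negative determinant {det}"
        )
    return 0.0, -np.inf


def ds_criterion(X: CovariateMatrix, T: ContrastMatrix) -> DsEvaluation:
    """Evaluate the D_s criterion for a covariate matrix and contrast matrix.

    Computed as |T'T - (B'T)'(B'T)| with B an orthonormal basis of col(X) —
    algebraically the residual SSP determinant of T after regression on X,
    valid for rank-deficient X because only the column space enters.
    """
    if X.n_subjects != T.n_subjects:
        raise ValidationError(
            f"X has {X.n_subjects} rows but T has {T.n_subjects}"
        )
    Tm = T.matrix
    P = X.basis.T @ Tm
    G = Tm.T @ Tm - P.T @ P
    ds, log_ds = _det_psd(G)
    t = T.n_arms
    n = T.n_subjects
    return DsEvaluation(
        ds_value=ds,
        log_ds=log_ds,
        ds_efficiency=ds_efficiency(ds, n, t),
        t=t,
        n_subjects=n,
    )


def ds_efficiency(ds_value: float, n_subjects: int, t: int) -> float:
    """D_s-efficiency: ``ds_value**(1/(t-1)) / N``, in [0, 1]."""
    if ds_value < 0:
        raise ValidationError(f"ds_value must be >= 0, got {ds_value}")
    if t < 2:
        raise ValidationError("need t >= 2")
    if n_subjects < t:
        raise ValidationError("need N >= t")
    return float(ds_value ** (1.0 / (t - 1)) / n_subjects)


def ds_via_ratio(X_full_rank: np.ndarray, T: ContrastMatrix) -> float:
    """Independent determinant-ratio form of the criterion: |F'F| / |X'X|
    with F = [X T].

    Requires a full-rank X (X'X nonsingular); intended as a test oracle, not
    used by the optimizer.
    """
    X = np.asarray(X_full_rank, dtype=float)
    if X.shape[0] != T.n_subjects:
        raise ValidationError("X and T row counts differ")
    XtX = X.T @ X
    sign, logdet_x = np.linalg.slogdet(XtX)
    # guard against a numerically singular X'X (e.g. duplicated columns)
    if sign <= 0 or np.linalg.cond(XtX) > 1e12:
        raise ValidationError(
            "X'X is singular; drop dependent columns or use ds_criterion"
        )
    F = np.hstack([X, T.matrix])
    FtF = F.T @ F
    sign_f, logdet_f = np.linalg.slogdet(FtF)
    if sign_f <= 0:
        return 0.0
    return float(np.exp(logdet_f - logdet_x))
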