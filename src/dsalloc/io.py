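"""CSV ingestion/emission and covariate balance reporting.

CSV files are comma-separated UTF-8 with a required header row (RFC 4180
quoting, decimal point).  Subject order is row order; arms are labeled
"A", "B", "C", ... in reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    Allocation,
    CovariateMatrix,
    DesignSpec,
    DsEvaluation,
    SubjectTable,
    ValidationError,
    ds_criterion,
    treatment_contrasts,
)

__all__ = ["BalanceReport", "read_subject_table", "write_allocation", "read_allocation", "balance_report"]


@dataclass(frozen=True)
class BalanceReport:
    """Arm-by-covariate balance summary for one allocation.

    ``categorical_tables`` maps covariate name -> level x arm count table;
    ``continuous_tables`` maps covariate name -> arm x (n, mean, sd) table
    (sample sd, n-1 denominator).  ``overall_efficiency`` is the
    allocation's D_s evaluation against the full covariate encoding.
    """

    categorical_tables: dict[str, pd.DataFrame]
    continuous_tables: dict[str, pd.DataFrame]
    overall_efficiency: DsEvaluation

    def to_text(self) -> str:
        lines: list[str] = []
        for name, tab in self.categorical_tables.items():
            lines.append(f"== {name} (counts per arm) ==")
            lines.append(tab.to_string())
            lines.append("")
        for name, tab in self.continuous_tables.items():
            lines.append(f"== {name} (per-arm mean / sd) ==")
            lines.append(tab.to_string(float_format=lambda v: f"{v:.3f}"))
            lines.append("")
        ev = self.overall_efficiency
        lines.append(f"D_s value: {ev.ds_value:.6g}")
        lines.append(f"D_s-efficiency: {ev.ds_efficiency:.4f}")
        return "\n".join(lines)


def read_subject_table(
    path: str | Path,
    categorical: tuple[str, ...] = (),
    continuous: tuple[str, ...] = (),
) -> SubjectTable:
    """Read and validate a subject covariate CSV.

    The file must have a header including ``subject_id`` and every declared
    covariate column.  Row order defines the subject index.  Missing values,
    duplicate ids and non-numeric continuous entries are rejected with
    row/column diagnostics.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file {path} does not exist")
    df = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=True)
    for col in categorical:
        if col in df.columns:
            df[col] = df[col].astype("string").astype(object)
    return SubjectTable(data=df, categorical=tuple(categorical), continuous=tuple(continuous))


def write_allocation(
    allocation: Allocation,
    table: SubjectTable,
    path: str | Path,
    spec: DesignSpec,
    metadata: dict | None = None,
) -> None:
    """Write ``subject_id,arm`` CSV plus a JSON metadata sidecar.

    The sidecar (``<path>.meta.json``) records the seed, efficiency and
    settings passed in ``metadata``.
    """
    if allocation.n_subjects != table.n_subjects:
        raise ValidationError("allocation length does not match the table")
    allocation.check(spec)
    path = Path(path)
    out = pd.DataFrame(
        {
            "subject_id": table.data["subject_id"].to_numpy(),
            "arm": [spec.arm_labels[k] for k in allocation.arm_of],
        }
    )
    out.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = {"arm_labels": list(spec.arm_labels), "arm_sizes": list(spec.arm_sizes)}
    meta.update(metadata or {})
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_allocation(path: str | Path, table: SubjectTable, spec: DesignSpec) -> Allocation:
    """Read an allocation CSV written by :func:`write_allocation`."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["subject_id", "arm"]:
        raise ValidationError("allocation CSV must have columns subject_id,arm")
    order = {sid: i for i, sid in enumerate(table.data["subject_id"])}
    if set(df["subject_id"]) != set(order):
        raise ValidationError("allocation subject_ids do not match the table")
    label_to_idx = {lab: k for k, lab in enumerate(spec.arm_labels)}
    arm_of = np.empty(len(df), dtype=np.int64)
    for sid, lab in zip(df["subject_id"], df["arm"]):
        if lab not in label_to_idx:
            raise ValidationError(f"unknown arm label {lab!r}")
        arm_of[order[sid]] = label_to_idx[lab]
    alloc = Allocation(arm_of)
    alloc.check(spec)
    return alloc


def balance_report(
    table: SubjectTable,
    allocation: Allocation,
    X: CovariateMatrix,
    spec: DesignSpec,
) -> BalanceReport:
    """Summarize covariate balance of an allocation across arms.

    Produces, for every categorical covariate, a level x arm count table
    and, for every continuous covariate, per-arm n/mean/sd, together with
    the allocation's D_s-efficiency against ``X``.
    """
    if allocation.n_subjects != table.n_subjects:
        raise ValidationError("allocation length does not match the table")
    allocation.check(spec)
    arms = pd.Categorical(
        [spec.arm_labels[k] for k in allocation.arm_of],
        categories=list(spec.arm_labels),
    )
    df = table.data
    categorical_tables: dict[str, pd.DataFrame] = {}
    for col in table.categorical:
        tab = pd.crosstab(df[col].astype(str), arms, dropna=False)
        tab.index.name = col
        tab.columns.name = "arm"
        categorical_tables[col] = tab
    continuous_tables: dict[str, pd.DataFrame] = {}
    for col in table.continuous:
        vals = pd.to_numeric(df[col])
        grp = vals.groupby(arms, observed=False)
        tab = pd.DataFrame(
            {"n": grp.size(), "mean": grp.mean(), "sd": grp.std(ddof=1)}
        )
        tab.index.name = "arm"
        continuous_tables[col] = tab
    T = treatment_contrasts(allocation, spec)
    ev = ds_criterion(X, T)
    return BalanceReport(
        categorical_tables=categorical_tables,
        continuous_tables=continuous_tables,
        overall_efficiency=ev,
    )
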