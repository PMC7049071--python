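"""Readers, writers and report rendering.

Two input paths feed the balance machinery: a pre-tabulated counts CSV
(first column covariate levels, one column per treatment group) and a
long-format subject-level CSV (one row per subject with a group label and a
covariate value).  Reports render the group/common distributions and the
JSD decomposition as text, CSV or JSON.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .balance import BalanceTable, GroupProfile, JSDDecomposition, rank_contributions
from .continuous import BinningSpec, bin_groups
from .exceptions import ValidationError

__all__ = [
    "LongRecords",
    "read_counts_csv",
    "read_long_csv",
    "tabulate_records",
    "write_counts_csv",
    "render_report",
    "glucose_example",
]

logger = logging.getLogger(__name__)

ROUNDING_CAVEAT = (
    "Note: displayed row/column sums may not equal the displayed total "
    "due to rounding; totals are computed from unrounded cells."
)
THRESHOLD_CAVEAT = (
    "No threshold defines an acceptable amount of imbalance; interpret the "
    "JSD relative to its maximum and to the covariate's potential to "
    "affect the outcome."
)


@dataclass(frozen=True)
class LongRecords:
    """Subject-level records: one (group, covariate value) pair per subject.

    ``kind`` declares the covariate as categorical (values kept as text) or
    continuous (values parsed as finite reals).  Records with a missing
    covariate value are excluded complete-case style; the exclusion count
    is retained and logged.
    """

    groups: tuple[str, ...]
    values: tuple = field(repr=False)
    kind: str = "categorical"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValidationError(
                f"kind must be 'categorical' or 'continuous', got {self.kind!r}"
            )
        if len(self.groups) != len(self.values):
            raise ValidationError("need one covariate value per group label")

    def __len__(self) -> int:
        return len(self.groups)


def read_counts_csv(path: str | Path) -> BalanceTable:
    """Read a covariate-level x treatment-group counts CSV.

    The first column holds covariate level names; every other column is a
    treatment group of integer counts.  File row/column order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"counts file not found: {path}")
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] < 2:
        raise ValidationError(
            f"{path}: need at least 2 group columns, found {df.shape[1]}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate covariate level {dup!r}")
    for col in df.columns:
        for level, value in df[col].items():
            num = pd.to_numeric(pd.Series([value]), errors="coerce").iloc[0]
            if pd.isna(num) or float(num) != int(num):
                raise ValidationError(
                    f"{path}: non-integer count at row {level!r}, column {col!r}: {value!r}"
                )
            if num < 0:
                raise ValidationError(
                    f"{path}: negative count at row {level!r}, column {col!r}: {value!r}"
                )
    return BalanceTable.from_dataframe(df.astype(int))


def write_counts_csv(t: BalanceTable, path: str | Path) -> None:
    """Write a BalanceTable so that :func:`read_counts_csv` round-trips it."""
    t.to_dataframe().to_csv(path)


def read_long_csv(
    path: str | Path,
    group_col: str,
    covariate_col: str,
    kind: str = "categorical",
) -> LongRecords:
    """Read subject-level long-format data.

    Rows with a missing covariate value are excluded (complete-case) and
    counted; rows with a missing group label are rejected.  For a
    continuous covariate every retained value must parse as a finite real.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"long-format file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (group_col, covariate_col):
        if col not in df.columns:
            raise ValidationError(
                f"{path}: column {col!r} not found (have: {list(df.columns)})"
            )
    if (df[group_col].str.strip() == "").any():
        line = int(df.index[df[group_col].str.strip() == ""][0]) + 2
        raise ValidationError(f"{path}: missing group label at line {line}")
    missing = df[covariate_col].str.strip() == ""
    n_excluded = int(missing.sum())
    if n_excluded:
        logger.info(
            "excluded %d record(s) with missing covariate values", n_excluded
        )
    kept = df.loc[~missing]
    groups = tuple(kept[group_col])
    if kind == "continuous":
        values = []
        for idx, raw in kept[covariate_col].items():
            try:
                v = float(raw)
            except ValueError:
                raise ValidationError(
                    f"{path}: unparseable continuous value {raw!r} at line {int(idx) + 2}"
                ) from None
            if not np.isfinite(v):
                raise ValidationError(
                    f"{path}: non-finite value {raw!r} at line {int(idx) + 2}"
                )
            values.append(v)
        values = tuple(values)
    else:
        values = tuple(kept[covariate_col])
    return LongRecords(groups, values, kind=kind, n_excluded=n_excluded)


def tabulate_records(
    r: LongRecords, spec: BinningSpec | None = None
) -> BalanceTable:
    """Cross-tabulate subject-level records into a BalanceTable.

    Categorical covariates are counted directly with first-appearance level
    and group order; continuous covariates require a :class:`BinningSpec`
    and delegate to :func:`jsdbalance.continuous.bin_groups`.
    """
    if r.kind == "categorical":
        if spec is not None:
            raise ValidationError("a BinningSpec applies only to continuous covariates")
        groups = list(dict.fromkeys(r.groups))
        levels = list(dict.fromkeys(str(v) for v in r.values))
        if len(groups) < 2:
            raise ValidationError("need at least 2 treatment groups")
        counts = pd.crosstab(
            pd.Series([str(v) for v in r.values], name="level"),
            pd.Series(list(r.groups), name="group"),
        ).reindex(index=levels, columns=groups, fill_value=0)
        return BalanceTable.from_dataframe(counts)
    if spec is None:
        raise ValidationError("a BinningSpec is required for a continuous covariate")
    by_group: dict[str, list[float]] = {}
    for g, v in zip(r.groups, r.values):
        by_group.setdefault(g, []).append(float(v))
    return bin_groups(by_group, spec)


def _text_report(d: JSDDecomposition, p: GroupProfile) -> str:
    buf = _io.StringIO()
    prof = p.to_dataframe()
    cells = d.cell_dataframe()
    w = max(12, max(len(str(l)) for l in d.covariate_levels) + 2)
    gw = max(14, max(len(g) for g in d.group_labels) + 2)

    def row(label: str, values: list[str]) -> str:
        return label.ljust(w) + "".join(v.rjust(gw) for v in values)

    buf.write("Group covariate distributions (common = unweighted mean)\n")
    buf.write(row("level", list(prof.columns)) + "\n")
    for level in prof.index:
        buf.write(row(str(level), [f"{v:.4f}" for v in prof.loc[level]]) + "\n")
    buf.write("\nJSD contributions (bits)\n")
    buf.write(row("level", list(cells.columns) + ["total"]) + "\n")
    for i, level in enumerate(cells.index):
        vals = [f"{v:.4f}" for v in cells.loc[level]] + [f"{d.level_totals[i]:.4f}"]
        buf.write(row(str(level), vals) + "\n")
    totals = [f"{v:.4f}" for v in d.group_totals] + [f"{d.overall:.4f}"]
    buf.write(row("total", totals) + "\n")
    buf.write(f"\noverall JSD: {d.overall:.4f} bits\n")
    buf.write(
        f"maximum JSD for {len(d.group_labels)} groups: {d.max_jsd:.4f} bits\n"
    )
    buf.write(f"normalized JSD (overall / maximum; extension): {d.normalized:.4f}\n")
    top_group, top_level, contrib, _ = rank_contributions(d)[0]
    buf.write(
        f"largest |cell| contribution: group {top_group!r}, level {top_level!r} "
        f"({contrib:+.4f} bits)\n"
    )
    buf.write("\n" + ROUNDING_CAVEAT + "\n")
    buf.write(THRESHOLD_CAVEAT + "\n")
    return buf.getvalue()


def _csv_report(d: JSDDecomposition, p: GroupProfile) -> str:
    prof = p.to_dataframe()
    cells = d.cell_dataframe()
    out = _io.StringIO()
    out.write("# group covariate distributions\n")
    prof.round(4).to_csv(out)
    out.write("# jsd contributions (bits)\n")
    block = cells.copy()
    block["total"] = d.level_totals
    totals = pd.DataFrame(
        [list(d.group_totals) + [d.overall]],
        index=pd.Index(["total"], name="level"),
        columns=block.columns,
    )
    pd.concat([block, totals]).round(4).to_csv(out)
    out.write(f"# overall_jsd_bits,{d.overall:.4f}\n")
    out.write(f"# max_jsd_bits,{d.max_jsd:.4f}\n")
    out.write(f"# {ROUNDING_CAVEAT}\n")
    return out.getvalue()


def _json_report(d: JSDDecomposition, p: GroupProfile) -> str:
    payload = {
        "groups": list(d.group_labels),
        "levels": list(d.covariate_levels),
        "group_distributions": {
            g: [float(v) for v in dist.probs]
            for g, dist in zip(p.group_labels, p.group_dists)
        },
        "common_distribution": [float(v) for v in p.common_dist.probs],
        "cell_contributions_bits": [[float(v) for v in row] for row in d.cell],
        "group_totals_bits": [float(v) for v in d.group_totals],
        "level_totals_bits": [float(v) for v in d.level_totals],
        "overall_jsd_bits": float(d.overall),
        "max_jsd_bits": float(d.max_jsd),
        "normalized_jsd": float(d.normalized),
        "notes": [ROUNDING_CAVEAT, THRESHOLD_CAVEAT],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def render_report(
    d: JSDDecomposition, p: GroupProfile, format: str = "text"
) -> str:
    """Render a balance report.

    Text and CSV formats display at 4 decimal places with marginal totals
    computed from unrounded cells (so displayed cells may not sum exactly
    to displayed totals — a caveat line says so); the JSON format carries
    full-precision values.  Output is deterministic: identical inputs give
    byte-identical reports.
    """
    if d.covariate_levels != p.common_dist.labels or d.group_labels != p.group_labels:
        raise ValidationError("decomposition and profile come from different tables")
    renderers = {"text": _text_report, "csv": _csv_report, "json": _json_report}
    if format not in renderers:
        raise ValidationError(
            f"unknown format {format!r} (choose from {sorted(renderers)})"
        )
    return renderers[format](d, p)


def glucose_example() -> BalanceTable:
    """The packaged glucose x neighborhood-deprivation contingency table.

    Counts of 93,583 outpatients cross-classified by baseline serum glucose
    (<109, 109-125, >125 mg/dL) and treatment group (Disadvantaged,
    Elderly, Reference) — the canonical worked example for the balance
    statistic and its decomposition.
    """
    ref = resources.files("jsdbalance").joinpath("data/glucose_counts.csv")
    with resources.as_file(ref) as path:
        return read_counts_csv(path)
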