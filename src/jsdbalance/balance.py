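"""JSD balance statistic across treatment groups, with decomposition.

Given a covariate-level x treatment-group contingency table of subject
counts, each group column is normalized to its own covariate distribution
p_k(C); the common distribution p~(C) is their unweighted mean; and the
balance statistic is the Jensen-Shannon divergence

    JSD = (1/N) sum_k D(p_k(C) || p~(C))        [bits]

Because the JSD is an average of sums over covariate levels, it splits
additively into per-cell terms

    cell[i, k] = (1/N) p_k(c_i) log2( p_k(c_i) / p~(c_i) )

whose column sums give each treatment group's contribution and whose row
sums give each covariate level's contribution.  Individual cells can be
negative (a group under-represented at a level relative to the mixture),
but every group total and every level total is non-negative.

The statistic depends only on the group-wise proportions, never the group
sizes, so it is invariant to rescaling any column — the sample-size
insensitivity that motivates using it over association tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .information import ProbabilityVector, jsd_distributions

__all__ = [
    "BalanceTable",
    "GroupProfile",
    "JSDDecomposition",
    "group_profiles",
    "jsd_balance",
    "decompose_jsd",
    "max_jsd",
    "rank_contributions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BalanceTable:
    """Covariate-level x treatment-group contingency counts.

    Rows are ordered covariate levels c_1..c_M (M >= 2), columns are
    treatment groups (N >= 2), cells are non-negative integer subject
    counts.  Every group column must have a positive total.  A covariate
    level with zero count in every group carries no information (its
    mixture probability would be 0/0) and is dropped with a warning.
    """

    covariate_levels: tuple[str, ...]
    group_labels: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        levels = tuple(str(x) for x in self.covariate_levels)
        groups = tuple(str(x) for x in self.group_labels)
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(levels), len(groups)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match {len(levels)} "
                f"levels and {len(groups)} groups"
            )
        if len(set(levels)) != len(levels):
            raise ValidationError("covariate levels must be unique")
        if len(set(groups)) != len(groups):
            raise ValidationError("group labels must be unique")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ValidationError("counts must be finite and non-negative")
        if np.any(counts != np.floor(counts)):
            raise ValidationError("counts must be integers")
        # drop all-zero covariate levels (mixture mass 0/0 there)
        empty = counts.sum(axis=1) == 0
        if np.any(empty):
            dropped = [l for l, e in zip(levels, empty) if e]
            logger.warning(
                "dropping covariate level(s) with zero count in every group: %s",
                ", ".join(dropped),
            )
            keep = ~empty
            levels = tuple(l for l, k in zip(levels, keep) if k)
            counts = counts[keep]
        if len(levels) < 2:
            raise ValidationError("need at least 2 covariate levels with counts")
        if len(groups) < 2:
            raise ValidationError("need at least 2 treatment groups")
        zero_cols = counts.sum(axis=0) == 0
        if np.any(zero_cols):
            bad = groups[int(np.argmax(zero_cols))]
            raise ValidationError(f"group {bad!r} has zero total count")
        object.__setattr__(self, "covariate_levels", levels)
        object.__setattr__(self, "group_labels", groups)
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BalanceTable":
        """Build from a DataFrame indexed by covariate level, one column per group."""
        return cls(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), df.to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.astype(int),
            index=pd.Index(self.covariate_levels, name="level"),
            columns=list(self.group_labels),
        )

    @property
    def n_levels(self) -> int:
        return len(self.covariate_levels)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def group_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class GroupProfile:
    """Per-group covariate distributions and their unweighted mixture."""

    group_dists: tuple[ProbabilityVector, ...]
    common_dist: ProbabilityVector
    group_labels: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        """Distributions as columns, plus the common (mixture) distribution."""
        data = {g: d.probs for g, d in zip(self.group_labels, self.group_dists)}
        data["common"] = self.common_dist.probs
        return pd.DataFrame(
            data, index=pd.Index(self.common_dist.labels, name="level")
        )


@dataclass(frozen=True)
class JSDDecomposition:
    """Additive split of the JSD balance statistic.

    ``cell[i, k] = (1/N) p_k(c_i) log2(p_k(c_i) / p~(c_i))`` in bits;
    ``group_totals`` and ``level_totals`` are its column and row sums, and
    both resum to ``overall``.  ``max_jsd = log2(N)`` is the ceiling the
    statistic could reach if the N groups had disjoint covariate support.
    """

    covariate_levels: tuple[str, ...]
    group_labels: tuple[str, ...]
    cell: np.ndarray = field(repr=False)
    group_totals: np.ndarray = field(repr=False)
    level_totals: np.ndarray = field(repr=False)
    overall: float = 0.0
    max_jsd: float = 0.0

    def cell_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cell,
            index=pd.Index(self.covariate_levels, name="level"),
            columns=list(self.group_labels),
        )

    @property
    def normalized(self) -> float:
        """overall / log2(N) — a [0, 1] convenience ratio (extension).

        The ceiling log2(N) is reported alongside the statistic; this ratio
        merely divides the two.  It is not a calibrated balance score and no
        acceptability threshold is attached to it.
        """
        return self.overall / self.max_jsd


def group_profiles(t: BalanceTable) -> GroupProfile:
    """Normalize each group column and form the common (mixture) distribution.

    Each group's covariate distribution is its column divided by its own
    column total; the common distribution is the unweighted mean of the
    group distributions — group sample sizes play no role.
    """
    probs = t.counts / t.counts.sum(axis=0)
    dists = tuple(
        ProbabilityVector(t.covariate_levels, probs[:, k]) for k in range(t.n_groups)
    )
    common = ProbabilityVector(t.covariate_levels, probs.mean(axis=1))
    return GroupProfile(dists, common, t.group_labels)


def jsd_balance(t: BalanceTable) -> float:
    """The JSD balance statistic of a contingency table, in bits.

    Equals the uniform-weight Jensen-Shannon divergence of the group
    covariate distributions; lies in ``[0, log2(N)]``, with 0 exactly when
    every group has the same covariate distribution.
    """
    profile = group_profiles(t)
    return jsd_distributions(list(profile.group_dists))


def decompose_jsd(t: BalanceTable) -> JSDDecomposition:
    """Split the JSD into cell, group, and covariate-level contributions.

    Empty cells (a level unobserved in one group) contribute exactly zero
    for that group, by the 0*log(0) = 0 convention.
    """
    profile = group_profiles(t)
    p = np.stack([d.probs for d in profile.group_dists], axis=1)  # (M, N)
    m = profile.common_dist.probs[:, None]
    n = t.n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / m, 1.0)
    cell = np.where(p > 0, (p / n) * np.log2(ratio), 0.0)
    return JSDDecomposition(
        covariate_levels=t.covariate_levels,
        group_labels=t.group_labels,
        cell=cell,
        group_totals=cell.sum(axis=0),
        level_totals=cell.sum(axis=1),
        overall=float(cell.sum()),
        max_jsd=max_jsd(n),
    )


def max_jsd(n_groups: int) -> float:
    """Upper bound log2(N) on the JSD of N groups, attained at disjoint support."""
    if n_groups < 2:
        raise ValidationError("need at least 2 groups")
    return float(np.log2(n_groups))


def rank_contributions(
    d: JSDDecomposition,
) -> list[tuple[str, str, float, float]]:
    """Cells ranked by absolute contribution, largest first.

    Returns ``(group, level, contribution, |contribution|)`` tuples sorted
    by descending absolute contribution; ties keep table order (level
    first, then group).
    """
    entries = []
    for i, level in enumerate(d.covariate_levels):
        for k, group in enumerate(d.group_labels):
            c = float(d.cell[i, k])
            entries.append((group, level, c, abs(c)))
    order = sorted(
        range(len(entries)),
        key=lambda idx: (-entries[idx][3], idx),
    )
    return [entries[idx] for idx in order]
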