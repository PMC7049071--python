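"""Discrete information-theory kernel.

Shannon entropy and its relatives — joint and conditional entropy, mutual
information, relative entropy (Kullback-Leibler divergence), Jeffreys
divergence, and the Jensen-Shannon divergence (JSD) of an arbitrary number
of discrete distributions — together with expected code length under a
prefix code.  All quantities are reported in bits (base-2 logarithms) by
default; kernel functions accept an optional ``base`` argument for nats or
hartleys.

Everywhere the continuity convention ``0 * log(0) = 0`` applies: terms whose
mass in the expectation-taking distribution is zero are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DomainError, ValidationError

__all__ = [
    "ProbabilityVector",
    "JointProbabilityTable",
    "PrefixCode",
    "entropy",
    "joint_entropy",
    "conditional_entropy",
    "mutual_information",
    "relative_entropy",
    "jeffreys_divergence",
    "jsd_distributions",
    "expected_code_length",
]

#: Tolerance on sum(p) == 1 for distributions built from pre-normalized reals.
NORMALIZATION_TOL = 1e-9


def _log(x: np.ndarray | float, base: float) -> np.ndarray | float:
    if base == 2.0:
        return np.log2(x)
    return np.log(x) / math.log(base)


@dataclass(frozen=True)
class ProbabilityVector:
    """A discrete probability distribution over labeled categories.

    Parameters
    ----------
    labels
        Ordered, unique category names.
    probs
        Non-negative reals, one per label, summing to 1 within ``1e-9``.
        Construction from raw counts via :meth:`from_counts` divides by the
        exact total, so normalization is exact on the primary input path.
    """

    labels: tuple[str, ...]
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 1 or len(labels) != probs.size:
            raise ValidationError(
                f"need one probability per label: {len(labels)} labels, "
                f"{probs.size} probabilities"
            )
        if len(set(labels)) != len(labels):
            raise ValidationError("labels must be unique")
        if not np.all(np.isfinite(probs)):
            raise ValidationError("probabilities must be finite")
        if np.any(probs < 0):
            bad = labels[int(np.argmin(probs))]
            raise ValidationError(f"negative probability at label {bad!r}")
        total = float(probs.sum())
        if abs(total - 1.0) > NORMALIZATION_TOL:
            raise ValidationError(
                f"probabilities sum to {total!r}, not 1 (tolerance "
                f"{NORMALIZATION_TOL:g})"
            )

    @classmethod
    def from_counts(
        cls, labels: Sequence[str], counts: Sequence[float]
    ) -> "ProbabilityVector":
        """Build a distribution from non-negative counts (exact division)."""
        arr = np.asarray(counts, dtype=float)
        if np.any(arr < 0):
            raise ValidationError("counts must be non-negative")
        total = arr.sum()
        if total <= 0:
            raise ValidationError("counts must have a positive total")
        return cls(tuple(labels), arr / total)

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ProbabilityVector":
        return cls(tuple(mapping), np.array(list(mapping.values()), float))

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    def reordered(self, labels: Sequence[str]) -> "ProbabilityVector":
        """Return the same distribution with categories in the given order."""
        if set(labels) != set(self.labels):
            raise ValidationError("reordering must use the same label set")
        idx = [self.labels.index(l) for l in labels]
        return ProbabilityVector(tuple(labels), self.probs[idx])


@dataclass(frozen=True)
class JointProbabilityTable:
    """A joint distribution over two labeled discrete variables.

    ``probs[i, j]`` is the probability of ``(row_labels[i], col_labels[j])``;
    the grand sum must be 1 within ``1e-9``.  Marginals are obtained by row
    or column summation.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        rows = tuple(str(x) for x in self.row_labels)
        cols = tuple(str(x) for x in self.col_labels)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "row_labels", rows)
        object.__setattr__(self, "col_labels", cols)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (len(rows), len(cols)):
            raise ValidationError(
                f"probability matrix shape {probs.shape} does not match "
                f"{len(rows)} row and {len(cols)} column labels"
            )
        if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
            raise ValidationError("row and column labels must each be unique")
        if not np.all(np.isfinite(probs)) or np.any(probs < 0):
            raise ValidationError("joint probabilities must be finite and >= 0")
        total = float(probs.sum())
        if abs(total - 1.0) > NORMALIZATION_TOL:
            raise ValidationError(f"joint probabilities sum to {total!r}, not 1")

    def row_marginal(self) -> ProbabilityVector:
        return ProbabilityVector(self.row_labels, self.probs.sum(axis=1))

    def col_marginal(self) -> ProbabilityVector:
        return ProbabilityVector(self.col_labels, self.probs.sum(axis=0))

    def transposed(self) -> "JointProbabilityTable":
        return JointProbabilityTable(self.col_labels, self.row_labels, self.probs.T)


@dataclass(frozen=True)
class PrefixCode:
    """Bit lengths of a prefix-free (instantaneous) binary code.

    The lengths must satisfy the Kraft inequality
    ``sum_i 2**(-length_i) <= 1``; by the Kraft-McMillan theorem this is
    exactly the condition for a prefix code with those lengths to exist.
    """

    labels: tuple[str, ...]
    code_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        lengths = tuple(int(x) for x in self.code_lengths)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "code_lengths", lengths)
        if len(labels) != len(lengths):
            raise ValidationError("need one code length per label")
        if len(set(labels)) != len(labels):
            raise ValidationError("labels must be unique")
        if any(l <= 0 for l in lengths):
            raise ValidationError("code lengths must be positive integers")
        kraft = sum(2.0 ** (-l) for l in lengths)
        if kraft > 1.0 + 1e-12:
            raise ValidationError(
                f"code lengths violate the Kraft inequality (sum 2^-l = {kraft:g} > 1); "
                "no prefix code with these lengths exists"
            )


def entropy(p: ProbabilityVector, base: float = 2.0) -> float:
    """Shannon entropy ``H(X) = -sum_i p_i log p_i``.

    For an M-category distribution the result lies in ``[0, log M]``:
    zero for a point mass, ``log M`` for the uniform distribution.
    """
    probs = p.probs
    nz = probs > 0
    return float(-(probs[nz] * _log(probs[nz], base)).sum())


def joint_entropy(j: JointProbabilityTable, base: float = 2.0) -> float:
    """Joint entropy ``H(X, Y)``: entropy of the flattened joint table."""
    probs = j.probs.ravel()
    nz = probs > 0
    return float(-(probs[nz] * _log(probs[nz], base)).sum())


def conditional_entropy(
    j: JointProbabilityTable, given: str = "cols", base: float = 2.0
) -> float:
    """Conditional entropy of one variable given the other.

    ``given="cols"`` returns H(rows | cols); ``given="rows"`` returns
    H(cols | rows).  Computed by direct summation of
    ``-sum f(x, y) log f(x | y)``; cells in zero-probability slices of the
    conditioning variable carry no joint mass and are skipped.  Satisfies
    the chain rule ``H(X | Y) = H(X, Y) - H(Y)``.
    """
    if given == "rows":
        j = j.transposed()
    elif given != "cols":
        raise ValidationError(f"axis selector must be 'rows' or 'cols', got {given!r}")
    joint = j.probs
    col = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(col > 0, joint / np.where(col > 0, col, 1.0), 0.0)
    nz = joint > 0
    return float(-(joint[nz] * _log(cond[nz], base)).sum())


def mutual_information(j: JointProbabilityTable, base: float = 2.0) -> float:
    """Mutual information ``I(X; Y) = H(X) + H(Y) - H(X, Y)``.

    Non-negative, symmetric in the two variables, and zero exactly when the
    joint factorizes into its marginals.
    """
    return (
        entropy(j.row_marginal(), base)
        + entropy(j.col_marginal(), base)
        - joint_entropy(j, base)
    )


def _check_common_labels(g: ProbabilityVector, f: ProbabilityVector) -> None:
    if g.labels != f.labels:
        if set(g.labels) == set(f.labels):
            raise ValidationError(
                "distributions share labels but in different orders; "
                "use .reordered() to align them"
            )
        raise ValidationError(
            f"label sets differ: {sorted(set(g.labels) ^ set(f.labels))}"
        )


def relative_entropy(
    g: ProbabilityVector, f: ProbabilityVector, base: float = 2.0
) -> float:
    """Relative entropy (Kullback-Leibler divergence) ``D(g || f)``.

    The expected extra code length, in bits, paid when outcomes drawn from
    ``g`` are encoded with a code optimal for ``f``:
    ``sum_i g_i log(g_i / f_i)``.  Non-negative (Gibbs' inequality), zero
    iff ``g == f``, and asymmetric in its arguments.

    Raises
    ------
    DomainError
        If ``g`` places mass on a label where ``f`` has none — the
        divergence is infinite.  The offending label is named.
    """
    _check_common_labels(g, f)
    gp, fp = g.probs, f.probs
    support = gp > 0
    bad = support & (fp == 0)
    if np.any(bad):
        label = g.labels[int(np.argmax(bad))]
        raise DomainError(
            f"D(g || f) is infinite: g has mass at label {label!r} where f has none"
        )
    return float((gp[support] * _log(gp[support] / fp[support], base)).sum())


def jeffreys_divergence(
    g: ProbabilityVector, f: ProbabilityVector, base: float = 2.0
) -> float:
    """Jeffreys divergence ``J(g; f) = D(g || f) + D(f || g)``.

    The symmetrized sum of the two directed relative entropies.  Finite only
    when the two distributions share support.
    """
    return relative_entropy(g, f, base) + relative_entropy(f, g, base)


def jsd_distributions(
    dists: Sequence[ProbabilityVector],
    weights: Sequence[float] | None = None,
    base: float = 2.0,
) -> float:
    """Jensen-Shannon divergence of N distributions on a common label set.

    The mixture ``m = sum_k w_k f_k`` is formed first and the divergence is
    the weighted average relative entropy from the mixture to each
    component, ``sum_k w_k D(f_k || m)``.  With the default uniform weights
    — the convention used throughout this package's balance reports — the
    result lies in ``[0, log N]``.  Always finite: the mixture's support
    covers each component's support by construction.

    Parameters
    ----------
    dists
        At least two distributions over the same ordered label set.
    weights
        Optional positive mixture weights summing to 1.  Uniform ``1/N``
        when omitted.  Weighted JSD is an extension; reported balance
        statistics use the unweighted form only.
    """
    if len(dists) < 2:
        raise ValidationError("JSD needs at least 2 distributions")
    ref = dists[0]
    for d in dists[1:]:
        _check_common_labels(d, ref)
    n = len(dists)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != n:
            raise ValidationError("need one weight per distribution")
        if np.any(w <= 0):
            raise ValidationError("weights must be positive")
        if abs(w.sum() - 1.0) > NORMALIZATION_TOL:
            raise ValidationError(f"weights sum to {w.sum()!r}, not 1")
    stacked = np.stack([d.probs for d in dists])  # (N, M)
    mixture = w @ stacked
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.where(stacked > 0, stacked / mixture, 1.0)
    terms = np.where(stacked > 0, stacked * _log(logratio, base), 0.0)
    return float((w[:, None] * terms).sum())


def expected_code_length(
    p: ProbabilityVector, code: PrefixCode, outcomes_per_codeword: int = 1
) -> float:
    """Expected code length, in bits per outcome, of a prefix code under p.

    ``sum_i p_i * length_i / outcomes_per_codeword``.  For a block code the
    distribution ``p`` is over blocks and ``outcomes_per_codeword`` is the
    block size; the result is then per original outcome.  Shannon's
    source-coding bound guarantees the result is at least the per-outcome
    entropy for every Kraft-valid code.
    """
    if outcomes_per_codeword < 1:
        raise ValidationError("outcomes_per_codeword must be a positive integer")
    if p.labels != code.labels:
        raise ValidationError(
            "distribution and code must be defined over the same ordered labels"
        )
    lengths = np.asarray(code.code_lengths, dtype=float)
    return float((p.probs * lengths).sum()) / outcomes_per_codeword
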