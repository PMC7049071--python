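"""Synthetic fixture generator.

Produces reproducible subject-level data in the two shapes the balance
machinery consumes: multinomial draws of a categorical covariate per
treatment group, and Gaussian-mixture samples of a continuous covariate per
group.  The mixture presets reproduce the canonical pathologies of the
standardized difference score — pairs of groups whose means coincide (so
the score is near zero) while the distributions plainly differ in spread,
skew, or modality.

All randomness flows through ``numpy.random.default_rng`` (the PCG64 bit
generator); a fixed seed fixes the entire output stream, and the generator
name is recorded in the fixture metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .balance import BalanceTable
from .exceptions import ValidationError
from .io import LongRecords

__all__ = [
    "FixtureSpec",
    "MixtureComponent",
    "generate_fixture",
    "generate_counts",
    "preset",
    "PRESET_NAMES",
]

PRNG_ALGORITHM = "numpy PCG64 (default_rng)"


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mu: float
    sigma: float


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic dataset.

    ``mode="multinomial"``: each entry of ``groups`` maps a group name to
    ``{level: probability}``; ``mode="gaussian_mixture"``: each entry maps a
    group name to a sequence of :class:`MixtureComponent` whose weights sum
    to 1.  ``n_per_group`` subjects are drawn per group with the given seed.
    """

    mode: str
    groups: Mapping[str, object]
    n_per_group: int
    seed: int
    metadata: dict = field(default_factory=lambda: {"prng": PRNG_ALGORITHM})

    def __post_init__(self) -> None:
        if self.mode not in ("multinomial", "gaussian_mixture"):
            raise ValidationError(f"unknown fixture mode {self.mode!r}")
        if len(self.groups) < 2:
            raise ValidationError("need at least 2 groups")
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be positive")
        for name, spec in self.groups.items():
            if self.mode == "multinomial":
                probs = np.array(list(spec.values()), dtype=float)
                if np.any(probs <= 0):
                    raise ValidationError(
                        f"group {name!r}: level probabilities must be positive"
                    )
                if abs(probs.sum() - 1.0) > 1e-9:
                    raise ValidationError(
                        f"group {name!r}: level probabilities sum to {probs.sum()!r}"
                    )
            else:
                weights = np.array([c.weight for c in spec], dtype=float)
                if np.any(weights <= 0):
                    raise ValidationError(
                        f"group {name!r}: component weights must be positive"
                    )
                if abs(weights.sum() - 1.0) > 1e-9:
                    raise ValidationError(
                        f"group {name!r}: component weights sum to {weights.sum()!r}"
                    )
                if any(c.sigma <= 0 for c in spec):
                    raise ValidationError(f"group {name!r}: sigmas must be positive")


def generate_counts(spec: FixtureSpec) -> BalanceTable:
    """Draw a multinomial fixture directly as a contingency table.

    Equivalent to tabulating :func:`generate_fixture` output but without
    materializing per-subject rows — the natural path for large ``n``.
    """
    if spec.mode != "multinomial":
        raise ValidationError("generate_counts applies to multinomial fixtures only")
    rng = np.random.default_rng(spec.seed)
    levels: list[str] = list(next(iter(spec.groups.values())))
    for name, probs in spec.groups.items():
        if list(probs) != levels:
            raise ValidationError(
                f"group {name!r} uses a different level set or order"
            )
    counts = np.column_stack(
        [
            rng.multinomial(spec.n_per_group, np.array(list(probs.values()), float))
            for probs in spec.groups.values()
        ]
    )
    return BalanceTable(tuple(levels), tuple(spec.groups), counts)


def generate_fixture(spec: FixtureSpec) -> LongRecords:
    """Draw subject-level records from a fixture recipe.

    Reproducible: the same spec (including seed) yields identical records.
    Multinomial mode emits categorical records in level order within each
    group; gaussian_mixture mode emits real-valued records.
    """
    rng = np.random.default_rng(spec.seed)
    groups: list[str] = []
    values: list = []
    if spec.mode == "multinomial":
        for name, probs in spec.groups.items():
            level_names = list(probs)
            counts = rng.multinomial(
                spec.n_per_group, np.array(list(probs.values()), float)
            )
            for level, c in zip(level_names, counts):
                groups.extend([name] * int(c))
                values.extend([level] * int(c))
        return LongRecords(tuple(groups), tuple(values), kind="categorical")
    for name, components in spec.groups.items():
        weights = np.array([c.weight for c in components], float)
        idx = rng.choice(len(components), size=spec.n_per_group, p=weights)
        mus = np.array([c.mu for c in components])[idx]
        sigmas = np.array([c.sigma for c in components])[idx]
        draws = rng.normal(mus, sigmas)
        groups.extend([name] * spec.n_per_group)
        values.extend(float(v) for v in draws)
    return LongRecords(tuple(groups), tuple(values), kind="continuous")


# Continuous two-group scenarios.  All but location-shift have matched group
# means, so their standardized difference converges to zero while the JSD
# stays bounded away from it.
_PRESETS: dict[str, dict[str, tuple[MixtureComponent, ...]]] = {
    "location-shift": {
        "A": (MixtureComponent(1.0, 0.0, 1.0),),
        "B": (MixtureComponent(1.0, 1.0, 1.0),),
    },
    "scale-difference": {
        "A": (MixtureComponent(1.0, 0.0, 1.0),),
        "B": (MixtureComponent(1.0, 0.0, 3.0),),
    },
    "skew-mirror": {
        # mirrored two-component mixtures, both with mean 0
        "A": (
            MixtureComponent(0.75, -0.5, 0.5),
            MixtureComponent(0.25, 1.5, 1.0),
        ),
        "B": (
            MixtureComponent(0.75, 0.5, 0.5),
            MixtureComponent(0.25, -1.5, 1.0),
        ),
    },
    "bimodal-vs-unimodal": {
        # matched means (0) and near-matched variances
        "A": (
            MixtureComponent(0.5, -2.0, 0.7),
            MixtureComponent(0.5, 2.0, 0.7),
        ),
        "B": (MixtureComponent(1.0, 0.0, 2.12),),
    },
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, n_per_group: int = 10_000, seed: int = 0) -> FixtureSpec:
    """A named two-group Gaussian-mixture scenario as a FixtureSpec."""
    if name not in _PRESETS:
        raise ValidationError(
            f"unknown preset {name!r} (choose from {list(_PRESETS)})"
        )
    return FixtureSpec(
        mode="gaussian_mixture",
        groups=_PRESETS[name],
        n_per_group=n_per_group,
        seed=seed,
    )
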