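"""Synthetic fixtures: importance vectors and classification datasets.

Every test input of the package is generated here, deterministically from
a seed.  Importance vectors come either from explicit value tiers (e.g.
"2 dominant, 8 helpful, 90 near-zero") or from a named benchmark
distribution.  Classification datasets are Gaussian noise matrices in
which the informative features are shifted between classes by a stated
standardized effect size; the remaining features are pure noise and hence
exchangeable with permuted labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .benchmarks import DISTRIBUTIONS
from .core import ItemSet
from .errors import ConfigError
from .pipeline import Dataset

__all__ = ["FixtureSpec", "generate_fixture", "tiered_items",
           "classification_dataset"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic test input.

    For ``kind="importance_vector"`` give either ``tiers`` — a sequence of
    ``(count, low, high)`` value ranges — or ``distribution`` (a benchmark
    distribution name) plus ``n_items``.  For ``kind="classification_dataset"``
    give the dataset geometry and the per-feature effect size (standardized
    mean difference between the two classes on informative features).
    """

    kind: str
    seed: int = 0
    # importance vectors
    tiers: Optional[tuple] = None
    distribution: Optional[str] = None
    n_items: int = 100
    # classification datasets
    n_cases: int = 100
    n_features: int = 20
    n_informative: int = 2
    effect_size: float = 1.0
    class_balance: float = 0.5

    def __post_init__(self):
        if self.kind not in ("importance_vector", "classification_dataset"):
            raise ConfigError(f"unknown fixture kind {self.kind!r}")
        if self.kind == "importance_vector":
            if (self.tiers is None) == (self.distribution is None):
                raise ConfigError(
                    "give exactly one of tiers= or distribution=")
            if self.distribution is not None \
                    and self.distribution not in DISTRIBUTIONS:
                raise ConfigError(
                    f"unknown distribution {self.distribution!r}")
            if self.tiers is not None:
                object.__setattr__(self, "tiers",
                                   tuple(tuple(t) for t in self.tiers))
        else:
            if self.n_informative > self.n_features:
                raise ConfigError("n_informative must be <= n_features")
            if self.effect_size < 0:
                raise ConfigError("effect_size must be >= 0")
            if not 0.0 < self.class_balance < 1.0:
                raise ConfigError("class_balance must be in (0, 1)")


def tiered_items(tiers: Sequence, seed: int = 0) -> ItemSet:
    """Importance vector from ``(count, low, high)`` tiers, largest first."""
    rng = np.random.default_rng(seed)
    chunks = [rng.uniform(lo, hi, int(cnt)) for cnt, lo, hi in tiers]
    return ItemSet.from_values(np.concatenate(chunks))


def classification_dataset(n_cases: int, n_features: int, n_informative: int,
                           effect_size: float, class_balance: float = 0.5,
                           seed: int = 0) -> Dataset:
    """Two-class Gaussian dataset with planted informative features.

    All features are N(0, 1) noise; in class 1 the first ``n_informative``
    features are shifted by ``effect_size`` standard deviations.
    """
    rng = np.random.default_rng(seed)
    n1 = max(2, int(round(class_balance * n_cases)))
    n1 = min(n1, n_cases - 2)
    y = np.array([1] * n1 + [0] * (n_cases - n1))
    X = rng.standard_normal((n_cases, n_features))
    X[y == 1, :n_informative] += effect_size
    perm = rng.permutation(n_cases)
    names = tuple(
        [f"signal{i + 1}" for i in range(n_informative)]
        + [f"noise{i + 1}" for i in range(n_features - n_informative)]
    )
    return Dataset(X[perm], y[perm], names)


def generate_fixture(spec: FixtureSpec):
    """Materialize a fixture; byte-identical for identical specs."""
    if spec.kind == "importance_vector":
        if spec.tiers is not None:
            return tiered_items(spec.tiers, seed=spec.seed)
        rng = np.random.default_rng(spec.seed)
        values = DISTRIBUTIONS[spec.distribution](rng, spec.n_items)
        return ItemSet.from_values(values)
    return classification_dataset(spec.n_cases, spec.n_features,
                                  spec.n_informative, spec.effect_size,
                                  spec.class_balance, seed=spec.seed)
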