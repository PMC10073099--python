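"""Recursive computed ABC analysis.

cABC analysis applied again to the previous subset "A" produces nested
sets "A", "AA", "AAA", ... of increasingly important items.  The recursion
terminates on one of:

* **uniform_distribution** — the candidate item list is compatible with a
  uniform distribution (one-sample Kolmogorov–Smirnov test, p > alpha).
  The uniform distribution is a fixed point of ABC analysis: any compact
  subset of a uniform sample is again uniform, and each further level
  would merely keep the top ~41% of items.
* **target_size_reached** — the candidate set is already at or below a
  contextual target size (e.g. the Miller 7+/-2 working-memory band).
* **max_depth** — a configured depth cap.
* **no_shrinkage** / **too_few_items** — structural stops: the partition
  no longer shrinks "A", or fewer than three items remain.

Classifier-performance stopping (the remaining criterion used in feature
selection) is injected by the pipeline layer through ``level_callback``;
this module is classifier-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional

import numpy as np
from scipy import stats

from .core import ABCPartition, ItemSet, partition
from .errors import ConfigError

__all__ = [
    "RecursionConfig",
    "RecursionLevel",
    "RecursionTrace",
    "UniformityResult",
    "ks_uniformity_test",
    "recursive_cabc",
]


class UniformityResult(NamedTuple):
    statistic: float
    p_value: float
    identical: bool  # all values numerically equal (identity, not uniform)


def ks_uniformity_test(values) -> UniformityResult:
    """One-sample Kolmogorov–Smirnov test against Uniform(min(x), max(x)).

    The uniform bounds are estimated from the sample itself, so the
    p-values are approximate; decisions close to the significance level
    should not be over-interpreted.  All-identical values form the
    *identity* distribution, which is not uniform: the test then reports
    ``p = 0`` with ``identical=True``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("uniformity test needs at least 3 values")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return UniformityResult(1.0, 0.0, True)
    res = stats.kstest(x, stats.uniform(loc=lo, scale=hi - lo).cdf)
    return UniformityResult(float(res.statistic), float(res.pvalue), False)


_UNIFORMITY_TESTS = {"ks": ks_uniformity_test}


@dataclass
class RecursionConfig:
    """Configuration of the recursive cABC analysis.

    Parameters
    ----------
    alpha
        Significance level of the uniformity stopping test; the recursion
        stops when the candidate list's p-value exceeds it.
    target_size
        Optional contextual stop: halt when the candidate set has at most
        this many items.  :meth:`miller` presets the upper edge of the
        7 +/- 2 band.
    max_depth
        Optional cap on the number of partition levels.
    uniformity_test
        Name of the registered uniformity test ("ks") or a callable
        ``values -> UniformityResult``.
    defer_uniformity
        If True, skip the uniformity check for the initial input and apply
        it only from the second level on (forces at least one split on
        uniform input).
    partition_options
        Keyword arguments forwarded to :func:`cabc.core.partition`.
    level_callback
        Optional ``RecursionLevel -> bool`` hook evaluated after each
        level; returning False stops the recursion with reason
        ``callback_stop``.  Used by the feature-selection pipeline for the
        classifier-performance criterion.
    """

    alpha: float = 0.05
    target_size: Optional[int] = None
    max_depth: Optional[int] = None
    uniformity_test: object = "ks"
    defer_uniformity: bool = False
    partition_options: dict = field(default_factory=dict)
    level_callback: Optional[Callable] = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.target_size is not None and self.target_size < 1:
            raise ConfigError("target_size must be >= 1")
        if self.max_depth is not None and self.max_depth < 0:
            raise ConfigError("max_depth must be >= 0")

    @classmethod
    def miller(cls, **kwargs) -> "RecursionConfig":
        """Preset stopping at the Miller 7 +/- 2 working-memory band."""
        kwargs.setdefault("target_size", 9)
        return cls(**kwargs)

    def _test(self) -> Callable:
        if callable(self.uniformity_test):
            return self.uniformity_test
        try:
            return _UNIFORMITY_TESTS[self.uniformity_test]
        except KeyError:
            raise ConfigError(
                f"unknown uniformity test {self.uniformity_test!r}") from None


@dataclass(frozen=True)
class RecursionLevel:
    """One level of the recursion: input list, its uniformity, its partition."""

    name: str                       # "A", "AA", "AAA", ... (the level's output)
    input_labels: tuple
    uniformity: Optional[UniformityResult]  # test of the level's *input* list
    partition: ABCPartition

    @property
    def set_a(self) -> tuple:
        return self.partition.set_a


@dataclass(frozen=True)
class RecursionTrace:
    """Full record of a recursive cABC analysis."""

    levels: tuple
    stop_reason: str
    final_set: tuple        # labels of the innermost "A" (or the input if depth 0)
    final_name: str         # "", "A", "AA", ... by depth
    final_uniformity: Optional[UniformityResult]
    alpha: float

    @property
    def depth(self) -> int:
        return len(self.levels)

    def level_sets(self) -> list:
        """Per-level "A" label tuples, outermost first."""
        return [lvl.set_a for lvl in self.levels]

    def to_dict(self) -> dict:
        def _uni(u):
            if u is None:
                return None
            return {"statistic": u.statistic, "p_value": u.p_value,
                    "identical": u.identical}

        return {
            "schema_version": 1,
            "alpha": self.alpha,
            "stop_reason": self.stop_reason,
            "final_set": list(self.final_set),
            "final_name": self.final_name,
            "final_uniformity": _uni(self.final_uniformity),
            "levels": [
                {
                    "name": lvl.name,
                    "input_labels": list(lvl.input_labels),
                    "uniformity": _uni(lvl.uniformity),
                    "partition": lvl.partition.to_dict(),
                }
                for lvl in self.levels
            ],
        }


STOP_REASONS = ("uniform_distribution", "target_size_reached", "max_depth",
                "no_shrinkage", "too_few_items", "callback_stop")


def recursive_cabc(items: ItemSet, config: RecursionConfig | None = None) -> RecursionTrace:
    """Apply cABC analysis recursively to successive "A" subsets.

    Before each level the candidate input is screened against the
    termination criteria (size, uniformity, depth); if none fires, the
    candidate is partitioned and its subset "A" becomes the next input.
    Every level is recorded.  Because each "A" is a strict subset, the
    recursion terminates after at most O(log n) levels.
    """
    if config is None:
        config = RecursionConfig()
    test = config._test()

    current = items
    levels: list[RecursionLevel] = []
    stop = None
    final_uni = None

    while True:
        depth = len(levels)
        if current.n < 3:
            stop = "too_few_items"
            break
        uni = None
        if not (config.defer_uniformity and depth == 0):
            uni = test(current.values)
            if uni.p_value > config.alpha:
                stop = "uniform_distribution"
                final_uni = uni
                break
        if config.target_size is not None and current.n <= config.target_size:
            stop = "target_size_reached"
            final_uni = uni
            break
        if config.max_depth is not None and depth >= config.max_depth:
            stop = "max_depth"
            final_uni = uni
            break
        part = partition(current, **config.partition_options)
        level = RecursionLevel(name="A" * (depth + 1),
                               input_labels=tuple(current.labels),
                               uniformity=uni, partition=part)
        levels.append(level)
        if len(part.set_a) >= current.n:
            stop = "no_shrinkage"
            break
        next_items = current.subset(part.set_a)
        if config.level_callback is not None and not config.level_callback(level):
            stop = "callback_stop"
            current = next_items
            break
        current = next_items

    final_set = tuple(current.labels) if not levels else levels[-1].set_a
    # on structural stops after a recorded level, the final set is that level's A;
    # on a depth-0 stop it is the untouched input
    if stop in ("no_shrinkage", "callback_stop") and levels:
        final_set = levels[-1].set_a
    return RecursionTrace(levels=tuple(levels), stop_reason=stop,
                          final_set=final_set, final_name="A" * len(levels),
                          final_uniformity=final_uni, alpha=config.alpha)
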