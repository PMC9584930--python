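"""Experiment layouts for trait-learning tasks.

An :class:`ExperimentDesign` describes one behavioural experiment: the set of
trait items, the Big-Five factor each item belongs to, the integer rating
scale, and how many profiles (runs) a participant learns about.  Each run
presents every item exactly once in a random order, so the number of trials
per run equals the number of items.

Five presets mirror the layouts of the published experiments:

========  =====================  =======  ========  =======
preset    items                  factors  profiles  scale
========  =====================  =======  ========  =======
exp1      60 trait adjectives    5        4         1-8
exp2      60 traits (2 factors)  2        4         1-8
exp3      60 traits (2 factors)  2        4         1-8
exp4      60 trait adjectives    5        4         1-8
exp5      50 IPIP statements     5        5         1-5
========  =====================  =======  ========  =======

exp1/exp4 use unequal item counts per factor (19, 13, 10, 10, 8);
exp2/exp3 use two factors with 30 items each; exp5 has 10 items per factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

BIG_FIVE = (
    "agreeableness",
    "conscientiousness",
    "extraversion",
    "neuroticism",
    "openness",
)

#: Items per Big-Five factor in the exp1/exp4 layout (min 8, max 19).
EXP1_FACTOR_COUNTS = (19, 13, 10, 10, 8)

PRESETS = ("exp1", "exp2", "exp3", "exp4", "exp5")


@dataclass(frozen=True)
class ExperimentDesign:
    """Immutable description of one experiment's stimulus layout."""

    item_ids: tuple[str, ...]
    factor_of: Mapping[str, str]
    scale_min: int
    scale_max: int
    n_profiles: int
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be below scale_max")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item ids")
        missing = [i for i in self.item_ids if i not in self.factor_of]
        if missing:
            raise ValueError(f"items without a factor label: {missing}")
        if self.n_profiles < 1:
            raise ValueError("n_profiles must be positive")

    # -- derived layout ----------------------------------------------------
    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def n_trials_per_run(self) -> int:
        # each item is presented exactly once per run
        return self.n_items

    @property
    def factors(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for i in self.item_ids:
            seen.setdefault(self.factor_of[i], None)
        return tuple(seen)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def factor_index(self) -> np.ndarray:
        """Integer factor label per item, aligned with ``item_ids``."""
        order = {f: k for k, f in enumerate(self.factors)}
        return np.array([order[self.factor_of[i]] for i in self.item_ids])

    @property
    def scale_mid(self) -> float:
        return (self.scale_min + self.scale_max) / 2.0

    def item_index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item {item_id!r}") from None

    def random_order(self, rng: np.random.Generator) -> np.ndarray:
        """One run's presentation order: a permutation of all item indices."""
        return rng.permutation(self.n_items)


def _layout(
    name: str,
    factors: Sequence[str],
    counts: Sequence[int],
    scale: tuple[int, int],
    n_profiles: int,
    prefix: str = "item",
) -> ExperimentDesign:
    ids, fmap = [], {}
    k = 0
    for factor, count in zip(factors, counts):
        for _ in range(count):
            k += 1
            iid = f"{prefix}{k:02d}"
            ids.append(iid)
            fmap[iid] = factor
    return ExperimentDesign(
        item_ids=tuple(ids),
        factor_of=fmap,
        scale_min=scale[0],
        scale_max=scale[1],
        n_profiles=n_profiles,
        name=name,
    )


def build_design(preset: str | Mapping = "exp1") -> ExperimentDesign:
    """Build an :class:`ExperimentDesign` from a preset name or a config dict.

    A config dict must provide ``items`` (mapping item id -> factor label),
    ``scale_min``, ``scale_max`` and ``n_profiles``; ``n_trials_per_run``, if
    given, must equal the item count.
    """
    if isinstance(preset, str):
        if preset in ("exp1", "exp4"):
            return _layout(preset, BIG_FIVE, EXP1_FACTOR_COUNTS, (1, 8), 4)
        if preset in ("exp2", "exp3"):
            return _layout(preset, BIG_FIVE[:2], (30, 30), (1, 8), 4)
        if preset == "exp5":
            return _layout(preset, BIG_FIVE, (10,) * 5, (1, 5), 5, prefix="ipip")
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")

    cfg = dict(preset)
    items = cfg["items"]
    n_trials = cfg.get("n_trials_per_run")
    if n_trials is not None and n_trials != len(items):
        raise ValueError(
            f"n_trials_per_run ({n_trials}) must equal the item count ({len(items)})"
        )
    return ExperimentDesign(
        item_ids=tuple(items),
        factor_of=dict(items),
        scale_min=int(cfg["scale_min"]),
        scale_max=int(cfg["scale_max"]),
        n_profiles=int(cfg.get("n_profiles", 1)),
        name=str(cfg.get("name", "custom")),
    )
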