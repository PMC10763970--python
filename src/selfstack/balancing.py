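"""Class selection and keep-first-N down-sampling.

Severely imbalanced cohorts (the thyroid table has 6771 healthy records
against 233 primary-hypothyroid ones) are balanced by keeping, for every
class with enough support, the first N records in file order and dropping
the rest.  The procedure is deterministic: no shuffling, no sampling.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .data_io import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "BalanceConfig",
    "BalancePlan",
    "class_counts",
    "select_classes",
    "downsample_first_n",
    "balance_cohort",
]


@dataclass(frozen=True)
class BalanceConfig:
    """Defaults follow the study conditions: classes with at least 200
    records are retained and each is cut to its first 230 records."""

    min_class_size: int = 200
    per_class_n: int = 230

    def __post_init__(self) -> None:
        if self.per_class_n < 1:
            raise ValueError("per_class_n must be >= 1")


@dataclass
class BalancePlan:
    """Audit record of a down-sampling run."""

    selected_classes: list[str]
    kept_indices: dict[str, list[int]]
    dropped_classes: list[tuple[str, str]] = field(default_factory=list)


def class_counts(cohort: Cohort) -> dict[str, int]:
    """Label -> record count, ordered by descending count then label."""
    counts = Counter(cohort.labels())
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def select_classes(cohort: Cohort, min_class_size: int = 200) -> list[str]:
    """Classes with at least ``min_class_size`` records, most frequent first."""
    return [c for c, k in class_counts(cohort).items() if k >= min_class_size]


def downsample_first_n(
    cohort: Cohort,
    classes: list[str],
    n: int = 230,
    allow_short: bool = False,
) -> tuple[Cohort, BalancePlan]:
    """Keep the first ``n`` records (file order) of each named class.

    Rows of unselected classes are dropped; the relative order of kept rows
    is preserved.  A class with fewer than ``n`` records raises unless
    ``allow_short`` is set, in which case all its records are kept and a
    warning is logged — silent truncation never happens.
    """
    counts = class_counts(cohort)
    for c in classes:
        have = counts.get(c, 0)
        if have < n and not allow_short:
            raise ValueError(
                f"class {c!r} has {have} records, fewer than the requested {n}"
            )
    wanted = set(classes)
    kept: dict[str, list[int]] = {c: [] for c in classes}
    order: list[int] = []
    for i, label in enumerate(cohort.labels()):
        if label in wanted and len(kept[label]) < n:
            kept[label].append(i)
            order.append(i)
    for c in classes:
        if len(kept[c]) < n:
            logger.warning(
                "class %r kept with only %d records (< %d)", c, len(kept[c]), n
            )
    plan = BalancePlan(selected_classes=list(classes), kept_indices=kept)
    return cohort.subset(order), plan


def balance_cohort(
    cohort: Cohort, config: BalanceConfig | None = None, allow_short: bool = False
) -> tuple[Cohort, BalancePlan]:
    """Select eligible classes then down-sample each to ``per_class_n``."""
    config = config or BalanceConfig()
    selected = select_classes(cohort, config.min_class_size)
    dropped = [
        (c, f"count {k} < min_class_size {config.min_class_size}")
        for c, k in class_counts(cohort).items()
        if k < config.min_class_size
    ]
    balanced, plan = downsample_first_n(
        cohort, selected, config.per_class_n, allow_short=allow_short
    )
    plan.dropped_classes = dropped
    for c, why in dropped:
        logger.info("dropped class %r: %s", c, why)
    return balanced, plan
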