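"""Child-report questionnaire scoring.

Scores the three instruments used alongside the preference task: the
Physical Self-Description Questionnaire short form (PSDQ-S; 40 items on
a 1-6 scale, 11 subscales), the Body Esteem Scale (BES; 23 items on a
1-5 scale, 3 subscales) and the Mood and Feelings Questionnaire short
version (MFQ; 13 items scored 0-2 and summed, total 0-26).

Item-to-subscale assignments and reversal keys for the PSDQ-S and BES
are the instruments' copyrighted scoring keys and are therefore shipped
as *skeleton* definitions: subscales are declared but their item maps
must be supplied from the source publications before scoring.  The MFQ
is a single summed total and ships complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence


class UnconfiguredScaleError(ValueError):
    """Scoring was attempted against a skeleton lacking its item map."""


@dataclass(frozen=True)
class ScaleDefinition:
    """Structure of one questionnaire.

    Items are numbered 1..n_items.  ``subscales`` maps each subscale
    name to its member item numbers (empty tuple = declared but
    unconfigured).  ``reversed_items`` are re-coded as
    ``min + max - response`` before aggregation, which is the mean of
    member items for Likert scales or their sum when ``aggregate`` is
    ``"sum"``.
    """

    name: str
    n_items: int
    response_min: int
    response_max: int
    subscales: Mapping[str, tuple[int, ...]]
    reversed_items: tuple[int, ...] = ()
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.response_min >= self.response_max:
            raise ValueError("response_min must be < response_max")
        if self.aggregate not in ("mean", "sum"):
            raise ValueError("aggregate must be 'mean' or 'sum'")
        for items in list(self.subscales.values()) + [self.reversed_items]:
            for i in items:
                if not 1 <= i <= self.n_items:
                    raise ValueError(f"item {i} outside 1..{self.n_items}")

    @property
    def configured(self) -> bool:
        return all(items for items in self.subscales.values())

    def with_item_map(
        self,
        subscales: Mapping[str, Sequence[int]],
        reversed_items: Sequence[int] = (),
    ) -> "ScaleDefinition":
        """Fill in the item map of a skeleton; subscale names must match."""
        if set(subscales) != set(self.subscales):
            raise ValueError(
                f"subscale names must be exactly {sorted(self.subscales)}"
            )
        return replace(
            self,
            subscales={k: tuple(v) for k, v in subscales.items()},
            reversed_items=tuple(reversed_items),
        )


@dataclass(frozen=True)
class ScaleResponse:
    """One child's item responses; ``None`` marks a missing item."""

    participant_id: str
    items: tuple[int | None, ...]


def score_scale(
    definition: ScaleDefinition,
    response: ScaleResponse,
    min_coverage: float = 0.8,
) -> dict[str, float]:
    """Score every subscale of a questionnaire for one respondent.

    Reversed items are re-coded first.  A subscale is scored when at
    least ``min_coverage`` of its items are present; mean scores use the
    present items and summed scores are prorated by
    ``n_items / n_present``.  Below the coverage threshold the subscale
    scores NaN.
    """
    if not definition.configured:
        raise UnconfiguredScaleError(
            f"{definition.name}: item map not configured; supply the "
            "instrument's scoring key via with_item_map()"
        )
    if len(response.items) != definition.n_items:
        raise ValueError(
            f"expected {definition.n_items} items, got {len(response.items)}"
        )
    lo, hi = definition.response_min, definition.response_max
    coded: list[float | None] = []
    for idx, v in enumerate(response.items, start=1):
        if v is None:
            coded.append(None)
            continue
        if not lo <= v <= hi:
            raise ValueError(f"item {idx} response {v} outside [{lo}, {hi}]")
        coded.append(lo + hi - v if idx in definition.reversed_items else v)

    scores: dict[str, float] = {}
    for name, items in definition.subscales.items():
        present = [coded[i - 1] for i in items if coded[i - 1] is not None]
        if len(present) < min_coverage * len(items) or not present:
            scores[name] = math.nan
        elif definition.aggregate == "mean":
            scores[name] = sum(present) / len(present)
        else:
            scores[name] = sum(present) * len(items) / len(present)
    return scores


PSDQ_SUBSCALES = (
    "Health",
    "Coordination",
    "Activity",
    "Body Fat",
    "Sport",
    "Global Physical",
    "Appearance",
    "Strength",
    "Flexibility",
    "Endurance",
    "Global Esteem",
)

BES_SUBSCALES = ("Appearance", "Weight", "Attribution")


def builtin_definitions() -> dict[str, ScaleDefinition]:
    """Skeletons for PSDQ-S and BES, plus the complete MFQ definition."""
    return {
        "psdq_s": ScaleDefinition(
            name="psdq_s",
            n_items=40,
            response_min=1,
            response_max=6,
            subscales={s: () for s in PSDQ_SUBSCALES},
        ),
        "bes": ScaleDefinition(
            name="bes",
            n_items=23,
            response_min=1,
            response_max=5,
            subscales={s: () for s in BES_SUBSCALES},
        ),
        "mfq": ScaleDefinition(
            name="mfq",
            n_items=13,
            response_min=0,
            response_max=2,
            subscales={"Total": tuple(range(1, 14))},
            aggregate="sum",
        ),
    }
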