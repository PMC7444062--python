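"""Activity catalog and forced-choice trial schedule generation.

The task presents every unordered pair of activities from a catalog of 8
sedentary and 8 physical activities: 120 unique pairs, of which 64 are
cross-category (one sedentary vs one physical — the only pairs that enter
the bias score) and 28 + 28 are within-category.  Pairs are presented in
4 blocks of 30 with breaks between blocks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class Category(str, Enum):
    """Activity category: sedentary or physical."""

    SEDENTARY = "SEDENTARY"
    PHYSICAL = "PHYSICAL"


class PairType(str, Enum):
    """How a trial pair combines categories."""

    CROSS = "CROSS"
    WITHIN_SED = "WITHIN_SED"
    WITHIN_PA = "WITHIN_PA"


@dataclass(frozen=True)
class Activity:
    """A single leisure activity shown in the task.

    Parameters
    ----------
    id : str
        Short stable token (lower-snake), used as the key in all files.
    label : str
        Human-readable display name.
    category : Category
        SEDENTARY or PHYSICAL.
    """

    id: str
    label: str
    category: Category

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("activity id must be non-empty")
        object.__setattr__(self, "category", Category(self.category))


class InvalidCatalogError(ValueError):
    """Raised when a catalog cannot support pair enumeration."""


@dataclass(frozen=True)
class ActivityCatalog:
    """Ordered collection of activities with unique ids.

    Custom catalogs must contain at least two activities in each category
    so that both within-category pair types exist.
    """

    activities: tuple[Activity, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "activities", tuple(self.activities))
        ids = [a.id for a in self.activities]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidCatalogError(f"duplicate activity ids: {dupes}")
        for cat in Category:
            if sum(a.category == cat for a in self.activities) < 2:
                raise InvalidCatalogError(
                    f"catalog needs >=2 {cat.value} activities"
                )

    def __iter__(self):
        return iter(self.activities)

    def __len__(self) -> int:
        return len(self.activities)

    def by_id(self, activity_id: str) -> Activity:
        for a in self.activities:
            if a.id == activity_id:
                return a
        raise KeyError(f"unknown activity id: {activity_id!r}")

    def ids(self, category: Category | None = None) -> tuple[str, ...]:
        return tuple(
            a.id
            for a in self.activities
            if category is None or a.category == category
        )

    def category_of(self, activity_id: str) -> Category:
        return self.by_id(activity_id).category

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [a.id for a in self.activities],
                "label": [a.label for a in self.activities],
                "category": [a.category.value for a in self.activities],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ActivityCatalog":
        return cls(
            tuple(
                Activity(row.id, row.label, Category(row.category))
                for row in frame.itertuples(index=False)
            )
        )


_PHYSICAL = [
    ("ball_sports", "Ball sports"),
    ("biking", "Biking"),
    ("dancing", "Dancing"),
    ("gymnastics_tumbling", "Gymnastics/tumbling"),
    ("outdoor_play", "Outdoor play"),
    ("running", "Running"),
    ("swimming", "Swimming"),
    ("walking", "Walking"),
]

_SEDENTARY = [
    ("arts_and_crafts", "Arts and crafts"),
    ("board_games", "Board games"),
    ("tablet", "Tablet"),
    ("listening_to_music", "Listening to music"),
    ("reading", "Reading"),
    ("talking", "Talking"),
    ("watching_tv", "Watching TV"),
    ("video_games", "Video games"),
]


def build_default_catalog() -> ActivityCatalog:
    """Return the standard 16-activity catalog (8 physical, 8 sedentary)."""
    acts = [Activity(i, lab, Category.PHYSICAL) for i, lab in _PHYSICAL]
    acts += [Activity(i, lab, Category.SEDENTARY) for i, lab in _SEDENTARY]
    return ActivityCatalog(tuple(acts))


@dataclass(frozen=True)
class TrialPair:
    """One forced-choice pair with a materialized left/right placement."""

    pair_id: int
    left: str
    right: str
    pair_type: PairType

    def __post_init__(self) -> None:
        if self.left == self.right:
            raise ValueError("pair members must differ")
        object.__setattr__(self, "pair_type", PairType(self.pair_type))

    @property
    def members(self) -> frozenset[str]:
        return frozenset((self.left, self.right))

    def swapped(self) -> "TrialPair":
        return TrialPair(self.pair_id, self.right, self.left, self.pair_type)


def _pair_type(catalog: ActivityCatalog, a: str, b: str) -> PairType:
    ca, cb = catalog.category_of(a), catalog.category_of(b)
    if ca != cb:
        return PairType.CROSS
    if ca == Category.SEDENTARY:
        return PairType.WITHIN_SED
    return PairType.WITHIN_PA


def enumerate_pairs(catalog: ActivityCatalog) -> list[TrialPair]:
    """All unordered activity pairs, each exactly once.

    Pairs are ordered deterministically by the sorted (id, id) tuple and
    numbered sequentially from 1.  For a catalog with ``s`` sedentary and
    ``p`` physical activities this yields ``s*p`` cross-category,
    ``C(s,2)`` within-sedentary and ``C(p,2)`` within-physical pairs.
    """
    ids = sorted(a.id for a in catalog)
    pairs = []
    for k, (a, b) in enumerate(itertools.combinations(ids, 2), start=1):
        pairs.append(TrialPair(k, a, b, _pair_type(catalog, a, b)))
    return pairs


@dataclass(frozen=True)
class TrialSchedule:
    """Blocked, counterbalanced presentation order of all pairs."""

    blocks: tuple[tuple[TrialPair, ...], ...]
    seed: int

    @property
    def trials(self) -> tuple[TrialPair, ...]:
        return tuple(p for block in self.blocks for p in block)

    def __len__(self) -> int:
        return sum(len(b) for b in self.blocks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, block in enumerate(self.blocks, start=1):
            for ti, p in enumerate(block, start=1):
                rows.append(
                    (bi, ti, p.pair_id, p.left, p.right, p.pair_type.value)
                )
        return pd.DataFrame(
            rows,
            columns=[
                "block",
                "trial_index",
                "pair_id",
                "left_id",
                "right_id",
                "pair_type",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = -1) -> "TrialSchedule":
        blocks = []
        for _, grp in frame.sort_values(["block", "trial_index"]).groupby(
            "block", sort=True
        ):
            blocks.append(
                tuple(
                    TrialPair(
                        int(r.pair_id), r.left_id, r.right_id, PairType(r.pair_type)
                    )
                    for r in grp.itertuples(index=False)
                )
            )
        return cls(tuple(blocks), seed)


def make_schedule(
    pairs: Sequence[TrialPair],
    n_blocks: int = 4,
    seed: int = 0,
    catalog: ActivityCatalog | None = None,
) -> TrialSchedule:
    """Partition pairs into equal blocks and randomize presentation.

    Blocks are stratified by pair type (dealt round-robin from a shuffled
    stratum) so each block's composition is comparable — with the default
    catalog, 16 cross + 7 + 7 within-category pairs per block.  Within each
    block the order is shuffled.  Left/right placement is randomized with
    the sedentary member on the left for exactly half (±1) of the
    cross-category pairs.  The same seed reproduces the schedule bit for
    bit.

    Parameters
    ----------
    pairs : sequence of TrialPair
        Typically the output of :func:`enumerate_pairs`.
    n_blocks : int
        Number of blocks; the pair count must be divisible by it.
    seed : int
        Seed for all randomization.
    catalog : ActivityCatalog, optional
        Used to identify the sedentary member of cross pairs for side
        balancing; defaults to the standard catalog.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if len(pairs) % n_blocks != 0:
        raise ValueError(
            f"{len(pairs)} pairs cannot be split into {n_blocks} equal blocks"
        )
    if catalog is None:
        catalog = build_default_catalog()
    rng = np.random.default_rng(seed)

    # side assignment: balance sedentary-left count over CROSS pairs
    cross = [p for p in pairs if p.pair_type == PairType.CROSS]
    order = rng.permutation(len(cross))
    sed_left_ids = {
        cross[i].pair_id for i in order[: (len(cross) + 1) // 2]
    }
    placed: dict[int, TrialPair] = {}
    for p in pairs:
        if p.pair_type == PairType.CROSS:
            left_is_sed = catalog.category_of(p.left) == Category.SEDENTARY
            want_sed_left = p.pair_id in sed_left_ids
            placed[p.pair_id] = p if left_is_sed == want_sed_left else p.swapped()
        else:
            placed[p.pair_id] = p if rng.random() < 0.5 else p.swapped()

    # stratified deal into blocks, continuing round-robin across strata so
    # block sizes stay equal even when a stratum is not divisible
    blocks: list[list[TrialPair]] = [[] for _ in range(n_blocks)]
    cursor = 0
    for ptype in PairType:
        stratum = [p for p in pairs if p.pair_type == ptype]
        for i in rng.permutation(len(stratum)):
            blocks[cursor % n_blocks].append(placed[stratum[i].pair_id])
            cursor += 1

    shuffled = tuple(
        tuple(block[i] for i in rng.permutation(len(block))) for block in blocks
    )
    return TrialSchedule(shuffled, seed)
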