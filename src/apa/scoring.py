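"""Explicit (VAS) and implicit (forced-choice) preference scoring.

The implicit bias score integrates choices ("wins") and reaction times
over the 64 cross-category trials.  With WIN_SED / WIN_PA the number of
trials where the sedentary / physical option was selected, RT_ALL the
mean reaction time over all responded cross-category trials, and RT_SED /
RT_PA the mean over trials won by each category:

    IW_SED = WIN_SED * (RT_ALL / RT_SED) - WIN_PA * (RT_ALL / RT_PA)
    IW_PA  = WIN_PA  * (RT_ALL / RT_PA)  - WIN_SED * (RT_ALL / RT_SED)
    raw    = IW_SED - IW_PA

Fast, frequent choices of one category push the score toward that
category.  ``raw`` spans roughly [-2N, +2N] for N responded trials; the
published score spans -100..+100, so we normalize by ``100 / (2N)`` —
the mildest rescaling under which a respondent who always picks one
category at equal reaction times scores exactly +/-100 — and clip the
rare RT-driven overshoot to the printed range, flagging when clipping
occurred.  Positive scores indicate a relative preference for sedentary
activities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from apa.task_schedule import (
    ActivityCatalog,
    Category,
    PairType,
    TrialPair,
    build_default_catalog,
)

#: default reaction-time cleaning window, seconds
DEFAULT_MIN_RT = 0.2
DEFAULT_MAX_RT = 10.0


@dataclass(frozen=True)
class VASResponse:
    """One visual-analog-scale rating of a single activity (0-100)."""

    activity_id: str
    liking: float
    wanting: float

    def __post_init__(self) -> None:
        for name in ("liking", "wanting"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")


@dataclass(frozen=True)
class VASProfile:
    """Category-level means of the explicit liking/wanting ratings."""

    sed_liking: float
    pa_liking: float
    sed_wanting: float
    pa_wanting: float
    n_sed: int
    n_pa: int


@dataclass(frozen=True)
class TrialResponse:
    """One forced-choice trial outcome.

    ``chosen`` and ``rt`` are present iff the child responded; reaction
    time is in seconds.
    """

    pair_id: int
    chosen: str | None
    rt: float | None
    responded: bool = True

    def __post_init__(self) -> None:
        if self.responded:
            if self.chosen is None or self.rt is None:
                raise ValueError("responded trial needs chosen and rt")
            if self.rt <= 0:
                raise ValueError(f"rt must be positive, got {self.rt}")
        else:
            if self.chosen is not None or self.rt is not None:
                raise ValueError("non-response carries no chosen/rt")


@dataclass(frozen=True)
class CleaningReport:
    """Counts of trials removed by :func:`clean_trials`, by reason."""

    n_input: int
    n_retained: int
    n_nonresponse: int
    n_too_fast: int
    n_too_slow: int


@dataclass(frozen=True)
class ForcedChoiceSummary:
    """Win counts and RT means over responded cross-category trials.

    ``rt_sed`` / ``rt_pa`` are ``None`` when the corresponding win count
    is zero (the mean over an empty set is never evaluated).
    """

    win_sed: int
    win_pa: int
    rt_all: float
    rt_sed: float | None
    rt_pa: float | None

    @property
    def n_cross_responded(self) -> int:
        return self.win_sed + self.win_pa


@dataclass(frozen=True)
class BiasScore:
    """Implicit bias score; positive = sedentary-leaning, range -100..+100."""

    iw_sed: float
    iw_pa: float
    raw: float
    bias: float
    clipped: bool


class ScoreUndefinedError(ValueError):
    """Raised when zero responded cross-category trials leave no score."""


def summarize_vas(
    responses: Iterable[VASResponse],
    catalog: ActivityCatalog | None = None,
) -> VASProfile:
    """Average liking and wanting ratings within each activity category.

    Every rated activity must belong to the catalog and each category
    must have at least one rating.
    """
    if catalog is None:
        catalog = build_default_catalog()
    liking: dict[Category, list[float]] = {c: [] for c in Category}
    wanting: dict[Category, list[float]] = {c: [] for c in Category}
    for r in responses:
        cat = catalog.category_of(r.activity_id)  # KeyError on unknown id
        liking[cat].append(r.liking)
        wanting[cat].append(r.wanting)
    for cat in Category:
        if not liking[cat]:
            raise ValueError(f"no ratings for category {cat.value}")
    sed, pa = Category.SEDENTARY, Category.PHYSICAL
    return VASProfile(
        sed_liking=float(np.mean(liking[sed])),
        pa_liking=float(np.mean(liking[pa])),
        sed_wanting=float(np.mean(wanting[sed])),
        pa_wanting=float(np.mean(wanting[pa])),
        n_sed=len(liking[sed]),
        n_pa=len(liking[pa]),
    )


def clean_trials(
    trials: Iterable[TrialResponse],
    min_rt: float = DEFAULT_MIN_RT,
    max_rt: float = DEFAULT_MAX_RT,
    no_clean: bool = False,
) -> tuple[list[TrialResponse], CleaningReport]:
    """Drop non-responses and out-of-window reaction times.

    With ``no_clean=True`` only non-responses are removed and the RT
    window is ignored.
    """
    if min_rt >= max_rt:
        raise ValueError(f"min_rt={min_rt} must be < max_rt={max_rt}")
    trials = list(trials)
    kept: list[TrialResponse] = []
    n_nr = n_fast = n_slow = 0
    for t in trials:
        if not t.responded:
            n_nr += 1
        elif no_clean:
            kept.append(t)
        elif t.rt < min_rt:
            n_fast += 1
        elif t.rt > max_rt:
            n_slow += 1
        else:
            kept.append(t)
    return kept, CleaningReport(len(trials), len(kept), n_nr, n_fast, n_slow)


def summarize_forced_choice(
    trials: Iterable[TrialResponse],
    pairs: Sequence[TrialPair],
    catalog: ActivityCatalog | None = None,
) -> ForcedChoiceSummary:
    """Count category wins and average RTs over cross-category trials.

    Within-category trials in the log are ignored: only pairs with one
    sedentary and one physical member inform the bias score.  Raises
    :class:`ScoreUndefinedError` if no cross-category trial was responded.
    """
    if catalog is None:
        catalog = build_default_catalog()
    by_id = {p.pair_id: p for p in pairs}
    rts_all: list[float] = []
    rts_by_cat: dict[Category, list[float]] = {c: [] for c in Category}
    for t in trials:
        try:
            pair = by_id[t.pair_id]
        except KeyError:
            raise KeyError(f"trial references unknown pair_id {t.pair_id}")
        if pair.pair_type != PairType.CROSS or not t.responded:
            continue
        if t.chosen not in pair.members:
            raise ValueError(
                f"chosen {t.chosen!r} is not a member of pair {t.pair_id}"
            )
        cat = catalog.category_of(t.chosen)
        rts_all.append(t.rt)
        rts_by_cat[cat].append(t.rt)
    if not rts_all:
        raise ScoreUndefinedError(
            "no responded cross-category trials; bias score undefined"
        )
    sed_rts = rts_by_cat[Category.SEDENTARY]
    pa_rts = rts_by_cat[Category.PHYSICAL]
    return ForcedChoiceSummary(
        win_sed=len(sed_rts),
        win_pa=len(pa_rts),
        rt_all=float(np.mean(rts_all)),
        rt_sed=float(np.mean(sed_rts)) if sed_rts else None,
        rt_pa=float(np.mean(pa_rts)) if pa_rts else None,
    )


def compute_bias(summary: ForcedChoiceSummary) -> BiasScore:
    """Reaction-time-weighted implicit bias score from a trial summary.

    Any term whose win count is zero contributes exactly zero; its
    undefined RT mean is never evaluated.  The normalized score is
    ``raw * 100 / (2 * N)`` with N the responded cross-category trials,
    clipped to [-100, +100].
    """
    n = summary.n_cross_responded
    if n <= 0:
        raise ScoreUndefinedError("n_cross_responded must be > 0")

    def term(win: int, rt: float | None) -> float:
        if win == 0:
            return 0.0
        if rt is None or rt <= 0:
            raise ValueError("positive RT mean required when win count > 0")
        return win * (summary.rt_all / rt)

    t_sed = term(summary.win_sed, summary.rt_sed)
    t_pa = term(summary.win_pa, summary.rt_pa)
    iw_sed = t_sed - t_pa
    iw_pa = t_pa - t_sed
    raw = iw_sed - iw_pa
    bias = raw * 100.0 / (2.0 * n)
    clipped = bias < -100.0 or bias > 100.0
    if clipped:
        bias = math.copysign(100.0, bias)
    return BiasScore(iw_sed=iw_sed, iw_pa=iw_pa, raw=raw, bias=bias, clipped=clipped)


def score_trials(
    trials: Iterable[TrialResponse],
    pairs: Sequence[TrialPair],
    catalog: ActivityCatalog | None = None,
    min_rt: float = DEFAULT_MIN_RT,
    max_rt: float = DEFAULT_MAX_RT,
    no_clean: bool = False,
) -> tuple[ForcedChoiceSummary, BiasScore, CleaningReport]:
    """Convenience pipeline: clean, summarize and score a trial log."""
    kept, report = clean_trials(trials, min_rt=min_rt, max_rt=max_rt, no_clean=no_clean)
    summary = summarize_forced_choice(kept, pairs, catalog)
    return summary, compute_bias(summary), report
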