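"""Post-processing of inferred admixture-event tables.

Haplotype-decay dating tools categorise each individual's admixture
history as (i) one date with two sources, (ii) one date with more than two
sources, or (iii) multiple dates; the complex categories are simplified
into two two-source single-date events each.  Dates in generations are
converted to calendar years, filtered (date-1 artefacts, low source
ancestry, pre-colonial dates), and date distributions between
source-geography labels are compared with a one-sided Wilcoxon rank-sum
(Mann-Whitney U) test, where "more recent" means numerically smaller
generation dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .copying import ValidationError

__all__ = [
    "AdmixtureEvent",
    "DateFilterConfig",
    "EVENT_CATEGORIES",
    "read_events",
    "simplify_complex_events",
    "generations_to_year",
    "filter_events",
    "restrict_one_event_per_individual",
    "compare_date_distributions",
]

EVENT_CATEGORIES = ("one-date-two-sources", "one-date-multiway", "multiple-dates")


@dataclass(frozen=True)
class AdmixtureEvent:
    """One dated admixture pulse between two best-guess source labels."""

    individual_id: str
    date_generations: float
    source1: str
    source2: str
    source_ancestry_fraction: float
    category: str = "one-date-two-sources"

    def __post_init__(self) -> None:
        if self.date_generations <= 0:
            raise ValidationError("admixture date must be positive (generations)")
        if not 0.0 <= self.source_ancestry_fraction <= 1.0:
            raise ValidationError("source ancestry fraction must lie in [0, 1]")
        if self.category not in EVENT_CATEGORIES:
            raise ValidationError(f"unknown event category {self.category!r}")


@dataclass(frozen=True)
class DateFilterConfig:
    """Filters and calendar conversion applied before date comparisons.

    ``drop_date_one`` removes events dated exactly 1 generation (a
    no-admixture artefact of decay-curve dating); ``min_ancestry`` drops
    events whose source contributes <= that fraction; ``max_generations``
    drops events at or beyond that age (pre-colonial).  Calendar years use
    ``y = reference_birth_year - generation_years * (g + 1)``.
    """

    drop_date_one: bool = True
    min_ancestry: float = 0.05
    max_generations: float = 30.0
    generation_years: float = 28.0
    reference_birth_year: int = 1990
    label_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_ancestry < 0 or self.max_generations <= 0:
            raise ValidationError("filter thresholds must be positive")
        if self.generation_years <= 0:
            raise ValidationError("generation time must be positive")


def read_events(path) -> list[AdmixtureEvent]:
    """Read an events TSV: individual_id, date, source1, source2, fraction, category."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    required = {"individual_id", "date", "source1", "source2", "fraction", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"events table missing columns: {sorted(missing)}")
    return [
        AdmixtureEvent(
            individual_id=row.individual_id,
            date_generations=float(row.date),
            source1=str(row.source1),
            source2=str(row.source2),
            source_ancestry_fraction=float(row.fraction),
            category=str(row.category),
        )
        for row in df.itertuples()
    ]


def simplify_complex_events(raw_events: Iterable[AdmixtureEvent]) -> list[AdmixtureEvent]:
    """Expand complex admixture histories into two-source single-date events.

    Category (i) records pass through unchanged; categories (ii) and (iii)
    are each described as two distinct events (the input record stands for
    the pair, so it is emitted twice with the simple category).
    """
    out: list[AdmixtureEvent] = []
    for ev in raw_events:
        if ev.category == "one-date-two-sources":
            out.append(ev)
        elif ev.category in ("one-date-multiway", "multiple-dates"):
            simple = replace(ev, category="one-date-two-sources")
            out.extend([simple, simple])
        else:  # pragma: no cover - guarded by AdmixtureEvent
            raise ValidationError(f"unknown event category {ev.category!r}")
    return out


def generations_to_year(g: float, cfg: DateFilterConfig | None = None) -> float:
    """Convert an admixture date in generations to a calendar year.

    ``y = reference_birth_year - generation_years * (g + 1)`` — by default
    1990 - 28*(g+1), anchored at the cohort's mean birth year with a
    28-year generation time.
    """
    if cfg is None:
        cfg = DateFilterConfig()
    if g < 0:
        raise ValidationError("generations must be >= 0")
    return cfg.reference_birth_year - cfg.generation_years * (g + 1.0)


def filter_events(
    events: Sequence[AdmixtureEvent], cfg: DateFilterConfig | None = None
) -> list[AdmixtureEvent]:
    """Apply the date and ancestry filters, preserving order.

    Drops events dated exactly 1 (when configured), events whose source
    ancestry fraction is <= ``min_ancestry``, and events dated at or past
    ``max_generations``.  Idempotent.
    """
    if cfg is None:
        cfg = DateFilterConfig()
    kept = []
    for ev in events:
        if cfg.drop_date_one and ev.date_generations == 1:
            continue
        if ev.source_ancestry_fraction <= cfg.min_ancestry:
            continue
        if ev.date_generations >= cfg.max_generations:
            continue
        kept.append(ev)
    return kept


def restrict_one_event_per_individual(
    events: Sequence[AdmixtureEvent],
) -> list[AdmixtureEvent]:
    """Keep only the strongest-signal event per individual.

    For individuals contributing several events (the simplified complex
    histories), retains the event with the largest source ancestry
    fraction (first wins ties).  A robustness-check view of the data.
    """
    best: dict[str, AdmixtureEvent] = {}
    order: list[str] = []
    for ev in events:
        if ev.individual_id not in best:
            best[ev.individual_id] = ev
            order.append(ev.individual_id)
        elif ev.source_ancestry_fraction > best[ev.individual_id].source_ancestry_fraction:
            best[ev.individual_id] = ev
    return [best[i] for i in order]


def compare_date_distributions(
    dates_a: Sequence[float],
    dates_b: Sequence[float],
    alternative: str = "A-more-recent",
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test on two admixture-date samples.

    Tests whether sample A is skewed towards more recent (numerically
    smaller) dates than sample B; ``alternative="B-more-recent"`` mirrors
    it.  Uses the exact null distribution when both samples are small
    (nA+nB <= 12) and tie-free, and the tie-corrected normal approximation
    otherwise.  Returns ``(U statistic of sample A, one-sided p)``.
    """
    a = np.asarray(dates_a, dtype=float)
    b = np.asarray(dates_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both date samples must be non-empty")
    if alternative == "A-more-recent":
        side = "less"
    elif alternative == "B-more-recent":
        side = "greater"
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=side, method=method)
    return float(res.statistic), float(res.pvalue)
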