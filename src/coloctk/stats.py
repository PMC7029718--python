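"""Enrichment statistics: contingency construction, Fisher's exact test,
odds ratio, combo score, classification and group-level aggregation.

The central statistic is the combo score

    C = (-log10 p) * log2(OR)

where p is the two-tailed Fisher's exact p-value and OR the odds ratio of
the observed-vs-expected 2x2 overlap table.  Positive C indicates
enrichment, negative C depletion; empirical cutoffs of 5 (enrichment) and
-2 (depletion) are the advisable defaults.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import scipy.stats

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "GroupResult",
    "ENRICH_CUTOFF",
    "DEPLETE_CUTOFF",
    "COMBO_CAP",
    "MIN_GROUP_SIZE",
    "build_contingency",
    "fisher_exact_two_tailed",
    "odds_ratio",
    "combo_score",
    "classify_enrichment",
    "aggregate_group_median",
    "mean_interval_size",
]

#: Empirical combo-score cutoffs for calling enrichment / depletion.
ENRICH_CUTOFF = 5.0
DEPLETE_CUTOFF = -2.0

#: Combo scores are capped at +/-300 for reporting and similarity matrices so
#: downstream Euclidean distances stay finite.
COMBO_CAP = 300.0

#: Groups smaller than this are exempt from outlier removal.
MIN_GROUP_SIZE = 3

_MIN_P = sys.float_info.min


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 observed-vs-expected overlap table.

    a: observed overlaps, b: query-only, c: database-only, d: neither;
    ``n_slots`` is the genome slot count the table was derived from.
    ``floored`` flags that a negative intermediate cell was floored at 0
    (the background genome size was too small for the data).
    """

    a: int
    b: int
    c: int
    d: int
    n_slots: int
    floored: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    def as_array(self):
        return [[self.a, self.b], [self.c, self.d]]


def build_contingency(
    n_query: int,
    n_db: int,
    obs: int,
    genome_size: int,
    mean_interval_size: float,
) -> ContingencyTable:
    """Build the observed-vs-expected table for one query-profile pair.

    The genome is discretized into ``n_slots = round(genome_size /
    mean_interval_size)`` slots of typical interval size; cells are
    ``a = obs``, ``b = n_query - obs``, ``c = n_db - obs`` and
    ``d = n_slots - n_query - n_db + obs``, each floored at 0 (flooring
    sets the ``floored`` flag).
    """
    if n_query < 0 or n_db < 0 or obs < 0:
        raise ValueError("counts must be non-negative")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if mean_interval_size <= 0:
        raise ValueError("mean_interval_size must be positive")
    n_slots = round(genome_size / mean_interval_size)
    b_raw = n_query - obs
    c_raw = n_db - obs
    d_raw = n_slots - n_query - n_db + obs
    floored = b_raw < 0 or c_raw < 0 or d_raw < 0
    return ContingencyTable(
        a=obs,
        b=max(0, b_raw),
        c=max(0, c_raw),
        d=max(0, d_raw),
        n_slots=n_slots,
        floored=floored,
    )


def fisher_exact_two_tailed(table: ContingencyTable) -> float:
    """Two-tailed Fisher's exact p-value of the table.

    Two-sided in the conventional sense: the sum of hypergeometric point
    probabilities no greater than that of the observed table, with row and
    column margins fixed.  Degenerate tables (any zero margin) give p = 1.
    The result is clamped to [min_float, 1].
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return min(1.0, max(_MIN_P, float(p)))


def odds_ratio(table: ContingencyTable, pseudocount: float = 0.5) -> float:
    """Odds ratio ad/bc; Haldane-Anscombe pseudocount only on zero-cell tables."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        s = pseudocount
        return ((a + s) * (d + s)) / ((b + s) * (c + s))
    return (a * d) / (b * c)


def combo_score(p_value: float, or_value: float, cap: float | None = COMBO_CAP) -> float:
    """Combo score C = (-log10 p) * log2(OR), capped at +/-``cap``.

    The sign follows log2(OR): positive for enrichment (OR > 1), negative
    for depletion (OR < 1), zero when p = 1 or OR = 1.
    """
    if not (0 < p_value <= 1):
        raise ValueError(f"p_value must be in (0, 1], got {p_value}")
    if or_value <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    c = (-math.log10(p_value)) * math.log2(or_value)
    if cap is not None:
        c = max(-cap, min(cap, c))
    return c


def classify_enrichment(
    combo: float,
    enrich_cutoff: float = ENRICH_CUTOFF,
    deplete_cutoff: float = DEPLETE_CUTOFF,
) -> str:
    """Classify a combo score: 'enriched' (>= enrich_cutoff, inclusive),
    'depleted' (<= deplete_cutoff, inclusive) or 'neutral'."""
    if not deplete_cutoff < enrich_cutoff:
        raise ValueError("deplete_cutoff must be below enrich_cutoff")
    if combo >= enrich_cutoff:
        return "enriched"
    if combo <= deplete_cutoff:
        return "depleted"
    return "neutral"


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-profile enrichment statistics."""

    profile_id: str
    overlaps: int
    query_hits: int
    p_value: float
    odds_ratio: float
    combo_score: float
    classification: str
    table: ContingencyTable
    group_id: str | None = None
    tissue: str | None = None
    sub_tissue: str | None = None
    cell_type: str | None = None
    target: str | None = None
    category: str | None = None


@dataclass(frozen=True)
class GroupResult:
    """Group-level enrichment: median combo of members plus the best member."""

    group_id: str
    median_combo: float
    best_profile_id: str
    n_members: int
    classification: str


def aggregate_group_median(
    results: Sequence[EnrichmentResult],
    enrich_cutoff: float = ENRICH_CUTOFF,
    deplete_cutoff: float = DEPLETE_CUTOFF,
) -> GroupResult:
    """Aggregate member results of one group into a median combo score.

    Even member counts take the mean of the two central values.  The best
    member (highest combo, ties by profile_id) is recorded for display.
    """
    if not results:
        raise ValueError("cannot aggregate an empty group")
    group_ids = {r.group_id for r in results}
    if len(group_ids) > 1:
        raise ValueError(f"results span multiple groups: {sorted(group_ids)}")
    med = float(median(r.combo_score for r in results))
    best = max(results, key=lambda r: (r.combo_score, r.profile_id))
    return GroupResult(
        group_id=results[0].group_id or "",
        median_combo=med,
        best_profile_id=best.profile_id,
        n_members=len(results),
        classification=classify_enrichment(med, enrich_cutoff, deplete_cutoff),
    )


def mean_interval_size(
    query_count: int, query_total_len: int, db_count: int, db_total_len: int
) -> float:
    """Mean interval size over the combined query + profile multiset.

    The expected slot count of the background genome must reflect both
    sets' scale, so the mean is taken over all intervals of both sets.
    """
    total = query_count + db_count
    if total == 0:
        raise ValueError("no intervals to average")
    return (query_total_len + db_total_len) / total
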