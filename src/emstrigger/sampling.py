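"""Month-stratified random selection of records for review.

The review scheme draws a fixed number of eligible records per calendar
month (25/month over a year gives the 300-record-per-organization sample).
Selection uses an explicitly seeded Mersenne Twister (MT19937) stream and a
partial Fisher–Yates shuffle, so a documented seed reproduces the draw on
any platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .records import EMSRecord

logger = logging.getLogger(__name__)

Month = tuple[int, int]  # (year, month)


@dataclass(frozen=True)
class SamplingPlan:
    per_month_count: int = 25
    seed: int = 0
    period: Optional[tuple[Month, Month]] = None  # inclusive (start, end)

    def __post_init__(self) -> None:
        if self.per_month_count < 1:
            raise ValueError("per_month_count must be >= 1")


def stratify_by_month(records: Iterable[EMSRecord]) -> dict[Month, list[EMSRecord]]:
    """Partition records into calendar year-month buckets of mission_start."""
    buckets: dict[Month, list[EMSRecord]] = {}
    for r in records:
        key = (r.mission_start.year, r.mission_start.month)
        buckets.setdefault(key, []).append(r)
    return dict(sorted(buckets.items()))


def _fisher_yates_draw(n: int, k: int, rng: np.random.Generator) -> list[int]:
    """First k indices of a Fisher-Yates shuffle of range(n)."""
    idx = list(range(n))
    for i in range(min(k, n)):
        j = i + int(rng.integers(0, n - i))
        idx[i], idx[j] = idx[j], idx[i]
    return idx[: min(k, n)]


def sample_monthly(
    buckets: Mapping[Month, Sequence[EMSRecord]], plan: SamplingPlan
) -> list[str]:
    """Draw min(k, bucket size) record ids per month without replacement.

    Buckets are processed in calendar order from a single MT19937 stream
    seeded by the plan, so the full selection is deterministic.  Buckets
    smaller than the cap are included in full.  Within a bucket, candidate
    order is normalized to (mission_start, record_id) before drawing, so
    the selection does not depend on input order.
    """
    rng = np.random.Generator(np.random.MT19937(plan.seed))
    selected: list[str] = []
    months = sorted(buckets)
    if plan.period is not None:
        start, end = plan.period
        months = [m for m in months if start <= m <= end]
    for month in months:
        bucket = sorted(
            buckets[month], key=lambda r: (r.mission_start, r.record_id)
        )
        if not bucket:
            logger.warning("empty bucket for month %s", month)
            continue
        if len(bucket) < plan.per_month_count:
            logger.warning(
                "month %s has only %d record(s); including all",
                month, len(bucket),
            )
        picks = _fisher_yates_draw(len(bucket), plan.per_month_count, rng)
        selected.extend(bucket[i].record_id for i in picks)
    return selected


def sample_records(
    records: Sequence[EMSRecord], plan: SamplingPlan
) -> list[EMSRecord]:
    """Convenience wrapper: stratify, draw, and return the records."""
    chosen = set(sample_monthly(stratify_by_month(records), plan))
    return [r for r in records if r.record_id in chosen]
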