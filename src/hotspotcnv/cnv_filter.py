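"""Post-call filtering: size/probe/z thresholds, large-CNV classification,
and rarity filtering against control CNV catalogs.

A call is *rare* when its carrier frequency is below 1% in every control
catalog it is compared against; frequency is accumulated over catalog
records matching the call at 50% reciprocal overlap (the field-standard
event-matching convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_io import CnvCall, ControlCatalog

__all__ = [
    "FilterPolicy",
    "AnnotatedCall",
    "apply_threshold_filters",
    "classify_large",
    "control_frequency",
    "rare_filter",
    "catalog_from_calls",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of the post-call filters.

    ``min_size_bp`` / ``large_size_bp`` encode the strict ">50 kbp" and
    ">500 kbp" cuts.  The probe-count and |mean z| thresholds are
    conventional values (the size/z/probe filter is standard practice but
    its exact cutoffs are a tuning choice); all are exposed in config.
    """

    min_size_bp: int = 50_001
    min_probes: int = 5
    min_abs_mean_z: float = 1.5
    large_size_bp: int = 500_001
    max_control_frequency: float = 0.01
    min_reciprocal_overlap: float = 0.5

    def __post_init__(self):
        if min(self.min_size_bp, self.min_probes, self.large_size_bp) <= 0:
            raise ValueError("size and probe thresholds must be positive")
        if self.min_abs_mean_z <= 0:
            raise ValueError("min_abs_mean_z must be positive")
        if not 0.0 <= self.max_control_frequency <= 1.0:
            raise ValueError("max_control_frequency must lie in [0, 1]")
        if not 0.0 < self.min_reciprocal_overlap <= 1.0:
            raise ValueError("min_reciprocal_overlap must lie in (0, 1]")


def apply_threshold_filters(
    calls: Sequence[CnvCall], policy: FilterPolicy | None = None
) -> list[CnvCall]:
    """Retain calls passing the size, probe-count and |mean z| thresholds."""
    policy = policy or FilterPolicy()
    return [
        c
        for c in calls
        if c.size_bp >= policy.min_size_bp
        and c.n_probes >= policy.min_probes
        and abs(c.mean_z) >= policy.min_abs_mean_z
    ]


def classify_large(
    calls: Sequence[CnvCall], policy: FilterPolicy | None = None
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Partition calls into (large, small) at the strict >500-kbp cut."""
    policy = policy or FilterPolicy()
    large = [c for c in calls if c.size_bp >= policy.large_size_bp]
    small = [c for c in calls if c.size_bp < policy.large_size_bp]
    return large, small


def control_frequency(
    call: CnvCall,
    catalog: ControlCatalog,
    min_reciprocal_overlap: float = 0.5,
) -> float:
    """Carrier frequency of a call in a control catalog.

    Sums carrier counts over catalog records with reciprocal overlap at
    or above the threshold, divided by the cohort size, capped at 1.
    """
    if catalog.cohort_size <= 0:
        raise ValueError("control cohort size must be positive")
    total = 0
    for iv, count in catalog.records:
        if call.interval.reciprocal_overlap(iv) >= min_reciprocal_overlap:
            total += count
    return min(total / catalog.cohort_size, 1.0)


@dataclass(frozen=True)
class AnnotatedCall:
    """A call annotated with its frequency in each control catalog."""

    call: CnvCall
    control_frequencies: tuple[float, ...]


def rare_filter(
    calls: Sequence[CnvCall],
    catalogs: Sequence[ControlCatalog],
    policy: FilterPolicy | None = None,
) -> list[AnnotatedCall]:
    """Retain calls rare (< max_control_frequency) in EVERY catalog."""
    policy = policy or FilterPolicy()
    if not catalogs:
        raise ValueError("rare_filter requires at least one control catalog")
    out = []
    for call in calls:
        freqs = tuple(
            control_frequency(call, cat, policy.min_reciprocal_overlap)
            for cat in catalogs
        )
        if all(f < policy.max_control_frequency for f in freqs):
            out.append(AnnotatedCall(call=call, control_frequencies=freqs))
    return out


def catalog_from_calls(
    calls: Sequence[CnvCall],
    cohort_size: int,
    min_reciprocal_overlap: float = 0.5,
) -> ControlCatalog:
    """Build a control catalog by clustering a cohort's calls.

    Calls are greedily clustered by reciprocal overlap against each
    cluster's founding interval; a cluster's carrier count is the number
    of distinct samples contributing to it.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    clusters: list[tuple] = []  # (founder interval, set of sample ids)
    for call in sorted(
        calls, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end)
    ):
        for founder, members in clusters:
            if call.interval.reciprocal_overlap(founder) >= min_reciprocal_overlap:
                members.add(call.sample_id)
                break
        else:
            clusters.append((call.interval, {call.sample_id}))
    records = tuple(
        (founder, min(len(members), cohort_size)) for founder, members in clusters
    )
    return ControlCatalog(cohort_size=cohort_size, records=records)
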