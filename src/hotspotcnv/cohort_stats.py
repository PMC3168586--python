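"""Case-control burden testing and cohort summary percentages.

The burden test compares the proportion of carriers of a variant class
(here: CNVs above a size threshold) between cases and controls with
Fisher's exact test.  The exact hypergeometric mass is computed with
log-gamma factorials so cohort sizes up to ~1e5 stay numerically stable;
both the one-sided (cases enriched) and the standard two-sided p-value
(sum of outcome probabilities not exceeding the observed outcome's) are
reported, since published p-values do not always state sidedness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .core_io import BurdenTable, CnvCall

__all__ = [
    "FisherResult",
    "DiagnosisTable",
    "count_carriers",
    "fisher_exact",
    "diagnosis_percentages",
    "format_percentage",
]

# relative slack when comparing point probabilities for the two-sided
# rule, guarding against float noise in exact ties (same convention as
# the common R / scipy implementations)
_TWO_SIDED_SLACK = 1 + 1e-7


@dataclass(frozen=True)
class FisherResult:
    p_one_sided_greater: float
    p_two_sided: float
    odds_ratio: float
    table: BurdenTable
    degenerate: bool = False


def count_carriers(
    calls: Sequence[CnvCall],
    sample_ids: Sequence[str],
    size_threshold_bp: int,
) -> tuple[int, int]:
    """(carriers, non-carriers) for one cohort roster.

    A carrier is a sample with at least one call strictly larger than
    the threshold; each sample counts once.  Samples with no calls are
    non-carriers, so the roster must cover everyone assayed.
    """
    roster = set(sample_ids)
    if len(roster) != len(sample_ids):
        raise ValueError("duplicate sample ids in roster")
    carriers: set[str] = set()
    for c in calls:
        if c.sample_id not in roster:
            raise ValueError(f"call for sample {c.sample_id!r} not in roster")
        if c.size_bp > size_threshold_bp:
            carriers.add(c.sample_id)
    return len(carriers), len(roster) - len(carriers)


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    # P(X = k) for k successes in n draws from N items with K successes
    k = np.asarray(k)
    return (
        gammaln(K + 1)
        - gammaln(k + 1)
        - gammaln(K - k + 1)
        + gammaln(N - K + 1)
        - gammaln(n - k + 1)
        - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def fisher_exact(table: BurdenTable) -> FisherResult:
    """Fisher's exact test on a 2x2 carrier table.

    One-sided (greater) tests enrichment of carriers among cases:
    p = P(X >= observed) under the hypergeometric null.  The two-sided
    p sums the probabilities of all outcomes no more probable than the
    observed one.  The odds ratio is the sample odds ratio ad/bc
    (infinity when bc = 0 and ad > 0).
    """
    a, b = table.case_carriers, table.case_noncarriers
    c, d = table.control_carriers, table.control_noncarriers
    ad, bc = a * d, b * c
    if bc == 0:
        odds_ratio = math.nan if ad == 0 else math.inf
    else:
        odds_ratio = ad / bc

    N = a + b + c + d
    K = a + c  # total carriers
    n = a + b  # cases
    if K == 0 or K == N or n == 0 or n == N:
        return FisherResult(1.0, 1.0, odds_ratio, table, degenerate=True)

    k_lo, k_hi = max(0, n + K - N), min(n, K)
    support = np.arange(k_lo, k_hi + 1)
    pmf = np.exp(_log_hypergeom_pmf(support, N, K, n))
    p_obs = pmf[a - k_lo]
    p_greater = float(min(pmf[support >= a].sum(), 1.0))
    p_two = float(min(pmf[pmf <= p_obs * _TWO_SIDED_SLACK].sum(), 1.0))
    return FisherResult(p_greater, p_two, odds_ratio, table)


@dataclass(frozen=True)
class DiagnosisTable:
    """Per-group diagnosis counts for a cohort summary table."""

    group_label: str
    n_group: int
    rows: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if self.n_group <= 0:
            raise ValueError("group size must be positive")
        for label, count in self.rows:
            if count < 0:
                raise ValueError(f"negative count for {label!r}")
            if count > self.n_group:
                raise ValueError(
                    f"count {count} for {label!r} exceeds group size {self.n_group}"
                )


def format_percentage(count: int, n_group: int) -> str:
    """Render "count (pct%)" with the percentage rounded half-up to one
    decimal; exact 0% and 100% print without a decimal."""
    if n_group <= 0:
        raise ValueError("group size must be positive")
    if count < 0 or count > n_group:
        raise ValueError(f"count {count} outside [0, {n_group}]")
    if count == 0:
        return f"{count} (0%)"
    if count == n_group:
        return f"{count} (100%)"
    pct = Decimal(100 * count) / Decimal(n_group)
    pct = pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{count} ({pct}%)"


def diagnosis_percentages(table: DiagnosisTable) -> list[tuple[str, str]]:
    """(diagnosis label, "count (pct%)") rows for one group."""
    return [
        (label, format_percentage(count, table.n_group))
        for label, count in table.rows
    ]
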