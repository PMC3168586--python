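"""Seeded simulation of hotspot-targeted aCGH arrays and cohorts.

The generator emulates a custom oligo array that tiles rearrangement
hotspots densely (median probe spacing ~2.6 kbp) and the genomic backbone
sparsely (~36 kbp), then synthesizes per-sample log2-ratio profiles with
Gaussian probe noise, a per-sample baseline offset, and embedded
heterozygous deletions (log2 shift -1) and duplications (+0.585).
Everything is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    CnvCall,
    CopyState,
    GenomicInterval,
    Probe,
    ProbeDesign,
    RegionClass,
    SampleProfile,
    ValueKind,
    chrom_sort_key,
)

__all__ = [
    "ArrayDesignSpec",
    "CnvKind",
    "CnvSpec",
    "NoiseModel",
    "SimTruth",
    "RecoveryReport",
    "generate_design",
    "simulate_sample",
    "simulate_cohort",
    "score_recovery",
    "place_cnvs_in_hotspots",
    "DESK_GENOME",
]

PROBE_LENGTH_BP = 50  # typical aCGH oligo footprint

# Reduced genome for desk-scale simulation; full hg18-scale sizes can be
# passed explicitly via chrom_sizes.
DESK_GENOME: dict[str, int] = {
    "chr1": 30_000_000,
    "chr2": 30_000_000,
    "chr3": 30_000_000,
}


@dataclass(frozen=True)
class ArrayDesignSpec:
    """Parameters of a hotspot-targeted array design.

    Defaults reproduce the full-scale geometry: 135,000 probes with median
    spacing 2.6 kbp inside 107 hotspot regions and 36 kbp in the backbone.
    ``desk_scale`` gives a ~10,000-probe design on a 3 x 30-Mbp genome for
    fast end-to-end experiments.
    """

    chrom_sizes: Mapping[str, int]
    n_hotspots: int = 107
    hotspot_spacing_bp: int = 2_600
    backbone_spacing_bp: int = 36_000
    n_probes_target: int = 135_000
    seed: int = 0

    def __post_init__(self):
        if self.hotspot_spacing_bp <= 0 or self.backbone_spacing_bp <= 0:
            raise ValueError("probe spacings must be positive")
        if self.n_hotspots < 0:
            raise ValueError("n_hotspots must be >= 0")
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must be non-empty")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "ArrayDesignSpec":
        kwargs = dict(
            chrom_sizes=dict(DESK_GENOME),
            n_hotspots=30,
            n_probes_target=10_000,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


class CnvKind:
    DELETION = "deletion"
    DUPLICATION = "duplication"


# expected log2 ratios for one copy lost/gained on a two-copy background
DEFAULT_SHIFTS = {CnvKind.DELETION: -1.0, CnvKind.DUPLICATION: math.log2(3 / 2)}


@dataclass(frozen=True)
class CnvSpec:
    """A CNV to embed in simulated samples."""

    interval: GenomicInterval
    kind: str
    log2_shift: float | None = None
    carrier_frequency: float = 0.0

    def __post_init__(self):
        if self.kind not in (CnvKind.DELETION, CnvKind.DUPLICATION):
            raise ValueError(f"unknown CNV kind {self.kind!r}")
        if self.log2_shift is None:
            object.__setattr__(self, "log2_shift", DEFAULT_SHIFTS[self.kind])
        if self.kind == CnvKind.DELETION and not self.log2_shift < 0:
            raise ValueError("deletion shift must be negative")
        if self.kind == CnvKind.DUPLICATION and not self.log2_shift > 0:
            raise ValueError("duplication shift must be positive")
        if not 0.0 <= self.carrier_frequency <= 1.0:
            raise ValueError("carrier frequency must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise: independent per-probe noise plus a per-sample
    whole-genome baseline offset modelling reference/dye effects."""

    probe_noise_sd: float = 0.2
    sample_baseline_sd: float = 0.05

    def __post_init__(self):
        if not (math.isfinite(self.probe_noise_sd) and self.probe_noise_sd >= 0):
            raise ValueError("probe_noise_sd must be finite and >= 0")
        if not (
            math.isfinite(self.sample_baseline_sd) and self.sample_baseline_sd >= 0
        ):
            raise ValueError("sample_baseline_sd must be finite and >= 0")


SimTruth = dict[str, list[CnvSpec]]
"""Per-sample list of the CNVs actually embedded in that sample."""


@dataclass(frozen=True)
class RecoveryReport:
    sensitivity: float
    false_calls_per_sample: float
    matched: tuple[tuple[str, CnvSpec, CnvCall], ...]
    n_truth: int
    n_false_calls: int


def _spacing_to_scale(spacing_bp: float) -> float:
    # exponential gaps with mean equal to the nominal spacing, so the
    # expected probe count is region length / spacing (the realized
    # median gap is then spacing * ln 2)
    return float(spacing_bp)


def generate_design(spec: ArrayDesignSpec) -> ProbeDesign:
    """Generate a probe design with hotspots placed uniformly at random.

    Hotspot regions get dense probes (exponential inter-probe gaps with
    mean ``hotspot_spacing_bp``); the rest of each chromosome is tiled
    at mean ``backbone_spacing_bp``.  Hotspot region length is derived
    from ``n_probes_target`` so the total probe count lands within ~5% of
    the target.  Deterministic for a fixed spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    chroms = sorted(spec.chrom_sizes, key=chrom_sort_key)
    sizes = {c: int(spec.chrom_sizes[c]) for c in chroms}
    genome = sum(sizes.values())

    backbone_expected = genome / spec.backbone_spacing_bp
    hotspot_regions: list[GenomicInterval] = []
    if spec.n_hotspots > 0:
        extra = spec.n_probes_target - backbone_expected
        if extra <= 0:
            raise ValueError(
                "n_probes_target leaves no probes for hotspots at this "
                "backbone spacing"
            )
        # a hotspot replaces backbone probes over its span with dense ones
        per_probe_gain = 1 / spec.hotspot_spacing_bp - 1 / spec.backbone_spacing_bp
        hotspot_len = int(extra / spec.n_hotspots / per_probe_gain)
        if hotspot_len > min(sizes.values()):
            raise ValueError(
                f"hotspot length {hotspot_len} bp exceeds the smallest "
                "chromosome; enlarge chromosomes or reduce n_probes_target"
            )
        # distribute hotspot counts across chromosomes proportional to size
        counts = {c: 0 for c in chroms}
        picks = rng.choice(
            chroms, size=spec.n_hotspots, p=[sizes[c] / genome for c in chroms]
        )
        for c in picks:
            counts[str(c)] += 1
        for c in chroms:
            n = counts[c]
            if n == 0:
                continue
            if n * hotspot_len > sizes[c]:
                raise ValueError(
                    f"hotspots exceed chromosome {c} length; reduce n_hotspots"
                )
            # place non-overlapping by spacing starts in disjoint bins
            free = sizes[c] - n * hotspot_len
            gaps = rng.dirichlet(np.ones(n + 1)) * free
            pos = 1
            for i in range(n):
                pos += int(gaps[i])
                start = max(1, pos)
                hotspot_regions.append(
                    GenomicInterval(c, start, start + hotspot_len - 1)
                )
                pos = start + hotspot_len

    hotspot_by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chroms}
    for hs in hotspot_regions:
        hotspot_by_chrom[hs.chrom].append(hs)
    for c in chroms:
        hotspot_by_chrom[c].sort(key=lambda iv: iv.start)

    probes: list[Probe] = []
    pid = 0
    bb_scale = _spacing_to_scale(spec.backbone_spacing_bp)
    hs_scale = _spacing_to_scale(spec.hotspot_spacing_bp)
    for c in chroms:
        regions = hotspot_by_chrom[c]
        pos = 1
        ri = 0
        while pos + PROBE_LENGTH_BP - 1 <= sizes[c]:
            while ri < len(regions) and regions[ri].end < pos:
                ri += 1
            in_hotspot = ri < len(regions) and regions[ri].start <= pos <= regions[ri].end
            pid += 1
            probes.append(
                Probe(
                    f"p{pid:06d}",
                    GenomicInterval(c, pos, pos + PROBE_LENGTH_BP - 1),
                    RegionClass.HOTSPOT if in_hotspot else RegionClass.BACKBONE,
                )
            )
            scale = hs_scale if in_hotspot else bb_scale
            gap = int(rng.exponential(scale))
            pos += max(gap, PROBE_LENGTH_BP + 1)

    design = ProbeDesign(probes, hotspot_regions=tuple(hotspot_regions))
    return design


def _shift_vector(design: ProbeDesign, truth_cnvs: Sequence[CnvSpec]) -> np.ndarray:
    """Per-probe log2 shift implied by the truth CNVs.

    A probe is inside a CNV if its interval overlaps the CNV interval.
    Overlapping truths of opposite sign are an error; for same-sign
    overlaps the first covering spec wins.
    """
    shifts = np.zeros(len(design))
    assigned = np.zeros(len(design), dtype=bool)
    for cnv in truth_cnvs:
        on = (
            (design.chroms == cnv.interval.chrom)
            & (design.starts <= cnv.interval.end)
            & (design.ends >= cnv.interval.start)
        )
        clash = on & assigned & (np.sign(shifts) != np.sign(cnv.log2_shift))
        if clash.any():
            raise ValueError(
                "overlapping truth CNVs of opposite sign in one sample"
            )
        fresh = on & ~assigned
        shifts[fresh] = cnv.log2_shift
        assigned |= on
    return shifts


def simulate_sample(
    design: ProbeDesign,
    truth_cnvs: Sequence[CnvSpec],
    noise: NoiseModel,
    seed: int,
    sample_id: str = "sample",
) -> SampleProfile:
    """Simulate one log2-ratio profile with the given embedded CNVs."""
    for cnv in truth_cnvs:
        if cnv.interval.chrom not in set(design.chroms.tolist()):
            raise ValueError(
                f"truth CNV on {cnv.interval.chrom} not covered by the design"
            )
    rng = np.random.default_rng(seed)
    baseline = rng.normal(0.0, noise.sample_baseline_sd) if noise.sample_baseline_sd else 0.0
    values = baseline + _shift_vector(design, truth_cnvs)
    if noise.probe_noise_sd > 0:
        values = values + rng.normal(0.0, noise.probe_noise_sd, size=len(design))
    return SampleProfile(sample_id, values, ValueKind.LOG2_RATIO)


def simulate_cohort(
    design: ProbeDesign,
    case_specs: Sequence[CnvSpec],
    control_specs: Sequence[CnvSpec],
    n_cases: int,
    n_controls: int,
    noise: NoiseModel,
    seed: int,
) -> tuple[list[SampleProfile], SimTruth]:
    """Simulate a case-control cohort.

    Each sample independently carries each of its group's CnvSpecs with
    that spec's carrier frequency.  Returns all profiles (cases first,
    sample ids ``case_###`` / ``ctrl_###``) and the exact truth.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("cohort sizes must be positive")
    rng = np.random.default_rng(seed)
    profiles: list[SampleProfile] = []
    truth: SimTruth = {}
    groups = [("case", case_specs, n_cases), ("ctrl", control_specs, n_controls)]
    for prefix, specs, n in groups:
        for i in range(1, n + 1):
            sid = f"{prefix}_{i:03d}"
            carried = [s for s in specs if rng.random() < s.carrier_frequency]
            sample_seed = int(rng.integers(0, 2**31 - 1))
            profiles.append(
                simulate_sample(design, carried, noise, sample_seed, sample_id=sid)
            )
            truth[sid] = carried
    return profiles, truth


def score_recovery(
    calls: Sequence[CnvCall],
    truth: SimTruth,
    min_reciprocal_overlap: float = 0.5,
) -> RecoveryReport:
    """Match calls to truth CNVs by sample, sign and reciprocal overlap.

    A truth event is recovered if some call in the same sample with the
    matching sign (deletion <-> decreased, duplication <-> increased)
    overlaps it reciprocally at or above the threshold.  Calls matching
    no truth event count as false calls.
    """
    if not 0.0 < min_reciprocal_overlap <= 1.0:
        raise ValueError("min_reciprocal_overlap must lie in (0, 1]")
    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    unknown = set(by_sample) - set(truth)
    if unknown:
        raise ValueError(f"calls for samples absent from truth: {sorted(unknown)}")

    state_for = {
        CnvKind.DELETION: CopyState.DECREASED,
        CnvKind.DUPLICATION: CopyState.INCREASED,
    }
    matched: list[tuple[str, CnvSpec, CnvCall]] = []
    used: set[int] = set()
    n_truth = 0
    for sid, events in truth.items():
        sample_calls = by_sample.get(sid, [])
        for ev in events:
            n_truth += 1
            best = None
            for c in sample_calls:
                if c.state is not state_for[ev.kind]:
                    continue
                ro = c.interval.reciprocal_overlap(ev.interval)
                if ro >= min_reciprocal_overlap and (best is None or ro > best[0]):
                    best = (ro, c)
            if best is not None:
                matched.append((sid, ev, best[1]))
                used.add(id(best[1]))
    false_calls = [c for c in calls if id(c) not in used]
    # a call overlapping a matched truth it was not the best match for is
    # not a false positive; discount any call matching some truth event
    n_false = 0
    for c in false_calls:
        hits = any(
            c.state is state_for[ev.kind]
            and c.interval.reciprocal_overlap(ev.interval) >= min_reciprocal_overlap
            for ev in truth.get(c.sample_id, [])
        )
        if not hits:
            n_false += 1
    n_samples = max(len(truth), 1)
    sensitivity = len(matched) / n_truth if n_truth else 1.0
    return RecoveryReport(
        sensitivity=sensitivity,
        false_calls_per_sample=n_false / n_samples,
        matched=tuple(matched),
        n_truth=n_truth,
        n_false_calls=n_false,
    )


def place_cnvs_in_hotspots(
    design: ProbeDesign,
    requests: Sequence[dict],
) -> list[CnvSpec]:
    """Place size-specified CNVs into distinct hotspot regions.

    Each request is a mapping with ``size_bp``, ``kind``, optional
    ``carrier_frequency`` and ``log2_shift``.  Requests are assigned, in
    order, to unused hotspot regions long enough to hold them, spread
    across chromosomes (least-loaded chromosome first) so that no single
    chromosome accumulates a large deleted/duplicated probe fraction,
    which would distort its z-normalization.  Centered in the region;
    deterministic given the design.
    """
    regions = sorted(
        design.hotspot_regions, key=lambda r: (chrom_sort_key(r.chrom), r.start)
    )
    used: set[int] = set()
    load: dict[str, int] = {}
    specs: list[CnvSpec] = []
    for req in requests:
        size = int(req["size_bp"])
        candidates = [
            (load.get(r.chrom, 0), chrom_sort_key(r.chrom), r.start, i)
            for i, r in enumerate(regions)
            if i not in used and r.length >= size
        ]
        placed = None
        if candidates:
            _, _, _, i = min(candidates)
            region = regions[i]
            mid = (region.start + region.end) // 2
            start = max(region.start, mid - size // 2)
            placed = GenomicInterval(region.chrom, start, start + size - 1)
            used.add(i)
            load[region.chrom] = load.get(region.chrom, 0) + 1
        if placed is None:
            raise ValueError(
                f"no unused hotspot region can hold a {size}-bp CNV"
            )
        specs.append(
            CnvSpec(
                interval=placed,
                kind=req["kind"],
                log2_shift=req.get("log2_shift"),
                carrier_frequency=float(req.get("carrier_frequency", 0.0)),
            )
        )
    return specs
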