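"""CNV calling: per-chromosome z-scoring, three-state HMM decoding, and
distance-based segment merging.

The calling model works on z-scores of log2 ratios, standardized with
chromosome-specific means and standard deviations so that states are
comparable across chromosomes and samples.  Each probe is assigned one of
three hidden copy-number states (decreased / normal / increased) by
Viterbi decoding of a homogeneous Gaussian-emission HMM.  State runs are
then turned into variants by two distance rules applied after decoding:

1. consecutive probes of the same non-normal state are merged into one
   segment while successive probe starts are less than 50 kbp apart;
2. two same-state segments separated by an intervening sequence of at
   most 5 probes spanning at most 10 kbp are fused, with the intervening
   probes counted into the variant, iterated to a fixed point.

The HMM is deliberately distance-independent: all genomic-distance
handling lives in the two explicit merge rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import (
    CnvCall,
    CopyState,
    GenomicInterval,
    ProbeDesign,
    SampleProfile,
    ValueKind,
    chrom_sort_key,
)

__all__ = [
    "HmmParams",
    "StatePath",
    "MergePolicy",
    "Segment",
    "zscore_normalize",
    "viterbi_decode",
    "states_to_segments",
    "bridge_merge",
    "call_sample",
    "SEX_CHROMS",
]

# state indexing used throughout this module
STATES = (CopyState.DECREASED, CopyState.NORMAL, CopyState.INCREASED)
_DEC, _NORM, _INC = 0, 1, 2
# tie-breaking preference: normal first, then decreased, then increased
_TIE_ORDER = (_NORM, _DEC, _INC)

SEX_CHROMS = frozenset({"chrX", "chrY"})


@dataclass(frozen=True)
class HmmParams:
    """Gaussian-emission HMM parameters, in z-score units.

    A heterozygous deletion (log2 ratio ~ -1 over typical aCGH noise sd
    0.2-0.4) lands near z = -2.5 to -5, duplications (+0.585) are
    attenuated; the default state means reflect that asymmetry.  The
    transition matrix shares one self-transition probability with the
    off-diagonal mass split evenly.
    """

    mean_dec: float = -2.5
    mean_norm: float = 0.0
    mean_inc: float = 2.0
    sd_dec: float = 1.0
    sd_norm: float = 1.0
    sd_inc: float = 1.0
    stay_prob: float = 0.999
    init_dec: float = 0.001
    init_norm: float = 0.998
    init_inc: float = 0.001

    def __post_init__(self):
        if not self.mean_dec < self.mean_norm < self.mean_inc:
            raise ValueError("state means must satisfy decreased < normal < increased")
        if min(self.sd_dec, self.sd_norm, self.sd_inc) <= 0:
            raise ValueError("state sds must be positive")
        if not 0.0 < self.stay_prob < 1.0:
            raise ValueError("stay_prob must lie in (0, 1)")
        total = self.init_dec + self.init_norm + self.init_inc
        if abs(total - 1.0) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")
        if min(self.init_dec, self.init_norm, self.init_inc) <= 0:
            raise ValueError("initial probabilities must be positive")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mean_dec, self.mean_norm, self.mean_inc])

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd_dec, self.sd_norm, self.sd_inc])

    @property
    def initial_probs(self) -> np.ndarray:
        return np.array([self.init_dec, self.init_norm, self.init_inc])

    @property
    def transition_matrix(self) -> np.ndarray:
        off = (1.0 - self.stay_prob) / 2.0
        t = np.full((3, 3), off)
        np.fill_diagonal(t, self.stay_prob)
        return t


@dataclass(frozen=True)
class StatePath:
    """Decoded per-probe states for one chromosome plus the Viterbi
    log joint probability of (path, data)."""

    states: tuple[CopyState, ...]
    log_score: float


@dataclass(frozen=True)
class MergePolicy:
    """Distance thresholds of the two post-decoding merge rules."""

    max_probe_gap_bp: int = 50_000
    bridge_max_probes: int = 5
    bridge_max_bp: int = 10_000

    def __post_init__(self):
        if min(self.max_probe_gap_bp, self.bridge_max_probes, self.bridge_max_bp) <= 0:
            raise ValueError("merge policy thresholds must be positive")


def zscore_normalize(profile: SampleProfile, design: ProbeDesign) -> SampleProfile:
    """Standardize log2 ratios per chromosome (sample sd, n-1 denominator).

    Removes whole-sample baseline offsets and chromosome-level shifts;
    after the transform every chromosome has mean 0 and sd 1.
    """
    if profile.value_kind is not ValueKind.LOG2_RATIO:
        raise ValueError("zscore_normalize expects a log2_ratio profile")
    if len(profile.values) != len(design):
        raise ValueError(
            f"profile length {len(profile.values)} does not match design "
            f"({len(design)} probes)"
        )
    z = np.empty_like(profile.values)
    for chrom, sl in design.chrom_slices().items():
        x = profile.values[sl]
        if len(x) < 2:
            raise ValueError(f"chromosome {chrom} has fewer than 2 probes")
        sd = x.std(ddof=1)
        if sd == 0.0:
            raise ValueError(f"zero within-chromosome variance on {chrom}")
        z[sl] = (x - x.mean()) / sd
    return SampleProfile(profile.sample_id, z, ValueKind.Z_SCORE)


def viterbi_decode(z: np.ndarray, params: HmmParams) -> StatePath:
    """Most probable three-state path under Gaussian emissions.

    All arithmetic is in log space.  Ties are broken toward normal,
    then decreased.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        return StatePath(states=(), log_score=0.0)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-score vector contains non-finite values")

    means, sds = params.means, params.sds
    # (n, 3) log emission densities
    log_b = (
        -0.5 * ((z[:, None] - means[None, :]) / sds[None, :]) ** 2
        - np.log(sds)[None, :]
        - 0.5 * math.log(2 * math.pi)
    )
    log_a = np.log(params.transition_matrix)
    log_pi = np.log(params.initial_probs)

    n = z.size
    delta = log_pi + log_b[0]
    back = np.zeros((n, 3), dtype=np.int8)
    for t in range(1, n):
        # candidate scores from each previous state, with tie preference
        arg = np.empty(3, dtype=np.int8)
        best = np.empty(3)
        for j in range(3):
            col = delta + log_a[:, j]
            bi = _TIE_ORDER[0]
            bv = col[bi]
            for i in _TIE_ORDER[1:]:
                if col[i] > bv:
                    bi, bv = i, col[i]
            arg[j] = bi
            best[j] = bv
        delta = best + log_b[t]
        back[t] = arg

    last = _TIE_ORDER[0]
    for i in _TIE_ORDER[1:]:
        if delta[i] > delta[last]:
            last = i
    log_score = float(delta[last])
    idx = np.empty(n, dtype=np.int8)
    idx[-1] = last
    for t in range(n - 1, 0, -1):
        idx[t - 1] = back[t, idx[t]]
    return StatePath(states=tuple(STATES[i] for i in idx), log_score=log_score)


@dataclass(frozen=True)
class Segment:
    """A run of same-state probes on one chromosome, as probe index span
    [first, last] into the chromosome's probe arrays."""

    state: CopyState
    first: int
    last: int

    @property
    def n_probes(self) -> int:
        return self.last - self.first + 1


def states_to_segments(
    path: StatePath,
    starts: np.ndarray,
    policy: MergePolicy,
) -> list[Segment]:
    """Maximal same-state non-normal runs, split at large probe gaps.

    A run is split wherever consecutive probe starts are
    ``max_probe_gap_bp`` or more apart (the merge rule admits only gaps
    strictly below the threshold).
    """
    states = path.states
    if len(states) != len(starts):
        raise ValueError("state path length does not match probe count")
    segments: list[Segment] = []
    i = 0
    n = len(states)
    while i < n:
        s = states[i]
        if s is CopyState.NORMAL:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and states[j + 1] is s
            and starts[j + 1] - starts[j] < policy.max_probe_gap_bp
        ):
            j += 1
        segments.append(Segment(state=s, first=i, last=j))
        i = j + 1
    return segments


def bridge_merge(
    segments: Sequence[Segment],
    starts: np.ndarray,
    ends: np.ndarray,
    policy: MergePolicy,
) -> list[Segment]:
    """Fuse same-state segments across short intervening sequences.

    Adjacent same-state segments whose intervening probes number at most
    ``bridge_max_probes`` and whose intervening span (bases strictly
    between the segments) is at most ``bridge_max_bp`` become one
    variant; the intervening probes are counted into it.  Applied
    iteratively until no further fusion is possible.
    """
    segs = sorted(segments, key=lambda s: s.first)
    changed = True
    while changed:
        changed = False
        out: list[Segment] = []
        k = 0
        while k < len(segs):
            cur = segs[k]
            while k + 1 < len(segs):
                nxt = segs[k + 1]
                if nxt.state is not cur.state:
                    break
                n_between = nxt.first - cur.last - 1
                span_between = int(starts[nxt.first]) - int(ends[cur.last]) - 1
                if n_between <= policy.bridge_max_probes and (
                    span_between <= policy.bridge_max_bp
                ):
                    cur = Segment(state=cur.state, first=cur.first, last=nxt.last)
                    changed = True
                    k += 1
                else:
                    break
            out.append(cur)
            k += 1
        segs = out
    return segs


def _segments_to_calls(
    segments: Sequence[Segment],
    chrom: str,
    starts: np.ndarray,
    ends: np.ndarray,
    z: np.ndarray,
    sample_id: str,
) -> list[CnvCall]:
    calls = []
    for seg in segments:
        mean_z = float(z[seg.first : seg.last + 1].mean())
        calls.append(
            CnvCall(
                sample_id=sample_id,
                interval=GenomicInterval(
                    chrom, int(starts[seg.first]), int(ends[seg.last])
                ),
                state=seg.state,
                n_probes=seg.n_probes,
                mean_z=mean_z,
            )
        )
    return calls


def call_sample(
    profile: SampleProfile,
    design: ProbeDesign,
    params: HmmParams | None = None,
    policy: MergePolicy | None = None,
    include_sex_chroms: bool = False,
) -> list[CnvCall]:
    """Full calling pipeline for one sample.

    z-score normalization, per-chromosome Viterbi decoding, gap-aware
    segmentation and bridge merging; returns sorted non-normal calls.
    chrX/chrY are excluded by default (a single male reference makes
    X-chromosome ratios sex-dependent rather than CNV-driven).
    """
    params = params or HmmParams()
    policy = policy or MergePolicy()
    zprof = zscore_normalize(profile, design)
    calls: list[CnvCall] = []
    for chrom, sl in design.chrom_slices().items():
        if chrom in SEX_CHROMS and not include_sex_chroms:
            continue
        z = zprof.values[sl]
        starts = design.starts[sl]
        ends = design.ends[sl]
        path = viterbi_decode(z, params)
        segments = states_to_segments(path, starts, policy)
        segments = bridge_merge(segments, starts, ends, policy)
        calls.extend(
            _segments_to_calls(segments, chrom, starts, ends, z, zprof.sample_id)
        )
    calls.sort(key=lambda c: (chrom_sort_key(c.interval.chrom), c.interval.start))
    return calls
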