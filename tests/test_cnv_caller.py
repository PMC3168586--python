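"""z-score normalization, Viterbi decoding against exhaustive enumeration,
and the two distance-based merge rules."""

import itertools
import math

import numpy as np
import pytest

from hotspotcnv.cnv_caller import (
    HmmParams,
    MergePolicy,
    Segment,
    StatePath,
    bridge_merge,
    call_sample,
    states_to_segments,
    viterbi_decode,
    zscore_normalize,
)
from hotspotcnv.core_io import (
    CopyState,
    GenomicInterval,
    SampleProfile,
    ValueKind,
)
from hotspotcnv.synthetic_array import (
    ArrayDesignSpec,
    CnvKind,
    CnvSpec,
    NoiseModel,
    generate_design,
    simulate_sample,
)

from conftest import make_design

D, N, I = CopyState.DECREASED, CopyState.NORMAL, CopyState.INCREASED
_IDX = {D: 0, N: 1, I: 2}
_STATES = (D, N, I)


def enumerate_map_path(z, params: HmmParams):
    """Independent oracle: maximize the log joint over all 3^n paths.

    Ties are broken toward normal, then decreased, by scanning candidate
    paths in an order where preferred states sort first.
    """
    z = np.asarray(z, dtype=float)
    log_a = np.log(params.transition_matrix)
    log_pi = np.log(params.initial_probs)

    def emis(t, s):
        mu, sd = params.means[s], params.sds[s]
        return (
            -0.5 * ((z[t] - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)
        )

    best_path, best_score = None, -math.inf
    order = (1, 0, 2)  # normal, decreased, increased
    for path in itertools.product(order, repeat=len(z)):
        s = log_pi[path[0]] + emis(0, path[0])
        for t in range(1, len(z)):
            s += log_a[path[t - 1], path[t]] + emis(t, path[t])
        if s > best_score:
            best_path, best_score = path, s
    return best_path, best_score


class TestZscoreNormalize:
    def test_four_probe_example(self):
        design = make_design({"chr1": [100, 200, 300, 400]})
        prof = SampleProfile("s", np.array([0.0, 0.0, 1.0, -1.0]), ValueKind.LOG2_RATIO)
        z = zscore_normalize(prof, design)
        np.testing.assert_allclose(
            z.values, [0.0, 0.0, 1.2247448714, -1.2247448714], atol=1e-9
        )
        assert z.value_kind is ValueKind.Z_SCORE

    def test_idempotent_on_standardized_input(self, rng):
        design = make_design({"chr1": list(range(1000, 101_000, 1000))})
        x = rng.normal(size=100)
        x = (x - x.mean()) / x.std(ddof=1)
        prof = SampleProfile("s", x, ValueKind.LOG2_RATIO)
        z = zscore_normalize(prof, design)
        np.testing.assert_allclose(z.values, x, atol=1e-9)

    def test_chromosomes_standardized_independently(self, rng):
        design = make_design(
            {"chr1": [100, 200, 300], "chr2": [100, 200, 300]}
        )
        base = rng.normal(size=3)
        values = np.concatenate([base, base + 5.0])  # cross-chromosome shift
        prof = SampleProfile("s", values, ValueKind.LOG2_RATIO)
        z = zscore_normalize(prof, design)
        np.testing.assert_allclose(z.values[:3], z.values[3:], atol=1e-9)

    def test_mean_zero_sd_one_per_chromosome(self, uniform_design, rng):
        values = rng.normal(0.3, 0.7, size=len(uniform_design))
        prof = SampleProfile("s", values, ValueKind.LOG2_RATIO)
        z = zscore_normalize(prof, uniform_design)
        for chrom, sl in uniform_design.chrom_slices().items():
            assert abs(z.values[sl].mean()) < 1e-9
            assert abs(z.values[sl].std(ddof=1) - 1) < 1e-9

    def test_zero_variance_names_chromosome(self):
        design = make_design({"chr1": [100, 200], "chr2": [100, 200]})
        prof = SampleProfile("s", np.array([1.0, 1.0, 0.0, 1.0]), ValueKind.LOG2_RATIO)
        with pytest.raises(ValueError, match="chr1"):
            zscore_normalize(prof, design)

    def test_single_probe_chromosome_rejected(self):
        design = make_design({"chr1": [100]})
        prof = SampleProfile("s", np.array([1.0]), ValueKind.LOG2_RATIO)
        with pytest.raises(ValueError):
            zscore_normalize(prof, design)


class TestViterbi:
    def test_flat_zero_is_all_normal(self):
        path = viterbi_decode(np.zeros(5), HmmParams())
        assert all(s is N for s in path.states)

    def test_strong_negative_run_decoded_decreased(self):
        # Enumeration (the ground truth here) extends the decreased run
        # through the trailing zeros at the default stickiness: returning
        # to normal costs more than emitting two z=0 probes as decreased,
        # and the chromosome end needs no switch back.
        z = np.array([0, 0, -4, -4, -4, 0, 0], dtype=float)
        params = HmmParams()
        path = viterbi_decode(z, params)
        expected, expected_score = enumerate_map_path(z, params)
        assert tuple(_IDX[s] for s in path.states) == expected
        assert path.log_score == pytest.approx(expected_score, abs=1e-9)
        assert all(s is D for s in path.states[2:5])

    def test_negative_run_with_looser_stickiness_is_exact(self):
        # at stay_prob 0.99 the decreased run covers exactly the -4 probes
        z = np.array([0, 0, -4, -4, -4, 0, 0], dtype=float)
        params = HmmParams(stay_prob=0.99)
        path = viterbi_decode(z, params)
        assert [s for s in path.states] == [N, N, D, D, D, N, N]
        expected, _ = enumerate_map_path(z, params)
        assert tuple(_IDX[s] for s in path.states) == expected

    def test_single_probe_closed_form(self):
        params = HmmParams()
        path = viterbi_decode(np.array([5.0]), params)

        def score(state, mu):
            return math.log(params.initial_probs[state]) - 0.5 * (5.0 - mu) ** 2

        expected = I if score(2, params.mean_inc) > score(1, params.mean_norm) else N
        assert path.states[0] is expected

    def test_empty_vector(self):
        path = viterbi_decode(np.array([]), HmmParams())
        assert path.states == ()
        assert path.log_score == 0.0

    def test_oracle_equivalence_random_instances(self, rng):
        """Viterbi equals exhaustive 3^n maximization on 200 random cases."""
        for _ in range(200):
            n = int(rng.integers(1, 9))
            z = rng.normal(0, 3, size=n)
            params = HmmParams(
                mean_dec=float(-rng.uniform(1, 4)),
                mean_inc=float(rng.uniform(1, 4)),
                sd_dec=float(rng.uniform(0.5, 2)),
                sd_norm=float(rng.uniform(0.5, 2)),
                sd_inc=float(rng.uniform(0.5, 2)),
                stay_prob=float(rng.uniform(0.5, 0.9999)),
            )
            expected, expected_score = enumerate_map_path(z, params)
            path = viterbi_decode(z, params)
            assert tuple(_IDX[s] for s in path.states) == expected
            assert path.log_score == pytest.approx(expected_score, rel=1e-12)

    def test_switch_count_monotone_in_stickiness(self, rng):
        """Lowering stay_prob never reduces the number of state switches."""
        for trial in range(20):
            z = rng.normal(0, 2, size=60)
            switches = []
            for stay in (0.9999, 0.999, 0.99, 0.9, 0.7):
                states = viterbi_decode(z, HmmParams(stay_prob=stay)).states
                switches.append(
                    sum(a is not b for a, b in zip(states, states[1:]))
                )
            assert switches == sorted(switches)


def _path(states):
    return StatePath(states=tuple(states), log_score=0.0)


class TestStatesToSegments:
    policy = MergePolicy()

    def test_close_probes_one_segment(self):
        starts = np.array([100_000, 110_000, 120_000])
        segs = states_to_segments(_path([D, D, D]), starts, self.policy)
        assert segs == [Segment(D, 0, 2)]

    def test_gap_at_threshold_splits(self):
        starts = np.array([100_000, 160_001])
        segs = states_to_segments(_path([D, D]), starts, self.policy)
        assert segs == [Segment(D, 0, 0), Segment(D, 1, 1)]

    def test_gap_just_below_threshold_merges(self):
        starts = np.array([100_000, 149_999])
        segs = states_to_segments(_path([D, D]), starts, self.policy)
        assert segs == [Segment(D, 0, 1)]

    def test_all_normal_no_segments(self):
        starts = np.array([100_000, 110_000, 120_000])
        assert states_to_segments(_path([N, N, N]), starts, self.policy) == []

    def test_state_change_breaks_run(self):
        starts = np.array([100_000, 110_000, 120_000])
        segs = states_to_segments(_path([D, I, D]), starts, self.policy)
        assert segs == [Segment(D, 0, 0), Segment(I, 1, 1), Segment(D, 2, 2)]


class TestBridgeMerge:
    policy = MergePolicy()

    def _probes(self, starts):
        starts = np.asarray(starts)
        return starts, starts + 50

    def test_four_probes_eight_kbp_bridged(self):
        # dec dec [4 normal probes over 8 kbp] dec dec
        starts, ends = self._probes(
            [0, 1_000, 2_000, 4_000, 6_000, 8_000, 10_050, 11_000]
        )
        segs = [Segment(D, 0, 1), Segment(D, 6, 7)]
        merged = bridge_merge(segs, starts, ends, self.policy)
        assert merged == [Segment(D, 0, 7)]

    def test_six_intervening_probes_not_merged(self):
        starts, ends = self._probes(
            [0, 1_000, 2_000, 3_000, 4_000, 5_000, 6_000, 7_000, 8_050, 9_000]
        )
        segs = [Segment(D, 0, 1), Segment(D, 8, 9)]
        assert bridge_merge(segs, starts, ends, self.policy) == segs

    def test_span_over_ten_kbp_not_merged(self):
        starts, ends = self._probes([0, 1_000, 5_000, 9_000, 13_200, 14_000])
        segs = [Segment(D, 0, 1), Segment(D, 4, 5)]
        assert bridge_merge(segs, starts, ends, self.policy) == segs

    def test_iterates_to_fixed_point(self):
        # three 1-probe segments, each pair bridgeable; chain must fuse fully
        starts, ends = self._probes([0, 4_000, 8_000, 12_000, 16_000])
        segs = [Segment(D, 0, 0), Segment(D, 2, 2), Segment(D, 4, 4)]
        assert bridge_merge(segs, starts, ends, self.policy) == [Segment(D, 0, 4)]

    def test_different_states_never_bridged(self):
        starts, ends = self._probes([0, 4_000, 8_000])
        segs = [Segment(D, 0, 0), Segment(I, 2, 2)]
        assert bridge_merge(segs, starts, ends, self.policy) == segs

    def test_idempotence_on_random_segmentations(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 60))
            starts = np.cumsum(rng.integers(200, 20_000, size=n))
            ends = starts + 50
            idx = np.sort(rng.choice(n, size=int(rng.integers(2, min(n, 10))), replace=False))
            segs = []
            for k in range(0, len(idx) - 1, 2):
                state = D if rng.random() < 0.5 else I
                segs.append(Segment(state, int(idx[k]), int(idx[k + 1])))
            segs = [
                s
                for i, s in enumerate(segs)
                if i == 0 or s.first > segs[i - 1].last
            ]
            once = bridge_merge(segs, starts, ends, self.policy)
            twice = bridge_merge(once, starts, ends, self.policy)
            assert once == twice


class TestCallSample:
    def test_noiseless_deletion_called_exactly(self):
        design = generate_design(ArrayDesignSpec.desk_scale(seed=12))
        region = design.hotspot_regions[0]
        mask = (
            (design.chroms == region.chrom)
            & (design.starts >= region.start)
            & (design.ends <= region.end)
        )
        idx = np.where(mask)[0][10:60]  # 50 probes, mid-hotspot
        iv = GenomicInterval(
            region.chrom, int(design.starts[idx[0]]), int(design.ends[idx[-1]])
        )
        cnv = CnvSpec(interval=iv, kind=CnvKind.DELETION, carrier_frequency=1.0)
        prof = simulate_sample(
            design, [cnv], NoiseModel(probe_noise_sd=0.01, sample_baseline_sd=0.0),
            seed=5,
        )
        calls = call_sample(prof, design)
        assert len(calls) == 1
        call = calls[0]
        assert call.state is CopyState.DECREASED
        assert call.interval == iv
        assert call.n_probes == 50
        assert call.mean_z < -1.5

    def test_flat_profile_no_calls(self, uniform_design, rng):
        values = rng.normal(0, 0.2, size=len(uniform_design))
        prof = SampleProfile("s", values, ValueKind.LOG2_RATIO)
        assert call_sample(prof, uniform_design) == []

    def test_deterministic(self, uniform_design, rng):
        values = rng.normal(0, 0.2, size=len(uniform_design))
        values[50:80] -= 1.0
        prof = SampleProfile("s", values, ValueKind.LOG2_RATIO)
        assert call_sample(prof, uniform_design) == call_sample(prof, uniform_design)

    def test_calls_sorted_and_nonoverlapping(self, uniform_design, rng):
        values = rng.normal(0, 0.2, size=len(uniform_design))
        values[20:40] -= 1.0
        values[100:130] += 0.585
        values[250:270] -= 1.0
        prof = SampleProfile("s", values, ValueKind.LOG2_RATIO)
        calls = call_sample(prof, uniform_design)
        assert len(calls) >= 2
        for a, b in zip(calls, calls[1:]):
            if a.interval.chrom == b.interval.chrom and a.state is b.state:
                assert a.interval.end < b.interval.start
        for c in calls:
            if c.state is CopyState.DECREASED:
                assert c.mean_z < 0
            else:
                assert c.mean_z > 0

    def test_sex_chromosomes_skipped_by_default(self, rng):
        design = make_design(
            {
                "chr1": list(range(10_000, 2_010_000, 10_000)),
                "chrX": list(range(10_000, 2_010_000, 10_000)),
            }
        )
        values = rng.normal(0, 0.2, size=len(design))
        sl = design.chrom_slices()["chrX"]
        values[sl.start + 50 : sl.start + 65] -= 1.0
        prof = SampleProfile("s", values, ValueKind.LOG2_RATIO)
        assert call_sample(prof, design) == []
        with_x = call_sample(prof, design, include_sex_chroms=True)
        assert any(c.interval.chrom == "chrX" for c in with_x)
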