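import numpy as np
import pytest

from shapealign import (
    AlignedPairSet,
    ReactivityProfile,
    SecondaryStructure,
    alignment_sensitivity,
    randomized_control,
    reactivity_difference_distribution,
    structure_compare,
)
from shapealign.evaluate import write_histogram_tsv
from shapealign.simulate import SimConfig, make_homologous_pair
from shapealign.types import MISSING


def _diag(n):
    return AlignedPairSet.from_pairs([(k, k) for k in range(n)], "reference")


class TestAlignmentSensitivity:
    def test_identical_sets_score_100(self):
        ref = _diag(100)
        assert alignment_sensitivity(ref, ref) == pytest.approx(100.0)

    def test_half_shared_scores_50(self):
        ref = _diag(100)
        test = AlignedPairSet.from_pairs([(k, k) for k in range(50)])
        assert alignment_sensitivity(test, ref) == pytest.approx(50.0)

    def test_extra_test_pairs_do_not_raise_sensitivity(self):
        ref = _diag(10)
        test = AlignedPairSet.from_pairs([(k, k) for k in range(10)] + [(10, 12)])
        assert alignment_sensitivity(test, ref) == pytest.approx(100.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            alignment_sensitivity(_diag(3), AlignedPairSet.from_pairs([]))

    def test_100_iff_reference_subset_of_test(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 30))
            ref_pairs = [(k, k) for k in range(n)]
            drop = bool(rng.random() < 0.5) and n > 1
            test_pairs = ref_pairs[1:] if drop else ref_pairs
            sens = alignment_sensitivity(
                AlignedPairSet.from_pairs(test_pairs), AlignedPairSet.from_pairs(ref_pairs)
            )
            assert (sens == 100.0) == (not drop)


def _structure(length, coords, sequence=None):
    return SecondaryStructure.from_pair_coords(length, coords, sequence)


class TestStructureCompare:
    def test_identical_structures(self):
        s = _structure(60, [(k, 59 - k) for k in range(10)])
        result = structure_compare(s, s)
        assert result.sens == 100.0 and result.ppv == 100.0

    def test_allowance_boundary_match(self):
        # one end equal, other end off by exactly the allowance -> matched
        ref = _structure(60, [(10, 45)])
        pred = _structure(60, [(10, 50)])
        result = structure_compare(pred, ref, allowance=5)
        assert result.sens == 100.0 and result.ppv == 100.0

    def test_neither_end_fixed_is_unmatched(self):
        ref = _structure(60, [(10, 45)])
        pred = _structure(60, [(12, 48)])
        result = structure_compare(pred, ref, allowance=5)
        assert result.sens == 0.0 and result.ppv == 0.0

    def test_allowance_zero_reduces_to_exact_matching(self):
        ref = _structure(60, [(10, 45), (11, 44)])
        pred = _structure(60, [(10, 45), (11, 43)])
        result = structure_compare(pred, ref, allowance=0)
        assert result.sens == pytest.approx(50.0)
        assert result.ppv == pytest.approx(50.0)

    def test_noncanonical_and_pseudoknot_pairs_filtered_from_both(self):
        seq = "GGGAAACCCAAAGGGAAACCC"
        # (0,8) G-C canonical; (3,12) A-G non-canonical; crossing pair flagged
        ref = _structure(21, [(0, 8), (3, 12)], seq)
        pred = _structure(21, [(0, 8)], seq)
        result = structure_compare(pred, ref, allowance=0)
        assert result.n_reference == 1  # A-G pair dropped
        assert result.sens == 100.0

    def test_symmetry_sens_equals_transposed_ppv(self, rng):
        for _ in range(20):
            length = 80
            a = _structure(length, _random_nested_pairs(rng, length))
            b = _structure(length, _random_nested_pairs(rng, length))
            if len(a.pairs) == 0 or len(b.pairs) == 0:
                continue
            allowance = int(rng.integers(0, 7))
            ab = structure_compare(a, b, allowance=allowance)
            ba = structure_compare(b, a, allowance=allowance)
            assert ab.sens == pytest.approx(ba.ppv)
            assert ab.ppv == pytest.approx(ba.sens)

    def test_allowance_monotonicity(self, rng):
        length = 80
        a = _structure(length, _random_nested_pairs(rng, length))
        b = _structure(length, _random_nested_pairs(rng, length))
        if len(a.pairs) == 0 or len(b.pairs) == 0:
            pytest.skip("degenerate random draw")
        results = [structure_compare(a, b, allowance=k) for k in range(8)]
        for prev, cur in zip(results, results[1:]):
            assert cur.sens >= prev.sens
            assert cur.ppv >= prev.ppv

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            structure_compare(_structure(10, [(0, 9)]), _structure(12, [(0, 9)]))


def _random_nested_pairs(rng, length, n_helices=4):
    pairs = []
    used = set()
    for _ in range(n_helices):
        x = int(rng.integers(0, length - 10))
        y = int(rng.integers(x + 4, min(length, x + 30)))
        if x in used or y in used:
            continue
        crossing = any(a < x < b < y or x < a < y < b for a, b in pairs)
        if not crossing:
            pairs.append((x, y))
            used.update((x, y))
    return pairs


class TestDiffDistribution:
    def _profiles(self, rx, ry):
        px = ReactivityProfile("x", "A" * len(rx), rx)
        py = ReactivityProfile("y", "A" * len(ry), ry)
        return px, py

    def test_identical_reactivities_fill_first_bin(self):
        px, py = self._profiles([0.5] * 5, [0.5] * 5)
        dist = reactivity_difference_distribution(_diag(5), px, py)
        assert dist.counts[0] == 5
        assert dist.counts.sum() == dist.n_pairs == 5

    def test_binning_of_two_known_differences(self):
        px, py = self._profiles([0.5, 0.5], [0.55, 0.75])
        dist = reactivity_difference_distribution(_diag(2), px, py, bin_width=0.1)
        assert dist.counts[0] == 1  # |d| = 0.05
        assert dist.counts[2] == 1  # |d| = 0.25
        assert dist.counts.sum() == 2

    def test_missing_reactivity_pairs_excluded(self):
        px, py = self._profiles([0.5, MISSING, 0.4], [0.5, 0.7, MISSING])
        dist = reactivity_difference_distribution(_diag(3), px, py)
        assert dist.n_pairs == 1
        assert dist.n_pairs_total == 3

    def test_nonpositive_bin_width_rejected(self):
        px, py = self._profiles([0.5], [0.5])
        with pytest.raises(ValueError):
            reactivity_difference_distribution(_diag(1), px, py, bin_width=0.0)


class TestRandomizedControl:
    def test_equal_reactivities_give_p_of_one(self):
        px = ReactivityProfile("x", "A" * 10, [0.7] * 10)
        py = ReactivityProfile("y", "A" * 10, [0.7] * 10)
        control = randomized_control(_diag(10), px, py, n_trials=4, seed=1)
        assert control.p_value == pytest.approx(1.0)
        np.testing.assert_array_equal(control.mean_counts, control.related.counts)

    def test_determinism_under_seed(self, rng):
        px = ReactivityProfile("x", "A" * 40, rng.exponential(0.8, 40))
        py = ReactivityProfile("y", "A" * 40, rng.exponential(0.8, 40))
        a = randomized_control(_diag(40), px, py, n_trials=8, seed=7)
        b = randomized_control(_diag(40), px, py, n_trials=8, seed=7)
        np.testing.assert_array_equal(a.mean_counts, b.mean_counts)
        np.testing.assert_array_equal(a.sd_counts, b.sd_counts)
        assert a.p_value == b.p_value

    def test_trials_conserve_reactivity_multiset(self, rng):
        """Randomization permutes values, so per-trial histograms hold
        exactly n_pairs observations each."""
        px = ReactivityProfile("x", "A" * 30, rng.exponential(0.8, 30))
        py = ReactivityProfile("y", "A" * 30, rng.exponential(0.8, 30))
        control = randomized_control(_diag(30), px, py, n_trials=6, seed=3)
        assert control.mean_counts.sum() == pytest.approx(control.related.n_pairs)

    def test_correlated_profiles_separate_from_randomized(self):
        """Related |d| mean < randomized |d| mean with Welch p < 0.01 on a
        synthetic correlated pair of ~2000 usable positions."""
        config = SimConfig(length=2200, indel_rate=0.0, substitution_rate=0.0,
                           related_delta_rate=8.0, missing_rate=0.02, seed=11)
        ancestor, descendant, truth = make_homologous_pair(config)
        control = randomized_control(truth, ancestor, descendant, n_trials=8, seed=5)
        assert control.related.n_pairs >= 2000
        assert control.related_mean < control.randomized_mean
        assert control.p_value < 0.01

    def test_too_few_usable_pairs_rejected(self):
        px = ReactivityProfile("x", "AC", [0.5, MISSING])
        py = ReactivityProfile("y", "AC", [0.5, 0.6])
        with pytest.raises(ValueError):
            randomized_control(_diag(2), px, py, n_trials=2, seed=0)

    def test_histogram_tsv_layout(self, tmp_path, rng):
        px = ReactivityProfile("x", "A" * 20, rng.exponential(0.8, 20))
        py = ReactivityProfile("y", "A" * 20, rng.exponential(0.8, 20))
        control = randomized_control(_diag(20), px, py, n_trials=3, seed=2)
        out = tmp_path / "hist.tsv"
        write_histogram_tsv(out, control)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == [
            "bin_low", "bin_high", "count", "randomized_mean", "randomized_sd",
        ]
        assert len(lines) == 1 + len(control.related.counts)
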