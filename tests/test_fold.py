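import numpy as np
import pytest

from conftest import HAIRPIN, HAIRPIN_STEM, hairpin_profile
from shapealign.fold import (
    ConsensusPairSet,
    ConstraintRejectedError,
    EngineNotFoundError,
    FoldJob,
    constrained_individual_fold,
    engine_version,
    extract_consensus_pairs,
    map_consensus_to_sequence,
    run_consensus_fold,
)

class TestExtractConsensusPairs:
    def test_strictly_greater_than_threshold(self):
        probs = {(2, 12): 0.96, (3, 11): 0.95, (4, 10): 0.951}
        kept = extract_consensus_pairs(probs, threshold=0.95, width=20)
        assert kept.coords() == [(2, 12), (4, 10)]  # 0.95 itself is dropped

    def test_retained_pairs_carry_probabilities(self):
        kept = extract_consensus_pairs({(1, 8): 0.99}, width=10)
        assert kept.pairs == ((1, 8, 0.99),)

    def test_empty_probability_set(self):
        kept = extract_consensus_pairs({}, width=5)
        assert len(kept) == 0

    def test_lowering_threshold_never_removes_pairs(self, rng):
        probs = {(int(i), int(i) + 4): float(p)
                 for i, p in zip(rng.integers(0, 40, 12) * 2, rng.random(12))}
        high = set(extract_consensus_pairs(probs, 0.9, width=100).coords())
        low = set(extract_consensus_pairs(probs, 0.5, width=100).coords())
        assert high <= low

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            extract_consensus_pairs({}, threshold=1.0)
        with pytest.raises(ValueError):
            extract_consensus_pairs({}, threshold=-0.1)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            extract_consensus_pairs({(0, 3): 1.2}, width=5)


class TestMapConsensusToSequence:
    def test_columns_map_through_upstream_gaps(self):
        pairs = ConsensusPairSet(((2, 10, 0.99),), 0.95, 12)
        row = "G-GCGAAAAGC-"  # column 2 -> seq 1, column 10 -> seq 9
        assert map_consensus_to_sequence(pairs, row) == [(1, 9)]

    def test_gap_column_drops_pair(self):
        pairs = ConsensusPairSet(((2, 10, 0.99),), 0.95, 12)
        row = "GG-CGAAAAGCC"
        assert map_consensus_to_sequence(pairs, row) == []

    def test_noncanonical_mapped_bases_dropped(self):
        pairs = ConsensusPairSet(((0, 11, 0.99),), 0.95, 12)
        row = "AGGCGAAAAGCC"  # maps to A-C: not WC/GU
        assert map_consensus_to_sequence(pairs, row) == []

    def test_positions_used_at_most_once(self):
        pairs = ConsensusPairSet(((0, 11, 0.99), (1, 10, 0.98)), 0.95, 12)
        row = "GGGCGAAAAGCC"
        mapped = map_consensus_to_sequence(pairs, row)
        flat = [pos for pair in mapped for pos in pair]
        assert len(flat) == len(set(flat))

    def test_row_width_mismatch_rejected(self):
        pairs = ConsensusPairSet(((0, 3, 0.99),), 0.95, 6)
        with pytest.raises(ValueError):
            map_consensus_to_sequence(pairs, "GGCC")


class TestFoldJobValidation:
    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            FoldJob((("a", HAIRPIN),), (None,))

    def test_profile_length_checked_against_ungapped_row(self):
        from shapealign import ReactivityProfile

        rows = (("a", HAIRPIN), ("b", HAIRPIN))
        short = ReactivityProfile("b", HAIRPIN[:19], np.full(19, 0.1))
        with pytest.raises(ValueError, match="length"):
            FoldJob(rows, (hairpin_profile("a"), short))


def test_missing_engine_raises_environment_error(monkeypatch):
    monkeypatch.setenv("PATH", "/nonexistent")
    with pytest.raises(EngineNotFoundError, match="RNAfold"):
        constrained_individual_fold("GGGAAACCC")


@pytest.mark.usefixtures("hairpin_rows", "hairpin_profiles")
class TestEnginePipeline:
    """Contract tests against the wrapped ViennaRNA engine on a designed
    hairpin whose stem folds unambiguously."""

    def test_engine_version_reported(self):
        assert "RNAfold" in engine_version()

    def test_consensus_fold_recovers_stem_with_high_probability(
        self, hairpin_rows, hairpin_profiles
    ):
        job = FoldJob(hairpin_rows, hairpin_profiles)
        consensus, probabilities = run_consensus_fold(job)
        kept = extract_consensus_pairs(probabilities, 0.95, width=job.width)
        assert set(HAIRPIN_STEM) <= set(kept.coords())

    def test_consensus_fold_is_deterministic(self, hairpin_rows, hairpin_profiles):
        job = FoldJob(hairpin_rows, hairpin_profiles)
        _, first = run_consensus_fold(job)
        _, second = run_consensus_fold(job)
        assert first == second

    def test_constrained_fold_contains_constraints(self):
        constraints = [(2, 17), (3, 16), (4, 15)]
        structure = constrained_individual_fold(HAIRPIN, None, constraints)
        assert set(constraints) <= set(structure.pair_coords())

    def test_unconstrained_fold_reduces_to_plain_mfe(self):
        with_empty = constrained_individual_fold(HAIRPIN, None, ())
        assert set(HAIRPIN_STEM) <= set(with_empty.pair_coords())

    def test_shape_profile_accepted_in_individual_fold(self):
        profile = hairpin_profile("probe")
        structure = constrained_individual_fold(HAIRPIN, profile, [(0, 19)])
        assert (0, 19) in structure.pair_coords()

    def test_two_step_pipeline_end_to_end(self, hairpin_rows, hairpin_profiles):
        job = FoldJob(hairpin_rows, hairpin_profiles)
        _, probabilities = run_consensus_fold(job)
        kept = extract_consensus_pairs(probabilities, 0.95, width=job.width)
        for (name, row), profile in zip(hairpin_rows, hairpin_profiles):
            constraints = map_consensus_to_sequence(kept, row)
            assert constraints  # ungapped rows: stem pairs survive mapping
            structure = constrained_individual_fold(row, profile, constraints)
            assert set(constraints) <= set(structure.pair_coords())

    def test_invalid_constraint_rejected_before_engine(self):
        with pytest.raises(ValueError, match="not canonical"):
            constrained_individual_fold("GGGGAAAAGGGG", None, [(0, 11)])
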