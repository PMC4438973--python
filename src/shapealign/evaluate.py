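"""Comparison statistics for alignments, structures and reactivity profiles.

* alignment sensitivity against a reference matched-pair set;
* secondary-structure sensitivity/PPV with a local refolding allowance;
* the distribution of absolute SHAPE reactivity differences over related
  nucleotide pairs, with a randomized (permutation) control and Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import AlignedPairSet, ReactivityProfile, SecondaryStructure

__all__ = [
    "alignment_sensitivity",
    "StructureComparison",
    "structure_compare",
    "DiffDistribution",
    "reactivity_difference_distribution",
    "RandomizedControl",
    "randomized_control",
    "write_histogram_tsv",
]


def alignment_sensitivity(test: AlignedPairSet, reference: AlignedPairSet) -> float:
    """Percentage of reference matched-nucleotide pairs found in ``test``.

    Exact pair identity — no positional allowance.
    """
    if len(reference) == 0:
        raise ValueError("sensitivity is undefined for an empty reference")
    shared = test.pairs & reference.pairs
    return 100.0 * len(shared) / len(reference)


@dataclass(frozen=True)
class StructureComparison:
    """Sensitivity / PPV of a predicted structure against a reference."""

    sens: float
    ppv: float
    allowance: int
    matched_reference: tuple
    unmatched_reference: tuple
    matched_predicted: tuple
    unmatched_predicted: tuple
    n_reference: int
    n_predicted: int


def _pairs_match(ref, pred, allowance: int) -> bool:
    x, y = ref
    xp, yp = pred
    return (x == xp and abs(y - yp) <= allowance) or (
        y == yp and abs(x - xp) <= allowance
    )


def structure_compare(
    predicted: SecondaryStructure,
    reference: SecondaryStructure,
    allowance: int = 5,
) -> StructureComparison:
    """Compare base-pair sets with a local refolding allowance.

    Pseudoknotted and non-canonical pairs (G-U excepted) are removed from
    both structures first.  A reference pair (x, y) is matched if some
    predicted pair (x', y') has one coinciding end and the other end within
    ``allowance`` nucleotides; ``allowance=0`` reduces to exact matching.
    """
    if predicted.length != reference.length:
        raise ValueError(
            f"structures have different lengths ({predicted.length} vs {reference.length})"
        )
    if allowance < 0:
        raise ValueError("allowance must be >= 0")
    ref_pairs = sorted(reference.filtered().pair_coords())
    pred_pairs = sorted(predicted.filtered().pair_coords())
    matched_ref = [
        r for r in ref_pairs if any(_pairs_match(r, p, allowance) for p in pred_pairs)
    ]
    matched_pred = [
        p for p in pred_pairs if any(_pairs_match(r, p, allowance) for r in ref_pairs)
    ]
    if not ref_pairs:
        raise ValueError("reference structure has no comparable (canonical, nested) pairs")
    sens = 100.0 * len(matched_ref) / len(ref_pairs)
    ppv = 100.0 * len(matched_pred) / len(pred_pairs) if pred_pairs else 0.0
    return StructureComparison(
        sens=sens,
        ppv=ppv,
        allowance=allowance,
        matched_reference=tuple(matched_ref),
        unmatched_reference=tuple(r for r in ref_pairs if r not in set(matched_ref)),
        matched_predicted=tuple(matched_pred),
        unmatched_predicted=tuple(p for p in pred_pairs if p not in set(matched_pred)),
        n_reference=len(ref_pairs),
        n_predicted=len(pred_pairs),
    )


@dataclass(frozen=True)
class DiffDistribution:
    """Histogram of absolute reactivity differences over related pairs."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_pairs: int
    n_pairs_total: int  # including pairs dropped for missing reactivity

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n_pairs:
            raise ValueError("histogram does not conserve the pair count")


def _paired_differences(
    pairs: AlignedPairSet, px: ReactivityProfile, py: ReactivityProfile
):
    idx = np.array(sorted(pairs.pairs), dtype=int).reshape(-1, 2)
    rx = px.reactivities[idx[:, 0]] if len(idx) else np.empty(0)
    ry = py.reactivities[idx[:, 1]] if len(idx) else np.empty(0)
    keep = ~(np.isnan(rx) | np.isnan(ry))
    return rx[keep], ry[keep], len(idx)


def _edges(max_diff: float, bin_width: float) -> np.ndarray:
    n_bins = max(1, int(np.ceil(max_diff / bin_width + 1e-12)))
    return np.arange(n_bins + 1) * bin_width


def reactivity_difference_distribution(
    pairs: AlignedPairSet,
    px: ReactivityProfile,
    py: ReactivityProfile,
    bin_width: float = 0.1,
) -> DiffDistribution:
    """Histogram of |r_x(i) - r_y(j)| over pairs with both reactivities present."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    rx, ry, n_total = _paired_differences(pairs, px, py)
    diffs = np.abs(rx - ry)
    edges = _edges(float(diffs.max()) if diffs.size else bin_width, bin_width)
    counts, _ = np.histogram(diffs, bins=edges)
    return DiffDistribution(edges, counts, int(diffs.size), n_total)


@dataclass(frozen=True)
class RandomizedControl:
    """Randomized-pairing control for the related-|Δ| distribution.

    ``mean_counts`` / ``sd_counts`` are per-bin across trials, on the same
    ``bin_edges`` as ``related``; ``p_value`` is a Welch two-sample t-test
    of related vs pooled randomized |Δ| samples.
    """

    related: DiffDistribution
    mean_counts: np.ndarray
    sd_counts: np.ndarray
    p_value: float
    n_trials: int
    related_mean: float
    randomized_mean: float


def randomized_control(
    pairs: AlignedPairSet,
    px: ReactivityProfile,
    py: ReactivityProfile,
    n_trials: int = 8,
    seed: int | None = None,
    bin_width: float = 0.1,
) -> RandomizedControl:
    """Permute one side's reactivities across paired positions, ``n_trials``
    times, and compare the resulting |Δ| distribution with the related one.

    The permutation preserves the multiset of reactivities and destroys only
    the pairing; each trial draws an independent uniform permutation from a
    generator seeded with ``seed``.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 randomization trials")
    rx, ry, n_total = _paired_differences(pairs, px, py)
    if rx.size < 2:
        raise ValueError("need at least 2 pairs with reactivity on both sides")
    rng = np.random.default_rng(seed)
    related_diffs = np.abs(rx - ry)
    trial_diffs = [np.abs(rx - rng.permutation(ry)) for _ in range(n_trials)]
    max_diff = max(
        float(related_diffs.max()), max(float(d.max()) for d in trial_diffs)
    )
    edges = _edges(max_diff, bin_width)
    related_counts, _ = np.histogram(related_diffs, bins=edges)
    related = DiffDistribution(edges, related_counts, int(rx.size), n_total)
    trial_counts = np.stack([np.histogram(d, bins=edges)[0] for d in trial_diffs])
    pooled = np.concatenate(trial_diffs)
    if np.ptp(related_diffs) == 0 and np.ptp(pooled) == 0:
        p_value = 1.0  # identical constant samples: no evidence of separation
    else:
        p_value = float(
            stats.ttest_ind(related_diffs, pooled, equal_var=False).pvalue
        )
    return RandomizedControl(
        related=related,
        mean_counts=trial_counts.mean(axis=0),
        sd_counts=trial_counts.std(axis=0, ddof=1),
        p_value=p_value,
        n_trials=n_trials,
        related_mean=float(related_diffs.mean()),
        randomized_mean=float(pooled.mean()),
    )


def write_histogram_tsv(path, control: RandomizedControl) -> None:
    """Per-bin TSV: bin_low, bin_high, count, randomized_mean, randomized_sd."""
    edges = control.related.bin_edges
    with open(path, "w") as fh:
        fh.write("bin_low\tbin_high\tcount\trandomized_mean\trandomized_sd\n")
        for k in range(len(control.related.counts)):
            fh.write(
                f"{edges[k]:.4f}\t{edges[k + 1]:.4f}\t{control.related.counts[k]}\t"
                f"{control.mean_counts[k]:.4f}\t{control.sd_counts[k]:.4f}\n"
            )


def write_sensitivity_tsv(path, rows) -> None:
    """Sensitivity table: one row per (pair label, mode, sensitivity)."""
    with open(path, "w") as fh:
        fh.write("sequence_1\tsequence_2\tmode\tsensitivity_pct\n")
        for name_x, name_y, mode, sens in rows:
            fh.write(f"{name_x}\t{name_y}\t{mode}\t{sens:.1f}\n")


def write_structure_comparison_tsv(path, rows) -> None:
    """Structure-accuracy table: one row per (RNA label, condition, sens, ppv)."""
    with open(path, "w") as fh:
        fh.write("rna\tcondition\tsens_pct\tppv_pct\tn_reference\tn_predicted\n")
        for label, condition, cmp_result in rows:
            fh.write(
                f"{label}\t{condition}\t{cmp_result.sens:.1f}\t{cmp_result.ppv:.1f}\t"
                f"{cmp_result.n_reference}\t{cmp_result.n_predicted}\n"
            )
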