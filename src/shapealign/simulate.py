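"""Synthetic homologous reactivity profiles with known true alignments.

The generator emulates the statistical structure the alignment method relies
on: per-nucleotide SHAPE reactivities with a low-reactivity component at
paired positions and a high-reactivity component at unpaired positions, and
homolog pairs whose related-position reactivity differences follow an
exponential-decay distribution.  Sequences diverge by per-site substitutions
and geometric-length indels, and the exact ancestor-descendant position
matching is returned alongside the descendant, so alignment recovery can be
scored against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import MISSING, AlignedPairSet, ReactivityProfile

__all__ = [
    "SimConfig",
    "random_structure_mask",
    "simulate_reactivity_profile",
    "evolve_homolog",
    "make_homologous_pair",
]

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic homolog generator.

    Attributes
    ----------
    length :
        Ancestor length in nucleotides (default 1500, small-subunit rRNA scale).
    substitution_rate :
        Per-site probability of a base substitution in the descendant
        (default 0.25, matching ~75% nucleotide identity between divergent
        eubacterial rRNAs).
    indel_rate :
        Per-site probability of starting an indel event (split evenly
        between insertion and deletion).
    mean_indel_length :
        Mean of the geometric indel length distribution, nt.
    related_delta_rate :
        Rate λ of the exponential |Δ| model: homologous positions differ in
        reactivity by Exp(λ) magnitudes (SHAPE units⁻¹).
    missing_rate :
        Per-position probability of missing (unprobed) reactivity.
    paired_fraction :
        Fraction of positions drawn from the low-reactivity (paired)
        component.
    paired_mean, unpaired_mean :
        Means of the exponential reactivity components, SHAPE units.
    seed :
        Default seed for functions not given one explicitly.
    """

    length: int = 1500
    substitution_rate: float = 0.25
    indel_rate: float = 0.02
    mean_indel_length: float = 3.0
    related_delta_rate: float = 4.0
    missing_rate: float = 0.05
    paired_fraction: float = 0.55
    paired_mean: float = 0.1
    unpaired_mean: float = 1.0
    seed: int = 2015

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        for name in ("substitution_rate", "indel_rate", "missing_rate", "paired_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.related_delta_rate <= 0:
            raise ValueError("related_delta_rate (lambda) must be positive")
        if self.mean_indel_length < 1:
            raise ValueError("mean_indel_length must be >= 1 nt")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_structure_mask(length: int, paired_fraction: float, seed) -> np.ndarray:
    """Boolean per-position mask, True = paired."""
    rng = _rng(seed)
    return rng.random(length) < paired_fraction


def simulate_reactivity_profile(
    structure_mask: np.ndarray, config: SimConfig, seed, name: str = "ancestor"
) -> ReactivityProfile:
    """Draw a reactivity profile for a random sequence over a structure mask.

    Paired positions draw from an exponential with mean ``paired_mean``,
    unpaired positions from one with mean ``unpaired_mean``; positions go
    MISSING independently at ``missing_rate``.
    """
    mask = np.asarray(structure_mask, dtype=bool)
    if mask.shape != (config.length,):
        raise ValueError(
            f"structure mask length {mask.size} != configured length {config.length}"
        )
    rng = _rng(seed)
    sequence = "".join(rng.choice(_BASES, size=config.length))
    means = np.where(mask, config.paired_mean, config.unpaired_mean)
    reactivities = rng.exponential(means)
    missing = rng.random(config.length) < config.missing_rate
    reactivities[missing] = MISSING
    return ReactivityProfile(name, sequence, reactivities)


def _perturb_reactivity(value: float, lam: float, rng: np.random.Generator) -> float:
    """Exponential-magnitude perturbation with |Δ| ~ Exp(lam) exactly.

    The sign is random where subtraction stays non-negative and forced
    positive otherwise, so values remain valid (>= 0) without clipping the
    difference magnitude.
    """
    magnitude = rng.exponential(1.0 / lam)
    sign = 1.0 if value - magnitude < 0 else (1.0 if rng.random() < 0.5 else -1.0)
    return value + sign * magnitude


def evolve_homolog(
    ancestor: ReactivityProfile, config: SimConfig, seed, name: str = "descendant"
):
    """Mutate an ancestor profile into a homolog with a known true alignment.

    Substitutions occur at ``substitution_rate`` per retained site; indel
    events start at ``indel_rate`` per site (half insertions, half deletions)
    with geometric lengths.  Retained positions keep the ancestor reactivity
    plus a sign-symmetric Exp(λ) perturbation; inserted positions draw fresh
    reactivities from the two-component model.  Missing data are injected at
    ``missing_rate`` and ancestor-missing positions stay missing.

    Returns ``(descendant ReactivityProfile, true AlignedPairSet)``.
    """
    rng = _rng(seed)
    lam = config.related_delta_rate
    p_event = config.indel_rate
    geo_p = 1.0 / config.mean_indel_length

    bases: list = []
    reactivities: list = []
    true_pairs: list = []

    def insert_run() -> None:
        length = rng.geometric(geo_p)
        for _ in range(length):
            bases.append(str(rng.choice(_BASES)))
            if rng.random() < config.missing_rate:
                reactivities.append(MISSING)
            else:
                paired = rng.random() < config.paired_fraction
                mean = config.paired_mean if paired else config.unpaired_mean
                reactivities.append(rng.exponential(mean))

    i = 0
    n = len(ancestor)
    while i < n:
        event = rng.random()
        if event < p_event / 2:
            i += int(rng.geometric(geo_p))  # deletion: skip ancestor positions
            continue
        if event < p_event:
            insert_run()
        base = ancestor.sequence[i]
        if rng.random() < config.substitution_rate:
            base = str(rng.choice(_BASES[_BASES != base]))
        r_anc = ancestor.reactivities[i]
        if np.isnan(r_anc) or rng.random() < config.missing_rate:
            r_desc = MISSING
        else:
            r_desc = _perturb_reactivity(float(r_anc), lam, rng)
        true_pairs.append((i, len(bases)))
        bases.append(base)
        reactivities.append(r_desc)
        i += 1

    if not bases:  # pathological all-deleted draw: keep the last position
        true_pairs.append((n - 1, 0))
        bases.append(ancestor.sequence[-1])
        reactivities.append(float(ancestor.reactivities[-1]))

    descendant = ReactivityProfile(name, "".join(bases), np.array(reactivities))
    return descendant, AlignedPairSet.from_pairs(true_pairs, source="reference")


def make_homologous_pair(config: SimConfig, seed=None):
    """Convenience wrapper: mask + ancestor + descendant + true alignment.

    Returns ``(ancestor, descendant, true AlignedPairSet)``; ``seed`` defaults
    to ``config.seed``.
    """
    root = np.random.default_rng(config.seed if seed is None else seed)
    mask_rng, anc_rng, evo_rng = (
        np.random.default_rng(s) for s in root.integers(0, 2**31 - 1, size=3)
    )
    mask = random_structure_mask(config.length, config.paired_fraction, mask_rng)
    ancestor = simulate_reactivity_profile(mask, config, anc_rng)
    descendant, truth = evolve_homolog(ancestor, config, evo_rng)
    return ancestor, descendant, truth
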