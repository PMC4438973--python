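"""Core domain objects: reactivity profiles, alignment pair sets, secondary structures.

Conventions used throughout the package:

* All in-memory coordinates are 0-based; every file interface is 1-based.
* Sequences are normalized to the RNA alphabet (``T`` -> ``U``, upper case).
* A missing SHAPE reactivity is represented by ``NaN`` (the constant
  :data:`MISSING`); the on-disk sentinel is ``-999``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "is_missing",
    "RNA_ALPHABET",
    "CANONICAL_PAIRS",
    "ShapeAlignError",
    "FormatError",
    "ReactivityProfile",
    "AlignedPairSet",
    "BasePair",
    "SecondaryStructure",
    "normalize_sequence",
]

#: Marker for an unprobed / undetermined reactivity.
MISSING: float = float("nan")

#: Characters accepted after normalization.
RNA_ALPHABET = frozenset("ACGUN")

#: Canonical base pairs: Watson-Crick plus the G-U wobble.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class ShapeAlignError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ShapeAlignError):
    """Malformed input file."""


def is_missing(value: float) -> bool:
    """True if ``value`` is the MISSING reactivity marker."""
    return isinstance(value, float) and math.isnan(value)


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Upper-case and DNA->RNA normalize, rejecting non-IUPAC characters.

    Characters outside ``{A, C, G, U, T, N}`` raise :class:`FormatError`.
    """
    norm = seq.upper().replace("T", "U")
    bad = set(norm) - RNA_ALPHABET
    if bad:
        raise FormatError(
            f"{context}: non-IUPAC character(s) {sorted(bad)!r} in sequence"
        )
    return norm


@dataclass(frozen=True)
class ReactivityProfile:
    """A named RNA sequence with one SHAPE reactivity per nucleotide.

    Parameters
    ----------
    name :
        Identifier (FASTA header), case preserved.
    sequence :
        Nucleotide string over ``{A, C, G, U, N}`` (normalized on input).
    reactivities :
        Array of per-nucleotide SHAPE reactivities in arbitrary SHAPE units;
        ``NaN`` marks missing data.  Small negative values are legitimate
        (SHAPE-MaP normalization can produce them) and are kept as-is.
    """

    name: str
    sequence: str
    reactivities: np.ndarray

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence, context=f"profile {self.name!r}")
        object.__setattr__(self, "sequence", seq)
        arr = np.asarray(self.reactivities, dtype=float)
        arr = np.array(arr, copy=True)
        arr.setflags(write=False)
        object.__setattr__(self, "reactivities", arr)
        if arr.ndim != 1 or len(arr) != len(seq):
            raise ValueError(
                f"profile {self.name!r}: {len(seq)} nucleotides but "
                f"{arr.size} reactivities"
            )
        finite_or_nan = np.isfinite(arr) | np.isnan(arr)
        if not finite_or_nan.all():
            raise ValueError(
                f"profile {self.name!r}: non-finite reactivity that is not MISSING"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.reactivities)

    @classmethod
    def without_reactivities(cls, name: str, sequence: str) -> "ReactivityProfile":
        """Profile with every position MISSING (sequence-only input)."""
        return cls(name, sequence, np.full(len(sequence), MISSING))


@dataclass(frozen=True)
class AlignedPairSet:
    """The matched (i, j) nucleotide pairs extracted from an alignment.

    ``i`` indexes the first sequence and ``j`` the second, both 0-based.
    The set must be a colinear partial matching: each index appears at most
    once per side and, sorted by ``i``, the ``j`` values strictly increase.
    """

    pairs: frozenset
    source: str = "predicted"

    def __post_init__(self) -> None:
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        ordered = sorted(pairs)
        seen_j = set()
        last_j = -1
        for i, j in ordered:
            if i < 0 or j < 0:
                raise ValueError("alignment pair with negative coordinate")
            if j in seen_j:
                raise ValueError(f"position {j} matched more than once in sequence 2")
            seen_j.add(j)
            if j <= last_j:
                raise ValueError("crossing pairs violate alignment colinearity")
            last_j = j
        # i-uniqueness is implied by set semantics + the sort, but check anyway
        i_values = [i for i, _ in ordered]
        if len(i_values) != len(set(i_values)):
            raise ValueError("position matched more than once in sequence 1")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs))

    @classmethod
    def from_pairs(cls, pairs: Iterable, source: str = "predicted") -> "AlignedPairSet":
        return cls(frozenset(tuple(p) for p in pairs), source)


@dataclass(frozen=True)
class BasePair:
    """A base pair (x, y), x < y, 0-based, with classification flags."""

    x: int
    y: int
    canonical: bool = True
    pseudoknot: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.x < self.y:
            raise ValueError(f"base pair ({self.x}, {self.y}) must satisfy 0 <= x < y")

    @property
    def coords(self) -> tuple:
        return (self.x, self.y)


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs on a sequence of known length.

    Each position participates in at most one pair.  Pairs carry a
    ``canonical`` flag (Watson-Crick or G-U when a sequence is available)
    and a ``pseudoknot`` flag (crossing / non-primary bracket tier).
    """

    length: int
    pairs: tuple = ()
    sequence: str | None = None

    def __post_init__(self) -> None:
        pairs = tuple(
            p if isinstance(p, BasePair) else BasePair(*p) for p in self.pairs
        )
        object.__setattr__(self, "pairs", pairs)
        if self.sequence is not None:
            seq = normalize_sequence(self.sequence, context="structure sequence")
            if len(seq) != self.length:
                raise ValueError("structure sequence length != declared length")
            object.__setattr__(self, "sequence", seq)
        used = set()
        for p in pairs:
            if p.y >= self.length:
                raise ValueError(f"pair {p.coords} outside structure of length {self.length}")
            for pos in p.coords:
                if pos in used:
                    raise ValueError(f"position {pos} participates in more than one pair")
                used.add(pos)

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_coords(self) -> frozenset:
        return frozenset(p.coords for p in self.pairs)

    def filtered(self) -> "SecondaryStructure":
        """Drop pseudoknotted and non-canonical pairs (G-U kept)."""
        kept = tuple(p for p in self.pairs if p.canonical and not p.pseudoknot)
        return SecondaryStructure(self.length, kept, self.sequence)

    @classmethod
    def from_pair_coords(
        cls,
        length: int,
        coords: Iterable,
        sequence: str | None = None,
    ) -> "SecondaryStructure":
        """Build a structure, deriving canonical and pseudoknot flags.

        Canonical flags are evaluated against ``sequence`` when given
        (otherwise every pair is taken at face value as canonical).
        Pseudoknot flags are assigned greedily: pairs are visited in 5'
        order and a pair crossing any previously accepted pair is flagged.
        """
        seq = normalize_sequence(sequence) if sequence is not None else None
        ordered = sorted((min(x, y), max(x, y)) for x, y in coords)
        accepted: list = []
        pairs = []
        for x, y in ordered:
            crossing = any(a < x < b < y or x < a < y < b for a, b in accepted)
            if not crossing:
                accepted.append((x, y))
            if seq is not None:
                canonical = (seq[x], seq[y]) in CANONICAL_PAIRS
            else:
                canonical = True
            pairs.append(BasePair(x, y, canonical=canonical, pseudoknot=crossing))
        return cls(length, tuple(pairs), seq)
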