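import numpy as np
import pytest

from shapealign import AlignmentParams, ReactivityProfile
from shapealign.types import MISSING


@pytest.fixture
def rng():
    return np.random.default_rng(20150520)


def random_profile(rng, length, name="p", missing_rate=0.15):
    """Random profile with exponential reactivities and injected missing data."""
    r = rng.exponential(0.7, size=length)
    r[rng.random(length) < missing_rate] = MISSING
    seq = "".join(rng.choice(list("ACGU"), size=length))
    return ReactivityProfile(name, seq, r)


def random_params(rng, mode):
    return AlignmentParams(
        m=-float(rng.uniform(0.5, 4.0)),
        b=float(rng.uniform(0.5, 4.0)),
        gop=-float(rng.uniform(0.5, 8.0)),
        gep=-float(rng.uniform(0.05, 2.0)),
        match=float(rng.uniform(0.0, 3.0)),
        mismatch=-float(rng.uniform(0.0, 3.0)),
        mode=mode,
    )


# A 20-nt hairpin whose 8-bp GC-rich stem folds unambiguously: used to test
# the consensus-folding pipeline without any external data.
HAIRPIN = "GCGCGCGGUUCGCCGCGCGC"
HAIRPIN_VARIANT = "GCGCACGGUUCGCCGUGCGC"  # covarying compensatory change
HAIRPIN_STEM = [(k, 19 - k) for k in range(8)]


def hairpin_profile(name, sequence=HAIRPIN):
    """SHAPE profile consistent with the hairpin: low stem, high loop."""
    react = np.array([0.1] * 8 + [1.2, 1.5, 1.4, 1.1] + [0.1] * 8)
    return ReactivityProfile(name, sequence, react)


@pytest.fixture
def hairpin_rows():
    return (
        ("seq1", HAIRPIN),
        ("seq2", HAIRPIN),
        ("seq3", HAIRPIN_VARIANT),
        ("seq4", HAIRPIN),
    )


@pytest.fixture
def hairpin_profiles(hairpin_rows):
    return tuple(hairpin_profile(name, row) for name, row in hairpin_rows)
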