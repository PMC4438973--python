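"""Pairwise column scoring: SHAPE-difference line and base-identity term.

The SHAPE comparison score for reactivities ``ri`` and ``rj`` is a clipped
line in the absolute difference d = |ri - rj|:

    s(ri, rj) = max(m * d + b,  m + b)

with slope ``m < 0`` and intercept ``b > 0``, so the score is ``b`` at d = 0,
declines linearly, and floors at the value attained at d = 1 (zero with the
published parameters m = -2, b = 2).  Comparisons involving a MISSING
reactivity score 0 (neutral).  In combined mode a base-identity term
(MATCH for identical bases, MISMATCH otherwise; ``N`` never matches) is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .types import ReactivityProfile, is_missing

__all__ = [
    "AlignmentParams",
    "SHAPE_ONLY_DEFAULTS",
    "COMBINED_DEFAULTS",
    "shape_score",
    "base_score",
    "column_score",
    "score_matrix",
    "load_params",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and gap parameters for SHAPE-based alignment.

    Attributes
    ----------
    m, b :
        Slope (score units per SHAPE unit, negative) and intercept of the
        SHAPE comparison line.
    gop, gep :
        Gap opening and extension penalties (both <= 0).  A gap of length L
        costs ``gop + L * gep``.
    match, mismatch :
        Base-identity bonus / penalty, used only in ``combined`` mode.
    mode :
        ``"shape_only"`` or ``"combined"``.
    """

    m: float = -2.0
    b: float = 2.0
    gop: float = -5.0
    gep: float = -0.25
    match: float = 2.0
    mismatch: float = -2.0
    mode: str = "shape_only"

    def __post_init__(self) -> None:
        if self.mode not in ("shape_only", "combined"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (self.m < 0 and self.b > 0):
            raise ValueError("require m < 0 and b > 0 (small differences must score high)")
        if self.gop > 0 or self.gep > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.mode == "combined" and not (self.match >= 0 >= self.mismatch):
            raise ValueError("combined mode requires MATCH >= 0 >= MISMATCH")

    @property
    def floor(self) -> float:
        """Minimum SHAPE comparison score (value of the line at d = 1)."""
        return self.m + self.b

    def with_mode(self, mode: str) -> "AlignmentParams":
        return replace(self, mode=mode)


#: Published optimum for SHAPE-only alignment.
SHAPE_ONLY_DEFAULTS = AlignmentParams(
    m=-2.0, b=2.0, gop=-5.0, gep=-0.25, mode="shape_only"
)

#: Published optimum when base identity is considered as well.
COMBINED_DEFAULTS = AlignmentParams(
    m=-2.0, b=2.0, gop=-6.0, gep=-1.0, match=2.0, mismatch=-2.0, mode="combined"
)


def default_params(mode: str) -> AlignmentParams:
    if mode == "shape_only":
        return SHAPE_ONLY_DEFAULTS
    if mode == "combined":
        return COMBINED_DEFAULTS
    raise ValueError(f"unknown mode {mode!r}")


def shape_score(ri: float, rj: float, params: AlignmentParams) -> float:
    """SHAPE comparison score; 0 (neutral) if either reactivity is MISSING."""
    if is_missing(ri) or is_missing(rj):
        return 0.0
    if not (math.isfinite(ri) and math.isfinite(rj)):
        raise ValueError("reactivity must be finite or MISSING")
    return max(params.m * abs(ri - rj) + params.b, params.m + params.b)


def base_score(xi: str, yj: str, params: AlignmentParams) -> float:
    """MATCH for identical bases, MISMATCH otherwise; N never matches."""
    if xi == yj and xi != "N":
        return params.match
    return params.mismatch


def column_score(
    i: int,
    j: int,
    px: ReactivityProfile,
    py: ReactivityProfile,
    params: AlignmentParams,
) -> float:
    """Score for aligning position ``i`` of ``px`` with ``j`` of ``py``."""
    if not 0 <= i < len(px):
        raise IndexError(f"position {i} outside profile {px.name!r}")
    if not 0 <= j < len(py):
        raise IndexError(f"position {j} outside profile {py.name!r}")
    score = shape_score(px.reactivities[i], py.reactivities[j], params)
    if params.mode == "combined":
        score += base_score(px.sequence[i], py.sequence[j], params)
    return score


def score_matrix(
    px: ReactivityProfile, py: ReactivityProfile, params: AlignmentParams
) -> np.ndarray:
    """Dense |px| x |py| matrix of column scores (vectorized)."""
    rx = px.reactivities[:, None]
    ry = py.reactivities[None, :]
    diff = np.abs(rx - ry)
    scores = np.maximum(params.m * diff + params.b, params.m + params.b)
    missing = np.isnan(rx) | np.isnan(ry)
    scores = np.where(missing, 0.0, scores)
    if params.mode == "combined":
        bx = np.frombuffer(px.sequence.encode(), dtype="S1")[:, None]
        by = np.frombuffer(py.sequence.encode(), dtype="S1")[None, :]
        matched = (bx == by) & (bx != b"N")
        scores = scores + np.where(matched, params.match, params.mismatch)
    return scores


def load_params(path, mode: str | None = None) -> AlignmentParams:
    """Read ``key = value`` parameter files (keys: m, b, gop, gep, match,
    mismatch, mode); unspecified keys take the published defaults for the
    file's (or caller's) mode."""
    raw: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            raw[key.lower()] = value
    mode = raw.pop("mode", mode or "shape_only").replace("-", "_")
    base = default_params(mode)
    numeric = {}
    for key, value in raw.items():
        if key not in ("m", "b", "gop", "gep", "match", "mismatch"):
            raise ValueError(f"{path}: unknown parameter {key!r}")
        numeric[key] = float(value)
    return replace(base, **numeric)
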