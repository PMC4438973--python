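"""Two-step SHAPE-directed consensus structure modeling.

Step 1 folds a multiple sequence alignment with ``RNAalifold`` (partition
function, ribosum scoring, per-sequence SHAPE pseudo-free energies, maximum
base-pair span 600 nt) and keeps consensus pairs whose pairing probability
exceeds 0.95.  Step 2 maps those alignment-column pairs onto each individual
sequence and refolds each sequence with ``RNAfold`` under hard pair
constraints, again with SHAPE pseudo-energies and the same span limit.

The folding engine (ViennaRNA) is wrapped, never reimplemented; its version
and every command line are logged.
"""

from __future__ import annotations

import logging
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

from .io import (
    GAP_CHARS,
    structure_from_dotbracket,
    write_clustal,
    write_shape_reactivities,
)
from .types import (
    CANONICAL_PAIRS,
    ReactivityProfile,
    SecondaryStructure,
    ShapeAlignError,
)

__all__ = [
    "EngineError",
    "EngineNotFoundError",
    "FoldJob",
    "engine_version",
    "run_consensus_fold",
    "ConsensusPairSet",
    "extract_consensus_pairs",
    "map_consensus_to_sequence",
    "constrained_individual_fold",
]

logger = logging.getLogger(__name__)

RNAALIFOLD = "RNAalifold"
RNAFOLD = "RNAfold"


class EngineError(ShapeAlignError):
    """The external folding engine failed."""


class EngineNotFoundError(EngineError):
    """Folding engine executable is not on PATH."""


class ConstraintRejectedError(EngineError):
    """The engine's output does not honor the requested pair constraints."""

    def __init__(self, missing_pairs):
        self.missing_pairs = tuple(sorted(missing_pairs))
        super().__init__(
            f"constraint pairs absent from folded structure: {self.missing_pairs}"
        )


def _require(executable: str) -> str:
    path = shutil.which(executable)
    if path is None:
        raise EngineNotFoundError(
            f"folding engine executable {executable!r} not found on PATH"
        )
    return path


def engine_version() -> str:
    """Version string of the wrapped ViennaRNA engine."""
    out = _run([_require(RNAFOLD), "--version"], cwd=None)
    return out.strip().splitlines()[0]


def _run(cmd, cwd, stdin_text: str | None = None) -> str:
    logger.info("engine command: %s", " ".join(cmd))
    proc = subprocess.run(
        cmd,
        cwd=cwd,
        input=stdin_text,
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise EngineError(
            f"{cmd[0]} exited with status {proc.returncode}: {proc.stderr.strip()}"
        )
    return proc.stdout


@dataclass(frozen=True)
class FoldJob:
    """Inputs for the consensus folding step.

    ``rows`` are ``(name, gapped alignment row)``; ``profiles`` are ungapped,
    one per row and length-matched to the row's gap-free sequence.
    """

    rows: tuple
    profiles: tuple
    max_pair_distance: int = 600
    ribosum: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if len(self.rows) < 2:
            raise ValueError("alignment folding needs at least 2 rows")
        if self.max_pair_distance <= 0:
            raise ValueError("max pair distance must be positive")
        widths = {len(row) for _, row in self.rows}
        if len(widths) != 1:
            raise ValueError("alignment rows have unequal widths")
        if len(self.profiles) != len(self.rows):
            raise ValueError("need exactly one SHAPE profile per alignment row")
        for (name, row), profile in zip(self.rows, self.profiles):
            ungapped = sum(1 for c in row if c not in GAP_CHARS)
            if profile is not None and len(profile) != ungapped:
                raise ValueError(
                    f"profile for row {name!r} has length {len(profile)}, "
                    f"gap-free row has {ungapped}"
                )

    @property
    def width(self) -> int:
        return len(self.rows[0][1])


@dataclass(frozen=True)
class ConsensusPairSet:
    """Alignment-column pairs retained at a pairing-probability threshold."""

    pairs: tuple  # ((i, j, probability), ...) sorted, 0-based columns
    threshold: float
    width: int

    def __post_init__(self) -> None:
        for i, j, p in self.pairs:
            if not 0 <= i < j < self.width:
                raise ValueError(f"consensus pair ({i}, {j}) outside alignment width")
            if not p > self.threshold:
                raise ValueError(
                    f"consensus pair ({i}, {j}) at p={p} does not exceed the threshold"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def coords(self):
        return [(i, j) for i, j, _ in self.pairs]


def run_consensus_fold(job: FoldJob, workdir=None):
    """Fold an alignment with RNAalifold (partition function + SHAPE).

    Returns ``(consensus SecondaryStructure on alignment columns,
    {(col_i, col_j): probability})``.  Pair probabilities are parsed from the
    engine's ``alifold.out``; columns are converted to 0-based.
    """
    exe = _require(RNAALIFOLD)
    tmp = None
    if workdir is None:
        tmp = tempfile.mkdtemp(prefix="shapealign_alifold_")
        workdir = tmp
    try:
        aln_path = os.path.join(workdir, "input.aln")
        write_clustal(aln_path, job.rows)
        shape_args = []
        if any(p is not None for p in job.profiles):
            shape_files = []
            for k, profile in enumerate(job.profiles, start=1):
                shape_path = os.path.join(workdir, f"seq{k}.shape")
                if profile is None:
                    raise ValueError("either all or no rows may carry SHAPE profiles")
                write_shape_reactivities(shape_path, profile, with_base=True)
                shape_files.append(f"seq{k}.shape")
            shape_args = [f"--shape={','.join(shape_files)}"]
        cmd = [
            exe,
            "-p",
            "--noPS",
            f"--maxBPspan={job.max_pair_distance}",
            *(["-r"] if job.ribosum else []),
            *shape_args,
            "input.aln",
        ]
        logger.info("engine version: %s", engine_version())
        stdout = _run(cmd, cwd=workdir)
        consensus_seq, consensus_db = _parse_alifold_stdout(stdout)
        probabilities = _parse_alifold_out(os.path.join(workdir, "alifold.out"))
    finally:
        if tmp is not None:
            shutil.rmtree(tmp, ignore_errors=True)
    sanitized = "".join(c if c in "ACGU" else "N" for c in consensus_seq)
    consensus = structure_from_dotbracket(consensus_db, sanitized)
    return consensus, probabilities


def _parse_alifold_stdout(stdout: str):
    lines = [ln for ln in stdout.splitlines() if ln.strip()]
    seq = None
    for k, line in enumerate(lines):
        token = line.split()[0]
        if set(token) <= set("ACGUN_-") and len(token) > 1:
            seq = token
            structure = lines[k + 1].split()[0] if k + 1 < len(lines) else None
            if structure and set(structure) <= set(".()[]{}<>,"):
                return seq, structure
    raise EngineError("could not parse consensus structure from RNAalifold output")


def _parse_alifold_out(path) -> dict:
    """Parse pair probabilities from alifold.out (1-based columns, '%')."""
    if not os.path.exists(path):
        raise EngineError("RNAalifold did not produce alifold.out (partition function)")
    probabilities: dict = {}
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 4 or not (fields[0].isdigit() and fields[1].isdigit()):
                continue
            i, j = int(fields[0]), int(fields[1])
            prob_field = next((f for f in fields[2:] if f.endswith("%")), None)
            if prob_field is None:
                continue
            probabilities[(i - 1, j - 1)] = float(prob_field.rstrip("%")) / 100.0
    return probabilities


def extract_consensus_pairs(
    probabilities: dict, threshold: float = 0.95, width: int | None = None
) -> ConsensusPairSet:
    """Keep pairs with probability strictly greater than ``threshold``."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    for p in probabilities.values():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"pairing probability {p} outside [0, 1]")
    kept = sorted(
        (min(i, j), max(i, j), p) for (i, j), p in probabilities.items() if p > threshold
    )
    if width is None:
        width = 1 + max((j for _, j, _ in kept), default=0)
        width = max(width, 1 + max((j for (_, j) in probabilities), default=0))
    return ConsensusPairSet(tuple(kept), threshold, width)


def map_consensus_to_sequence(pairs: ConsensusPairSet, alignment_row: str) -> list:
    """Map alignment-column pairs onto one row's ungapped coordinates.

    A pair is dropped for this sequence if either column is a gap in the row
    or the mapped bases cannot form a canonical (WC/G-U) pair.  Returns
    sorted 0-based ``(x, y)`` sequence coordinates.
    """
    if len(alignment_row) != pairs.width:
        raise ValueError(
            f"alignment row width {len(alignment_row)} != consensus width {pairs.width}"
        )
    col_to_seq: dict = {}
    seq_chars: list = []
    for col, char in enumerate(alignment_row):
        if char not in GAP_CHARS:
            col_to_seq[col] = len(seq_chars)
            seq_chars.append(char.upper().replace("T", "U"))
    mapped = []
    for i, j, _ in pairs.pairs:
        if i not in col_to_seq or j not in col_to_seq:
            continue
        x, y = col_to_seq[i], col_to_seq[j]
        if (seq_chars[x], seq_chars[y]) in CANONICAL_PAIRS:
            mapped.append((x, y))
    return sorted(mapped)


def constrained_individual_fold(
    sequence: str,
    shape: ReactivityProfile | None = None,
    constraints=(),
    max_pair_distance: int = 600,
) -> SecondaryStructure:
    """MFE fold of one sequence under hard pair constraints + SHAPE data.

    ``constraints`` are 0-based, non-crossing, canonical (x, y) pairs; the
    returned structure is guaranteed to contain all of them (the engine is
    invoked with enforced constraints and the output is verified).  With no
    constraints and no SHAPE profile this reduces to the engine's plain MFE
    prediction.
    """
    exe = _require(RNAFOLD)
    sequence = sequence.upper().replace("T", "U")
    n = len(sequence)
    constraints = sorted(tuple(c) for c in constraints)
    for x, y in constraints:
        if not 0 <= x < y < n:
            raise ValueError(f"constraint pair ({x}, {y}) outside sequence")
        if (sequence[x], sequence[y]) not in CANONICAL_PAIRS:
            raise ValueError(f"constraint pair ({x}, {y}) is not canonical")
    with tempfile.TemporaryDirectory(prefix="shapealign_rnafold_") as workdir:
        cmd = [exe, "--noPS", f"--maxBPspan={max_pair_distance}"]
        stdin_lines = [">query", sequence]
        if constraints:
            chars = ["."] * n
            for x, y in constraints:
                chars[x], chars[y] = "(", ")"
            stdin_lines.append("".join(chars))
            cmd += ["-C", "--enforceConstraint"]
        if shape is not None:
            if len(shape) != n:
                raise ValueError("SHAPE profile length != sequence length")
            shape_path = os.path.join(workdir, "query.shape")
            write_shape_reactivities(shape_path, shape, with_base=True)
            cmd.append(f"--shape={shape_path}")
        stdout = _run(cmd, cwd=workdir, stdin_text="\n".join(stdin_lines) + "\n")
    structure_line = _parse_rnafold_stdout(stdout, n)
    structure = structure_from_dotbracket(structure_line, sequence)
    missing = set(constraints) - set(structure.pair_coords())
    if missing:
        raise ConstraintRejectedError(missing)
    return structure


def _parse_rnafold_stdout(stdout: str, n: int) -> str:
    for line in stdout.splitlines():
        token = line.split()[0] if line.strip() else ""
        if len(token) == n and set(token) <= set(".()[]{}<>,"):
            return token
    raise EngineError("could not parse MFE structure from RNAfold output")
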