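"""Readers and writers for the plain-text formats the tool touches.

Formats: FASTA (sequences and gapped alignment rows), Clustal, two-column
SHAPE reactivity files (1-based position, reactivity, ``-999`` = missing),
CT and dot-bracket secondary structures, and a TSV alignment report.

File coordinates are 1-based; everything in memory is 0-based.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO

from .types import (
    MISSING,
    AlignedPairSet,
    BasePair,
    FormatError,
    ReactivityProfile,
    SecondaryStructure,
    is_missing,
    normalize_sequence,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_shape_reactivities",
    "write_shape_reactivities",
    "read_reference_alignment",
    "pairs_from_gapped_rows",
    "read_structure",
    "write_pairwise_alignment",
    "gapped_rows",
    "write_clustal",
]

GAP_CHARS = frozenset("-.")

#: On-disk sentinel for a missing reactivity.
SHAPE_SENTINEL = -999.0


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list:
    """Read a FASTA file into ``[(name, sequence), ...]`` in file order.

    Sequences are upper-cased and T->U normalized; header case is preserved.
    Malformed headers, empty records and non-IUPAC characters raise
    :class:`FormatError` naming the offending line.
    """
    records: list = []
    name = None
    chunks: list = []
    header_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    _close_fasta_record(records, name, chunks, header_line, path)
                name = line[1:].strip()
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
                header_line = lineno
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before any FASTA header"
                    )
                try:
                    chunks.append(normalize_sequence(line))
                except FormatError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
    if name is None:
        raise FormatError(f"{path}: no FASTA records found")
    _close_fasta_record(records, name, chunks, header_line, path)
    return records


def _close_fasta_record(records, name, chunks, header_line, path) -> None:
    seq = "".join(chunks)
    if not seq:
        raise FormatError(f"{path}:{header_line}: empty FASTA record {name!r}")
    records.append((name, seq))


def write_fasta(path, records: Iterable, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start : start + width] + "\n")


# ---------------------------------------------------------------------------
# SHAPE reactivity files


def read_shape_reactivities(path, sequence: str) -> ReactivityProfile:
    """Read a two-column SHAPE file aligned to ``sequence``.

    Lines are ``<1-based position> [base] <reactivity>``; the optional middle
    column (nucleotide letter, as written by some toolchains) is ignored.
    Positions absent from the file and the sentinel ``-999`` map to MISSING.
    """
    sequence = normalize_sequence(sequence)
    reactivities = np.full(len(sequence), MISSING)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise FormatError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            try:
                pos = int(fields[0])
                value = float(fields[-1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric position or reactivity"
                ) from None
            if not 1 <= pos <= len(sequence):
                raise FormatError(
                    f"{path}:{lineno}: position {pos} outside sequence of "
                    f"length {len(sequence)}"
                )
            reactivities[pos - 1] = MISSING if value == SHAPE_SENTINEL else value
    name = os.path.splitext(os.path.basename(str(path)))[0]
    return ReactivityProfile(name, sequence, reactivities)


def write_shape_reactivities(path, profile: ReactivityProfile, *, with_base: bool = False) -> None:
    """Write a profile in the two-column dialect (``-999`` for MISSING).

    ``with_base=True`` emits the three-column ``pos base value`` variant
    expected by the folding engine.
    """
    with open(path, "w") as fh:
        for idx, value in enumerate(profile.reactivities, start=1):
            out = SHAPE_SENTINEL if is_missing(value) else value
            if with_base:
                fh.write(f"{idx} {profile.sequence[idx - 1]} {out:.6g}\n")
            else:
                fh.write(f"{idx} {out:.6g}\n")


# ---------------------------------------------------------------------------
# Reference alignments


def pairs_from_gapped_rows(row_x: str, row_y: str, source: str = "reference") -> AlignedPairSet:
    """Matched-position pairs from two gapped rows of equal length.

    A column contributes a pair only when both rows are non-gap.
    """
    if len(row_x) != len(row_y):
        raise FormatError("aligned rows have unequal lengths")
    pairs = []
    i = j = 0
    for cx, cy in zip(row_x, row_y):
        gx, gy = cx in GAP_CHARS, cy in GAP_CHARS
        if not gx and not gy:
            pairs.append((i, j))
        if not gx:
            i += 1
        if not gy:
            j += 1
    return AlignedPairSet.from_pairs(pairs, source)


def read_reference_alignment(path):
    """Read a pairwise reference alignment (aligned FASTA or Clustal).

    Returns ``((name_x, row_x), (name_y, row_y), AlignedPairSet)`` built from
    the first two rows.  Gap characters are ``-`` and ``.``.
    """
    with open(path) as fh:
        head = fh.readline()
    if head.upper().startswith("CLUSTAL"):
        aln = AlignIO.read(path, "clustal")
        rows = [(rec.id, str(rec.seq)) for rec in aln]
        rows = [(name, _normalize_gapped(name, row)) for name, row in rows]
    else:
        rows = [
            (name, seq) for name, seq in _read_gapped_fasta(path)
        ]
    if len(rows) < 2:
        raise FormatError(f"{path}: reference alignment needs >= 2 rows")
    widths = {len(row) for _, row in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: aligned rows have unequal lengths {sorted(widths)}")
    (name_x, row_x), (name_y, row_y) = rows[0], rows[1]
    return (name_x, row_x), (name_y, row_y), pairs_from_gapped_rows(row_x, row_y)


def _normalize_gapped(name: str, row: str) -> str:
    ungapped = "".join(c for c in row if c not in GAP_CHARS)
    normalize_sequence(ungapped, context=f"alignment row {name!r}")
    out = []
    for c in row:
        out.append("-" if c in GAP_CHARS else c.upper().replace("T", "U"))
    return "".join(out)


def _read_gapped_fasta(path) -> list:
    """FASTA reader variant that tolerates gap characters in rows."""
    records: list = []
    name = None
    chunks: list = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, _normalize_gapped(name, "".join(chunks))))
                name = line[1:].strip()
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}:{lineno}: data before FASTA header")
                chunks.append(line)
    if name is None:
        raise FormatError(f"{path}: no alignment rows found")
    records.append((name, _normalize_gapped(name, "".join(chunks))))
    return records


def write_clustal(path, rows: Sequence, width: int = 60) -> None:
    """Write ``[(name, gapped_row), ...]`` as a Clustal file."""
    names = [name[:30].replace(" ", "_") for name, _ in rows]
    pad = max(len(n) for n in names) + 4
    length = len(rows[0][1])
    with open(path, "w") as fh:
        fh.write("CLUSTAL W (shapealign)\n\n")
        for start in range(0, length, width):
            for name, row in zip(names, (r for _, r in rows)):
                fh.write(f"{name:<{pad}}{row[start:start + width]}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Secondary structures

_OPENERS = "([{<"
_CLOSERS = ")]}>"


def read_structure(path, dialect: str = "auto") -> SecondaryStructure:
    """Read a secondary structure from a CT or dot-bracket file.

    ``dialect`` is ``"ct"``, ``"dotbracket"`` or ``"auto"`` (by extension,
    ``.ct`` -> CT).  Pairs are returned 0-based.  The canonical flag is
    evaluated against the sequence when one is present in the file;
    dot-bracket tiers beyond ``()`` and crossing CT pairs are flagged as
    pseudoknots.
    """
    if dialect == "auto":
        dialect = "ct" if str(path).lower().endswith(".ct") else "dotbracket"
    if dialect == "ct":
        return _read_ct(path)
    if dialect == "dotbracket":
        return _read_dotbracket(path)
    raise ValueError(f"unknown structure dialect {dialect!r}")


def _read_ct(path) -> SecondaryStructure:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = [ln for ln in lines if ln.strip()]
    if not body:
        raise FormatError(f"{path}: empty CT file")
    try:
        length = int(body[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: malformed CT header") from None
    rows = body[1 : 1 + length]
    if len(rows) != length:
        raise FormatError(f"{path}: CT declares {length} rows, found {len(rows)}")
    bases = []
    partner = np.zeros(length, dtype=int)
    for row in rows:
        fields = row.split()
        if len(fields) < 6:
            raise FormatError(f"{path}: CT row with fewer than 6 columns: {row!r}")
        idx = int(fields[0])
        bases.append(fields[1])
        partner[idx - 1] = int(fields[4])
    sequence = normalize_sequence("".join(bases), context=f"{path}")
    coords = set()
    for i1 in range(1, length + 1):
        j1 = partner[i1 - 1]
        if j1 == 0:
            continue
        if not 1 <= j1 <= length or partner[j1 - 1] != i1:
            raise FormatError(
                f"{path}: inconsistent pairing table: {i1} pairs {j1} but "
                f"{j1} pairs {partner[j1 - 1] if 1 <= j1 <= length else '?'}"
            )
        coords.add((min(i1, j1) - 1, max(i1, j1) - 1))
    return SecondaryStructure.from_pair_coords(length, coords, sequence)


def _read_dotbracket(path) -> SecondaryStructure:
    """Dot-bracket file: optional ``>`` header, optional sequence line,
    then the structure line.  ``()`` is the primary tier; ``[] {} <>`` are
    pseudoknot tiers."""
    sequence = None
    structure = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip().split()[0] if raw.strip() else ""
            if not line or line.startswith(">") or line.startswith("#"):
                continue
            if all(c in "." + _OPENERS + _CLOSERS + ",_" for c in line):
                structure = line
                break
            if sequence is None:
                sequence = normalize_sequence(line, context=f"{path}")
            else:
                raise FormatError(f"{path}: multiple sequence lines before structure")
    if structure is None:
        raise FormatError(f"{path}: no dot-bracket structure line found")
    if sequence is not None and len(sequence) != len(structure):
        raise FormatError(f"{path}: sequence and structure lengths differ")
    return structure_from_dotbracket(structure, sequence)


def structure_from_dotbracket(structure: str, sequence: str | None = None) -> SecondaryStructure:
    """Parse a dot-bracket string (with pseudoknot bracket tiers)."""
    stacks: dict = {opener: [] for opener in _OPENERS}
    close_of = dict(zip(_CLOSERS, _OPENERS))
    pairs = []
    for pos, char in enumerate(structure):
        if char in _OPENERS:
            stacks[char].append(pos)
        elif char in _CLOSERS:
            opener = close_of[char]
            if not stacks[opener]:
                raise FormatError(f"unbalanced {char!r} at position {pos + 1}")
            x = stacks[opener].pop()
            if sequence is not None:
                from .types import CANONICAL_PAIRS

                canonical = (sequence[x], sequence[pos]) in CANONICAL_PAIRS
            else:
                canonical = True
            pairs.append(
                BasePair(x, pos, canonical=canonical, pseudoknot=(opener != "("))
            )
    leftovers = [op for op, stack in stacks.items() if stack]
    if leftovers:
        raise FormatError(f"unbalanced opening bracket(s) {leftovers!r}")
    return SecondaryStructure(len(structure), tuple(pairs), sequence)


def structure_to_dotbracket(structure: SecondaryStructure) -> str:
    """Render nested pairs as ``()`` and pseudoknotted pairs as ``[]``."""
    chars = ["."] * structure.length
    for p in structure.pairs:
        o, c = ("[", "]") if p.pseudoknot else ("(", ")")
        chars[p.x], chars[p.y] = o, c
    return "".join(chars)


# ---------------------------------------------------------------------------
# Pairwise alignment output


def gapped_rows(columns: Sequence, seq_x: str, seq_y: str) -> tuple:
    """Render alignment columns as two gapped rows."""
    row_x = []
    row_y = []
    for ci, cj in columns:
        row_x.append("-" if ci is None else seq_x[ci])
        row_y.append("-" if cj is None else seq_y[cj])
    return "".join(row_x), "".join(row_y)


def write_pairwise_alignment(
    alignment,
    profile_x: ReactivityProfile,
    profile_y: ReactivityProfile,
    path,
    format: str = "aligned-fasta",
) -> None:
    """Write a pairwise alignment as gapped FASTA or a per-column TSV.

    The TSV has one line per alignment column: column index (1-based),
    x position (1-based or ``-``), x base, x reactivity, then the same for y.
    """
    for ci, cj in alignment.columns:
        if ci is not None and not 0 <= ci < len(profile_x):
            raise ShapeAlignInternalError(f"x position {ci} outside profile")
        if cj is not None and not 0 <= cj < len(profile_y):
            raise ShapeAlignInternalError(f"y position {cj} outside profile")
    if format == "aligned-fasta":
        row_x, row_y = gapped_rows(
            alignment.columns, profile_x.sequence, profile_y.sequence
        )
        write_fasta(path, [(profile_x.name, row_x), (profile_y.name, row_y)])
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write(
                "column\tx_pos\tx_base\tx_reactivity\ty_pos\ty_base\ty_reactivity\n"
            )
            for col, (ci, cj) in enumerate(alignment.columns, start=1):
                fh.write(f"{col}\t{_tsv_side(ci, profile_x)}\t{_tsv_side(cj, profile_y)}\n")
    else:
        raise ValueError(f"unknown alignment output format {format!r}")


def _tsv_side(idx, profile: ReactivityProfile) -> str:
    if idx is None:
        return "-\t-\t-"
    r = profile.reactivities[idx]
    r_str = "NA" if is_missing(r) else f"{r:.4f}"
    return f"{idx + 1}\t{profile.sequence[idx]}\t{r_str}"


class ShapeAlignInternalError(Exception):
    """Alignment refers to positions outside its profiles."""
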