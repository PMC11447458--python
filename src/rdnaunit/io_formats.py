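"""Shared domain types and text-format I/O (FASTA, GFF3, WIG/bedGraph, TSV).

Coordinate convention
---------------------
Everything inside the package is 0-based half-open (``[start, end)``).
GFF3 files are written and read with the standard 1-based inclusive
convention; the conversion happens only here, and a write/read round trip
is the identity.

Units are stored on the sense strand in transcription order: the first
base of the unit is the transcription start site (5' end of the 5'-ETS)
and the intergenic spacer (IGS) closes the unit, so in a tandem array the
promoter at the IGS 3' end abuts the next unit's TSS.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ParseError, ValidationError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class RegionType(Enum):
    """Feature classes used throughout the pipeline.

    The first eight members are the canonical structural regions of one
    rDNA repeat unit, in transcription order.
    """

    ETS5 = "ETS5"
    R18S = "R18S"
    ITS1 = "ITS1"
    R5_8S = "R5_8S"
    ITS2 = "ITS2"
    R28S = "R28S"
    ETS3 = "ETS3"
    IGS = "IGS"
    PROMOTER = "PROMOTER"
    TSS = "TSS"
    TERMINATOR = "TERMINATOR"
    CPG_ISLAND = "CPG_ISLAND"
    REPEAT = "REPEAT"
    TRACT = "TRACT"
    G4 = "G4"


#: The eight structural regions of a unit, 5'->3'.
CANONICAL_ORDER: tuple[RegionType, ...] = (
    RegionType.ETS5,
    RegionType.R18S,
    RegionType.ITS1,
    RegionType.R5_8S,
    RegionType.ITS2,
    RegionType.R28S,
    RegionType.ETS3,
    RegionType.IGS,
)

#: Structural regions that are rRNA genes.
GENE_REGIONS: tuple[RegionType, ...] = (
    RegionType.R18S,
    RegionType.R5_8S,
    RegionType.R28S,
)


@dataclass
class SequenceRecord:
    """A named DNA sequence (unit, read, query or gene)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("SequenceRecord id must be non-empty")
        self.seq = self.seq.upper()
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains illegal characters: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Feature:
    """A typed half-open interval on a unit, plus-strand only."""

    region_type: RegionType
    start: int
    end: int
    strand: str = "+"
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"{self.region_type.value}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand != "+":
            raise ValidationError("only plus-strand features are supported")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-base sequencing depth over one unit."""

    unit_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValidationError("depth must be one-dimensional")
        if np.any(self.depth < 0):
            raise ValidationError("depth values must be non-negative")

    def __len__(self) -> int:
        return len(self.depth)


def structural_features(features: Iterable[Feature]) -> list[Feature]:
    """The subset of *features* belonging to the eight canonical regions."""
    canon = set(CANONICAL_ORDER)
    return [f for f in features if f.region_type in canon]


def validate_unit_layout(features: Sequence[Feature], unit_length: int | None = None) -> None:
    """Check that structural features are in canonical order and disjoint.

    Raises :class:`ValidationError` on overlap, wrong order, or features
    extending past *unit_length* (when given). Non-structural features
    (repeats, islands, promoter...) are ignored.
    """
    struct = sorted(structural_features(features), key=lambda f: f.start)
    order = [f.region_type for f in struct]
    expected = [r for r in CANONICAL_ORDER if r in set(order)]
    if order != expected:
        raise ValidationError(
            f"structural features out of canonical order: "
            f"{[r.value for r in order]}"
        )
    for prev, cur in zip(struct, struct[1:]):
        if cur.start < prev.end:
            raise ValidationError(
                f"structural features overlap: {prev.region_type.value} "
                f"[{prev.start},{prev.end}) and {cur.region_type.value} "
                f"[{cur.start},{cur.end})"
            )
    if unit_length is not None:
        for f in features:
            if f.end > unit_length:
                raise ValidationError(
                    f"feature {f.region_type.value} [{f.start},{f.end}) "
                    f"extends past unit length {unit_length}"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and whitespace-stripped; characters outside
    A/C/G/T/N raise :class:`ParseError` naming the offending line.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    desc = ""
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        records.append(SequenceRecord(id=header, seq="".join(chunks), description=desc))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                body = line[1:].strip()
                if not body:
                    raise ParseError("empty FASTA header", line=lineno)
                flush()
                parts = body.split(None, 1)
                header = parts[0]
                desc = parts[1] if len(parts) == 2 else ""
                chunks = []
            else:
                if header is None:
                    raise ParseError("sequence data before first FASTA header", line=lineno)
                up = line.upper()
                bad = set(up) - DNA_ALPHABET
                if bad:
                    raise ParseError(
                        f"illegal sequence character(s) {''.join(sorted(bad))!r}",
                        line=lineno,
                    )
                chunks.append(up)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at *width* columns."""
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_SAFE = "".join(
    c for c in map(chr, range(33, 127)) if c not in "%;=&,\t"
)


def _attr_escape(value: str) -> str:
    return urllib.parse.quote(value, safe=_GFF_SAFE + " ")


def _attr_unescape(value: str) -> str:
    return urllib.parse.unquote(value)


def write_gff3(features: Sequence[Feature], unit_id: str, path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive columns 4 and 5).

    Structural features are validated for canonical order and
    non-overlap first. Reading the file back with :func:`read_gff3`
    returns the identical 0-based features.
    """
    validate_unit_layout(features)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: (f.start, f.end, f.region_type.value)):
            attrs = ";".join(
                f"{_attr_escape(k)}={_attr_escape(v)}" for k, v in sorted(f.attributes.items())
            ) or "."
            fh.write(
                "\t".join(
                    [
                        unit_id,
                        "rdnaunit",
                        f.region_type.value,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    """Read a GFF3 file written by this package back into 0-based features."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"expected 9 tab-separated columns, got {len(cols)}", line=lineno)
            try:
                rtype = RegionType(cols[2])
            except ValueError as exc:
                raise ParseError(f"unknown feature type {cols[2]!r}", line=lineno) from exc
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError("non-integer coordinates", line=lineno) from exc
            attrs: dict[str, str] = {}
            if cols[8] not in (".", ""):
                for item in cols[8].split(";"):
                    if not item:
                        continue
                    if "=" not in item:
                        raise ParseError(f"malformed attribute {item!r}", line=lineno)
                    k, v = item.split("=", 1)
                    attrs[_attr_unescape(k)] = _attr_unescape(v)
            feats.append(
                Feature(region_type=rtype, start=start1 - 1, end=end1, strand=cols[6], attributes=attrs)
            )
    return feats


# ---------------------------------------------------------------------------
# WIG / bedGraph coverage
# ---------------------------------------------------------------------------

def read_wig(path: str | Path, unit_length: int) -> CoverageTrack:
    """Read a fixedStep/variableStep WIG or 4-column bedGraph track.

    Returns a per-base :class:`CoverageTrack` of exactly *unit_length*
    values; positions absent from the file have depth 0. A position past
    *unit_length* raises :class:`ParseError`.
    """
    depth = np.zeros(unit_length, dtype=float)
    unit_id = ""
    mode: str | None = None  # "fixed" | "variable" | "bedgraph"
    chrom = ""
    pos = 0  # next 0-based position (fixedStep)
    step = 1
    span = 1

    def put(start0: int, count: int, value: float, lineno: int) -> None:
        if start0 < 0 or start0 + count > unit_length:
            raise ParseError(
                f"interval [{start0},{start0 + count}) exceeds unit length {unit_length}",
                line=lineno,
            )
        if value < 0:
            raise ParseError("negative depth", line=lineno)
        depth[start0 : start0 + count] = value

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(item.split("=", 1) for item in line.split()[1:])
                try:
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1
                except KeyError as exc:
                    raise ParseError("fixedStep needs chrom= and start=", line=lineno) from exc
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                mode = "fixed"
                unit_id = unit_id or chrom
                continue
            if line.startswith("variableStep"):
                kv = dict(item.split("=", 1) for item in line.split()[1:])
                try:
                    chrom = kv["chrom"]
                except KeyError as exc:
                    raise ParseError("variableStep needs chrom=", line=lineno) from exc
                span = int(kv.get("span", 1))
                mode = "variable"
                unit_id = unit_id or chrom
                continue
            fields = line.split()
            if mode == "fixed":
                if len(fields) != 1:
                    raise ParseError("fixedStep data lines carry one value", line=lineno)
                put(pos, span, float(fields[0]), lineno)
                pos += step
            elif mode == "variable":
                if len(fields) != 2:
                    raise ParseError("variableStep data lines carry position and value", line=lineno)
                put(int(fields[0]) - 1, span, float(fields[1]), lineno)
            else:
                if len(fields) != 4:
                    raise ParseError(
                        "expected bedGraph line (chrom start end value) or a WIG header",
                        line=lineno,
                    )
                chrom, s, e, v = fields
                unit_id = unit_id or chrom
                start0, end0 = int(s), int(e)
                if end0 <= start0:
                    raise ParseError("bedGraph interval end must exceed start", line=lineno)
                put(start0, end0 - start0, float(v), lineno)

    return CoverageTrack(unit_id=unit_id or "unit", depth=depth)


def write_wig(track: CoverageTrack, path: str | Path) -> None:
    """Write a coverage track as fixedStep WIG (start=1, step=1)."""
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={track.unit_id} start=1 step=1\n")
        for v in track.depth:
            fh.write(f"{v:g}\n")
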