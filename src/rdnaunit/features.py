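"""Compositional and repeat statistics of a unit.

Covers the catalogue reported for avian rDNA units: per-region GC
content, CpG islands under the Gardiner-Garden & Frommer criterion
(> 200 bp, GC > 50%, observed/expected CpG > 0.6), perfect
microsatellites (unit size 2-6), dispersed motif + base-complement
counts, polypurine/polypyrimidine (H-DNA-prone) tracts, and
G-quadruplex motifs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ParameterError, ValidationError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _check_seq(seq: str, allow_n: bool = False) -> str:
    if not seq:
        raise ParameterError("sequence must be non-empty")
    seq = seq.upper()
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ParameterError(f"sequence contains unsupported characters: {''.join(sorted(bad))}")
    return seq


def gc_content(seq: str) -> float:
    """GC percentage of an N-free sequence, reported to 0.1."""
    seq = _check_seq(seq)
    return round(100.0 * (seq.count("G") + seq.count("C")) / len(seq), 1)


class RepeatKind(Enum):
    MICROSAT = "MICROSAT"
    MOTIF = "MOTIF"
    MOTIF_COMPLEMENT = "MOTIF_COMPLEMENT"
    PUR_TRACT = "PUR_TRACT"
    PYR_TRACT = "PYR_TRACT"
    G4 = "G4"


@dataclass(frozen=True)
class RepeatHit:
    """One detected repeat, tract or quadruplex occurrence."""

    kind: RepeatKind
    motif: str
    copies: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind is RepeatKind.MICROSAT and self.end - self.start != len(self.motif) * self.copies:
            raise ValidationError("MICROSAT span must equal |motif| * copies")


@dataclass(frozen=True)
class CpGIsland:
    """A CpG island: > 200 bp, GC > 0.5, obs/exp CpG > 0.6.

    ``oe_ratio`` is (N_CpG * L) / (N_C * N_G) over the island, with
    N_CpG the overlapping CG dinucleotide count.
    """

    start: int
    end: int
    gc_frac: float
    oe_ratio: float

    def __post_init__(self) -> None:
        if self.end - self.start <= 200:
            raise ValidationError("CpG island must be longer than 200 bp")
        if not self.gc_frac > 0.5:
            raise ValidationError("CpG island GC fraction must exceed 0.5")
        if not self.oe_ratio > 0.6:
            raise ValidationError("CpG island obs/exp ratio must exceed 0.6")

    @property
    def length(self) -> int:
        return self.end - self.start


def _island_stats(pref_g, pref_c, pref_cg, a: int, b: int) -> tuple[float, float]:
    L = b - a
    n_g = pref_g[b] - pref_g[a]
    n_c = pref_c[b] - pref_c[a]
    n_cg = pref_cg[b - 1] - pref_cg[a] if b - 1 > a else 0
    gc_frac = (n_g + n_c) / L
    oe = (n_cg * L) / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
    return float(gc_frac), float(oe)


def cpg_islands(seq: str, min_len: int = 201, min_gc: float = 0.5, min_oe: float = 0.6) -> list[CpGIsland]:
    """Maximal non-overlapping CpG islands, greedy leftmost-longest.

    Scanning 5'->3', the island is opened at the smallest start ``a``
    admitting any qualifying stretch (length >= min_len, GC > min_gc,
    obs/exp > min_oe) and closed at the largest end ``b`` such that
    ``[a, b)`` qualifies; the scan resumes at ``b``. This realizes the
    island criterion as a deterministic, oracle-testable search.
    """
    seq = _check_seq(seq)
    if min_len < 2:
        raise ParameterError("min_len must be >= 2")
    if not (0 <= min_gc < 1) or min_oe < 0:
        raise ParameterError("min_gc must be in [0,1) and min_oe >= 0")
    n = len(seq)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_g = (codes == ord("G")).astype(np.int64)
    is_c = (codes == ord("C")).astype(np.int64)
    cg_start = np.zeros(n, dtype=np.int64)
    if n >= 2:
        cg_start[:-1] = is_c[:-1] & is_g[1:]
    pref_g = np.concatenate(([0], np.cumsum(is_g)))
    pref_c = np.concatenate(([0], np.cumsum(is_c)))
    pref_cg = np.concatenate(([0], np.cumsum(cg_start)))

    islands: list[CpGIsland] = []
    a = 0
    while a <= n - min_len:
        bs = np.arange(a + min_len, n + 1)
        L = bs - a
        n_g = pref_g[bs] - pref_g[a]
        n_c = pref_c[bs] - pref_c[a]
        n_cg = pref_cg[bs - 1] - pref_cg[a]
        gc_ok = (n_g + n_c) > min_gc * L
        with np.errstate(divide="ignore", invalid="ignore"):
            prod = (n_c * n_g).astype(float)
            oe = np.where(prod > 0, n_cg * L / np.where(prod > 0, prod, 1.0), 0.0)
        ok = gc_ok & (oe > min_oe)
        if ok.any():
            b = int(bs[np.flatnonzero(ok)[-1]])
            gc_frac, oe_val = _island_stats(pref_g, pref_c, pref_cg, a, b)
            islands.append(CpGIsland(start=int(a), end=b, gc_frac=gc_frac, oe_ratio=oe_val))
            a = b
        else:
            a += 1
    return islands


def cpg_island_coverage(islands: list[CpGIsland], unit_length: int) -> float:
    """Percentage of the unit covered by (non-overlapping) islands."""
    if unit_length <= 0:
        raise ParameterError("unit_length must be positive")
    ordered = sorted(islands, key=lambda i: i.start)
    total = 0
    prev_end = -1
    for isl in ordered:
        if isl.start < prev_end:
            raise ValidationError("islands overlap")
        if isl.end > unit_length:
            raise ValidationError("island extends past unit length")
        total += isl.length
        prev_end = isl.end
    return round(100.0 * total / unit_length, 1)


def _primitive(motif: str) -> bool:
    """True if the motif is not itself a repetition of a shorter unit."""
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def find_microsatellites(
    seq: str,
    min_unit: int = 2,
    max_unit: int = 6,
    min_copies: int = 3,
) -> list[RepeatHit]:
    """Maximal perfect tandem repeats of primitive 2-6 bp units.

    Within one periodic stretch, every phase that still reaches
    ``min_copies`` whole copies is reported as its own hit (so e.g. a
    run listing both (ACCCG)n and (CCCGA)n phases is reproduced). A hit
    is maximal: it cannot be extended by a whole copy on either side.
    """
    seq = _check_seq(seq, allow_n=True)
    if min_unit < 1:
        raise ParameterError("min_unit must be >= 1")
    if max_unit < min_unit or min_copies < 2:
        raise ParameterError("need max_unit >= min_unit and min_copies >= 2")
    n = len(seq)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits: set[RepeatHit] = set()
    for p in range(min_unit, max_unit + 1):
        if n < p * min_copies:
            break
        eq = codes[:-p] == codes[p:]
        # maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)
        for i0, i1 in zip(run_starts, run_ends):
            stretch_end = i1 + p  # periodic stretch is [i0, i1 + p)
            for s in range(i0, min(i0 + p, stretch_end)):
                copies = (stretch_end - s) // p
                if copies < min_copies:
                    continue
                motif = seq[s : s + p]
                if "N" in motif or not _primitive(motif):
                    continue
                hits.add(
                    RepeatHit(
                        kind=RepeatKind.MICROSAT,
                        motif=motif,
                        copies=int(copies),
                        start=int(s),
                        end=int(s + copies * p),
                    )
                )
    return sorted(hits, key=lambda h: (h.start, h.end, h.motif))


def count_motif_and_complement(seq: str, motif: str) -> tuple[int, int]:
    """Overlapping occurrence counts of *motif* and of its base complement.

    The pairing convention is complement (not reverse complement): the
    dispersed-repeat pairs reported for avian rDNA — (CGG)/(GCC),
    (GCGA)/(CGCT) — are base-complement pairs read on the same strand.
    """
    seq = _check_seq(seq, allow_n=True)
    if not motif:
        raise ParameterError("motif must be non-empty")
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ParameterError("motif must be over A/C/G/T")
    comp = motif.translate(_COMPLEMENT)

    def count(m: str) -> int:
        c = 0
        i = seq.find(m)
        while i != -1:
            c += 1
            i = seq.find(m, i + 1)
        return c

    return count(motif), count(comp)


def find_pur_pyr_tracts(seq: str, min_len: int = 10) -> list[RepeatHit]:
    """Maximal all-purine (A/G) and all-pyrimidine (C/T) runs >= min_len.

    Extended tracts of this kind are bendable and prone to triplex
    (H-form) DNA.
    """
    seq = _check_seq(seq)
    if min_len < 2:
        raise ParameterError("min_len must be >= 2")
    hits: list[RepeatHit] = []
    for kind, cls in ((RepeatKind.PUR_TRACT, "AG"), (RepeatKind.PYR_TRACT, "CT")):
        for m in re.finditer(f"[{cls}]{{{min_len},}}", seq):
            hits.append(
                RepeatHit(kind=kind, motif=m.group(), copies=1, start=m.start(), end=m.end())
            )
    return sorted(hits, key=lambda h: (h.start, h.end))


def find_g4_motifs(seq: str, min_run: int = 3, loop_min: int = 1, loop_max: int = 7) -> list[RepeatHit]:
    """Non-overlapping G-quadruplex motifs, leftmost first.

    A motif is four runs of >= ``min_run`` G separated by three loops of
    ``loop_min``..``loop_max`` arbitrary bases.
    """
    seq = _check_seq(seq, allow_n=True)
    if min_run < 2:
        raise ParameterError("min_run must be >= 2")
    if loop_min < 1 or loop_min > loop_max:
        raise ParameterError("need 1 <= loop_min <= loop_max")
    pattern = re.compile(
        f"G{{{min_run},}}(?:[ACGTN]{{{loop_min},{loop_max}}}?G{{{min_run},}}){{3}}"
    )
    hits = []
    for m in pattern.finditer(seq):
        hits.append(
            RepeatHit(kind=RepeatKind.G4, motif=m.group(), copies=1, start=m.start(), end=m.end())
        )
    return hits
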