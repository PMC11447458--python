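"""Synthetic rDNA repeat units, read sets and coverage tracks with known truth.

The default (``coturnix``) preset emulates the structure of the Japanese
quail rDNA repeat unit: eight canonical regions at the published lengths
(total 21166 bp), per-region GC targets, a 19-nt Pol I promoter motif
immediately 5' of the TSS (i.e. at the IGS 3' end, tandem-repeat sense),
a poly-T + inverted-repeat transcription terminator closing the 3'-ETS,
and a catalogue of planted microsatellites, purine/pyrimidine tracts,
dispersed motifs and a G-quadruplex.

Region backgrounds use an exact-composition model: each region gets
exactly ``round(length * gc)`` G/C bases at random positions (G vs C and
A vs T each fair coin flips), so realized GC matches its target to
within one base. Dinucleotide statistics remain i.i.d.-like, so the CpG
observed/expected ratio of background sequence sits near 1.

Planted features are flanked by short "guard" edits (a base that cannot
extend the planted pattern) so that every planted microsatellite, tract
and G4 is recoverable at its exact recorded coordinates by the scanners
in :mod:`rdnaunit.features`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import ParameterError, SpecError
from .io_formats import (
    CANONICAL_ORDER,
    CoverageTrack,
    Feature,
    RegionType,
    SequenceRecord,
    revcomp,
)

# Published layout of the quail unit (bp) and per-region GC targets.
DEFAULT_REGION_LENGTHS: dict[RegionType, int] = {
    RegionType.ETS5: 1779,
    RegionType.R18S: 1823,
    RegionType.ITS1: 2047,
    RegionType.R5_8S: 157,
    RegionType.ITS2: 658,
    RegionType.R28S: 4185,
    RegionType.ETS3: 639,
    RegionType.IGS: 9878,
}

DEFAULT_REGION_GC: dict[RegionType, float] = {
    RegionType.ETS5: 0.741,
    RegionType.R18S: 0.55,
    RegionType.ITS1: 0.768,
    RegionType.R5_8S: 0.55,
    RegionType.ITS2: 0.780,
    RegionType.R28S: 0.55,
    RegionType.ETS3: 0.721,
    RegionType.IGS: 0.663,
}

#: The quail Pol I promoter core (19 nt).
DEFAULT_PROMOTER_MOTIF = "TTGCTCCGCAGGAGCGAGC"

# Default planted terminator: T-run of 6, then an 8-bp arm, a 6-bp
# spacer, and the arm's reverse complement.
_TERM_T_RUN = 6
_TERM_ARM = "GACGCAGG"
_TERM_SPACER = "ACACAC"


def terminator_sequence(t_run: int = _TERM_T_RUN, arm: str = _TERM_ARM, spacer: str = _TERM_SPACER) -> str:
    return "T" * t_run + arm + spacer + revcomp(arm)


class PlantKind(Enum):
    MICROSAT = "MICROSAT"
    MOTIF_DISPERSED = "MOTIF_DISPERSED"
    PUR_PYR_TRACT = "PUR_PYR_TRACT"
    G4 = "G4"
    TERMINATOR = "TERMINATOR"
    CPG_ISLAND = "CPG_ISLAND"


_KIND_TO_REGION_TYPE = {
    PlantKind.MICROSAT: RegionType.REPEAT,
    PlantKind.MOTIF_DISPERSED: RegionType.REPEAT,
    PlantKind.PUR_PYR_TRACT: RegionType.TRACT,
    PlantKind.G4: RegionType.G4,
    PlantKind.TERMINATOR: RegionType.TERMINATOR,
    PlantKind.CPG_ISLAND: RegionType.CPG_ISLAND,
}


@dataclass
class PlantedFeature:
    """One feature written over the background of a region.

    Exactly one of (``motif`` + ``copies``) or ``sequence`` or ``length``
    describes the payload: microsatellites use motif/copies, literal
    elements use ``sequence``, and planted CpG islands use ``length``
    (their sequence is synthesized at generation time).
    """

    kind: PlantKind
    region: RegionType
    offset: int
    motif: str | None = None
    copies: int | None = None
    sequence: str | None = None
    length: int | None = None

    def payload_length(self) -> int:
        if self.kind is PlantKind.MICROSAT:
            if not self.motif or not self.copies or self.copies < 1:
                raise SpecError("MICROSAT needs a motif and copies >= 1")
            return len(self.motif) * self.copies
        if self.kind is PlantKind.CPG_ISLAND:
            if not self.length or self.length < 1:
                raise SpecError("CPG_ISLAND needs a positive length")
            return self.length
        if self.sequence is None:
            raise SpecError(f"{self.kind.value} needs a literal sequence")
        return len(self.sequence)

    def materialize(self, rng: np.random.Generator, gc: float) -> str:
        if self.kind is PlantKind.MICROSAT:
            return self.motif * self.copies  # type: ignore[operator]
        if self.kind is PlantKind.CPG_ISLAND:
            return _cpg_island_sequence(self.length, gc, rng)  # type: ignore[arg-type]
        seq = self.sequence.upper()  # type: ignore[union-attr]
        if self.kind is PlantKind.PUR_PYR_TRACT:
            if not (set(seq) <= set("AG") or set(seq) <= set("CT")):
                raise SpecError("PUR_PYR_TRACT sequence must be all-purine or all-pyrimidine")
        return seq


@dataclass
class UnitSpec:
    """Everything needed to synthesize one unit deterministically."""

    region_lengths: dict[RegionType, int] = field(default_factory=lambda: dict(DEFAULT_REGION_LENGTHS))
    region_gc: dict[RegionType, float] = field(default_factory=lambda: dict(DEFAULT_REGION_GC))
    planted: list[PlantedFeature] = field(default_factory=list)
    promoter_motif: str = DEFAULT_PROMOTER_MOTIF
    seed: int = 0
    unit_id: str = "synthetic_unit"

    def __post_init__(self) -> None:
        for r in CANONICAL_ORDER:
            if self.region_lengths.get(r, 0) <= 0:
                raise SpecError(f"region {r.value} needs a positive length")
            if not (0.0 < self.region_gc.get(r, 0.5) < 1.0):
                raise SpecError(f"region {r.value} GC must be in (0, 1)")

    @property
    def total_length(self) -> int:
        return sum(self.region_lengths[r] for r in CANONICAL_ORDER)


@dataclass
class PlantedTruth:
    """A synthetic unit plus the ground truth of everything planted in it."""

    unit: SequenceRecord
    features: list[Feature]
    coverage_params: dict[str, float] = field(default_factory=dict)

    def feature(self, region_type: RegionType) -> Feature:
        for f in self.features:
            if f.region_type is region_type:
                return f
        raise KeyError(region_type.value)

    def of_kind(self, kind: PlantKind) -> list[Feature]:
        return [f for f in self.features if f.attributes.get("kind") == kind.value]


def _background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """Exact-composition background: round(length*gc) G/C at random positions."""
    n_gc = int(round(length * gc))
    arr = np.empty(length, dtype="<U1")
    strong = rng.random(length)  # G vs C / A vs T coin flips
    perm = rng.permutation(length)
    gc_pos, at_pos = perm[:n_gc], perm[n_gc:]
    arr[gc_pos] = np.where(strong[gc_pos] < 0.5, "G", "C")
    arr[at_pos] = np.where(strong[at_pos] < 0.5, "A", "T")
    return arr


def _cpg_island_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """A stretch with CpG dinucleotide frequency ~1.5x the i.i.d. expectation."""
    p_cg_step = 1.5 * (gc / 2.0) ** 2 * 2.0  # per 2-base step
    out: list[str] = []
    while len(out) < length:
        if rng.random() < p_cg_step and len(out) + 2 <= length:
            out.extend(("C", "G"))
        else:
            b = rng.random()
            if b < gc / 2:
                out.append("G")
            elif b < gc:
                out.append("C")
            elif b < gc + (1 - gc) / 2:
                out.append("A")
            else:
                out.append("T")
    return "".join(out)


_PYR_GUARD = "C"  # guard written next to purine tracts / G-runs
_PUR_GUARD = "A"  # guard written next to pyrimidine tracts


def _other_base(avoid: str) -> str:
    for b in "CATG":
        if b != avoid:
            return b
    raise AssertionError


def _apply_guards(arr: np.ndarray, start: int, end: int, planted: PlantedFeature, seq: str) -> None:
    """Edit flanking bases so the planted pattern cannot extend outward."""
    n = len(arr)
    if planted.kind is PlantKind.MICROSAT:
        if start > 0:
            arr[start - 1] = _other_base(seq[-1])
        if end < n:
            arr[end] = _other_base(seq[0])
    elif planted.kind is PlantKind.PUR_PYR_TRACT:
        guard = _PYR_GUARD if seq[0] in "AG" else _PUR_GUARD
        if start > 0:
            arr[start - 1] = guard
        if end < n:
            arr[end] = guard
    elif planted.kind is PlantKind.G4:
        # no G-run may end within loop distance upstream, and the final
        # run must not extend downstream
        lo = max(0, start - 8)
        for i in range(lo, start):
            if arr[i] == "G":
                arr[i] = "C"
        if end < n:
            arr[end] = _PYR_GUARD
    elif planted.kind is PlantKind.TERMINATOR:
        if start > 0 and arr[start - 1] == "T":
            arr[start - 1] = "C"


#: flank width (bp) that guard edits may touch; planted features must be
#: at least this far apart
GUARD_MARGIN = 8


def generate_unit(spec: UnitSpec) -> PlantedTruth:
    """Synthesize a unit and its ground-truth annotation.

    Deterministic for a fixed ``spec.seed``. Region backgrounds are laid
    down first, then planted features overwrite the background at their
    recorded offsets (with flank guards), then the promoter motif is
    written at the IGS 3' end and the terminator at the 3'-ETS 3' end
    (unless a TERMINATOR plant overrides it).
    """
    rng = np.random.default_rng(spec.seed)
    total = spec.total_length

    region_start: dict[RegionType, int] = {}
    pos = 0
    chunks: list[np.ndarray] = []
    for r in CANONICAL_ORDER:
        region_start[r] = pos
        chunks.append(_background(spec.region_lengths[r], spec.region_gc[r], rng))
        pos += spec.region_lengths[r]
    arr = np.concatenate(chunks)

    features: list[Feature] = []
    for r in CANONICAL_ORDER:
        features.append(
            Feature(region_type=r, start=region_start[r], end=region_start[r] + spec.region_lengths[r])
        )

    planted = list(spec.planted)
    if not any(p.kind is PlantKind.TERMINATOR for p in planted):
        term = terminator_sequence()
        planted.append(
            PlantedFeature(
                kind=PlantKind.TERMINATOR,
                region=RegionType.ETS3,
                offset=spec.region_lengths[RegionType.ETS3] - len(term),
                sequence=term,
            )
        )

    # validate placement: inside region, pairwise-disjoint incl. guard margin
    intervals: list[tuple[int, int, PlantedFeature]] = []
    for p in planted:
        plen = p.payload_length()
        rlen = spec.region_lengths[p.region]
        if p.offset < 0 or p.offset + plen > rlen:
            raise SpecError(
                f"planted {p.kind.value} at {p.region.value}+{p.offset} "
                f"(length {plen}) exceeds region bounds (0..{rlen})"
            )
        abs_start = region_start[p.region] + p.offset
        intervals.append((abs_start, abs_start + plen, p))
    intervals.sort(key=lambda t: t[0])
    for (s1, e1, p1), (s2, e2, p2) in zip(intervals, intervals[1:]):
        if s2 < e1 + GUARD_MARGIN:
            raise SpecError(
                f"planted features too close: {p1.kind.value}@{e1} and "
                f"{p2.kind.value}@{s2} (need {GUARD_MARGIN} bp separation)"
            )

    for abs_start, abs_end, p in intervals:
        seq = p.materialize(rng, spec.region_gc[p.region])
        arr[abs_start:abs_end] = list(seq)
        _apply_guards(arr, abs_start, abs_end, p, seq)
        attrs = {"kind": p.kind.value}
        if p.kind is PlantKind.MICROSAT:
            attrs["motif"] = p.motif or ""
            attrs["copies"] = str(p.copies)
        elif p.kind is not PlantKind.CPG_ISLAND:
            attrs["sequence"] = seq
        if p.kind is PlantKind.PUR_PYR_TRACT:
            attrs["tract_class"] = "PUR" if seq[0] in "AG" else "PYR"
        features.append(
            Feature(region_type=_KIND_TO_REGION_TYPE[p.kind], start=abs_start, end=abs_end, attributes=attrs)
        )

    # promoter immediately 5' of the TSS: at the IGS 3' end in tandem sense
    motif = spec.promoter_motif.upper()
    if motif:
        if len(motif) > spec.region_lengths[RegionType.IGS]:
            raise SpecError("promoter motif longer than the IGS")
        arr[total - len(motif) : total] = list(motif)
        features.append(
            Feature(
                region_type=RegionType.PROMOTER,
                start=total - len(motif),
                end=total,
                attributes={"sequence": motif},
            )
        )
    features.append(Feature(region_type=RegionType.TSS, start=0, end=1))

    unit = SequenceRecord(id=spec.unit_id, seq="".join(arr), description=f"synthetic rDNA unit seed={spec.seed}")

    # ground-truth integrity: every planted literal occurs where recorded
    for f in features:
        lit = f.attributes.get("sequence")
        if lit and unit.seq[f.start : f.end] != lit:
            raise AssertionError("planted feature does not match recorded coordinates")

    return PlantedTruth(unit=unit, features=features, coverage_params={"depth": 100.0, "noise_sd": 10.0})


def generate_coverage(
    truth: PlantedTruth,
    depth: float,
    noise_sd: float,
    seed: int,
    attenuation: int = 200,
) -> CoverageTrack:
    """RNA-seq-like coverage: a plateau from the TSS to the 28S 3' end,
    a linear attenuation ramp past the 28S border, and zero elsewhere.

    Truncated Gaussian noise (floored at 0) is added wherever the
    expected depth is positive. Deterministic per *seed*.
    """
    if depth <= 0:
        raise ParameterError("depth must be positive")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(truth.unit)
    tss = truth.feature(RegionType.TSS).start
    end28 = truth.feature(RegionType.R28S).end

    mean = np.zeros(n)
    mean[tss:end28] = depth
    ramp_end = min(n, end28 + attenuation)
    ramp_len = ramp_end - end28
    if ramp_len > 0:
        mean[end28:ramp_end] = depth * (1.0 - (np.arange(ramp_len) + 1) / (ramp_len + 1))
    if noise_sd > 0:
        noisy = mean > 0
        mean[noisy] = np.maximum(0.0, mean[noisy] + rng.normal(0.0, noise_sd, noisy.sum()))
    return CoverageTrack(unit_id=truth.unit.id, depth=mean)


_LOGNORM_SIGMA = 0.5  # shape of the read-length spread


def generate_reads(
    truth: PlantedTruth,
    n: int,
    mean_len: int,
    sub_rate: float,
    seed: int,
) -> list[SequenceRecord]:
    """Long reads drawn from a two-copy tandem concatenation of the unit.

    Lengths are log-normal with the requested mean, clipped to
    [200, unit length]; substitution errors are i.i.d. per base at
    *sub_rate*. Each read's description records its true origin interval
    on the tandem concatenation.
    """
    if n <= 0:
        raise ParameterError("n must be positive")
    if not (0 <= sub_rate < 0.5):
        raise ParameterError("sub_rate must be in [0, 0.5)")
    if mean_len < 200:
        raise ParameterError("mean_len must be at least 200")
    rng = np.random.default_rng(seed)
    unit_len = len(truth.unit)
    tandem = truth.unit.seq + truth.unit.seq
    codes = np.frombuffer(tandem.encode(), dtype=np.uint8)
    base_for = np.frombuffer(b"ACGT", dtype=np.uint8)
    code_to_idx = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code_to_idx[ord(b)] = i

    mu = np.log(mean_len) - _LOGNORM_SIGMA**2 / 2.0
    lengths = np.clip(rng.lognormal(mu, _LOGNORM_SIGMA, n).astype(int), 200, unit_len)
    reads: list[SequenceRecord] = []
    for i in range(n):
        ln = int(lengths[i])
        start = int(rng.integers(0, 2 * unit_len - ln + 1))
        sub = codes[start : start + ln].copy()
        if sub_rate > 0:
            mask = rng.random(ln) < sub_rate
            k = int(mask.sum())
            if k:
                idx = code_to_idx[sub[mask]]
                shift = rng.integers(1, 4, k)
                sub[mask] = base_for[(idx + shift) % 4]
        reads.append(
            SequenceRecord(
                id=f"read{i:05d}",
                seq=sub.tobytes().decode(),
                description=f"origin={start}:{start + ln} unit={truth.unit.id}",
            )
        )
    return reads


def generate_background_reads(n: int, mean_len: int, seed: int, gc: float = 0.5) -> list[SequenceRecord]:
    """Random non-rDNA reads (i.i.d. bases at *gc*), for classifier tests."""
    if n <= 0:
        raise ParameterError("n must be positive")
    if mean_len < 200:
        raise ParameterError("mean_len must be at least 200")
    rng = np.random.default_rng(seed)
    mu = np.log(mean_len) - _LOGNORM_SIGMA**2 / 2.0
    lengths = np.clip(rng.lognormal(mu, _LOGNORM_SIGMA, n).astype(int), 200, None)
    probs = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    out = []
    for i in range(n):
        seq = "".join(rng.choice(list("GCAT"), size=int(lengths[i]), p=probs))
        out.append(SequenceRecord(id=f"bg{i:05d}", seq=seq, description="background"))
    return out


def coturnix_planted() -> list[PlantedFeature]:
    """The default planted catalogue, echoing the repeat classes reported
    for the quail unit (microsatellites, dispersed motifs, bendable
    purine/pyrimidine tracts, a G-quadruplex, a boosted-CpG stretch)."""
    P = PlantedFeature
    K = PlantKind
    R = RegionType
    return [
        P(K.MICROSAT, R.ETS5, 300, motif="GTGCC", copies=4),
        P(K.MOTIF_DISPERSED, R.ETS5, 800, sequence="CAGACAGGACAGACAGGCAGA"),
        P(K.MICROSAT, R.ITS1, 200, motif="TC", copies=5),
        P(K.MICROSAT, R.ITS1, 600, motif="CGGG", copies=3),
        P(K.PUR_PYR_TRACT, R.ITS1, 1200, sequence="GAGAGGGAGAAGGGAGGAAGAGGGAGAGGG"),
        P(K.PUR_PYR_TRACT, R.ITS1, 1600, sequence="CTCCTTCCCTCTCCCTTCCTCTCC"),
        P(K.MICROSAT, R.ITS2, 100, motif="CG", copies=6),
        P(K.MICROSAT, R.ITS2, 300, motif="GTTC", copies=4),
        P(K.MICROSAT, R.ETS3, 450, motif="ACCCG", copies=5),
        P(K.MICROSAT, R.IGS, 2000, motif="GACCT", copies=4),
        P(K.G4, R.IGS, 4000, sequence="GGGAGGGAGGGAGGG"),
        P(K.MOTIF_DISPERSED, R.IGS, 5000, sequence="GAGGGG" * 5),
        P(K.PUR_PYR_TRACT, R.IGS, 6000, sequence="AAGGGAGGAGAGGGAGGAAGAGGAGGGAAGAGAGGGAGGA"),
        P(K.PUR_PYR_TRACT, R.IGS, 7000, sequence="CCTTCTCCCTCCTTTCCCTCTCCCTTCTCC"),
        P(K.CPG_ISLAND, R.IGS, 8200, length=300),
    ]


def coturnix_spec(seed: int = 1, **overrides) -> UnitSpec:
    """The default study preset: published layout + planted catalogue."""
    spec = UnitSpec(planted=coturnix_planted(), seed=seed, unit_id="coturnix_synthetic")
    if overrides:
        spec = replace(spec, **overrides)
    return spec


def write_truth_manifest(truth: PlantedTruth, path: str | Path) -> None:
    """JSON manifest of the planted truth (id, length, feature table)."""
    payload = {
        "unit_id": truth.unit.id,
        "unit_length": len(truth.unit),
        "coverage_params": truth.coverage_params,
        "features": [
            {
                "type": f.region_type.value,
                "start": f.start,
                "end": f.end,
                "attributes": f.attributes,
            }
            for f in sorted(truth.features, key=lambda f: (f.start, f.end, f.region_type.value))
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
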