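"""Structural annotation of a unit: reference-guided boundary transfer,
coverage-based TSS calling, terminator detection and promoter location.

Boundary transfer mirrors how the quail unit was annotated against the
fully annotated chicken unit: each region boundary of the reference is
represented by a short anchor sequence centered on the boundary, the
anchor is aligned to the target (best infix alignment, edlib), and the
boundary maps to the anchor's center in target coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .errors import NoSignalError, NotFoundError, ParameterError, ValidationError
from .io_formats import (
    CANONICAL_ORDER,
    CoverageTrack,
    Feature,
    RegionType,
    SequenceRecord,
    revcomp,
    structural_features,
)


@dataclass
class ReferenceUnit:
    """An annotated unit used as the source of boundary transfer."""

    record: SequenceRecord
    features: list[Feature]

    def __post_init__(self) -> None:
        struct = structural_features(self.features)
        if not struct:
            raise ValidationError("reference unit carries no structural features")
        struct.sort(key=lambda f: f.start)
        for prev, cur in zip(struct, struct[1:]):
            if cur.start < prev.end:
                raise ValidationError("reference structural features overlap")
        self._struct = struct

    @property
    def structural(self) -> list[Feature]:
        return list(self._struct)


def transfer_boundaries(
    target: SequenceRecord,
    ref: ReferenceUnit,
    anchor_length: int = 40,
    min_identity: float = 0.6,
) -> list[Feature]:
    """Map the reference's region boundaries onto *target*.

    For each boundary an ``anchor_length``-bp reference window centered
    on it is aligned to the target (best local/infix alignment); the
    boundary maps to the anchor center. Anchors below *min_identity*
    are flagged: the adjacent features carry an ``unmapped`` attribute
    and their shared coordinate is interpolated from the nearest mapped
    boundaries, scaled by reference distances.
    """
    if not target.seq or not ref.record.seq:
        raise ValidationError("target and reference must be non-empty")
    struct = ref.structural
    shortest_gene = min(
        (f.length for f in struct if f.region_type.name.startswith("R")),
        default=min(f.length for f in struct),
    )
    if len(target) < shortest_gene:
        raise ValidationError(
            f"target ({len(target)} bp) shorter than the shortest reference gene ({shortest_gene} bp)"
        )

    boundaries = [f.start for f in struct] + [struct[-1].end]
    half = anchor_length // 2
    ref_seq = ref.record.seq
    mapped: list[int | None] = []
    for b in boundaries:
        a0 = max(0, b - half)
        a1 = min(len(ref_seq), b + half)
        anchor = ref_seq[a0:a1]
        res = edlib.align(anchor, target.seq, mode="HW", task="locations")
        dist = res["editDistance"]
        identity = 1.0 - dist / len(anchor)
        if identity < min_identity or not res["locations"]:
            mapped.append(None)
            continue
        loc_start = res["locations"][0][0]
        mapped.append(loc_start + (b - a0))

    # interpolate unmapped boundaries between nearest mapped neighbours
    est = list(mapped)
    known = [i for i, m in enumerate(mapped) if m is not None]
    if not known:
        raise ValidationError("no reference boundary could be mapped onto the target")
    for i, m in enumerate(mapped):
        if m is not None:
            continue
        left = max((j for j in known if j < i), default=None)
        right = min((j for j in known if j > i), default=None)
        if left is not None and right is not None:
            frac = (boundaries[i] - boundaries[left]) / (boundaries[right] - boundaries[left])
            est[i] = int(round(mapped[left] + frac * (mapped[right] - mapped[left])))
        elif left is not None:
            est[i] = mapped[left] + (boundaries[i] - boundaries[left])
        else:
            est[i] = mapped[right] - (boundaries[right] - boundaries[i])
        est[i] = min(max(est[i], 0), len(target))

    for prev, cur in zip(est, est[1:]):
        if cur <= prev:
            raise ValidationError(
                "mapped boundaries are not increasing; reference and target "
                "appear structurally incompatible"
            )

    out: list[Feature] = []
    for i, f in enumerate(struct):
        attrs = dict(f.attributes)
        flags = []
        if mapped[i] is None:
            flags.append("start")
        if mapped[i + 1] is None:
            flags.append("end")
        if flags:
            attrs["unmapped"] = ",".join(flags)
        out.append(Feature(region_type=f.region_type, start=est[i], end=est[i + 1], attributes=attrs))
    return out


def find_tss(track: CoverageTrack, frac: float = 0.1, sustain: int = 50) -> int:
    """Call the transcription start site from a coverage track.

    The plateau is the median of the top decile of depths; the TSS is
    the smallest position ``p`` such that depth >= ``frac * plateau``
    holds at every base of ``[p, p + sustain)``.
    """
    if not (0 < frac <= 1):
        raise ParameterError("frac must be in (0, 1]")
    if sustain < 1:
        raise ParameterError("sustain must be >= 1")
    depth = track.depth
    if len(depth) == 0 or not np.any(depth > 0):
        raise NoSignalError("coverage track has no positive depth")
    if sustain > len(depth):
        raise ParameterError("sustain exceeds track length")
    top = np.sort(depth)[-max(1, len(depth) // 10) :]
    plateau = float(np.median(top))
    ok = depth >= frac * plateau
    # rolling all-true over windows of length `sustain`
    csum = np.concatenate(([0], np.cumsum(ok)))
    window_sums = csum[sustain:] - csum[:-sustain]
    hits = np.flatnonzero(window_sums == sustain)
    if len(hits) == 0:
        raise NoSignalError("no sustained coverage onset found")
    return int(hits[0])


@dataclass
class TerminatorParams:
    """Shape of the poly-T + inverted-repeat terminator search."""

    min_t_run: int = 5
    max_gap: int = 30
    min_arm: int = 6
    max_arm: int = 16
    max_spacer: int = 20
    search_window: int = 800

    def __post_init__(self) -> None:
        for name in ("min_t_run", "max_gap", "min_arm", "max_arm", "max_spacer", "search_window"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.max_arm < self.min_arm:
            raise ParameterError("max_arm must be >= min_arm")


def find_terminator(
    unit: SequenceRecord,
    end_of_28S: int,
    params: TerminatorParams | None = None,
) -> Feature:
    """Locate the transcription terminator downstream of the 28S gene.

    Scans ``[end_of_28S, end_of_28S + search_window)`` 5'->3' for the
    first run of >= ``min_t_run`` T's followed within ``max_gap`` bases
    by an inverted repeat: an arm of >= ``min_arm`` whose reverse
    complement recurs within ``max_spacer`` bases downstream. Returns a
    TERMINATOR feature spanning T-run start to second-arm end. Arms are
    tried longest-first at each position, so the reported element is the
    5'-most qualifying site with its longest local arm.
    """
    params = params or TerminatorParams()
    if not (0 <= end_of_28S < len(unit)):
        raise ParameterError("end_of_28S outside the unit")
    win_end = min(len(unit), end_of_28S + params.search_window)
    window = unit.seq[end_of_28S:win_end]

    for m in re.finditer(f"T{{{params.min_t_run},}}", window):
        run_start, run_end = m.start(), m.end()
        for gap in range(0, params.max_gap + 1):
            arm_start = run_end + gap
            for arm_len in range(params.max_arm, params.min_arm - 1, -1):
                arm = window[arm_start : arm_start + arm_len]
                if len(arm) < arm_len:
                    continue
                rc = revcomp(arm)
                search_from = arm_start + arm_len
                region = window[search_from : search_from + params.max_spacer + arm_len]
                idx = region.find(rc)
                if idx != -1 and idx <= params.max_spacer:
                    end = search_from + idx + arm_len
                    return Feature(
                        region_type=RegionType.TERMINATOR,
                        start=end_of_28S + run_start,
                        end=end_of_28S + end,
                        attributes={
                            "t_run": str(run_end - run_start),
                            "arm": arm,
                            "spacer": str(idx),
                            "min_t_run": str(params.min_t_run),
                            "min_arm": str(params.min_arm),
                            "max_spacer": str(params.max_spacer),
                        },
                    )
    raise NotFoundError(
        f"no poly-T + inverted-repeat terminator in [{end_of_28S}, {win_end}) of {unit.id}"
    )


def locate_promoter(
    unit: SequenceRecord,
    motif: SequenceRecord,
    max_mismatch: int = 4,
    window: tuple[int, int] | None = None,
) -> list[tuple[int, int]]:
    """All positions in *window* where the unit matches *motif* within
    ``max_mismatch`` Hamming mismatches, sorted by mismatches then position."""
    if len(motif) == 0:
        raise ParameterError("promoter motif must be non-empty")
    if max_mismatch < 0:
        raise ParameterError("max_mismatch must be >= 0")
    w0, w1 = window if window is not None else (0, len(unit))
    if not (0 <= w0 < w1 <= len(unit)):
        raise ParameterError(f"window [{w0},{w1}) outside unit of length {len(unit)}")
    if len(motif) > w1 - w0:
        raise ParameterError("motif longer than the search window")

    sub = np.frombuffer(unit.seq[w0:w1].encode(), dtype=np.uint8)
    mot = np.frombuffer(motif.seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(sub, len(mot))
    mismatches = (windows != mot).sum(axis=1)
    hits = [(w0 + int(p), int(mismatches[p])) for p in np.flatnonzero(mismatches <= max_mismatch)]
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits
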