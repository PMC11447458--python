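"""Cross-unit comparison and report generation.

Builds a Table-1-style summary of two annotated units: per-region
lengths, length deltas and GC percentages; gene-by-gene global-alignment
identities; promoter Hamming distance; CpG-island coverage of each unit.

Identity convention: global alignment with match +1, mismatch -1, linear
gap -2; identity = 100 * matched columns / alignment columns, so gaps
count against identity and identity(a, a) = 100. The convention is
printed in the report header.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._align import global_alignment_stats
from .errors import ParameterError, ValidationError
from .features import cpg_island_coverage, cpg_islands, gc_content
from .io_formats import CANONICAL_ORDER, Feature, GENE_REGIONS, RegionType, SequenceRecord

_REPORT_HEADER = (
    "# identity: global alignment, match +1 / mismatch -1 / gap -2; "
    "identity = 100 * matches / alignment columns"
)


def pairwise_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """End-to-end alignment identity of two sequences, percent to 0.1."""
    sa = a.seq if isinstance(a, SequenceRecord) else str(a).upper()
    sb = b.seq if isinstance(b, SequenceRecord) else str(b).upper()
    if not sa or not sb:
        raise ParameterError("pairwise_identity needs two non-empty sequences")
    _, matches, columns = global_alignment_stats(sa, sb)
    return round(100.0 * matches / columns, 1)


def promoter_distance(a: SequenceRecord | str, b: SequenceRecord | str) -> int:
    """Hamming distance between two equal-length promoter sequences."""
    sa = a.seq if isinstance(a, SequenceRecord) else str(a).upper()
    sb = b.seq if isinstance(b, SequenceRecord) else str(b).upper()
    if len(sa) != len(sb):
        raise ParameterError(
            "promoter_distance needs equal lengths; for unequal sequences use pairwise_identity"
        )
    return sum(1 for x, y in zip(sa, sb) if x != y)


@dataclass
class ComparisonReport:
    """Deterministic two-unit comparison (rendered as TSV or Markdown)."""

    unit_a: str
    unit_b: str
    region_table: pd.DataFrame  # region, length_a, length_b, delta_length, gc_a, gc_b
    gene_identity: dict[str, float]
    promoter_mismatches: int | None
    cpg_coverage_a: float | None
    cpg_coverage_b: float | None

    def to_tsv(self) -> str:
        lines = [_REPORT_HEADER]
        lines.append("section\tname\t" + "\t".join(self.region_table.columns[1:]))
        for _, row in self.region_table.iterrows():
            lines.append(
                "region\t"
                + row["region"]
                + f"\t{int(row['length_a'])}\t{int(row['length_b'])}"
                + f"\t{int(row['delta_length'])}\t{row['gc_a']:.1f}\t{row['gc_b']:.1f}"
            )
        for gene, ident in self.gene_identity.items():
            lines.append(f"gene_identity\t{gene}\t{ident:.1f}")
        if self.promoter_mismatches is not None:
            lines.append(f"promoter\tmismatches\t{self.promoter_mismatches}")
        if self.cpg_coverage_a is not None:
            lines.append(f"cpg_coverage\t{self.unit_a}\t{self.cpg_coverage_a:.1f}")
        if self.cpg_coverage_b is not None:
            lines.append(f"cpg_coverage\t{self.unit_b}\t{self.cpg_coverage_b:.1f}")
        return "\n".join(lines) + "\n"

    def to_markdown(self) -> str:
        out = [f"## Comparison: {self.unit_a} vs {self.unit_b}", "", _REPORT_HEADER, ""]
        out.append("| region | length A | length B | delta | GC A (%) | GC B (%) |")
        out.append("|---|---|---|---|---|---|")
        for _, row in self.region_table.iterrows():
            out.append(
                f"| {row['region']} | {int(row['length_a'])} | {int(row['length_b'])} "
                f"| {int(row['delta_length'])} | {row['gc_a']:.1f} | {row['gc_b']:.1f} |"
            )
        out.append("")
        for gene, ident in self.gene_identity.items():
            out.append(f"- {gene} identity: {ident:.1f}%")
        if self.promoter_mismatches is not None:
            out.append(f"- promoter mismatches: {self.promoter_mismatches}")
        if self.cpg_coverage_a is not None:
            out.append(f"- CpG island coverage of {self.unit_a}: {self.cpg_coverage_a:.1f}%")
        if self.cpg_coverage_b is not None:
            out.append(f"- CpG island coverage of {self.unit_b}: {self.cpg_coverage_b:.1f}%")
        return "\n".join(out) + "\n"


def _region_map(features: Sequence[Feature], label: str) -> dict[RegionType, Feature]:
    out: dict[RegionType, Feature] = {}
    for f in features:
        if f.region_type in set(CANONICAL_ORDER) and f.region_type not in out:
            out[f.region_type] = f
    for r in CANONICAL_ORDER:
        if r not in out:
            raise ValidationError(f"unit {label} is missing canonical region {r.value}")
    return out


def _find_promoter(features: Sequence[Feature]) -> Feature | None:
    for f in features:
        if f.region_type is RegionType.PROMOTER:
            return f
    return None


def build_report(
    unit_a: SequenceRecord,
    features_a: Sequence[Feature],
    unit_b: SequenceRecord,
    features_b: Sequence[Feature],
    compute_cpg: bool = True,
) -> ComparisonReport:
    """Assemble the full comparison of two annotated units.

    Both units must carry the complete canonical annotation; a missing
    region raises an error naming it. ``delta_length`` is
    ``length_b - length_a`` per region.
    """
    map_a = _region_map(features_a, unit_a.id)
    map_b = _region_map(features_b, unit_b.id)

    rows = []
    for r in CANONICAL_ORDER:
        fa, fb = map_a[r], map_b[r]
        rows.append(
            {
                "region": r.value,
                "length_a": fa.length,
                "length_b": fb.length,
                "delta_length": fb.length - fa.length,
                "gc_a": gc_content(unit_a.seq[fa.start : fa.end]),
                "gc_b": gc_content(unit_b.seq[fb.start : fb.end]),
            }
        )
    region_table = pd.DataFrame(rows)

    gene_identity = {}
    for g in GENE_REGIONS:
        fa, fb = map_a[g], map_b[g]
        gene_identity[g.value] = pairwise_identity(
            unit_a.seq[fa.start : fa.end], unit_b.seq[fb.start : fb.end]
        )

    promoter_mm: int | None = None
    pa, pb = _find_promoter(features_a), _find_promoter(features_b)
    if pa is not None and pb is not None and pa.length == pb.length:
        promoter_mm = promoter_distance(
            unit_a.seq[pa.start : pa.end], unit_b.seq[pb.start : pb.end]
        )

    cov_a = cov_b = None
    if compute_cpg:
        cov_a = cpg_island_coverage(cpg_islands(unit_a.seq), len(unit_a))
        cov_b = cpg_island_coverage(cpg_islands(unit_b.seq), len(unit_b))

    return ComparisonReport(
        unit_a=unit_a.id,
        unit_b=unit_b.id,
        region_table=region_table,
        gene_identity=gene_identity,
        promoter_mismatches=promoter_mm,
        cpg_coverage_a=cov_a,
        cpg_coverage_b=cov_b,
    )
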