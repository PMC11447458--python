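"""Compositional and repeat statistics, checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdnaunit import (
    CANONICAL_ORDER,
    PlantKind,
    RepeatKind,
    count_motif_and_complement,
    cpg_island_coverage,
    cpg_islands,
    find_g4_motifs,
    find_microsatellites,
    find_pur_pyr_tracts,
    gc_content,
)
from rdnaunit.errors import ParameterError, ValidationError
from rdnaunit.features import CpGIsland
from conftest import random_dna
from oracles import brute_cpg_islands, brute_microsatellites, naive_motif_count


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATAT", 0.0),
            ("GCGC", 100.0),
            ("TTGCTCCGCAGGAGCGAGC", 68.4),  # the quail Pol I promoter core
            ("ACGT", 50.0),
        ],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_rejects_empty_and_n(self):
        with pytest.raises(ParameterError):
            gc_content("")
        with pytest.raises(ParameterError):
            gc_content("ACGNT")

    def test_concatenation_is_length_weighted_mean(self, truth):
        parts, total_gc = [], 0.0
        for r in CANONICAL_ORDER:
            f = truth.feature(r)
            sub = truth.unit.seq[f.start : f.end]
            parts.append((len(sub), gc_content(sub)))
        weighted = sum(n * g for n, g in parts) / sum(n for n, _ in parts)
        assert abs(gc_content(truth.unit.seq) - weighted) <= 0.05


class TestCpgIslands:
    def test_at_repeat_has_no_island(self):
        assert cpg_islands("AT" * 150) == []

    def test_cg_repeat_is_one_island_with_oe_two(self):
        islands = cpg_islands("CG" * 150)
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.start, isl.end) == (0, 300)
        assert isl.oe_ratio == pytest.approx(2.0)
        assert isl.gc_frac == pytest.approx(1.0)

    def test_short_cg_repeat_fails_length_criterion(self):
        assert cpg_islands("CG" * 75) == []

    def test_island_embedded_in_at_background(self, rng):
        seq = "AT" * 200 + "CG" * 150 + "TA" * 200
        islands = cpg_islands(seq)
        assert len(islands) == 1
        # the maximal qualifying stretch contains the CG block; its ends
        # may sit in the AT flanks while GC stays above the 50% floor
        assert islands[0].start <= 400 and islands[0].end >= 700

    @pytest.mark.parametrize("gc", [0.4, 0.5, 0.6])
    def test_matches_brute_force_oracle(self, rng, gc):
        for _ in range(8):
            seq = random_dna(rng, int(rng.integers(220, 700)), gc=gc)
            got = [(i.start, i.end) for i in cpg_islands(seq)]
            assert got == brute_cpg_islands(seq)

    def test_invariants_enforced_on_construction(self):
        with pytest.raises(ValidationError):
            CpGIsland(start=0, end=150, gc_frac=0.8, oe_ratio=1.0)
        with pytest.raises(ValidationError):
            CpGIsland(start=0, end=300, gc_frac=0.4, oe_ratio=1.0)
        with pytest.raises(ValidationError):
            CpGIsland(start=0, end=300, gc_frac=0.8, oe_ratio=0.5)

    def test_coverage_arithmetic(self):
        islands = [CpGIsland(start=0, end=500, gc_frac=0.8, oe_ratio=1.0)]
        assert cpg_island_coverage(islands, 1000) == 50.0
        assert cpg_island_coverage([], 1000) == 0.0

    def test_coverage_rejects_overlap(self):
        islands = [
            CpGIsland(start=0, end=500, gc_frac=0.8, oe_ratio=1.0),
            CpGIsland(start=400, end=800, gc_frac=0.8, oe_ratio=1.0),
        ]
        with pytest.raises(ValidationError):
            cpg_island_coverage(islands, 1000)

    def test_unit_coverage_self_consistent(self, truth):
        islands = cpg_islands(truth.unit.seq)
        total = sum(i.length for i in islands)
        expected = round(100.0 * total / len(truth.unit), 1)
        assert cpg_island_coverage(islands, len(truth.unit)) == expected


class TestMicrosatellites:
    def test_printed_ets3_terminal_repeat_string(self):
        # the published 3'-ETS terminal repeat region, listed as (CCCGA)3
        seq = "CCCGACCCGACCCGACCGACCCGACCCGACCGA"
        hits = {(h.start, h.motif, h.copies) for h in find_microsatellites(seq)}
        assert (0, "CCCGA", 3) in hits

    def test_dinucleotide_phases(self):
        hits = {(h.start, h.motif, h.copies) for h in find_microsatellites("ATATATAT")}
        assert (0, "AT", 4) in hits
        assert (1, "TA", 3) in hits

    def test_two_copies_not_reported(self):
        assert find_microsatellites("ACGTACGT") == []

    def test_non_primitive_motifs_excluded(self):
        hits = find_microsatellites("ATATATATATAT", min_unit=2, max_unit=6)
        assert all(h.motif in ("AT", "TA") for h in hits)

    def test_matches_brute_force_oracle(self, rng):
        for i in range(12):
            alphabet = ["AC", "ACG", "ACGT"][i % 3]
            length = int(rng.integers(30, 220))
            seq = "".join(rng.choice(list(alphabet), size=length))
            got = {(h.start, h.motif, h.copies) for h in find_microsatellites(seq)}
            assert got == brute_microsatellites(seq)

    def test_planted_microsatellites_recovered_exactly(self, truth):
        hits = {
            (h.start, h.end, h.motif, h.copies) for h in find_microsatellites(truth.unit.seq)
        }
        for f in truth.of_kind(PlantKind.MICROSAT):
            key = (f.start, f.end, f.attributes["motif"], int(f.attributes["copies"]))
            assert key in hits

    def test_param_validation(self):
        with pytest.raises(ParameterError):
            find_microsatellites("ACGT", min_unit=0)


class TestMotifAndComplement:
    def test_examples(self):
        assert count_motif_and_complement("CGGCGGCGG", "CGG") == (3, 0)
        assert count_motif_and_complement("GGGG", "GGG") == (2, 0)
        assert count_motif_and_complement("CGGGCCGCC", "CGG") == (1, 2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            count_motif_and_complement("", "CGG")

    def test_invalid_motif_rejected(self):
        with pytest.raises(ParameterError):
            count_motif_and_complement("ACGT", "CNG")

    @settings(max_examples=60, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=1, max_size=120),
        motif=st.text(alphabet="ACGT", min_size=1, max_size=5),
    )
    def test_matches_naive_scan(self, seq, motif):
        n_m, n_c = count_motif_and_complement(seq, motif)
        comp = motif.translate(str.maketrans("ACGT", "TGCA"))
        assert n_m == naive_motif_count(seq, motif)
        assert n_c == naive_motif_count(seq, comp)


class TestTracts:
    def test_all_purine_run(self):
        hits = find_pur_pyr_tracts("GAGAGAGAGAGA")
        assert len(hits) == 1
        assert hits[0].kind is RepeatKind.PUR_TRACT
        assert (hits[0].start, hits[0].end) == (0, 12)

    def test_all_pyrimidine_run(self):
        hits = find_pur_pyr_tracts("TTTTTCCCCCTTTTT")
        assert len(hits) == 1
        assert hits[0].kind is RepeatKind.PYR_TRACT
        assert (hits[0].start, hits[0].end) == (0, 15)

    def test_alternating_acgt_has_no_tract(self):
        assert find_pur_pyr_tracts("ACGT" * 20) == []

    def test_planted_tracts_recovered_exactly(self, truth):
        hits = {(h.start, h.end) for h in find_pur_pyr_tracts(truth.unit.seq)}
        for f in truth.of_kind(PlantKind.PUR_PYR_TRACT):
            assert (f.start, f.end) in hits

    def test_min_len_validation(self):
        with pytest.raises(ParameterError):
            find_pur_pyr_tracts("ACGT", min_len=1)


class TestG4:
    def test_gaggg_repeat_is_one_quadruplex(self):
        hits = find_g4_motifs("GAGGGG" * 4)
        assert len(hits) == 1

    def test_canonical_g3_quadruplex(self):
        hits = find_g4_motifs("GGGAGGGAGGGAGGG")
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (0, 15)

    def test_at_repeat_has_none(self):
        assert find_g4_motifs("ATATATATAT") == []

    def test_planted_g4_recovered_exactly(self, truth):
        hits = {(h.start, h.end) for h in find_g4_motifs(truth.unit.seq)}
        for f in truth.of_kind(PlantKind.G4):
            assert (f.start, f.end) in hits

    def test_loop_bounds_validated(self):
        with pytest.raises(ParameterError):
            find_g4_motifs("GGGG", loop_min=5, loop_max=2)
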