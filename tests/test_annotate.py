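"""Boundary transfer, TSS calling, terminator and promoter location."""

import numpy as np
import pytest

from rdnaunit import (
    CANONICAL_ORDER,
    CoverageTrack,
    PlantKind,
    ReferenceUnit,
    RegionType,
    SequenceRecord,
    TerminatorParams,
    find_terminator,
    find_tss,
    generate_coverage,
    locate_promoter,
    transfer_boundaries,
)
from rdnaunit.errors import NoSignalError, NotFoundError, ParameterError, ValidationError
from rdnaunit.io_formats import structural_features
from conftest import random_dna
from oracles import brute_tss


def _mutate(seq: str, rate: float, rng) -> str:
    out = list(seq)
    for p in np.flatnonzero(rng.random(len(seq)) < rate):
        out[p] = {"A": "G", "C": "T", "G": "A", "T": "C"}[out[p]]
    return "".join(out)


@pytest.fixture(scope="module")
def reference(truth):
    return ReferenceUnit(record=truth.unit, features=structural_features(truth.features))


class TestTransferBoundaries:
    def test_identity_mapping(self, truth, reference):
        feats = transfer_boundaries(truth.unit, reference)
        expected = {f.region_type: (f.start, f.end) for f in reference.structural}
        got = {f.region_type: (f.start, f.end) for f in feats}
        assert got == expected

    def test_insertion_shifts_downstream_boundaries(self, truth, reference):
        its1 = truth.feature(RegionType.ITS1)
        cut = (its1.start + its1.end) // 2
        target = SequenceRecord(
            id="ins", seq=truth.unit.seq[:cut] + "ACGTACGTAC" + truth.unit.seq[cut:]
        )
        feats = {f.region_type: f for f in transfer_boundaries(target, reference)}
        for f in reference.structural:
            if f.end <= cut:
                assert feats[f.region_type].end == f.end
            if f.start >= cut:
                assert feats[f.region_type].start == f.start + 10
        assert feats[RegionType.ETS5].start == 0
        assert feats[RegionType.IGS].end == len(target)

    def test_translation_equivariance(self, truth, reference, rng):
        k = 37
        target = SequenceRecord(id="shift", seq=random_dna(rng, k) + truth.unit.seq)
        feats = transfer_boundaries(target, reference)
        for f, rf in zip(sorted(feats, key=lambda f: f.start), reference.structural):
            assert f.start == rf.start + k
            assert f.end == rf.end + k

    def test_diverged_region_flagged_but_neighbors_map(self, truth, reference, rng):
        """Replacing ITS2 wholesale must not derail the flanking gene boundaries."""
        its2 = truth.feature(RegionType.ITS2)
        target = SequenceRecord(
            id="div",
            seq=truth.unit.seq[: its2.start]
            + random_dna(rng, its2.length)
            + truth.unit.seq[its2.end :],
        )
        feats = {f.region_type: f for f in transfer_boundaries(target, reference)}
        # boundaries anchored in the conserved genes stay put (anchors are
        # half-conserved at the ITS2 borders, fully conserved elsewhere)
        assert abs(feats[RegionType.R5_8S].start - truth.feature(RegionType.R5_8S).start) <= 5
        assert abs(feats[RegionType.R28S].end - truth.feature(RegionType.R28S).end) <= 5

    def test_mutated_target_still_maps_within_tolerance(self, truth, reference):
        rng = np.random.default_rng(77)
        target = SequenceRecord(id="mut", seq=_mutate(truth.unit.seq, 0.02, rng))
        feats = transfer_boundaries(target, reference)
        for f, rf in zip(sorted(feats, key=lambda f: f.start), reference.structural):
            assert abs(f.start - rf.start) <= 5
            assert abs(f.end - rf.end) <= 5

    def test_target_shorter_than_shortest_gene_rejected(self, reference):
        with pytest.raises(ValidationError, match="shorter"):
            transfer_boundaries(SequenceRecord(id="t", seq="ACGT" * 10), reference)


class TestFindTss:
    def test_noiseless_step(self):
        depth = np.concatenate([np.zeros(500), np.full(9500, 100.0)])
        assert find_tss(CoverageTrack(unit_id="u", depth=depth)) == 500

    def test_all_zero_track_rejected(self):
        with pytest.raises(NoSignalError):
            find_tss(CoverageTrack(unit_id="u", depth=np.zeros(1000)))

    def test_matches_brute_force_on_noisy_tracks(self, rng):
        for _ in range(10):
            onset = int(rng.integers(100, 1500))
            depth = np.concatenate([np.zeros(onset), np.full(3000 - onset, 80.0)])
            depth = np.maximum(0, depth + rng.normal(0, 8.0, 3000) * (depth > 0))
            track = CoverageTrack(unit_id="u", depth=depth)
            assert find_tss(track) == brute_tss(list(track.depth))

    def test_recovers_planted_tss_from_synthetic_coverage(self, truth):
        depth = 100.0
        track = generate_coverage(truth, depth=depth, noise_sd=0.1 * depth, seed=21)
        called = find_tss(track)
        planted = truth.feature(RegionType.TSS).start
        assert abs(called - planted) <= 25


class TestFindTerminator:
    def _embed(self, rng, payload: str, offset: int, total: int = 1000) -> str:
        # AC-repeat background cannot form poly-T runs or inverted arms
        bg = ("AC" * total)[:total]
        return bg[:offset] + payload + bg[offset + len(payload) :]

    def test_planted_terminator_found_at_offset(self, rng):
        payload = "TTTTTT" + "ACACA" + "GCGAGC" + "AATT" + "GCTCGC"
        seq = self._embed(rng, payload, 120)
        feat = find_terminator(SequenceRecord(id="u", seq=seq), end_of_28S=0)
        assert feat.start == 120
        assert feat.end == 120 + len(payload)

    def test_no_terminator_in_ac_repeat(self):
        unit = SequenceRecord(id="u", seq="AC" * 400)
        with pytest.raises(NotFoundError, match=r"\[0, 800\)"):
            find_terminator(unit, end_of_28S=0)

    def test_first_of_two_sites_returned(self, rng):
        site = "TTTTTT" + "ACACA" + "GCGAGC" + "AATT" + "GCTCGC"
        seq = self._embed(rng, site, 100)
        seq = seq[:400] + site + seq[400 + len(site) :]
        feat = find_terminator(SequenceRecord(id="u", seq=seq), end_of_28S=0)
        assert feat.start == 100

    def test_recovers_planted_terminator_in_unit(self, truth):
        term = truth.of_kind(PlantKind.TERMINATOR)[0]
        feat = find_terminator(truth.unit, truth.feature(RegionType.R28S).end)
        assert abs(feat.start - term.start) <= 5
        assert abs(feat.end - term.end) <= 5

    def test_param_validation(self):
        with pytest.raises(ParameterError):
            TerminatorParams(min_t_run=0)
        with pytest.raises(ParameterError):
            find_terminator(SequenceRecord(id="u", seq="ACGT"), end_of_28S=10)


class TestLocatePromoter:
    MOTIF = SequenceRecord(id="m", seq="TTGCTCCGCAGGAGCGAGC")

    def test_exact_motif_single_hit(self, rng):
        seq = random_dna(rng, 300).replace("T", "A") + self.MOTIF.seq + random_dna(rng, 100).replace("T", "A")
        unit = SequenceRecord(id="u", seq=seq)
        hits = locate_promoter(unit, self.MOTIF, window=(250, 400))
        assert hits[0] == (300, 0)
        assert all(mm > 0 for _, mm in hits[1:])

    def test_single_substitution_counted(self, rng):
        body = list(self.MOTIF.seq)
        body[5] = "A" if body[5] != "A" else "G"
        seq = ("AC" * 200)[:200] + "".join(body) + ("AC" * 60)[:120]
        hits = locate_promoter(SequenceRecord(id="u", seq=seq), self.MOTIF, window=(150, 339))
        assert (200, 1) in hits
        assert hits[0] == (200, 1)

    def test_no_hits_in_poly_a(self):
        unit = SequenceRecord(id="u", seq="A" * 200)
        assert locate_promoter(unit, self.MOTIF, max_mismatch=4) == []

    def test_saturation_returns_every_position(self, rng):
        unit = SequenceRecord(id="u", seq=random_dna(rng, 100))
        hits = locate_promoter(unit, self.MOTIF, max_mismatch=len(self.MOTIF.seq))
        assert sorted(p for p, _ in hits) == list(range(0, 100 - 19 + 1))

    def test_empty_motif_rejected(self, truth):
        with pytest.raises(ParameterError):
            locate_promoter(truth.unit, SequenceRecord(id="m", seq=""))

    def test_finds_planted_promoter_in_unit(self, truth):
        L = len(truth.unit)
        hits = locate_promoter(truth.unit, self.MOTIF, window=(L - 2000, L))
        assert hits[0] == (truth.feature(RegionType.PROMOTER).start, 0)
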