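# Methods

This note records the models, conventions and numerical choices behind
`rdnaunit`, in the order the pipeline runs.

## Coordinates and orientation

All internal coordinates are 0-based half-open; GFF3 output is 1-based
inclusive and the conversion happens only in `io_formats` (a write/read
round trip is the identity). Units are stored on the sense strand in
transcription order: position 0 is the TSS (5' end of the 5'-ETS) and
the IGS closes the unit. Because the locus is tandemly repeated, "the
promoter immediately 5' of the TSS" maps to the 3' end of the IGS — the
promoter of the *next* copy in the array. No minus-strand features
exist. `N` is allowed in reads but rejected by the composition
statistics (GC, CpG, tracts), where it would make the quantities
ill-defined; those operations raise instead of silently skipping.

## Synthetic units

The generator's defaults are the study conditions of the avian unit it
emulates: region lengths 1779 / 1823 / 2047 / 157 / 658 / 4185 / 639 /
9878 bp (total 21166), GC targets 0.741 / 0.55 / 0.768 / 0.55 / 0.780 /
0.55 / 0.721 / 0.663 (spacer values as published, genes at a
representative 0.55), the 19-nt promoter `TTGCTCCGCAGGAGCGAGC`, and a
terminator of a 6-T run, an 8-bp arm, a 6-bp spacer and the arm's
reverse complement at the 3'-ETS 3' end.

**Background model.** Each region's background carries *exactly*
`round(length × gc)` G/C bases at uniformly random positions (G vs C
and A vs T fair coin flips). This exact-composition (permutation) model
was chosen over i.i.d. base sampling so that realized GC matches its
target to within one base deterministically — at 500 bp and GC 0.74 the
i.i.d. binomial standard deviation is already ≈ 0.02, which would make
"realized within ±0.02 of target" an unreliable property rather than a
guarantee. Dinucleotide statistics remain i.i.d.-like; in particular
the background CpG observed/expected ratio sits near 1.

**Consequence worth knowing:** because every region has GC > 0.5 and
obs/exp ≈ 1, the *entire* synthetic unit qualifies as one CpG island,
and the synthetic CpG-island coverage is ~100%. Real rDNA units contain
methylation-shaped CpG depletion that the background model does not
emulate; passing island tests therefore demonstrate correctness of the
detector, not realism of genomic CpG structure. A `CPG_ISLAND` plant
with CpG boosted to 1.5× expectation exists to exercise the detector's
contrast in both directions on custom low-GC specs.

**Planted features and guards.** Planted microsatellites, tracts, G4s
and dispersed motifs overwrite the background at recorded offsets. The
generator then edits single flanking bases ("guards": a base that
cannot extend the planted pattern — e.g. a pyrimidine beside a purine
tract, a non-G after a G4, no G within 8 bp upstream of a G4) so that
the scanners recover every planted feature at its exact recorded
coordinates. Planted features must keep ≥ 8 bp separation so guards
never overwrite payloads. This is a deliberate property of the truth
generator: recoverability is part of the ground-truth contract, and
tolerance to flank extension is tested separately on random sequences
via the brute-force oracles.

**Reads** are sampled from a two-copy tandem concatenation of the unit
(junction-spanning reads are what make IGS assembly possible in the
tandem-array reality); lengths are log-normal (σ = 0.5) around the
requested mean, clipped to [200, unit length]; errors are i.i.d.
substitutions only — indels are excluded so the polishing stand-in has
an exact oracle. **Coverage** is a plateau from the TSS to the 28S
3' end, a linear attenuation ramp (default 200 bp) past the 28S border
emulating transcription attenuation there, zero elsewhere, with
truncated Gaussian noise (floored at 0) where the expected depth is
positive. The true tandem copy number of the locus is unknown; the
two-copy concatenation is a testing device, not a biological claim.

## Read recovery

**Fishing.** BLAST-style selection is replaced by canonical k-mer
containment: `shared_frac = |kmers(read) ∩ kmers(query)| /
|kmers(read)|` over distinct canonical (min of forward/reverse-
complement) k-mers. Defaults k = 15, threshold 0.10: at 5% substitution
error the expected k-mer survival is 0.95¹⁵ ≈ 0.46, far above
threshold, while a random read shares ≈ |query k-mers| / 4¹⁵ ≈ 4·10⁻⁵.
Reads shorter than k are skipped with a warning rather than an error.
Performance tests use the whole unit as the query because synthetic
reads are drawn from the whole unit (IGS included); a gene-only query
would by construction miss IGS-only reads regardless of classifier
quality.

**Polishing** takes substitution-aligned placements (offset + read),
and at each position with coverage ≥ 3 replaces the draft base by the
strict majority base (> half of covering reads). Ties keep the draft
base — conservative editing, in the spirit of "checking" a draft
against higher-accuracy reads. With error-free reads covering every
position at depth ≥ 3 the polished sequence equals the truth exactly,
and polishing is idempotent.

## Structural annotation

**Boundary transfer.** Each reference boundary is represented by a
40-bp anchor centered on it; the anchor is aligned to the target with
edlib in infix ("HW") mode and the boundary maps to the anchor center.
Anchor length 40 is short enough to stay inside conserved gene ends yet
effectively unique in a 21 kb unit; anchors with identity < 60%
(edit-distance identity) are treated as unmapped — that floor keeps
anchors from latching spuriously onto the divergent IGS. Unmapped
boundaries are interpolated from the nearest mapped neighbours (scaled
by reference distances) and the affected features carry an
`unmapped=start|end` attribute, so downstream consumers can tell
measured from estimated coordinates. Non-monotonic mappings raise — a
target that reorders regions is structurally incompatible, not poorly
aligned.

**TSS.** The published workflow found the start point by eye in a
genome browser; here it is formalized reproducibly: plateau = median of
the top decile of depths; TSS = smallest position where depth ≥
`frac × plateau` (default 0.1) holds for `sustain` (default 50)
consecutive bases. Both knobs are exposed; the defaults tolerate 10%
relative noise while rejecting isolated spikes.

**Terminator.** First (5'-most) occurrence, within a default 800 bp
window after the 28S 3' end, of a ≥ 5-T run followed within ≤ 30 bp by
an inverted repeat: an arm of ≥ 6 bp (searched longest-first, up to
16 bp) whose reverse complement recurs within ≤ 20 bp downstream. The
published description gives the pattern but no lengths; all bounds are
parameters recorded in the output attributes.

**Promoter.** Plain Hamming scan of the motif over a window (default
≤ 4 mismatches), hits sorted by mismatches then position. No PWM — the
known avian Pol I promoters differ by 1–4 substitutions over 19 nt, a
regime where Hamming distance is the honest model.

## Sequence characterization

**CpG islands.** The island criterion (> 200 bp, GC > 50%, obs/exp CpG
= (N_CpG·L)/(N_C·N_G) > 0.6) defines a property of stretches, not a
search algorithm. The search implemented is greedy leftmost-longest:
open an island at the smallest start that admits any qualifying
stretch, close it at the largest qualifying end, resume after it. This
is deterministic, produces non-overlapping maximal stretches, and is
verified against an independent brute-force enumeration of all
(start, end) pairs. Edge behaviour to be aware of: a maximal stretch
may extend into low-GC flanks for as long as aggregate GC stays above
50%, so island ends are soft by nature of the criterion (window-based
published algorithms share this fuzziness).

**Microsatellites.** Perfect tandem runs of primitive (aperiodic)
2–6 bp units with ≥ 3 copies. Within one periodic stretch every phase
that still reaches 3 whole copies is reported as its own hit (the
published catalogues list multiple phases of one run, e.g. (ACCCG)₅ /
(CCCGA)₃ / (CCGAC)₃ over one terminal stretch), and each hit is
maximal: not extendable by a whole copy on either side. Homopolymers
are excluded (unit ≥ 2); imperfect/degenerate repeats are out of scope
for the perfect-repeat finder.

**Dispersed motif pairs.** The published dispersed "inverted repeat"
pairs — (CGG)/(GCC), (GCGA)/(CGCT) — are base-complement pairs read on
the same strand, not reverse complements; `count_motif_and_complement`
therefore counts a motif and its base complement, with overlapping
scan semantics. Published counts under an unstated convention are
treated as context, not as targets.

**Tracts and G4.** Purine (A/G) and pyrimidine (C/T) tracts are maximal
single-class runs ≥ 10 bp (H-DNA-prone bendable elements). G4 motifs
are non-overlapping leftmost matches of four G-runs (≥ 3) separated by
three 1–7 nt loops; no thermodynamic scoring is attempted.

## Comparison and identity

Pairwise identity uses global Needleman–Wunsch with match +1, mismatch
−1, linear gap −2; identity = 100 × matches / alignment columns, so
gaps count against identity and identity(a, a) = 100. Because many
alignments can share the optimal score, the kernel maximizes
(score, matches, −columns) lexicographically — a deterministic and
symmetric tie-break that makes "identity" well defined without
reference to a particular traceback. The convention and scoring are
printed in every report header. The kernel is numba-compiled; pairs up
to a few kb align in well under a second, and the comparison report
applies it to gene regions only (18S / 5.8S / 28S).

## Problem sizes and verification

The test suite and the acceptance script run entirely on synthetic
data: a 21166 bp unit, 200 rDNA reads vs 1800 background reads for the
classifier (mean length 1000, 5% substitutions), a ~14,000-read-
equivalent tiled pileup (150 bp reads, 10× depth) for polishing, and
brute-force oracle corpora of 200 random sequences each (≤ 800 bp for
islands, ≤ 500 bp for microsatellites, ≤ 200 bp pairs for identity).
Oracles are plain-Python enumerations sharing no code with the
implementations; the alignment score is additionally cross-checked
against Biopython's `PairwiseAligner` on random pairs.

## Known limitations

- Substitution-only error and read models; no indels, homopolymer
  artifacts or signal-level nanopore behaviour.
- The synthetic background has no methylation-shaped CpG depletion, no
  higher-order repeat structure, and no copy-to-copy variation between
  tandem units.
- Boundary transfer assumes collinear units; rearranged or partially
  deleted targets raise rather than being locally re-aligned.
- The perfect-repeat finder does not report degenerate repeats
  (single-IUPAC-position variants of published catalogues).
- The identity definition (gaps in the denominator, fixed scoring) is
  one reasonable convention; published identity figures computed with
  unknown aligners may differ by a few tenths of a percent.
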