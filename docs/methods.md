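# Methods

## Scope and model

`ifcascade` implements the computational design rules for type I–F
Cascade (PaeCascade) CRISPRa: guide selection against promoter windows,
crRNA array assembly and Csy4 processing, the positional mismatch
tolerance of crRNA:DNA pairing, and rule-based off-target enumeration.
It does not model activation strength: no sequence-level activity score,
chromatin state, or expression readout is predicted. Design outputs are
candidate lists and rankings derived from geometry and matching rules
only.

## Coordinates and conventions

All internal coordinates are 0-based, half-open, on the forward strand.
TSS-relative offsets are signed and gene-strand-relative (negative =
upstream in the direction of transcription) and are anchored at the
**PAM-proximal protospacer base**, the functional seed side; the anchor
is not standardized in the literature, so it is fixed here once and used
consistently by the window classifier, the promoter filter and the
synthetic planter. Spacer positions are numbered 1-based from the
PAM-proximal end. Emitted BED is 0-based half-open.

## Guide design

* PAM scan: every window with `CC` immediately 5′ of a full-length
  protospacer, both strands, N-containing windows excluded (N never
  matches a PAM base).
* Design range [−500, −100] bp, optimal window [−200, −100] bp
  (inclusive at both ends; in_range is the remainder of the design
  range). Both are configurable; they are heuristics summarizing a
  six-gene activation screen, not guarantees.
* Csy3 stoichiometry: ⌈L/6⌉ copies. The documented anchor points
  (14 nt → 3, 32 nt → 6, 50 nt → 9) force the ceiling rule among simple
  per-6-nt rules; lengths below 6 nt are rejected as below the minimal
  binding unit.
* Spacer extension: PAM-distal genomic continuation in steps of 6 nt
  (32 + 6k). Lengths above 56 nt are allowed but logged as beyond the
  validated range.
* Pair spacing: measured leftmost-to-leftmost on the forward axis (the
  anchor used for published pair distances is unstated; this choice is
  deterministic and strand-independent). 50–75 bp is classed optimal;
  pairs sort optimal-first, then by |spacing − 62.5|.
* Ranking: stable sort by window class, then |offset − optimal-window
  center|, then coordinate — fully deterministic.

## crRNA arrays

A pre-crRNA is `DR (spacer DR)×n` with a 28-nt direct repeat. Csy4
cleavage is modeled after repeat position 20: 20-nt hairpin upstream of
the cut, 8-nt handle downstream. This register is forced by the mature
crRNA architecture (8-nt handle + spacer + 20-nt hairpin = repeat
length 28). Processing conserves every nucleotide: leader (20 nt) +
crRNAs + trailer (8 nt) concatenate back to the pre-crRNA, which the
test-suite asserts exactly. The repeat sequence itself is user-supplied
configuration; `EXAMPLE_REPEAT` is a synthetic 28-mer used only by tests
and demos, because the package does not presume a biological repeat as
ground truth.

## Mismatch model and off-target rules

Effective mismatches are mismatching positions outside the tolerated
set. The default tolerated set is **{6, 12, 18} ∪ {24–32}** (the
every-sixth flip-out positions plus the PAM-distal tail); the seed is
{1–5, 7, 8}. Two wordings of the distal boundary circulate (24–32 vs
25–32); they differ only at position 24, which the every-sixth rationale
includes, so 24 is tolerated by default and the set is configurable. The
substitution rule for generated variants is the Watson–Crick complement
of the reference base, which guarantees a mismatch without introducing
ambiguity codes.

Rule sets are declarative: spacer length, IUPAC PAM pattern and side,
position mask, mismatch cap, and whether off-targets must carry a PAM.
Defaults: Cascade = 32 nt, 5′-CC, default mask, ≤4 effective; SpCas9
comparator = 20 nt, 3′-NGG, empty mask, ≤4. Cascade off-target
candidates require the CC PAM by default because PAM recognition is
mechanistically required for binding; this can be disabled to search on
sequence similarity alone. An N in the genome counts as a mismatch at
any position and never satisfies a PAM base.

The production enumerator scans each strand with a PAM-anchored
prefilter and then Hamming-checks surviving windows. Its correctness is
not argued but tested: `brute_force_oracle` re-implements the contract
as a forward-axis, no-prefilter, no-early-exit rescan with its own
IUPAC table and reverse-complement, and the suite asserts exact hit-list
equality on 100 seeded 10-kb genomes carrying planted decoys, for both
rule sets, plus strand-symmetry and monotonicity properties.

## Promoter filter

Promoters are `[tss − w, tss + w + 1)` with w = 2000 bp by default, so a
site exactly 2 kb away is retained. A hit passes if **any** protospacer
base overlaps a promoter interval; it is annotated with the nearest
overlapped gene (ties broken lexicographically) and the signed
forward-axis distance from its PAM-proximal base to that TSS. Because
retention is overlap-based but the distance is anchor-based, a site
whose anchor sits just beyond the boundary (< spacer length) can in
principle be retained with |distance| slightly above w; the planted
grids used in tests anchor sites with the PAM-proximal base nearest the
TSS, where the reported cut-off is exactly 2.0 kb.

## Synthetic data

The generator emulates the study's genomic inputs at desk scale:
i.i.d. background at GC 0.41 (human-like; configurable), genes as
TSS+strand annotations, on-targets written as `CC + spacer` in
gene-strand orientation at a requested offset, and decoys as
complement-substituted variants at chosen positions, placed near a gene
or at random loci. One integer seed drives everything. Collisions are
resolved by bounded retry (100 attempts); a plant whose full site
already occurs elsewhere is rejected and re-placed (the check can be
disabled to plant deliberately identical sites, as the promoter-grid
experiment requires). Each plant records its expected fate — effective
count, detectability under the rule cap, promoter overlap — against
which the pipeline is scored.

What the background does **not** model: real promoter composition, CpG
islands, repeats, chromatin. Passing end-to-end tests therefore
demonstrates that the rules are implemented correctly and recover
planted truth, not that the heuristic windows predict activation on real
promoters.

## Problem sizes and determinism

Test and acceptance workloads use 10–50 kb genomes: oracle equivalence
on 100 × 10 kb, decoy ladders on 50 kb, end-to-end recovery on 20 seeded
datasets of 20 kb with 3 genes and 9 decoys each. These sizes give every
rule multiple planted positive and negative instances while keeping the
whole suite fast and exactly reproducible; the algorithms themselves are
linear in genome length and run unchanged on larger FASTA inputs.
Hypothesis-based property tests run derandomized; all other randomness
flows from explicit integer seeds.

## Known limitations

* No activity model: candidates inside the optimal window are not
  differentiated by predicted activation strength.
* No bulge/indel off-targets; substitution-only matching.
* The Csy4 cleavage register is inferred from segment-length arithmetic;
  an alternative register would shift handle/hairpin assignment but not
  spacer recovery.
* Pair-distance and offset anchors are package conventions where the
  literature is silent; they are documented above and configurable where
  they interact with thresholds.
* The promoter rule substitutes the plain ±2 kb TSS window for
  curated regulatory-track promoter definitions, which are not
  reproducible from first principles.
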