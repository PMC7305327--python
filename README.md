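# ifcascade

Guide design and off-target prediction for **type I–F Cascade (PaeCascade)
CRISPR activation** in mammalian cells.

The *Pseudomonas aeruginosa* type I–F Cascade is a four-subunit
(Csy1–Csy4) crRNA-guided DNA-binding complex. Fused to a transcription
activation domain, it acts as a programmable CRISPRa effector: a crRNA
directs it to a promoter, where it recruits the activator to the target
gene's TSS. Designing crRNAs for this system differs from Cas9 guide
design in every load-bearing detail — PAM, spacer geometry, stoichiometry
and mismatch tolerance — and `ifcascade` implements those rules as a
tested, scriptable pipeline for anyone planning type I–F CRISPRa
experiments or analysing their specificity.

## The model

* **PAM and spacer.** Cascade recognizes a 5′-CC PAM on the non-target
  strand; the crRNA spacer is identical in sequence to the protospacer on
  the PAM-carrying strand. The canonical spacer is 32 nt.
* **TSS window.** Activation works with guides −500 to −100 bp upstream
  of the TSS (gene-strand-relative, measured at the PAM-proximal base),
  and best in the −200…−100 bp window. Pairs of guides spaced 50–75 bp
  apart act synergistically.
* **Csy3 stoichiometry.** Each Csy3 subunit binds 6 nt of spacer, so a
  spacer of length L recruits ⌈L/6⌉ Csy3 copies (3 at 14 nt, 6 at 32 nt,
  9 at 50 nt). Extending the spacer at the PAM-distal end in steps of
  6 nt (38, 44, 50, 56 …) recruits more activator-fused Csy3.
* **crRNA arrays.** A pre-crRNA laid out `DR–spacer1–DR–spacer2–DR`
  (28-nt direct repeats) is processed by Csy4, which cuts each repeat
  after position 20. Every mature crRNA is therefore
  8-nt handle + spacer + 20-nt hairpin.
* **Mismatch tolerance.** crRNA:DNA pairing follows a 5+1 pattern: every
  sixth base is flipped out of the duplex, so mismatches at positions
  6, 12, 18, 24 are tolerated, as are PAM-distal positions 24–32; the
  PAM-proximal seed (1–5, 7, 8) is critical. Off-target search counts
  only *effective* mismatches — those outside the tolerated set
  {6, 12, 18} ∪ {24–32} — and keeps sites with ≤ 4 of them that lie
  within ±2 kb of a TSS. A SpCas9 comparator rule (20-nt spacer, 3′-NGG,
  ≤ 4 mismatches anywhere) runs in the same machinery.

All computation is exercised on seeded synthetic genomes with planted
ground truth (`ifcascade.synthetic_data`), so every rule is verifiable
end to end.

## Worked example

Simulate a small annotated genome with planted guides and decoys, design
guides, and predict off-targets:

```console
$ ifcascade simulate --out sim --seed 11 --length 15000
wrote dataset (9 planted features) to sim

$ ifcascade design --fasta sim/genome.fa --tss sim/tss.bed --out design
97 candidates, 1594 pairs -> design

$ head -4 design/candidates.tsv | cut -f1-4,8-10
gene_id  seq_name  strand  start  tss_offset  window_class  csy3_copies
gene1    chr1      +       3600   -150        optimal       6
gene1    chr1      +       3599   -151        optimal       6
gene1    chr1      +       3598   -152        optimal       6
```

The top candidate is the planted guide 150 bp upstream of gene1's TSS,
classed `optimal` (−200…−100 window) with 6 Csy3 copies for its 32-nt
spacer. `design/pairs.tsv` ranks guide pairs, optimal 50–75 bp spacings
first (`spacing 63 → optimal`). Off-target prediction for that spacer:

```console
$ ifcascade offtarget --fasta sim/genome.fa --tss sim/tss.bed \
      --spacer AATCGGGACACTGAGATTTGTCAGCGTCTACT --out ot
4 hits across 1 spacers -> ot

$ head -3 ot/offtargets_spacer1.tsv | cut -f1-4,8-11
seq_name  strand  start  end   effective_mismatches  on_target  nearest_gene  tss_distance
chr1      +       2421   2453  0                     False      gene1         -1329
chr1      -       2843   2875  0                     False      gene1         -876
```

These are planted decoys whose mismatches all fall at tolerated
positions: 0 *effective* mismatches despite differing from the query, and
within 2 kb of a TSS — exactly the sites the masking rule is built to
catch. Assembling a two-spacer array and processing it with Csy4:

```console
$ ifcascade array --spacers spacers.txt --repeat GTTCACTGCCGTATAGGCAGCTAAGAAA --out arr
2 mature crRNAs from a 148-nt pre-crRNA -> arr

$ cat arr/crrnas.tsv
index  handle    spacer                            hairpin               length
1      CTAAGAAA  ACGTACGTACGTACGTACGTACGTACGTACGT  GTTCACTGCCGTATAGGCAG  60
2      CTAAGAAA  TTTTACGTACGTACGTACGTACGTACGTACGT  GTTCACTGCCGTATAGGCAG  60
```

Each crRNA carries the 8-nt handle and 20-nt hairpin fixed by the Csy4
cleavage register. (The repeat shown is the package's synthetic example;
supply your system's own repeat for real designs.)

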