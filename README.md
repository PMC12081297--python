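# indeltax

Sequence-context-aware classification of small insertions and deletions
(InDels) for mutational-signature analysis, with the profile statistics
that go with it and **PRRDetect**, a classifier of post-replicative
repair deficiency.

## The problem

InDel mutational signatures are only as informative as the channels the
mutations are counted into.  The prevailing 83-channel scheme
(COSMIC-83 / PCAWG ID-83) aggregates all 1 bp InDels at homopolymers
longer than 5–6 bp into single terminal bins — yet those long tracts
are precisely where mismatch-repair deficiency (MMRd) and replicative
polymerase proofreading dysfunction (Pol-dys) leave their most
discriminating marks.  Under the legacy scheme, MMRd deletion
signatures become indistinguishable from normal replication-slippage
signatures.

`indeltax` implements a redefined InDel taxonomy built on a
*segmentation* of each InDel: the shortest motif prefix (the **unit**)
that, read 3′ from the event anchor, forms the longest uninterrupted
tandem run through the InDel and on into the reference context.  From
the segmentation, each left-aligned parsimonious InDel is assigned to
exactly one channel in six divisions — 1 bp insertions, 1 bp
deletions, ≥2 bp insertions, ≥2 bp deletions, microhomology-mediated
deletions (binned by deletion length *L* × homology length *M*), and
complex InDels.  The full crossing yields **476** channels;
consolidation against cohort signal reduces them to the **89-channel**
production scheme, which keeps per-length homopolymer bins out to ≥9 bp
and flanking-base context at short runs.  The legacy **83-channel**
scheme is reimplemented for comparison.  (The published channel tables
live in supplementary materials; the tables shipped here are a
documented reconstruction, versioned `reconstructed-1.0` — see
`docs/methods.md`.)

On top of the taxonomy the package provides: bootstrap cosine envelopes
for calling a profile distinct from background, background subtraction,
non-negative least-squares exposure refitting, a parametric-bootstrap
excess-variation test with FDR control, hypermutator detection
(profile clustering + Gaussian-mixture burden modelling), signature
clustering, replicative strand asymmetry (leading/lagging odds ratios
against repeat-content expectations), a bootstrap-NMF rank-selection
harness, and PRRDetect — a multinomial elastic-net classifier of
{MMRd, Pol-dys, mixed, PRR-proficient} built on seven signature-exposure
features with the decision rule *call negative iff P(Neg) > 0.5*.

A first-class synthetic-data module generates toy references with
planted homopolymers, tandem repeats, microhomology sites and
nonrepetitive loci; VCFs of planted InDels whose channel is known *by
construction*; signature-mixture catalogs; labelled classifier cohorts;
and strand-annotation BEDs.  Everything the tests and the acceptance
script consume is generated by this module at run time.

## Worked example

Generate a toy genome with planted InDels covering every channel, build
an 89-channel catalog, and inspect the segmentation:

```bash
indeltax synth vcf --seed 7 --per-channel 3 \
    --fasta-out toy.fa --vcf-out toy.vcf --truth-out truth.tsv
# planted 381 InDels

indeltax catalog --vcf toy.vcf --ref toy.fa --scheme ind89 --out catalog.tsv
# wrote 1 samples x 89 channels to catalog.tsv

indeltax segment --vcf toy.vcf --ref toy.fa --out seg.tsv
```

`catalog.tsv` is a channels × samples count table; its top rows for
this seed are

```
channel
complex       21
mh:L5+:M4+    15
mh:L5+:M1      9
mh:L5+:M2      9
mh:L5+:M3      9
```

i.e. 21 complex InDels and the planted microhomology deletions binned
by their L×M classes (`mh:L5+:M4+` collects deletions of length ≥5
with ≥4 bp of junction homology).  `seg.tsv` holds the per-variant
segmentation:

```
chrom  pos0  op_class   motif  unit  unit_len  copies_in_indel  copies_in_context  total_copies  L  M
chr1   10    insertion  C      C     1         1                0                  1
```

— a C inserted at a site with no pre-existing C run (one tandem copy in
total: the inserted one).  Classifying the same VCF per variant
(`indeltax classify --scheme ind89 --per-variant pv.tsv`) reproduces
the generator's truth labels for all 381 events.

Other entry points: `indeltax compare` (bootstrap background
envelopes), `indeltax fit` / `indeltax excess` (refitting and
excess-variation testing), `indeltax asymmetry` (replication-strand
bias), `indeltax prrdetect train|predict|evaluate`, and `indeltax synth
reference|vcf|catalog|cohort|bed`.  The same functionality is available
as a library (`import indeltax`).

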