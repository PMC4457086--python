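# Methods

## The measurement model

The package analyses RNase-footprinted native elongating transcript
sequencing (RNET-seq) of a bacterium. Paused RNA-polymerase elongation
complexes are isolated, the nascent RNA 5' of the polymerase footprint is
trimmed away with RNases, and the protected 3'-proximal fragment is
sequenced. Two properties of the protected fragment carry the information
the pipeline extracts:

1. **Its 3'-end position.** Among the reads of an analysis class covering a
   genomic position, the fraction phi whose 3' end falls exactly there
   measures how often the polymerase sat with its active site at that base.
   A position is called a pause site under `P(phi_min, delta_min)` when
   `phi = end3/depth >= phi_min` and the class coverage `depth >= delta_min`
   (module `pause`). Published regimes implemented as defaults: P(0.9, 100)
   and P(0.9, 160) for the bulk >= 21-nt classes of the wild-type and
   Gre-deletion strains, P(0.9, 50) for single-length classes, and
   P(0.7, 100) where more sites are wanted without changing the motif.
   Adjacent qualifying positions are reported independently; delta is
   coverage depth (a `delta_on_end3` switch exposes the alternative
   3'-end-count reading).
2. **Its length.** The RNase-protected length encodes the translocation
   state of the complex: 14 nt post-translocated, 15 nt pre-translocated,
   and 14 + 1 + b nt when backtracked by b bp (`state_from_length`).
   Reads shorter than 14 nt are "sub-footprint" initiation-region species
   and are excluded from pause calling; reads >= 21 nt carry no RNase cut
   signature and form the bulk class used for genome-wide work.

Pause motifs ("pause-inducing elements", PIEs) are summarised as base
frequency matrices over non-template-strand windows anchored at the pause
3'-end base, offsets -15..+5 with no offset 0 (-1 = 3'-end base, +1 =
incoming-NTP position). Per-offset information content is
`IC_j = 2 + sum_b p_jb log2 p_jb` bits with an optional small-sample
correction `3/(2 ln2 n)` floored at zero. The motif-level score is the
log-likelihood ratio `sum_j sum_b n_jb log2(p_jb / q_b)` against the
genomic base composition, labelled "MAP-like" in outputs: it is a standard
LLR summary, not a reimplementation of any particular published scoring
formula.

Transcription errors are read off the CIGAR/MD mismatches of
substitution-only alignments, re-expressed in transcript orientation (minus
-strand bases complemented), and indexed by offset from the 3' end. Rates
are per opportunity: the G-to-A rate at an offset is mismatches divided by
reads whose reference base there is G (a `--per-aligned-base` style switch
is not needed because the `ErrorMatrix` stores both numerators and
denominators; per-aligned-base rates can be formed from `to_frame()`).
Multi-mapped reads are excluded from error matrices (unique-best only)
although they are counted in pileups — mismatch calls at repeats are
unreliable, coverage at repeats is still real. The enrichment threshold for
one substitution type is mean + 1 SD of its rates pooled over offsets
-12..-1 of the 14-18-nt classes.

## The synthetic-data generator

The generator (`simulate`) emulates the statistical structure the analysis
assumes, with full ground truth. What it models, and why:

* **Genome and annotation.** A random genome (default 20 kb, GC 0.5) with
  non-overlapping genes on alternating strands (default 20), each with a
  5' UTR of 20-60 nt (bacterial UTRs are short), a CDS of 150-450 nt and a
  20-nt 3' UTR. The first two genes overlap by 60 bp at their 3' ends so
  convergent/antisense analyses have signal. rRNA can be emitted as seven
  byte-identical copies to exercise multi-mapping. Per-gene expression
  multipliers are log-normal (sigma 0.6) and are drawn from the *genome*
  seed: two strains simulated on one genome share them, as isogenic strains
  share an expression programme — this is what makes the between-strain
  region comparison behave like the real experiment, where between-gene
  variance is large but between-strain, within-gene variance is small.
* **Planted pause motifs.** `plant_pauses` edits the genome so each site
  carries its element on the non-template strand: the wild-type element
  G(-10) + T(-3)G(-2)C(-1) + G(+1), or the Gre-deletion element G(-11) +
  T(-7)/T(-4) + G(-1), with sites >= 30 bp from gene ends and >= 25 bp
  apart. Misincorporating sites additionally carry a CpG context (C at -2,
  G at -1); non-misincorporating Gre-deletion sites get an explicit non-C
  base at -2 as a matched control, so the penultimate-C comparison isolates
  the error channel rather than background composition.
* **Occupancy.** A read's 3'-end position is drawn over all transcribed
  positions with weight `expression` (background) or `expression x
  dwell_weight` (planted; default 200). At that weight a planted site's
  phi saturates near `w/(w + (L-1))` ~ 0.93 for footprint-length classes —
  inside the P(0.9, 50) calling regime — but only ~0.89 for 21-30-nt bulk
  reads, which is why the package's bulk analyses of synthetic data use the
  relaxed P(0.7, 100) regime (the motif is unchanged by the relaxation).
* **Translocation-state occupancies.** Qualitative only in the source
  experiments, so these are calibration choices. They were set, by
  closed-form mixture arithmetic over states x RNase shift x read
  categories, to reproduce the observed modal protected lengths (16 nt with
  Gre factors, 18 nt without): wild type background
  {post .10, pre .25, bt1 .40, bt2 .18, bt3 .07} and planted
  {.10, .35, .40, .10, .05}; deletion strain background
  {.05, .10, .15, .25, .45} and planted {.05, .15, .20, .25, .35}. The
  deletion strain is deeply backtracked everywhere (no Gre rescue); the
  wild type sits mostly pre-translocated/1-bp backtracked.
* **Misincorporation channel.** With the site's rate (default 8e-3 at
  planted CpG sites of the deletion strain, 0 for wild type), a read whose
  drawn state is backtracked and whose 3' reference base is G has its 3'
  base replaced by A. Conditioning on backtracked states (rather than
  forcing a state change) encodes the same biology — misincorporation-
  induced pauses are backtracked — while keeping the per-length G-to-A
  rate at -1 exactly equal to the parameter, so the error stage's estimate
  is an unbiased binomial proportion. It also yields the observed rising
  rate from 14 to 18 nt: 14-15-nt reads are never backtracked (rate 0) and
  16-17-nt classes are state mixtures (intermediate rates).
* **RNase T1 5'-end bias.** With probability `rnase_t1_bias` (default 0.5)
  the 5' trim point of a footprint read moves up to 2 nt upstream onto the
  nearest position whose 5' neighbour is G (T1 cuts GpN). The cap keeps the
  length-to-state mapping only mildly corrupted, mirroring the real
  under-estimation of the 14/15-nt classes; because the shift is determined
  by the local sequence it is *deterministic per site and state*, which is
  why planted-pause recovery pools P(0.9, 50) calls over the 14-20-nt
  classes instead of relying on any single class.
* **Read categories.** 10% initiation reads (6-13 nt, 3' ends just
  downstream of a TSS) and 25% incompletely trimmed reads (21-30 nt,
  uniform; no T1 signature) complete the 6-30-nt length range; both keep
  the true 3'-end position.
* **Sequencing noise.** Uniform substitutions at 1e-4 per base (Phred ~38
  throughout, matching the constant Q=38 written to FASTQ).

Lossless SAM output carries the true position, an all-match CIGAR and
MD/NM tags encoding every planted mismatch, so the standard ingest path
(`pysam` + MD reconstruction) reproduces the truth table exactly; this
round trip is itself a test.

What the generator does **not** model — and hence what passing tests do not
show about real data: polymerase kinetics (no rates, no NTP dependence),
ribosome coupling, R-loops, adapter-ligation artifacts, indels, quality-
score structure, context-dependent sequencing error, the G(-9) preference
of real post-translocated (14-nt) pause sites, operon structure beyond
one-gene operons, and reads spanning the circular origin (the simulator
stays 60 bp away from the sequence ends).

## Numerical and design choices

* Coordinates are 0-based half-open internally, 1-based in human-readable
  TSVs, 0-based in BED. Offset conventions have no 0 (-1 abuts +1).
* Pseudocount 0.25 per base per matrix column: keeps IC and LLR finite at
  small n without dominating at n >= 50. IC display uses a uniform
  background; the LLR score uses genomic composition.
* The naive mapper is seed-and-extend with the seed length shrunk to
  `len(read) // (max_mismatch + 1)` so the pigeonhole guarantee makes it
  exhaustive-equivalent at desk scale; mapq is a documented convention
  (42 unique / 3 for 2-4 hits / 0 for >4), chosen so the mapq_mean > 10
  uniqueness filter separates unique from 7-copy-rRNA mappings.
* Multi-mapped reads are counted at every location in pileups and gene
  counts (both inclusion and exclusion bias repeats; inclusion is the
  documented choice) but excluded from error matrices.
* Welch's unequal-variance two-tailed t-test is the default strain
  comparison (a paired switch exists); genes enter at normalised count
  > 0.1 in both strains. The Up-region experiment plants a 3-fold dwell
  increase in the 50 bp upstream of each start codon of one strain —
  large enough to clear the between-gene variance, small enough that the
  compositional dilution of the other regions stays non-significant.
* TSS distance profiles default to 25-bp bins over +/-500 bp, nearest
  same-strand TSS, signed downstream-positive.
* Ties in the modal read length go to the smaller length; no tie occurs at
  the default conditions.
* Degenerate inputs: empty pause lists produce empty (valid) outputs;
  matrices require >= 1 window; `state_from_length` rejects lengths outside
  6-30; gene windows of genes shorter than 100 bp overlap and are flagged.

## Problem sizes

The default experiments use a 20-kb genome, 20 genes, 40 planted sites and
1.5-4 x 10^5 reads — sizes chosen so every recovery check retains at least
~10^4 Bernoulli trials (binomial SE small against its effect) while the
whole suite and the acceptance script each run in minutes on one CPU. The
deletion-strain dataset is sized so its 18-nt class alone holds >= 10^5
reads, the regime in which the misincorporation parameter is recovered
within 3 binomial SE.

## Known limitations

The pause statistic assumes substitution-only, fixed-length alignments;
indel-containing records are excluded (and counted) rather than realigned.
phi at a planted site is bounded away from 1 by through-reads, so extreme
thresholds (phi_min > 0.95) under-call even perfect sites at finite dwell
weight. The per-site determinism of the RNase-bias shift exaggerates
between-class variability relative to real digestion, which is stochastic
per molecule; analyses that pool length classes are unaffected. Real-data
features such as mapping ambiguity beyond exact repeats, library-dependent
ligation bias and RNase A (CpN/UpN) cut preference are not modelled.
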