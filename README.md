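# rnetseq

Analysis toolkit for RNase-footprinted native elongating transcript
sequencing (RNET-seq) of bacteria: from strand-specific alignments of
RNase-protected nascent-transcript fragments to called RNA-polymerase pause
sites, pause-motif matrices, translocation-state profiles, per-position
transcription-error rates and gene/region pausing metrics — plus a
synthetic elongation-complex read generator with full ground truth for
validating every stage.

## The science in brief

In an elongation complex the RNase-protected length of the nascent RNA
encodes the polymerase's translocation state: 14 nt post-translocated,
15 nt pre-translocated, 14+1+b nt when backtracked by b bp. RNET-seq reads
therefore carry two signals at once:

* **Where the polymerase paused.** For every genomic position and strand,
  with δ the read depth of the analysis class and φ the fraction of those
  reads whose 3′ RNA end lies exactly there, a pause site satisfies
  **P(φ_min, δ_min)**: φ ≥ φ_min and δ ≥ δ_min (e.g. P(0.9, 100) on bulk
  ≥21-nt reads, P(0.9, 50) on single-length classes).
* **In which register it paused.** Building the pause-inducing-element
  (PIE) matrix separately per read length locates the upstream riboG–dC
  base pair of the RNA–DNA hybrid at −9/−10/−11 from the 3′ end for the
  post-translocated, pre-translocated and 1-bp-backtracked registers, and
  the downstream element T G C₋₁ G₊₁ spans the active site. Information
  content per offset is `IC_j = 2 + Σ_b p_jb log₂ p_jb` bits.

A third signal lives in the mismatches: a G-to-A misincorporation at the
3′ RNA end (CpG context, template strand) triggers backtracking, so in
cells lacking the Gre rescue factors the per-opportunity G→A rate at
offset −1 rises with read length and reaches ~8×10⁻³ in the 18-nt class,
while proofreading keeps it below detection in the wild type. Error
matrices are accumulated per read length from CIGAR/MD mismatches in
transcript orientation.

## Worked example

```python
import rnetseq as r
from rnetseq import pause as P, motif as M

genome, genes, tss = r.generate_genome(20000, gc=0.5, n_genes=20, seed=1)
genome, sites = r.plant_pauses(genome, genes, 40, "WT_PIE", r.WT_PROFILE, seed=2)
sim = r.simulate_reads(genome, genes, sites, r.WT_PROFILE, 100_000, seed=3)

# ingest the lossless SAM through the standard path
open("reads.sam", "w").write(sim.sam_text)
reads, report = r.read_alignments("reads.sam", genome=genome)

tracks = P.build_pileup(reads, {genome.replicon_id: len(genome)}, "bulk_ge21")
pauses = P.call_pauses_all(tracks, 0.7, 100)
windows, _ = M.extract_windows(pauses, genome)
m = M.frequency_matrix(windows)
print(len(pauses), M.top_ic_offsets(m, 5), m.consensus()[4:9])
```

The same computation is narrated by the numbered drivers. Running them in
order (`python analysis/01_simulate_strains.py` …) prints, for example:

```
WT: 150000 reads, modal length 16 nt, G 5' of trimmed read starts 0.39
dGreAB: 400000 reads, modal length 18 nt, G 5' of trimmed read starts 0.45
WT: 38 bulk sites at P(0.7,100); union of single-length P(0.9,50) calls
    recovers the planted sites at precision 1.000 / recall 1.000
WT: bulk PIE over 38 sites, total IC 9.8 bits, ... consensus excerpt GTGCG
  15-nt class: G-richest upstream offset -10 (fraction 1.00)
dGreAB ... 16-nt class: G-richest upstream offset -11 (fraction 1.00)
  recovered misincorporation rate 8.49e-03 over 35928 18-nt opportunities
  at planted CpG sites (configured 8.0e-03)
penultimate C at -2: 1.00 in the error group (13 sites) vs 0.00 in the
  error-free group (16 sites)
  Up: p=0.0302 (significant)   Head/Tail/Down: n.s.
```

Reading the numbers: the Gre-deletion profile shifts the modal protected
length from 16 to 18 nt (an enriched backtracked population); pause calling
recovers every planted motif with no false positives; the per-length PIEs
place the upstream G at −10 in the wild type versus −11 in the deletion
strain; the error stage re-estimates the planted 8×10⁻³ misincorporation
rate from the read mismatches alone; error-containing 18-nt pause reads
favour C at the penultimate position; and a planted 5′-UTR (Up-window)
dwell increase is significant only in the Up region.

Each driver writes its tables under `results/` (pause TSV/BED, PIE and
error matrices, gene counts, Welch comparison).

A `rnetseq` command-line wrapper exposes the same stages
(`rnetseq simulate`, `rnetseq ingest`, `rnetseq run-all`, `rnetseq
validate`) for shell use; see `rnetseq --help`.

Real data are ingested the same way: `rnetseq ingest --alignments
sample.bam --genome-fasta ref.fa --annotation-gff genes.gff3 --tss-tsv
tss.tsv --phi 0.9 --delta 100` accepts any SAM/BAM with CIGAR and MD tags
(indel-containing records are excluded and counted).

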