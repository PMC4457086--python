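"""Canonical synthetic-data experiments at the package's study conditions.

Each function runs one self-contained analysis on simulated data — the same
computations the numbered analysis drivers narrate — so that the test suite,
the acceptance script and the drivers all share a single implementation.
The default problem sizes (20-kb genome, 20 genes, 40 planted sites,
1-4 x 10^5 reads) keep every experiment in the minutes range on one CPU
while leaving >= 10^4-10^5 observations for the statistical checks.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genes as genes_mod
from . import io as io_mod
from . import motif as motif_mod
from . import pause as pause_mod
from . import simulate as sim_mod
from .errors import accumulate_errors, matrices_by_length
from .genes import DGREAB_TOTAL_MAPPED_READS, WT_TOTAL_MAPPED_READS

GENOME_KW = dict(n_bp=20_000, gc=0.5, n_genes=20)
N_SITES = 40
#: footprint classes scanned when recovering planted pauses; the RNase-bias
#: shift concentrates each site's reads in a site-specific length class, so
#: recovery takes the union of per-class calls at P(0.9, 50).
RECOVERY_LENGTHS = tuple(range(14, 21))


@dataclass
class StrainDataset:
    """One simulated strain: inputs, truth and parsed alignments."""

    strain: sim_mod.StrainProfile
    genome: sim_mod.SimGenome
    genes: list
    tss: pd.DataFrame
    pauses: list
    sim: sim_mod.SimulatedData
    reads: list

    @property
    def replicon_lengths(self):
        return {self.genome.replicon_id: len(self.genome)}

    @property
    def annotation(self):
        return io_mod.AnnotationSet.from_sim(self.genes, self.tss)

    @property
    def truth_sites(self):
        return {(p.position, p.strand) for p in self.pauses}


def load_sim_alignments(sim: sim_mod.SimulatedData):
    """Round-trip the simulator's SAM through the standard ingest path."""
    fd, path = tempfile.mkstemp(suffix=".sam")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(sim.sam_text)
        reads, _ = io_mod.read_alignments(path, genome=sim.genome)
    finally:
        os.unlink(path)
    return reads


def strain_dataset(
    strain_name: str,
    n_reads: int,
    seed: int,
    n_sites: int = N_SITES,
    misinc_fraction: float | None = None,
    up_region_dwell: float = 1.0,
    genome_seed: int | None = None,
) -> StrainDataset:
    """Simulate one strain at the default study conditions and ingest it.

    ``genome_seed`` defaults to ``seed``; pass the same value for two strains
    to put them on an identical genome (isogenic comparison).
    """
    strain = {"WT": sim_mod.WT_PROFILE, "dGreAB": sim_mod.DGREAB_PROFILE}[strain_name]
    gseed = seed if genome_seed is None else genome_seed
    genome0, genes, tss = sim_mod.generate_genome(seed=gseed, **GENOME_KW)
    motif_class = "WT_PIE" if strain_name == "WT" else "dGre_PIE"
    if n_sites > 0:
        genome, pauses = sim_mod.plant_pauses(
            genome0,
            genes,
            n_sites,
            motif_class,
            strain,
            seed=gseed + 1,
            misinc_fraction=misinc_fraction,
        )
    else:
        genome, pauses = genome0, []
    sim = sim_mod.simulate_reads(
        genome,
        genes,
        pauses,
        strain,
        n_reads,
        seed=seed + 2,
        up_region_dwell=up_region_dwell,
    )
    return StrainDataset(
        strain=strain,
        genome=genome,
        genes=genes,
        tss=tss,
        pauses=pauses,
        sim=sim,
        reads=load_sim_alignments(sim),
    )


def save_dataset(ds: StrainDataset, outdir) -> None:
    """Persist a simulated strain dataset as plain-text artifacts."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io_mod.write_fasta(ds.genome, out / "genome.fa")
    io_mod.write_gff3(ds.genes, ds.genome.replicon_id, out / "genes.gff3")
    io_mod.write_tss(ds.tss, out / "tss.tsv")
    ds.sim.write(
        fastq_path=out / "reads.fastq",
        sam_path=out / "reads.sam",
        truth_path=out / "truth.tsv",
    )
    with open(out / "pauses.json", "w") as fh:
        json.dump(
            {
                "strain": ds.strain.name,
                "pauses": [
                    {
                        "position": p.position,
                        "strand": p.strand,
                        "motif_class": p.motif_class,
                        "dwell_weight": p.dwell_weight,
                        "state_distribution": p.state_distribution,
                        "misincorporation_rate": p.misincorporation_rate,
                        "gene_id": p.gene_id,
                    }
                    for p in ds.pauses
                ],
            },
            fh,
            indent=1,
        )


def load_dataset(outdir) -> StrainDataset:
    """Reload a dataset written by :func:`save_dataset` via the standard
    readers (FASTA/GFF3/TSV/SAM), re-ingesting the alignments."""
    import json
    from pathlib import Path

    out = Path(outdir)
    fasta = io_mod.read_fasta(out / "genome.fa")
    rep, seq = next(iter(fasta.items()))
    genome = sim_mod.SimGenome(replicon_id=rep, sequence=seq)
    genes = io_mod.read_gff3(out / "genes.gff3")
    tss = io_mod.read_tss(out / "tss.tsv")
    with open(out / "pauses.json") as fh:
        meta = json.load(fh)
    strain = {"WT": sim_mod.WT_PROFILE, "dGreAB": sim_mod.DGREAB_PROFILE}[
        meta["strain"]
    ]
    pauses = [sim_mod.PlantedPause(**p) for p in meta["pauses"]]
    reads, _ = io_mod.read_alignments(out / "reads.sam", genome=genome)
    sim = sim_mod.SimulatedData(
        genome=genome,
        genes=genes,
        pauses=pauses,
        strain=strain,
        fastq_text="",
        sam_text="",
        truth=sim_mod.read_truth(out / "truth.tsv"),
    )
    return StrainDataset(
        strain=strain,
        genome=genome,
        genes=genes,
        tss=tss,
        pauses=pauses,
        sim=sim,
        reads=reads,
    )


# ---------------------------------------------------------------------------
# experiments


def read_total_ratio() -> float:
    """Sequencing-depth ratio of the two published libraries."""
    return DGREAB_TOTAL_MAPPED_READS / WT_TOTAL_MAPPED_READS


def footprint_length_for_state(state: str, seed: int = 0) -> int:
    """Protected length produced for one forced translocation state.

    Runs the generator with every stochastic channel off and a degenerate
    state distribution, and reads the single resulting length off the truth
    table.
    """
    dist = {s: (1.0 if s == state else 0.0) for s in sim_mod.STATES}
    profile = sim_mod.StrainProfile(
        name="forced",
        background_state_distribution=dist,
        pause_state_distribution=dist,
        rnase_t1_bias=0.0,
        sequencing_error_rate=0.0,
        untrimmed_prob=0.0,
        initiation_prob=0.0,
    )
    genome, genes, _ = sim_mod.generate_genome(5000, 0.5, 4, seed=seed)
    sim = sim_mod.simulate_reads(genome, genes, [], profile, 200, seed=seed + 1)
    lengths = sim.truth["length"].unique()
    if len(lengths) != 1:
        raise AssertionError(f"forced state {state} gave lengths {lengths}")
    return int(lengths[0])


def modal_read_length(ds: StrainDataset) -> int:
    return pause_mod.modal_length(pause_mod.read_length_histogram(ds.reads))


def pause_recovery(
    ds: StrainDataset,
    phi: float = 0.9,
    delta: int = 50,
    lengths=RECOVERY_LENGTHS,
):
    """Precision/recall of P(phi, delta) calls against the planted truth.

    Pauses are called independently in each footprint length class and the
    called sites are pooled (union over classes).
    """
    called: set = set()
    for L in lengths:
        tracks = pause_mod.build_pileup(ds.reads, ds.replicon_lengths, f"L{L}")
        for s in pause_mod.call_pauses_all(tracks, phi, delta):
            called.add((s.position, s.strand))
    truth = ds.truth_sites
    tp = len(called & truth)
    precision = tp / len(called) if called else 0.0
    recall = tp / len(truth) if truth else 0.0
    return precision, recall, len(called)


def bulk_pause_sites(ds: StrainDataset, phi: float = 0.7, delta: int = 100):
    """Bulk-class (>= 21 nt) pause sites at the relaxed P(0.7, 100) regime."""
    tracks = pause_mod.build_pileup(
        ds.reads, ds.replicon_lengths, pause_mod.BULK_CLASS
    )
    return pause_mod.call_pauses_all(tracks, phi, delta)


def bulk_pie(ds: StrainDataset, phi: float = 0.7, delta: int = 100):
    """PIE frequency matrix of the bulk-class pause set."""
    sites = bulk_pause_sites(ds, phi, delta)
    windows, _ = motif_mod.extract_windows(sites, ds.genome)
    if not windows:
        raise ValueError("no bulk pause sites were called")
    return motif_mod.frequency_matrix(windows), sites


def g_offset_by_class(
    ds: StrainDataset,
    lengths=(14, 15, 16, 17, 18),
    phi: float = 0.9,
    delta: int = 50,
    mapq_min: float = 10.0,
) -> dict:
    """Most G-rich upstream offset (-9/-10/-11) per single-length class."""
    matrices = {}
    for L in lengths:
        tracks = pause_mod.build_pileup(ds.reads, ds.replicon_lengths, f"L{L}")
        sites = pause_mod.call_pauses_all(tracks, phi, delta)
        sites, _ = pause_mod.filter_mapq(sites, mapq_min)
        if not sites:
            continue
        windows, _ = motif_mod.extract_windows(sites, ds.genome)
        if windows:
            matrices[L] = motif_mod.frequency_matrix(windows)
    return motif_mod.g_position_profile(matrices)


def misincorporation_recovery(ds: StrainDataset, length: int = 18):
    """Estimate the 3'-terminal G-to-A rate at the planted CpG pause sites.

    Restricts to exact-``length`` reads whose 3' end is one of the planted
    misincorporating positions (ground-truth inputs of the simulation) and
    runs the standard error-matrix accumulation on them.  Returns
    ``(rate, n_opportunities)``.
    """
    site_keys = {
        (p.position, p.strand) for p in ds.pauses if p.misincorporation_rate > 0
    }
    sub = [
        a
        for a in ds.reads
        if a.length == length and (a.pos3, a.strand) in site_keys
    ]
    m = accumulate_errors(sub, length)
    return m.rate_at("G", "A", -1), m.opportunities_at("G", -1)


def error_trend(ds: StrainDataset, lengths=range(14, 19)):
    """G-to-A rate at -1 versus footprint length, with the Spearman trend."""
    from .errors import error_rate_by_backtrack

    mats = matrices_by_length(ds.reads, lengths=lengths)
    return error_rate_by_backtrack(mats)


def penultimate_c_contrast(
    ds: StrainDataset, length: int = 18, phi: float = 0.9, delta: int = 50
):
    """C fraction at -2 in the error-containing vs error-free PIE groups.

    Called on the exact-``length`` class; sites whose reference 3' base is G
    are split by whether any read carries the 3'-terminal G-to-A.
    Returns ``(c_frac_error, c_frac_clean, n_error_sites, n_clean_sites)``.
    """
    sub = [a for a in ds.reads if a.length == length]
    tracks = pause_mod.build_pileup(sub, ds.replicon_lengths, f"L{length}")
    sites = pause_mod.call_pauses_all(tracks, phi, delta)
    sites, _ = pause_mod.filter_mapq(sites, 10.0)
    err_sites, clean_sites, em, cm = motif_mod.split_by_3prime_error(
        sites, sub, ds.genome
    )
    if em is None or cm is None:
        raise ValueError("one of the error/clean groups is empty")
    ci = "ACGT".index("C")
    return (
        float(em.row(-2)[ci] / em.n_sites),
        float(cm.row(-2)[ci] / cm.n_sites),
        len(err_sites),
        len(clean_sites),
    )


def up_region_comparison(
    seed: int,
    n_reads: int = 60_000,
    up_factor: float = 3.0,
) -> pd.DataFrame:
    """Welch comparison of the four 50-bp gene regions between two strains.

    Both strains share one genome (and hence per-gene expression levels);
    the second strain's elongation-complex occupancy is raised ``up_factor``-
    fold in the 50 bp upstream of each start codon, modelling Gre-dependent
    5'-UTR backtrack pausing.  No pause motifs are planted, so the Up window
    is the only systematic difference.
    """
    a = strain_dataset("WT", n_reads, seed=seed, n_sites=0, genome_seed=seed)
    b = strain_dataset(
        "dGreAB",
        n_reads,
        seed=seed + 1000,
        n_sites=0,
        genome_seed=seed,
        up_region_dwell=up_factor,
    )
    ta, _ = genes_mod.count_gene_reads(a.reads, a.annotation)
    tb, _ = genes_mod.count_gene_reads(b.reads, b.annotation)
    return genes_mod.compare_strains(ta, tb)
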