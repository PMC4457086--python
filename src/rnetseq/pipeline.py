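"""Orchestration: simulate -> ingest -> pause -> motif -> errors -> genes.

A single YAML-serialisable :class:`RunConfig` drives every stage; all
randomness flows from its ``seed``.  Each stage logs record counts, every
output TSV carries the config hash in a leading comment line, and the run
manifest maps artifact paths to SHA-256 checksums so deterministic reruns
are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import errors as err_mod
from . import genes as genes_mod
from . import io as io_mod
from . import motif as motif_mod
from . import pause as pause_mod
from . import simulate as sim_mod

log = logging.getLogger("rnetseq")

STRAINS = {"WT": sim_mod.WT_PROFILE, "dGreAB": sim_mod.DGREAB_PROFILE}


@dataclass
class RunConfig:
    seed: int
    outdir: str
    strain: str = "WT"
    # synthetic mode (used when alignments is None)
    n_bp: int = 20000
    gc: float = 0.5
    n_genes: int = 20
    n_sites: int = 40
    n_reads: int = 100_000
    motif_class: str = "WT_PIE"
    dwell_weight: float = 200.0
    misinc_fraction: float | None = None
    up_region_dwell: float = 1.0
    # real mode inputs
    alignments: str | None = None
    genome_fasta: str | None = None
    annotation_gff: str | None = None
    tss_tsv: str | None = None
    # analysis thresholds
    bulk_phi: float = 0.9
    bulk_delta: int = 100
    single_phi: float = 0.9
    single_delta: int = 50
    mapq_min: float = 10.0
    single_lengths: tuple = (14, 15, 16, 17, 18)
    total_mapped: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "single_lengths" in data:
            data["single_lengths"] = tuple(data["single_lengths"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["single_lengths"] = list(self.single_lengths)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def hash(self) -> str:
        data = asdict(self)
        data.pop("outdir")  # analysis parameters only, not where they land
        blob = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(config: RunConfig) -> list:
    """Return a list of human-readable violations (empty when valid)."""
    v = []
    if config.seed is None:
        v.append("seed is required")
    if config.strain not in STRAINS:
        v.append(f"unknown strain {config.strain!r}")
    for name in ("bulk_phi", "single_phi"):
        phi = getattr(config, name)
        if not 0.0 < phi <= 1.0:
            v.append(f"{name}={phi} outside (0, 1]")
    for name in ("bulk_delta", "single_delta"):
        if getattr(config, name) < 1:
            v.append(f"{name} must be >= 1")
    if config.motif_class not in ("WT_PIE", "dGre_PIE", "none"):
        v.append(f"unknown motif_class {config.motif_class!r}")
    if config.alignments is None and config.n_reads < 1:
        v.append("n_reads must be >= 1 in synthetic mode")
    if config.alignments is not None and config.genome_fasta is None:
        v.append("real mode needs genome_fasta alongside alignments")
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order; returns {path: sha256}."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    strain = STRAINS[config.strain]
    artifacts: list[Path] = []

    # --- stage 1: simulate or ingest -------------------------------------
    if config.alignments is None:
        log.info("simulate: %d reads on %d bp", config.n_reads, config.n_bp)
        genome0, genes, tss = sim_mod.generate_genome(
            config.n_bp, config.gc, config.n_genes, seed=config.seed
        )
        genome, pauses = sim_mod.plant_pauses(
            genome0,
            genes,
            config.n_sites,
            config.motif_class,
            strain,
            seed=config.seed + 1,
            dwell_weight=config.dwell_weight,
            misinc_fraction=config.misinc_fraction,
        )
        sim = sim_mod.simulate_reads(
            genome,
            genes,
            pauses,
            strain,
            config.n_reads,
            seed=config.seed + 2,
            up_region_dwell=config.up_region_dwell,
        )
        io_mod.write_fasta(genome, out / "genome.fa")
        io_mod.write_gff3(genes, genome.replicon_id, out / "genes.gff3")
        io_mod.write_tss(tss, out / "tss.tsv")
        sim.write(
            fastq_path=out / "reads.fastq",
            sam_path=out / "reads.sam",
            truth_path=out / "truth.tsv",
        )
        artifacts += [
            out / "genome.fa",
            out / "genes.gff3",
            out / "tss.tsv",
            out / "reads.fastq",
            out / "reads.sam",
            out / "truth.tsv",
        ]
        sam_path = out / "reads.sam"
        annotation = io_mod.AnnotationSet.from_sim(genes, tss)
    else:
        log.info("ingest: %s", config.alignments)
        fasta = io_mod.read_fasta(config.genome_fasta)
        rep, seq = next(iter(fasta.items()))
        genome = sim_mod.SimGenome(replicon_id=rep, sequence=seq)
        sam_path = Path(config.alignments)
        annotation = io_mod.AnnotationSet.from_files(
            config.annotation_gff, config.tss_tsv
        )

    reads, skip = io_mod.read_alignments(sam_path, genome=genome)
    log.info("ingest: kept %d alignments, skipped %s", len(reads), skip.as_dict())
    total_mapped = config.total_mapped or len(reads)
    rep_lengths = {genome.replicon_id: len(genome)}

    # --- stage 2: pause calling ------------------------------------------
    classes = [pause_mod.BULK_CLASS] + [f"L{L}" for L in config.single_lengths]
    pause_sets: dict[str, list] = {}
    for cls in classes:
        tracks = pause_mod.build_pileup(reads, rep_lengths, length_class=cls)
        if cls == pause_mod.BULK_CLASS:
            phi, delta = config.bulk_phi, config.bulk_delta
        else:
            phi, delta = config.single_phi, config.single_delta
        sites = pause_mod.call_pauses_all(tracks, phi, delta)
        pause_sets[cls] = sites
        log.info("pause[%s]: %d sites at P(%.2f, %d)", cls, len(sites), phi, delta)
    io_mod.write_pause_bed(pause_sets[pause_mod.BULK_CLASS], out / "pauses_bulk.bed")
    all_rows = [s for cls in classes for s in pause_sets[cls]]
    io_mod.write_pause_tsv(all_rows, out / "pauses.tsv")
    artifacts += [out / "pauses_bulk.bed", out / "pauses.tsv"]

    # --- stage 3: motifs ---------------------------------------------------
    bg = None
    from .seqs import base_composition

    bg = base_composition(genome.sequence)
    motif_frames = []
    for cls in classes:
        sites = pause_sets[cls]
        if cls != pause_mod.BULK_CLASS:
            sites = pause_mod.filter_mapq(sites, config.mapq_min)[0]
        if not sites:
            continue
        windows, skipped = motif_mod.extract_windows(sites, genome)
        if not windows:
            continue
        m = motif_mod.frequency_matrix(windows, background=bg)
        ic, total_ic = motif_mod.information_content(m)
        df = m.to_frame()
        df.insert(0, "length_class", cls)
        df["information_bits"] = ic
        motif_frames.append(df)
        log.info(
            "motif[%s]: %d sites, %.1f total bits, LLR %.1f",
            cls, m.n_sites, total_ic, motif_mod.motif_score(m),
        )
    if motif_frames:
        _write_tsv(pd.concat(motif_frames), out / "pie_matrices.tsv", cfg_hash)
        artifacts.append(out / "pie_matrices.tsv")

    # --- stage 4: error profiles ------------------------------------------
    mats = err_mod.matrices_by_length(reads, lengths=config.single_lengths)
    err_frames = [m.to_frame() for m in mats.values()]
    _write_tsv(pd.concat(err_frames), out / "error_matrices.tsv", cfg_hash)
    trend, rho, pval = err_mod.error_rate_by_backtrack(mats)
    _write_tsv(trend, out / "ga_rate_by_length.tsv", cfg_hash)
    artifacts += [out / "error_matrices.tsv", out / "ga_rate_by_length.tsv"]
    log.info("errors: G-to-A at -1 by length, spearman rho=%.2f p=%.3g", rho, pval)

    # --- stage 5: gene metrics --------------------------------------------
    table, audit = genes_mod.count_gene_reads(reads, annotation, total_mapped)
    _write_tsv(table, out / "gene_counts.tsv", cfg_hash)
    artifacts.append(out / "gene_counts.tsv")
    log.info("genes: %s", audit)
    cats = genes_mod.categorize_pauses(pause_sets[pause_mod.BULK_CLASS], annotation)
    cat_df = pd.DataFrame(
        {"category": list(cats), "fraction": list(cats.values())}
    )
    _write_tsv(cat_df, out / "pause_categories.tsv", cfg_hash)
    artifacts.append(out / "pause_categories.tsv")
    hist = pause_mod.read_length_histogram(reads)
    hist_df = pd.DataFrame({"length": list(hist), "count": list(hist.values())})
    _write_tsv(hist_df, out / "read_length_histogram.tsv", cfg_hash)
    artifacts.append(out / "read_length_histogram.tsv")

    manifest = {str(p): _sha256(p) for p in artifacts}
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config_hash": cfg_hash, "artifacts": manifest}, fh, indent=2)
    return manifest
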