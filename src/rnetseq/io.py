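"""Readers/writers for the standard formats and a naive desk-scale mapper.

Alignments are re-expressed in *transcript orientation*: the per-base pairs
of an :class:`AlignedRead` run 5'->3' along the nascent RNA, so offset -1 is
always the 3'-end base and, for minus-strand reads, both reference and read
bases are complemented relative to the genomic top strand.  This is the
orientation in which "G-to-A error" has its usual meaning.

Coordinates are 0-based half-open internally; 1-based only in human-readable
TSV reports and SAM itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqs import revcomp, seq_to_u8
from .simulate import SimGene, SimGenome


@dataclass
class AlignedRead:
    """One mapped, substitution-only nascent-transcript fragment."""

    read_id: str
    replicon: str
    strand: str
    ref_start: int  # 0-based inclusive
    ref_end: int  # 0-based exclusive
    mapq: int
    ref_bases: str  # reference bases, transcript orientation (5'->3')
    read_bases: str  # read bases, transcript orientation (5'->3')
    n_hits: int = 1

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def pos3(self) -> int:
        """Genomic coordinate of the 3'-end base."""
        return self.ref_end - 1 if self.strand == "+" else self.ref_start

    @property
    def pairs(self):
        """Ordered (offset_from_3'_end, ref_base, read_base) triples.

        Offsets run -length..-1; offset -1 is the 3'-end base.
        """
        L = self.length
        return [
            (i - L, self.ref_bases[i], self.read_bases[i]) for i in range(L)
        ]

    def mismatches(self):
        """(offset, ref_base, read_base) for substituted positions only."""
        L = self.length
        return [
            (i - L, r, q)
            for i, (r, q) in enumerate(zip(self.ref_bases, self.read_bases))
            if r != q
        ]


@dataclass
class SkipReport:
    """Bookkeeping of records excluded from the default alignment stream."""

    unmapped: int = 0
    indel_or_clipped: int = 0
    malformed: int = 0
    total_kept: int = 0

    def as_dict(self):
        return dict(self.__dict__)


_MATCH_OPS = {0, 7, 8}  # M, =, X


def read_alignments(sam_path, genome: SimGenome | dict | None = None):
    """Parse SAM/BAM into transcript-orientation :class:`AlignedRead` objects.

    Reference bases come from the MD tag; when MD is absent the supplied
    ``genome`` (a :class:`SimGenome` or ``{replicon: sequence}`` dict) is
    used instead, and with neither available a ``ValueError`` is raised.
    Records containing insertions, deletions or clips are excluded from the
    stream and tallied in the returned :class:`SkipReport` (the analysis
    considers the 12 substitution types only).

    Returns ``(reads, report)``.
    """
    ref_lookup = None
    if isinstance(genome, SimGenome):
        ref_lookup = {genome.replicon_id: genome.sequence}
    elif isinstance(genome, dict):
        ref_lookup = genome

    reads: list[AlignedRead] = []
    report = SkipReport()
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                report.unmapped += 1
                continue
            cig = rec.cigartuples
            if cig is None or any(op not in _MATCH_OPS for op, _ in cig):
                report.indel_or_clipped += 1
                continue
            seq = rec.query_sequence
            if seq is None:
                report.malformed += 1
                continue
            if rec.has_tag("MD"):
                try:
                    ref = rec.get_reference_sequence().upper()
                except Exception as exc:  # malformed MD
                    raise ValueError(
                        f"read {rec.query_name}: cannot reconstruct reference "
                        f"({exc})"
                    ) from exc
            elif ref_lookup is not None:
                ref = ref_lookup[rec.reference_name][
                    rec.reference_start : rec.reference_end
                ]
            else:
                raise ValueError(
                    f"read {rec.query_name}: no MD tag and no genome supplied"
                )
            if len(ref) != len(seq):
                report.malformed += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            if strand == "-":
                ref_tx, read_tx = revcomp(ref), revcomp(seq)
            else:
                ref_tx, read_tx = ref, seq
            n_hits = rec.get_tag("NH") if rec.has_tag("NH") else 1
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    replicon=rec.reference_name,
                    strand=strand,
                    ref_start=rec.reference_start,
                    ref_end=rec.reference_end,
                    mapq=rec.mapping_quality,
                    ref_bases=ref_tx,
                    read_bases=read_tx,
                    n_hits=int(n_hits),
                )
            )
            report.total_kept += 1
    return reads, report


# ---------------------------------------------------------------------------
# naive mapper (synthetic genomes only)


def _mapq_from_hits(n_best: int) -> int:
    # documented convention: unique best 42, 2-4 best hits 3, >4 hits 0
    if n_best == 1:
        return 42
    if n_best <= 4:
        return 3
    return 0


def naive_map(
    reads,
    genome: SimGenome,
    max_mismatch: int = 2,
    seed_k: int = 12,
):
    """Seed-and-extend mapper for desk-scale genomes.

    ``reads`` is an iterable of ``(read_id, sequence)`` with sequences in
    transcript orientation (as in FASTQ).  All hits at the minimal mismatch
    count <= ``max_mismatch`` are reported on both strands, ordered by
    (replicon, position, strand).  The effective seed length is shrunk to
    ``len(read) // (max_mismatch + 1)`` when needed so that the pigeonhole
    guarantee holds: any alignment with <= ``max_mismatch`` substitutions
    contains at least one exact seed.

    Returns ``(hits, unmapped)`` where ``hits`` is a list of
    :class:`AlignedRead` (read bases vs genomic reference, n_hits set) and
    ``unmapped`` maps read_id -> reason.
    """
    gseq = genome.sequence
    g8 = seq_to_u8(gseq)
    n = len(gseq)

    hits_out: list[AlignedRead] = []
    unmapped: dict[str, str] = {}

    index_cache: dict[int, dict] = {}

    def kmer_index(k: int) -> dict:
        if k not in index_cache:
            idx: dict[str, list[int]] = {}
            for i in range(n - k + 1):
                idx.setdefault(gseq[i : i + k], []).append(i)
            index_cache[k] = idx
        return index_cache[k]

    for read_id, seq in reads:
        L = len(seq)
        k = min(seed_k, L // (max_mismatch + 1))
        if k < 4:
            k = min(4, L)
        if L < k or L < 4:
            unmapped[read_id] = f"read shorter than seed ({L} nt)"
            continue
        idx = kmer_index(k)
        read8 = seq_to_u8(seq)
        rc8 = seq_to_u8(revcomp(seq))
        best: dict[tuple, int] = {}
        for strand, q8, qstr in (("+", read8, seq), ("-", rc8, revcomp(seq))):
            starts = set()
            for off in range(0, L - k + 1, k):
                for p in idx.get(qstr[off : off + k], ()):
                    s = p - off
                    if 0 <= s <= n - L:
                        starts.add(s)
            for s in starts:
                mm = int((g8[s : s + L] != q8).sum())
                if mm <= max_mismatch:
                    best[(s, strand)] = mm
        if not best:
            unmapped[read_id] = "no alignment within mismatch budget"
            continue
        min_mm = min(best.values())
        locs = sorted(key for key, mm in best.items() if mm == min_mm)
        mapq = _mapq_from_hits(len(locs))
        for s, strand in locs:
            ref = gseq[s : s + L]
            if strand == "-":
                ref_tx, read_tx = revcomp(ref), seq
            else:
                ref_tx, read_tx = ref, seq
            hits_out.append(
                AlignedRead(
                    read_id=read_id,
                    replicon=genome.replicon_id,
                    strand=strand,
                    ref_start=s,
                    ref_end=s + L,
                    mapq=mapq,
                    ref_bases=ref_tx,
                    read_bases=read_tx,
                    n_hits=len(locs),
                )
            )
    hits_out.sort(key=lambda a: (a.replicon, a.ref_start, a.strand, a.read_id))
    return hits_out, unmapped


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationSet:
    genes: list
    tss: pd.DataFrame  # columns: replicon, position (0-based), strand

    @classmethod
    def from_sim(cls, genes, tss):
        return cls(genes=list(genes), tss=tss.copy())

    @classmethod
    def from_files(cls, gff_path, tss_path):
        return cls(genes=read_gff3(gff_path), tss=read_tss(tss_path))


def write_fasta(genome: SimGenome, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.replicon_id, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path) -> dict:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_gff3(genes, replicon_id: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = (
                f"ID={g.gene_id};biotype={g.biotype};operon_id={g.operon_id};"
                f"copy_number={g.copy_number};tss={g.tss + 1};"
                f"cds_start={g.cds_start + 1};cds_end={g.cds_end + 1};"
                f"expression={g.expression:.6g}"
            )
            fh.write(
                f"{replicon_id}\trnetseq-sim\tgene\t{g.tx_lo + 1}\t{g.tx_hi}\t."
                f"\t{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> list:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type("gene", order_by="start"):
        a = feat.attributes
        genes.append(
            SimGene(
                gene_id=a["ID"][0],
                biotype=a["biotype"][0],
                strand=feat.strand,
                tss=int(a["tss"][0]) - 1,
                cds_start=int(a["cds_start"][0]) - 1,
                cds_end=int(a["cds_end"][0]) - 1,
                tx_lo=feat.start - 1,
                tx_hi=feat.end,
                operon_id=a["operon_id"][0],
                copy_number=int(a["copy_number"][0]),
                expression=float(a["expression"][0]),
            )
        )
    return genes


def write_tss(tss: pd.DataFrame, path) -> None:
    out = tss.copy()
    out["position"] = out["position"] + 1  # 1-based in external TSV
    out.to_csv(path, sep="\t", index=False)


def read_tss(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["position"] = df["position"] - 1
    return df


# ---------------------------------------------------------------------------
# pause-site export


def write_pause_bed(pauses, path) -> None:
    """BED6 export; score = round(1000 * phi), single-base intervals."""
    with open(path, "w") as fh:
        for p in pauses:
            fh.write(
                f"{p.replicon}\t{p.position}\t{p.position + 1}\t"
                f"pause\t{round(1000 * p.phi)}\t{p.strand}\n"
            )


def write_pause_tsv(pauses, path) -> None:
    df = pd.DataFrame(
        {
            "replicon": [p.replicon for p in pauses],
            "position_1based": [p.position + 1 for p in pauses],
            "strand": [p.strand for p in pauses],
            "phi": [p.phi for p in pauses],
            "delta": [p.delta for p in pauses],
            "mapq_mean": [p.mapq_mean for p in pauses],
            "length_class": [p.length_class for p in pauses],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
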