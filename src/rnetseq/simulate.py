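"""Synthetic elongation-complex read generator with full ground truth.

The generator emulates the statistical structure of RNase-footprinted
nascent-transcript sequencing of a bacterium: elongation complexes dwell at
planted pause motifs, the RNase-protected fragment length encodes the
translocation state of the polymerase (14 nt post-translocated, 15 nt
pre-translocated, 14+1+b nt when backtracked by b bp), RNase T1 biases the
5' trim point toward GpN cuts, backtracked complexes ending on a genomic G
can carry a 3'-terminal G-to-A misincorporation, and a uniform sequencing
substitution channel runs on top.  Every read is logged in a truth table so
downstream stages can be scored against known answers.

Three read categories are produced:

* ``footprint`` — fully 5'-trimmed reads whose length encodes the
  translocation state (plus an optional RNase-bias shift of at most +2 nt);
* ``untrimmed`` — incompletely trimmed reads of 21-30 nt; these form the
  "bulk" class used for genome-wide pause calling and carry no RNase cut
  signature;
* ``initiation`` — sub-footprint reads of 6-13 nt whose 3' ends sit just
  downstream of a transcription start site, mimicking abortive/initiation
  complexes.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .seqs import BASES, COMP_U8, random_dna, revcomp, seq_to_u8

STATES = ("post", "pre", "backtrack1", "backtrack2", "backtrack3")
#: extra protected nucleotides beyond the 14-nt post-translocated footprint
STATE_EXTRA = {"post": 0, "pre": 1, "backtrack1": 2, "backtrack2": 3, "backtrack3": 4}

MIN_READ_LEN = 6
MAX_READ_LEN = 30

#: pause motifs on the non-template strand, keyed by offset from the 3'-end
#: base (offset -1 is the 3'-end base itself; there is no offset 0).
WT_PIE_MOTIF = {-10: "G", -3: "T", -2: "G", -1: "C", +1: "G"}
DGRE_PIE_MOTIF = {-11: "G", -7: "T", -4: "T", -1: "G"}
#: extra context planted at misincorporating sites: a CpG so the 3'-terminal
#: base is a G preceded by C (the penultimate-C signature of error reads)
CPG_CONTEXT = {-2: "C", -1: "G"}


@dataclass(frozen=True)
class SimGenome:
    replicon_id: str
    sequence: str
    circular: bool = True
    gc_content: float = 0.5

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        if set(self.sequence) - set(BASES):
            raise ValueError("genome sequence may contain only A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimGene:
    """One annotated gene.

    ``cds_start``/``cds_end`` are the genomic coordinates (0-based) of the
    first base of the start codon and the last base of the stop codon in
    transcription direction; for minus-strand genes cds_start > cds_end.
    ``tx_lo``/``tx_hi`` bound the transcribed span (half-open, top-strand
    coordinates) including 5' and 3' UTRs.
    """

    gene_id: str
    biotype: str  # mRNA | rRNA | tRNA | ncRNA
    strand: str  # '+' | '-'
    tss: int
    cds_start: int
    cds_end: int
    tx_lo: int
    tx_hi: int
    operon_id: str = ""
    copy_number: int = 1
    expression: float = 1.0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.strand == "+" and self.tss > self.cds_start:
            raise ValueError(f"{self.gene_id}: TSS downstream of start codon")
        if self.strand == "-" and self.tss < self.cds_start:
            raise ValueError(f"{self.gene_id}: TSS downstream of start codon")

    @property
    def utr5_length(self) -> int:
        return abs(self.cds_start - self.tss)


@dataclass(frozen=True)
class StrainProfile:
    """Strain-level generator settings.

    ``background_state_distribution`` applies to non-planted positions,
    ``pause_state_distribution`` seeds newly planted sites.  Probabilities
    are over the five translocation states in :data:`STATES` order.
    """

    name: str
    background_state_distribution: dict
    pause_state_distribution: dict
    default_misincorporation_rate: float = 0.0
    rnase_t1_bias: float = 0.5
    sequencing_error_rate: float = 1e-4
    untrimmed_prob: float = 0.25
    initiation_prob: float = 0.10

    def __post_init__(self):
        for dist in (self.background_state_distribution, self.pause_state_distribution):
            if set(dist) != set(STATES):
                raise ValueError("state distribution must cover all five states")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("state distribution must sum to 1")

    def state_probs(self, which: str) -> np.ndarray:
        dist = (
            self.background_state_distribution
            if which == "background"
            else self.pause_state_distribution
        )
        return np.array([dist[s] for s in STATES], dtype=float)


# Calibrated so the simulated modal read length reproduces the observed
# strain contrast (mode 16 nt with Gre factors present, 18 nt without),
# after mixing planted and background positions and applying the RNase-bias
# shift.  The occupancy split is a modelling choice: the wild type is kept
# mostly pre-translocated/1-bp backtracked (rapid Gre rescue), the deletion
# strain deeply backtracked.
WT_PROFILE = StrainProfile(
    name="WT",
    background_state_distribution=dict(
        zip(STATES, (0.10, 0.25, 0.40, 0.18, 0.07))
    ),
    pause_state_distribution=dict(zip(STATES, (0.10, 0.35, 0.40, 0.10, 0.05))),
    default_misincorporation_rate=0.0,
)

DGREAB_PROFILE = StrainProfile(
    name="dGreAB",
    background_state_distribution=dict(
        zip(STATES, (0.05, 0.10, 0.15, 0.25, 0.45))
    ),
    pause_state_distribution=dict(zip(STATES, (0.05, 0.15, 0.20, 0.25, 0.35))),
    default_misincorporation_rate=8e-3,
)


@dataclass
class PlantedPause:
    position: int  # genomic coordinate (0-based) of the intended 3'-end base
    strand: str
    motif_class: str  # WT_PIE | dGre_PIE | none
    dwell_weight: float
    state_distribution: dict
    misincorporation_rate: float = 0.0
    gene_id: str = ""

    def __post_init__(self):
        if abs(sum(self.state_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("state_distribution must sum to 1")
        if not 0.0 <= self.misincorporation_rate <= 1.0:
            raise ValueError("misincorporation_rate must be a fraction")


TRUTH_COLUMNS = [
    "read_id",
    "replicon",
    "strand",
    "pos3",
    "start",
    "length",
    "category",
    "state",
    "protected_length",
    "rnase_shift",
    "misincorporated",
    "misinc_offset",
    "seq_error_offsets",
]


@dataclass
class SimulatedData:
    """Everything one simulation run produced, plus its inputs."""

    genome: SimGenome
    genes: list
    pauses: list
    strain: StrainProfile
    fastq_text: str
    sam_text: str
    truth: pd.DataFrame

    def write(self, fastq_path=None, sam_path=None, truth_path=None):
        if fastq_path:
            with open(fastq_path, "w") as fh:
                fh.write(self.fastq_text)
        if sam_path:
            with open(sam_path, "w") as fh:
                fh.write(self.sam_text)
        if truth_path:
            write_truth(self.truth, truth_path)


# ---------------------------------------------------------------------------
# genome generation


def generate_genome(
    n_bp: int,
    gc: float = 0.5,
    n_genes: int = 20,
    seed: int = 0,
    rrna_copies: int = 0,
    utr3_length: int = 20,
    expression_sigma: float = 0.6,
    replicon_id: str = "simchr",
):
    """Random genome with non-overlapping genes on both strands.

    Genes alternate strands, so adjacent +/- pairs transcribe convergently;
    the first pair is placed with a 60-bp overlap of their 3' regions to
    guarantee an antisense-overlap case.  With ``rrna_copies`` > 0 one rRNA
    unit is emitted as that many byte-identical copies (multi-mapping test
    bed).  Per-gene expression multipliers are drawn log-normally here, from
    the genome seed, so two strains simulated on the same genome share them.

    Returns ``(SimGenome, genes, tss_table)`` where ``tss_table`` is a
    DataFrame with columns replicon/position/strand (0-based positions).
    """
    if n_bp < 2000:
        raise ValueError("n_bp must be >= 2000")
    rng = np.random.default_rng(seed)
    seq = bytearray(random_dna(rng, n_bp, gc).encode("ascii"))

    margin = 60
    genes: list[SimGene] = []
    cursor = margin
    for i in range(n_genes):
        utr5 = int(rng.integers(20, 61))
        cds_len = 3 * int(rng.integers(50, 151))
        span = utr5 + cds_len + utr3_length
        if i == 0:
            gap = 0
        elif i == 1:
            gap = -60  # convergent pair overlaps by 60 bp at the 3' ends
        else:
            gap = int(rng.integers(30, 100))
        lo = cursor + gap
        hi = lo + span
        if hi > n_bp - margin:
            raise ValueError(
                f"n_genes={n_genes} incompatible with n_bp={n_bp}: ran out of room"
            )
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            gene = SimGene(
                gene_id=f"g{i + 1:03d}",
                biotype="mRNA",
                strand="+",
                tss=lo,
                cds_start=lo + utr5,
                cds_end=lo + utr5 + cds_len - 1,
                tx_lo=lo,
                tx_hi=hi,
                operon_id=f"op{i + 1:03d}",
            )
        else:
            gene = SimGene(
                gene_id=f"g{i + 1:03d}",
                biotype="mRNA",
                strand="-",
                tss=hi - 1,
                cds_start=hi - 1 - utr5,
                cds_end=hi - utr5 - cds_len,
                tx_lo=lo,
                tx_hi=hi,
                operon_id=f"op{i + 1:03d}",
            )
        genes.append(gene)
        cursor = hi
    # a couple of structural-RNA genes for categorisation analyses
    if n_genes >= 8:
        genes[-1].biotype = "tRNA"
        genes[-2].biotype = "ncRNA"

    if rrna_copies > 0:
        unit_len = 120
        unit = random_dna(rng, unit_len, gc)
        expr = float(rng.lognormal(0.0, expression_sigma))
        for c in range(rrna_copies):
            lo = cursor + 40
            hi = lo + unit_len
            if hi > n_bp - margin:
                raise ValueError("not enough room for requested rRNA copies")
            seq[lo:hi] = unit.encode("ascii")
            genes.append(
                SimGene(
                    gene_id=f"rrn{c + 1}",
                    biotype="rRNA",
                    strand="+",
                    tss=lo,
                    cds_start=lo,
                    cds_end=hi - 1,
                    tx_lo=lo,
                    tx_hi=hi,
                    operon_id="rrnOp",
                    copy_number=rrna_copies,
                    expression=expr,
                )
            )
            cursor = hi

    n_mrna_like = sum(1 for g in genes if g.biotype != "rRNA")
    expr_draws = rng.lognormal(0.0, expression_sigma, size=n_mrna_like)
    k = 0
    for g in genes:
        if g.biotype != "rRNA":
            g.expression = float(expr_draws[k])
            k += 1

    genome = SimGenome(
        replicon_id=replicon_id,
        sequence=seq.decode("ascii"),
        circular=True,
        gc_content=gc,
    )
    tss = pd.DataFrame(
        {
            "replicon": replicon_id,
            "position": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
        }
    )
    return genome, genes, tss


# ---------------------------------------------------------------------------
# pause planting


def _offset_to_genomic(pos: int, strand: str, offset: int) -> int:
    """Genomic coordinate of a motif offset around a pause 3'-end base.

    Offset -1 is the 3'-end base itself and +1 the next downstream base;
    there is no offset 0.
    """
    if offset == 0:
        raise ValueError("offset 0 does not exist in the -1/+1 scheme")
    step = offset + 1 if offset < 0 else offset
    return pos + step if strand == "+" else pos - step


def plant_pauses(
    genome: SimGenome,
    genes: list,
    n_sites: int,
    motif_class: str,
    strain: StrainProfile,
    seed: int = 0,
    dwell_weight: float = 200.0,
    min_gap: int = 25,
    edge_margin: int = 30,
    misinc_fraction: float | None = None,
):
    """Edit the genome so ``n_sites`` positions carry a pause motif.

    The motif is written on the non-template strand at fixed offsets from the
    intended 3'-end base.  A fraction ``misinc_fraction`` of sites (default:
    all if the strain misincorporates at all, none otherwise) additionally
    get a CpG context (C at -2, G at -1) and the strain's misincorporation
    rate; the rest keep rate 0.  Sites sit >= ``edge_margin`` bp from gene
    ends and >= ``min_gap`` bp apart.
    """
    if motif_class not in ("WT_PIE", "dGre_PIE", "none"):
        raise ValueError(f"unknown motif_class {motif_class!r}")
    if misinc_fraction is None:
        misinc_fraction = 1.0 if strain.default_misincorporation_rate > 0 else 0.0
    if n_sites == 0:
        return genome, []

    rng = np.random.default_rng(seed)
    candidates = []
    for gi, g in enumerate(genes):
        if g.biotype != "mRNA":
            continue
        lo = g.tx_lo + edge_margin
        hi = g.tx_hi - edge_margin
        for p in range(lo, hi):
            candidates.append((p, gi))
    if not candidates:
        raise ValueError("no eligible positions to plant pauses")
    order = rng.permutation(len(candidates))

    chosen: list[tuple[int, int]] = []
    taken: list[int] = []
    for oi in order:
        p, gi = candidates[oi]
        if any(abs(p - q) < min_gap for q in taken):
            continue
        chosen.append((p, gi))
        taken.append(p)
        if len(chosen) == n_sites:
            break
    if len(chosen) < n_sites:
        raise ValueError(
            f"could not place {n_sites} pause sites {min_gap} bp apart; "
            f"only {len(chosen)} eligible"
        )

    n_misinc = int(round(misinc_fraction * n_sites))
    seq = bytearray(genome.sequence.encode("ascii"))
    pauses = []
    for i, (p, gi) in enumerate(chosen):
        g = genes[gi]
        is_misinc = i < n_misinc and strain.default_misincorporation_rate > 0
        motif: dict[int, str] = {}
        if motif_class == "WT_PIE":
            motif.update(WT_PIE_MOTIF)
        elif motif_class == "dGre_PIE":
            motif.update(DGRE_PIE_MOTIF)
            if is_misinc:
                motif.update(CPG_CONTEXT)
            else:
                # matched control: exclude the CpG context so a penultimate-C
                # signal is attributable to the misincorporation channel
                motif[-2] = str(rng.choice(["A", "G", "T"]))
        for off, base in motif.items():
            gpos = _offset_to_genomic(p, g.strand, off)
            b = base if g.strand == "+" else chr(COMP_U8[ord(base)])
            seq[gpos] = ord(b)
        pauses.append(
            PlantedPause(
                position=p,
                strand=g.strand,
                motif_class=motif_class,
                dwell_weight=dwell_weight,
                state_distribution=dict(strain.pause_state_distribution),
                misincorporation_rate=(
                    strain.default_misincorporation_rate if is_misinc else 0.0
                ),
                gene_id=g.gene_id,
            )
        )
    pauses.sort(key=lambda s: s.position)
    edited = replace(genome, sequence=seq.decode("ascii"))
    return edited, pauses


# ---------------------------------------------------------------------------
# read simulation


def _cum(probs: np.ndarray) -> np.ndarray:
    c = np.cumsum(probs)
    c[-1] = 1.0
    return c


def simulate_reads(
    genome: SimGenome,
    genes: list,
    pauses: list,
    strain: StrainProfile,
    n_reads: int,
    seed: int = 0,
    up_region_dwell: float = 1.0,
    read_id_prefix: str = "r",
) -> SimulatedData:
    """Draw ``n_reads`` reads and emit FASTQ + lossless SAM + truth table.

    3'-end positions are sampled over all transcribed positions with weight
    ``expression`` (background) or ``expression * dwell_weight`` (planted
    site); ``up_region_dwell`` multiplies the weight of the 50 bp upstream of
    each start codon, modelling strain-specific 5'-UTR pausing.  The SAM
    records carry the true position, an all-match CIGAR and MD/NM tags
    reflecting every planted mismatch, so alignment is lossless.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    top = seq_to_u8(genome.sequence)
    n = len(top)
    seq_str = genome.sequence

    # --- candidate 3'-end positions for elongation reads
    pos_parts, strand_parts, weight_parts, gene_parts = [], [], [], []
    for gi, g in enumerate(genes):
        span = np.arange(g.tx_lo, g.tx_hi)
        w = np.full(span.size, g.expression / g.copy_number, dtype=float)
        if up_region_dwell != 1.0 and g.biotype == "mRNA":
            if g.strand == "+":
                up = (span >= g.cds_start - 50) & (span < g.cds_start)
            else:
                up = (span > g.cds_start) & (span <= g.cds_start + 50)
            w[up] *= up_region_dwell
        pos_parts.append(span)
        strand_parts.append(
            np.full(span.size, 0 if g.strand == "+" else 1, dtype=np.int8)
        )
        weight_parts.append(w)
        gene_parts.append(np.full(span.size, gi, dtype=np.int32))
    cand_pos = np.concatenate(pos_parts)
    cand_strand = np.concatenate(strand_parts)
    cand_weight = np.concatenate(weight_parts)
    cand_gene = np.concatenate(gene_parts)

    cand_site = np.full(cand_pos.size, -1, dtype=np.int32)
    index = {}
    for ci in range(cand_pos.size):
        index[(int(cand_pos[ci]), int(cand_strand[ci]))] = ci
    site_rate = np.zeros(max(len(pauses), 1))
    site_cum = np.tile(_cum(strain.state_probs("pause")), (max(len(pauses), 1), 1))
    for si, s in enumerate(pauses):
        ci = index.get((s.position, 0 if s.strand == "+" else 1))
        if ci is None:
            raise ValueError(f"planted pause at {s.position} not inside a gene body")
        cand_weight[ci] *= s.dwell_weight
        cand_site[ci] = si
        site_rate[si] = s.misincorporation_rate
        site_cum[si] = _cum(
            np.array([s.state_distribution[st] for st in STATES], dtype=float)
        )

    n_init = int(rng.binomial(n_reads, strain.initiation_prob))
    n_elong = n_reads - n_init

    idx = rng.choice(cand_pos.size, size=n_elong, p=cand_weight / cand_weight.sum())
    pos3 = cand_pos[idx]
    minus = cand_strand[idx] == 1
    site = cand_site[idx]

    # translocation states
    u = rng.random(n_elong)
    bg_cum = _cum(strain.state_probs("background"))
    state = np.searchsorted(bg_cum, u, side="right").astype(np.int8)
    at_site = site >= 0
    if at_site.any():
        sc = site_cum[site[at_site]]
        state[at_site] = (u[at_site, None] > sc).sum(axis=1).astype(np.int8)
    state = np.clip(state, 0, 4)
    footprint = (14 + state).astype(np.int32)

    # incomplete 5' trimming -> bulk-class reads (21-30 nt)
    untrimmed = rng.random(n_elong) < strain.untrimmed_prob
    ulen = rng.integers(21, MAX_READ_LEN + 1, size=n_elong)
    length = np.where(untrimmed, np.maximum(footprint, ulen), footprint).astype(
        np.int32
    )

    # 3'-terminal G-to-A misincorporation on backtracked complexes
    base3 = top[pos3].copy()
    base3[minus] = COMP_U8[top[pos3[minus]]]
    rate = np.where(site >= 0, site_rate[np.clip(site, 0, None)], 0.0)
    misinc = (state >= 2) & (base3 == ord("G")) & (rng.random(n_elong) < rate)

    # RNase T1 bias: shift the 5' trim point <=2 nt upstream onto a GpN cut
    biased = (rng.random(n_elong) < strain.rnase_t1_bias) & ~untrimmed
    shift = np.zeros(n_elong, dtype=np.int32)
    start = np.where(minus, pos3, pos3 - length + 1)
    # neighbour base 5' of the read start, in transcript orientation
    plus_m = ~minus
    ok = np.zeros((3, n_elong), dtype=bool)
    for e in range(3):
        nb = np.empty(n_elong, dtype=np.uint8)
        nb[plus_m] = top[np.clip(start[plus_m] - 1 - e, 0, n - 1)]
        end_m = pos3[minus] + length[minus]
        nb[minus] = COMP_U8[top[np.clip(end_m + e, 0, n - 1)]]
        ok[e] = nb == ord("G")
    chosen_e = np.full(n_elong, -1, dtype=np.int32)
    for e in (2, 1, 0):
        chosen_e[ok[e]] = e
    apply = biased & (chosen_e > 0)
    shift[apply] = chosen_e[apply]
    length = length + shift

    # uniform sequencing-substitution channel
    n_err = rng.binomial(length, strain.sequencing_error_rate)

    if np.any((length < MIN_READ_LEN) | (length > MAX_READ_LEN + 2)):
        raise ValueError("simulated read length outside supported bounds")

    # --- initiation (sub-footprint) reads near TSSs
    if n_init > 0:
        gexp = np.array([g.expression for g in genes])
        gsel = rng.choice(len(genes), size=n_init, p=gexp / gexp.sum())
        ilen = rng.integers(MIN_READ_LEN, 14, size=n_init).astype(np.int32)
        jit = rng.integers(0, 6, size=n_init)
        itss = np.array([genes[gi].tss for gi in gsel])
        iminus = np.array([genes[gi].strand == "-" for gi in gsel])
        ipos3 = np.where(iminus, itss - (ilen - 1) - jit, itss + ilen - 1 + jit)
        ierr = rng.binomial(ilen, strain.sequencing_error_rate)

    # --- assemble per-read records
    fastq = _io.StringIO()
    sam = _io.StringIO()
    sam.write("@HD\tVN:1.6\tSO:unsorted\n")
    sam.write(f"@SQ\tSN:{genome.replicon_id}\tLN:{n}\n")
    sam.write("@PG\tID:rnetseq-sim\tPN:rnetseq-sim\n")
    truth_rows = []

    def emit(rid, p3, is_minus, L, category, state_label, protected, shft, do_mis, k_err):
        strand_c = "-" if is_minus else "+"
        lo = p3 if is_minus else p3 - L + 1
        if lo < 0 or lo + L > n:
            raise ValueError("read outside genome bounds")
        ref_top = seq_str[lo : lo + L]
        tx = revcomp(ref_top) if is_minus else ref_top
        mis_off = ""
        err_offs = []
        if do_mis or k_err:
            read = list(tx)
            if do_mis:
                read[L - 1] = "A"
                mis_off = "-1"
            if k_err:
                for _ in range(int(k_err)):
                    i = int(rng.integers(0, L))
                    cur = read[i]
                    alts = [b for b in BASES if b != cur]
                    read[i] = alts[int(rng.integers(0, 3))]
                    err_offs.append(str(i - L))
            read_tx = "".join(read)
            # SAM stores the read in reference orientation
            read_ref = revcomp(read_tx) if is_minus else read_tx
            mism_cols = [i for i in range(L) if read_ref[i] != ref_top[i]]
        else:
            read_tx = tx
            read_ref = ref_top
            mism_cols = []
        md_parts, prev = [], 0
        for c in mism_cols:
            md_parts.append(str(c - prev))
            md_parts.append(ref_top[c])
            prev = c + 1
        md_parts.append(str(L - prev))
        md = "".join(md_parts)
        flag = 16 if is_minus else 0
        sam.write(
            f"{rid}\t{flag}\t{genome.replicon_id}\t{lo + 1}\t42\t{L}M\t*\t0\t0\t"
            f"{read_ref}\t{'G' * L}\tNM:i:{len(mism_cols)}\tMD:Z:{md}\tNH:i:1\n"
        )
        fastq.write(f"@{rid}\n{read_tx}\n+\n{'G' * L}\n")
        truth_rows.append(
            (
                rid,
                genome.replicon_id,
                strand_c,
                int(p3),
                int(lo),
                int(L),
                category,
                state_label,
                int(protected),
                int(shft),
                int(bool(do_mis)),
                mis_off,
                ",".join(err_offs),
            )
        )

    pos3_l = pos3.tolist()
    minus_l = minus.tolist()
    length_l = length.tolist()
    state_l = state.tolist()
    footprint_l = footprint.tolist()
    shift_l = shift.tolist()
    untrim_l = untrimmed.tolist()
    misinc_l = misinc.tolist()
    nerr_l = n_err.tolist()
    for r in range(n_elong):
        emit(
            f"{read_id_prefix}{r:07d}",
            pos3_l[r],
            minus_l[r],
            length_l[r],
            "untrimmed" if untrim_l[r] else "footprint",
            STATES[state_l[r]],
            footprint_l[r],
            shift_l[r],
            misinc_l[r],
            nerr_l[r],
        )
    if n_init > 0:
        for r in range(n_init):
            emit(
                f"{read_id_prefix}{n_elong + r:07d}",
                int(ipos3[r]),
                bool(iminus[r]),
                int(ilen[r]),
                "initiation",
                "initiation",
                int(ilen[r]),
                0,
                False,
                int(ierr[r]),
            )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedData(
        genome=genome,
        genes=genes,
        pauses=pauses,
        strain=strain,
        fastq_text=fastq.getvalue(),
        sam_text=sam.getvalue(),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# truth-table I/O


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in ("misinc_offset", "seq_error_offsets")},
        keep_default_na=False,
    )
    return df[TRUTH_COLUMNS] if len(df.columns) else df
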