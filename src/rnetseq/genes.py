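"""Gene- and region-level read accounting and strain comparisons.

Reads are assigned to a gene when their alignment overlaps it on the same
strand and overlaps no other same-strand gene (strand-aware union rule;
ambiguous reads are dropped and counted).  Counts are normalised to
reads-per-million-mapped, rRNA counts are divided by the operon copy number
(seven in E. coli), and each gene contributes four 50-bp windows: Up
(upstream of the start codon, i.e. the 5'-UTR side), Head (downstream of
the start codon), Tail (upstream of the stop codon) and Down (downstream of
the stop codon).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: total mapped reads of the two published libraries; inputs for
#: normalisation when re-analysing the deposited data.
WT_TOTAL_MAPPED_READS = 6_967_786
DGREAB_TOTAL_MAPPED_READS = 11_174_399

REGIONS = ("Up", "Head", "Tail", "Down")
REGION_SIZE = 50

PAUSE_CATEGORIES = (
    "mRNA_CDS",
    "mRNA_5UTR",
    "mRNA_3UTR",
    "tRNA",
    "rRNA",
    "ncRNA",
    "antisense",
    "intergenic",
)


def normalize(raw, total_mapped: int):
    """Reads-per-million-mapped: 1e6 * raw / total."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return 1e6 * np.asarray(raw, dtype=float) / total_mapped


def region_windows(gene, size: int = REGION_SIZE) -> dict:
    """The four windows in transcription orientation, 0-based half-open.

    For a plus-strand gene with start-codon base c and stop-codon last base
    e: Up = [c-size, c), Head = [c, c+size), Tail = [e+1-size, e+1),
    Down = [e+1, e+1+size); minus-strand genes are mirrored.  Genes shorter
    than ``2*size`` get overlapping Head/Tail windows, flagged via the
    second return value.

    Returns ``(windows, short_gene_flag)``.
    """
    c, e = gene.cds_start, gene.cds_end
    if gene.strand == "+":
        win = {
            "Up": (c - size, c),
            "Head": (c, c + size),
            "Tail": (e + 1 - size, e + 1),
            "Down": (e + 1, e + 1 + size),
        }
        short = (e + 1 - c) < 2 * size
    else:
        win = {
            "Up": (c + 1, c + 1 + size),
            "Head": (c + 1 - size, c + 1),
            "Tail": (e, e + size),
            "Down": (e - size, e),
        }
        short = (c + 1 - e) < 2 * size
    return win, short


def count_gene_reads(
    alignments,
    annotation,
    total_mapped: int | None = None,
    rrna_copy_correction: bool = True,
):
    """Per-gene sense/antisense counts plus the four region windows.

    Returns ``(table, audit)``: a DataFrame with one row per gene (raw and
    normalised gene counts, per-region sense and antisense counts) and a
    dict with assigned/ambiguous/unassigned totals so that
    assigned + ambiguous + unassigned == number of alignments.
    """
    genes = annotation.genes if hasattr(annotation, "genes") else list(annotation)
    n_reads = len(alignments)
    total = total_mapped if total_mapped is not None else max(n_reads, 1)

    starts = np.array([a.ref_start for a in alignments], dtype=np.int64)
    ends = np.array([a.ref_end for a in alignments], dtype=np.int64)
    plus = np.array([a.strand == "+" for a in alignments])

    # same-strand overlap counts per read, for the union ambiguity rule
    overlap_count = {True: np.zeros(n_reads, np.int32), False: np.zeros(n_reads, np.int32)}
    gene_masks = []
    for g in genes:
        m = (starts < g.tx_hi) & (ends > g.tx_lo)
        gene_masks.append(m)
        overlap_count[g.strand == "+"] += m.astype(np.int32)

    same_strand_hits = np.where(plus, overlap_count[True], overlap_count[False])
    ambiguous = int((same_strand_hits > 1).sum())
    unassigned = int((same_strand_hits == 0).sum())

    rows = []
    for g, m in zip(genes, gene_masks):
        same = plus == (g.strand == "+")
        sense_m = m & same & (same_strand_hits == 1)
        anti_m = m & ~same
        raw = float(sense_m.sum())
        anti_raw = float(anti_m.sum())
        if rrna_copy_correction and g.biotype == "rRNA" and g.copy_number > 1:
            raw /= g.copy_number
            anti_raw /= g.copy_number
        row = {
            "gene_id": g.gene_id,
            "biotype": g.biotype,
            "strand": g.strand,
            "operon_id": g.operon_id,
            "tx_lo": g.tx_lo,
            "raw_count": raw,
            "normalized_count": float(normalize(raw, total)),
            "antisense_raw_count": anti_raw,
            "antisense_normalized_count": float(normalize(anti_raw, total)),
        }
        win, short = region_windows(g)
        row["short_gene"] = short
        for name, (lo, hi) in win.items():
            in_win = (starts < hi) & (ends > lo)
            s = float((in_win & same).sum())
            a_ = float((in_win & ~same).sum())
            if rrna_copy_correction and g.biotype == "rRNA" and g.copy_number > 1:
                s /= g.copy_number
                a_ /= g.copy_number
            row[f"{name}_sense"] = s
            row[f"{name}_sense_norm"] = float(normalize(s, total))
            row[f"{name}_antisense"] = a_
            row[f"{name}_antisense_norm"] = float(normalize(a_, total))
        rows.append(row)

    table = pd.DataFrame(rows)
    audit = {
        "assigned": int((same_strand_hits == 1).sum()),
        "ambiguous": ambiguous,
        "unassigned": unassigned,
        "total": n_reads,
    }
    return table, audit


def compare_strains(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    min_norm: float = 0.1,
    regions=REGIONS,
    paired: bool = False,
    alpha: float = 0.05,
    first_in_operon_only: bool = False,
) -> pd.DataFrame:
    """Per-region two-tailed t-test between two strains' region counts.

    mRNA genes with gene-level normalised counts above ``min_norm`` in both
    strains enter the test; Welch's unequal-variance test is the default, a
    paired test is available.  With ``first_in_operon_only`` the comparison
    is restricted to monocistronic operons and first genes of polycistronic
    operons (here: the operon's 5'-most gene in transcription direction).
    Returns a table with region, per-strain means, p-value and significance
    at ``alpha``.
    """
    a = table_a.set_index("gene_id")
    b = table_b.set_index("gene_id")
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    keep = (
        (a["biotype"] == "mRNA")
        & (a["normalized_count"] > min_norm)
        & (b["normalized_count"] > min_norm)
    )
    a, b = a[keep], b[keep]
    if first_in_operon_only and "operon_id" in a.columns:
        firsts = set()
        for _, grp in a.groupby("operon_id"):
            if (grp["strand"] == "+").all():
                firsts.add(grp["tx_lo"].idxmin())
            elif (grp["strand"] == "-").all():
                firsts.add(grp["tx_lo"].idxmax())
            else:  # mixed-strand operon record: keep all members
                firsts.update(grp.index)
        a, b = a.loc[a.index.isin(firsts)], b.loc[b.index.isin(firsts)]
    if len(a) < 2:
        raise ValueError("fewer than 2 genes pass the normalised-count filter")
    rows = []
    for region in regions:
        col = f"{region}_sense_norm"
        x, y = a[col].to_numpy(), b[col].to_numpy()
        if paired:
            t, p = stats.ttest_rel(x, y)
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append(
            {
                "region": region,
                "n_genes": len(x),
                "mean_a": float(x.mean()),
                "mean_b": float(y.mean()),
                "t": float(t),
                "p_value": float(p),
                "significant": bool(p <= alpha),
            }
        )
    return pd.DataFrame(rows)


def sense_antisense_correlation(table: pd.DataFrame, region: str = "Tail"):
    """Pearson correlation of sense vs antisense region counts.

    Returns ``(r, p, scatter)`` with the per-gene scatter table.
    """
    s = table[f"{region}_sense_norm"].to_numpy()
    a = table[f"{region}_antisense_norm"].to_numpy()
    if len(s) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    r, p = stats.pearsonr(s, a)
    scatter = pd.DataFrame(
        {"gene_id": table["gene_id"], "sense": s, "antisense": a}
    )
    return float(r), float(p), scatter


def categorize_pauses(pauses, annotation) -> dict:
    """Fractions of pause sites per RNA type.

    Precedence: sense-strand feature (mRNA split into 5'UTR / CDS / 3'UTR
    using the gene's TSS and codon bounds; tRNA/rRNA/ncRNA by biotype) >
    antisense (overlaps a gene on the opposite strand only) > intergenic.
    """
    genes = annotation.genes if hasattr(annotation, "genes") else list(annotation)
    counts = dict.fromkeys(PAUSE_CATEGORIES, 0)
    for p in pauses:
        pos = p.position
        sense_cat = None
        is_anti = False
        for g in genes:
            if not (g.tx_lo <= pos < g.tx_hi):
                continue
            if g.strand == p.strand:
                if g.biotype != "mRNA":
                    sense_cat = g.biotype
                else:
                    lo_cds = min(g.cds_start, g.cds_end)
                    hi_cds = max(g.cds_start, g.cds_end)
                    if lo_cds <= pos <= hi_cds:
                        sense_cat = "mRNA_CDS"
                    elif (g.strand == "+" and pos < lo_cds) or (
                        g.strand == "-" and pos > hi_cds
                    ):
                        sense_cat = "mRNA_5UTR"
                    else:
                        sense_cat = "mRNA_3UTR"
                break
            is_anti = True
        if sense_cat is not None:
            counts[sense_cat] += 1
        elif is_anti:
            counts["antisense"] += 1
        else:
            counts["intergenic"] += 1
    total = max(sum(counts.values()), 1)
    return {k: v / total for k, v in counts.items()}


def tss_distance_profile(
    items,
    tss: pd.DataFrame,
    max_dist: int = 500,
    bin_size: int = 25,
):
    """Histogram of signed distances to the nearest same-strand TSS.

    ``items`` yield ``(position, strand)`` via attributes or tuples;
    distance is positive downstream of the TSS in transcription direction.
    Items with no TSS within ``max_dist`` are excluded and counted.
    Returns ``(series indexed by bin start, n_excluded)``; bin index b
    covers distances [b*bin_size, (b+1)*bin_size).
    """
    by_strand = {
        s: np.sort(tss.loc[tss["strand"] == s, "position"].to_numpy())
        for s in "+-"
    }
    bins: dict[int, int] = {}
    excluded = 0
    for it in items:
        pos = it.position if hasattr(it, "position") else it[0]
        strand = it.strand if hasattr(it, "strand") else it[1]
        sites = by_strand.get(strand)
        if sites is None or len(sites) == 0:
            excluded += 1
            continue
        j = np.searchsorted(sites, pos)
        cand = [c for c in (j - 1, j) if 0 <= c < len(sites)]
        nearest = min(cand, key=lambda c: abs(pos - sites[c]))
        d = pos - sites[nearest] if strand == "+" else sites[nearest] - pos
        if abs(d) > max_dist:
            excluded += 1
            continue
        b = int(np.floor(d / bin_size))
        bins[b] = bins.get(b, 0) + 1
    series = pd.Series(bins, dtype=int).sort_index()
    series.index.name = "bin"
    return series, excluded
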