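"""Per-read-position substitution matrices indexed from the 3' end.

For each exact read length L, every aligned base of every (unique-best)
substitution-only alignment contributes once: to the opportunity count of
its transcript-orientation reference base at its offset (-L..-1, -1 = 3'
end), and, if mismatched, to the count of its ref->read substitution type.
Rates are per opportunity: the G-to-A rate at an offset is the fraction of
reads with reference G there that read A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seqs import BASES

SUBSTITUTION_TYPES = [
    (r, a) for r in BASES for a in BASES if r != a
]  # the 12 ordered substitution types


@dataclass
class ErrorMatrix:
    length: int
    mismatches: np.ndarray  # (L, 4, 4): offset x ref x read, diagonal zero
    opportunities: np.ndarray  # (L, 4): offset x ref
    n_reads: int = 0
    n_skipped: int = 0  # wrong length / multi-mapped reads not counted

    @property
    def offsets(self):
        return list(range(-self.length, 0))

    def rate(self, ref: str, alt: str) -> np.ndarray:
        """Per-offset substitution rate, NaN where no opportunities."""
        ri, ai = BASES.index(ref), BASES.index(alt)
        opp = self.opportunities[:, ri].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(opp > 0, self.mismatches[:, ri, ai] / opp, np.nan)

    def rate_at(self, ref: str, alt: str, offset: int) -> float:
        return float(self.rate(ref, alt)[offset + self.length])

    def opportunities_at(self, ref: str, offset: int) -> int:
        return int(self.opportunities[offset + self.length, BASES.index(ref)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, off in enumerate(self.offsets):
            for r, a in SUBSTITUTION_TYPES:
                ri, ai = BASES.index(r), BASES.index(a)
                opp = self.opportunities[i, ri]
                mm = self.mismatches[i, ri, ai]
                rows.append(
                    (self.length, off, r, a, int(mm), int(opp),
                     mm / opp if opp else np.nan)
                )
        return pd.DataFrame(
            rows,
            columns=["length", "offset", "ref", "alt", "mismatches",
                     "opportunities", "rate"],
        )


def accumulate_errors(
    alignments,
    length: int,
    unique_only: bool = True,
) -> ErrorMatrix:
    """Substitution matrix over all alignments of one exact length.

    Multi-mapped reads (n_hits > 1) are excluded by default: mismatch calls
    at repeated loci are unreliable.  Alignments of a different length are
    skipped and tallied.
    """
    base_to_idx = np.full(256, -1, dtype=np.int8)
    for j, b in enumerate(BASES):
        base_to_idx[ord(b)] = j

    refs, quals = [], []
    n_skipped = 0
    for a in alignments:
        if a.length != length or (unique_only and a.n_hits > 1):
            n_skipped += 1
            continue
        refs.append(a.ref_bases)
        quals.append(a.read_bases)
    n_reads = len(refs)
    mism = np.zeros((length, 4, 4), dtype=np.int64)
    opp = np.zeros((length, 4), dtype=np.int64)
    if n_reads:
        rmat = base_to_idx[
            np.frombuffer("".join(refs).encode(), np.uint8).reshape(n_reads, length)
        ]
        qmat = base_to_idx[
            np.frombuffer("".join(quals).encode(), np.uint8).reshape(n_reads, length)
        ]
        if (rmat < 0).any() or (qmat < 0).any():
            raise ValueError("non-ACGT base in alignment pairs")
        for i in range(length):
            opp[i] = np.bincount(rmat[:, i], minlength=4)
            diff = rmat[:, i] != qmat[:, i]
            if diff.any():
                np.add.at(mism[i], (rmat[diff, i], qmat[diff, i]), 1)
    return ErrorMatrix(
        length=length,
        mismatches=mism,
        opportunities=opp,
        n_reads=n_reads,
        n_skipped=n_skipped,
    )


def matrices_by_length(alignments, lengths=range(14, 19), unique_only=True) -> dict:
    by_len: dict[int, list] = {L: [] for L in lengths}
    for a in alignments:
        if a.length in by_len:
            by_len[a.length].append(a)
    return {
        L: accumulate_errors(by_len[L], L, unique_only=unique_only)
        for L in lengths
    }


def enrichment_threshold(
    matrices: dict,
    ref: str,
    alt: str,
    offsets=range(-12, 0),
) -> float:
    """Mean + 1 SD of one substitution type's rates over -12..-1, 14-18 nt.

    Pooling the per-(length, offset) rates across the footprint classes
    gives the background band; a position is "enriched" when its rate
    exceeds this threshold.
    """
    vals = []
    for L, m in matrices.items():
        r = m.rate(ref, alt)
        for off in offsets:
            if -L <= off <= -1:
                v = r[off + L]
                if not np.isnan(v):
                    vals.append(v)
    if not vals:
        raise ValueError("no populated offsets in -12..-1")
    vals = np.asarray(vals)
    return float(vals.mean() + vals.std(ddof=0))


def enriched_positions(matrices: dict, ref: str, alt: str) -> list:
    """(length, offset) pairs whose rate exceeds the enrichment threshold."""
    thr = enrichment_threshold(matrices, ref, alt)
    out = []
    for L, m in sorted(matrices.items()):
        r = m.rate(ref, alt)
        for off in range(-12, 0):
            if -L <= off <= -1 and not np.isnan(r[off + L]) and r[off + L] > thr:
                out.append((L, off))
    return out


def error_rate_by_backtrack(
    matrices: dict,
    ref: str = "G",
    alt: str = "A",
    offset: int = -1,
) -> tuple:
    """3'-end substitution rate versus read length (backtracking distance).

    Longer footprints correspond to deeper backtracking; a misincorporation
    that triggers backtracking shows up as a rate rising with length.
    Returns ``(table, spearman_rho, spearman_p)`` where the table has
    columns length/rate/opportunities.
    """
    rows = []
    for L, m in sorted(matrices.items()):
        rows.append((L, m.rate_at(ref, alt, offset), m.opportunities_at(ref, offset)))
    df = pd.DataFrame(rows, columns=["length", "rate", "opportunities"])
    sub = df.dropna(subset=["rate"])
    if len(sub) >= 3 and sub["rate"].nunique() > 1:
        rho, p = stats.spearmanr(sub["length"], sub["rate"])
    else:
        rho, p = np.nan, np.nan
    return df, float(rho) if rho == rho else np.nan, float(p) if p == p else np.nan
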