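"""Strand-specific 3'-end pileups and the P(phi, delta) pause statistic.

A genomic position is a pause site when, among the reads of the analysis
class covering it, the fraction phi whose 3' RNA end falls exactly there is
at least ``phi_min`` while the coverage depth delta is at least
``delta_min``.  Published regimes: P(0.9, 100) and P(0.9, 160) for the bulk
(>=21-nt) classes of the wild-type and Gre-deletion strains, P(0.7, 100) for
category/TSS profiles, and P(0.9, 50) for single-length classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqs import BASES, revcomp

#: length classes: 'bulk_ge21' (reads >= 21 nt) or 'L<n>' (exact length)
BULK_CLASS = "bulk_ge21"

SUB_FOOTPRINT = "sub-footprint"


def class_filter(length_class: str):
    """Predicate on aligned length for a named read-length class."""
    if length_class == BULK_CLASS:
        return lambda L: L >= 21
    if length_class == "all":
        return lambda L: True
    if length_class.startswith("L"):
        n = int(length_class[1:])
        if not 6 <= n <= 30:
            raise ValueError(f"exact length class out of range: {length_class}")
        return lambda L: L == n
    raise ValueError(f"unknown length class {length_class!r}")


@dataclass
class PileupTrack:
    replicon: str
    strand: str
    depth: np.ndarray  # reads of the class covering each position
    end3: np.ndarray  # reads of the class whose 3' end is the position
    mapq_sum: np.ndarray  # summed mapq of the 3'-end reads
    length_class: str = BULK_CLASS

    @property
    def phi(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.depth > 0, self.end3 / self.depth, 0.0)


@dataclass
class PauseSite:
    replicon: str
    position: int  # 0-based coordinate of the 3'-end base
    strand: str
    phi: float
    delta: int
    mapq_mean: float
    length_class: str = BULK_CLASS

    @property
    def key(self):
        return (self.replicon, self.position, self.strand)


def build_pileup(
    alignments,
    replicon_lengths: dict,
    length_class: str = BULK_CLASS,
) -> dict:
    """Per-(replicon, strand) pileup tracks for one read-length class.

    Multi-mapped reads contribute at every reported location.  Returns a
    dict keyed by ``(replicon, strand)``.
    """
    keep = class_filter(length_class)
    tracks = {}
    for rep, n in replicon_lengths.items():
        for strand in "+-":
            tracks[(rep, strand)] = PileupTrack(
                replicon=rep,
                strand=strand,
                depth=np.zeros(n, dtype=np.int64),
                end3=np.zeros(n, dtype=np.int64),
                mapq_sum=np.zeros(n, dtype=np.float64),
                length_class=length_class,
            )
    # accumulate depth via a difference array, 3' ends directly
    diffs = {k: np.zeros(len(t.depth) + 1, dtype=np.int64) for k, t in tracks.items()}
    for a in alignments:
        if not keep(a.length):
            continue
        if a.replicon not in replicon_lengths:
            raise ValueError(f"read {a.read_id}: unknown replicon {a.replicon}")
        if a.ref_start < 0 or a.ref_end > replicon_lengths[a.replicon]:
            raise ValueError(f"read {a.read_id}: alignment outside replicon bounds")
        t = tracks[(a.replicon, a.strand)]
        d = diffs[(a.replicon, a.strand)]
        d[a.ref_start] += 1
        d[a.ref_end] -= 1
        p3 = a.pos3
        t.end3[p3] += 1
        t.mapq_sum[p3] += a.mapq
    for k, t in tracks.items():
        t.depth[:] = np.cumsum(diffs[k][:-1])
    return tracks


def call_pauses(
    track: PileupTrack,
    phi_min: float,
    delta_min: int,
    delta_on_end3: bool = False,
) -> list:
    """All positions with end3/depth >= phi_min and depth >= delta_min.

    Adjacent qualifying positions are reported independently (no merging).
    With ``delta_on_end3`` the depth requirement is applied to the 3'-end
    count instead of coverage (alternative reading of the depth criterion).
    """
    if not 0.0 < phi_min <= 1.0:
        raise ValueError("phi_min must be in (0, 1]")
    if delta_min < 1:
        raise ValueError("delta_min must be >= 1")
    depth_for_delta = track.end3 if delta_on_end3 else track.depth
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(track.depth > 0, track.end3 / track.depth, 0.0)
    mask = (phi >= phi_min) & (depth_for_delta >= delta_min)
    out = []
    for pos in np.flatnonzero(mask):
        n_end = track.end3[pos]
        out.append(
            PauseSite(
                replicon=track.replicon,
                position=int(pos),
                strand=track.strand,
                phi=float(phi[pos]),
                delta=int(track.depth[pos]),
                mapq_mean=float(track.mapq_sum[pos] / n_end) if n_end else 0.0,
                length_class=track.length_class,
            )
        )
    return out


def call_pauses_all(tracks: dict, phi_min: float, delta_min: int, **kw) -> list:
    out = []
    for key in sorted(tracks):
        out.extend(call_pauses(tracks[key], phi_min, delta_min, **kw))
    return out


def filter_mapq(pauses, threshold: float = 10.0):
    """Split pause sites into (kept, rejected) by mean mapping quality.

    Kept iff mapq_mean is strictly greater than the threshold, the
    mapping-uniqueness filter applied to single-length pause sets.
    """
    kept = [p for p in pauses if p.mapq_mean > threshold]
    rejected = [p for p in pauses if not (p.mapq_mean > threshold)]
    return kept, rejected


def state_from_length(L: int) -> str:
    """Translocation label encoded by a protected-fragment length.

    14 nt -> post-translocated, 15 nt -> pre-translocated, 14+1+b nt ->
    b-bp backtracked; lengths below 14 are sub-footprint (initiation-region
    species, not a translocation state).
    """
    if not 6 <= L <= 30:
        raise ValueError(f"read length {L} outside the 6-30 nt range")
    if L < 14:
        return SUB_FOOTPRINT
    if L == 14:
        return "post"
    if L == 15:
        return "pre"
    return f"backtrack{L - 15}"


def rnase_signature_fraction(alignments, genome, by_length: bool = False):
    """Composition of the genomic base immediately 5' of the read start.

    RNase T1 cuts GpN bonds, so T1-generated 5' ends leave a G immediately
    upstream (transcript orientation); RNase A leaves C or U.  Returns a
    dict base -> fraction, or {length: {base: fraction}} with ``by_length``.
    """
    seq = genome.sequence if hasattr(genome, "sequence") else genome
    n = len(seq)
    counts: dict = {}
    for a in alignments:
        if a.strand == "+":
            if a.ref_start == 0:
                continue
            b = seq[a.ref_start - 1]
        else:
            if a.ref_end >= n:
                continue
            b = revcomp(seq[a.ref_end])
        key = a.length if by_length else None
        counts.setdefault(key, dict.fromkeys(BASES, 0))
        if b in counts[key]:
            counts[key][b] += 1

    def norm(c):
        tot = sum(c.values())
        return {b: (c[b] / tot if tot else 0.0) for b in BASES}

    if by_length:
        return {L: norm(c) for L, c in sorted(counts.items())}
    return norm(counts.get(None, dict.fromkeys(BASES, 0)))


def read_length_histogram(alignments) -> dict:
    """Counts of aligned read lengths over the supported 6-30 nt range."""
    hist = {L: 0 for L in range(6, 31)}
    for a in alignments:
        if a.length in hist:
            hist[a.length] += 1
    return hist


def modal_length(hist: dict) -> int:
    """Most frequent read length (smallest wins ties)."""
    return max(sorted(hist), key=lambda L: hist[L])
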