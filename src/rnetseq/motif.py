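"""Pause-motif matrices: windows, frequencies, information content, scores.

Windows are read off the non-template DNA strand (the strand with the same
sequence as the nascent RNA) anchored at the pause 3'-end base.  Offsets
follow the -1/+1 convention: -1 is the 3'-end base, +1 the next downstream
base (the incoming-NTP position), and there is no offset 0.  The default
window spans -15..+5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqs import BASES, revcomp, seq_to_u8

DEFAULT_WINDOW = (-15, 5)


def window_offsets(window=DEFAULT_WINDOW):
    lo, hi = window
    if lo >= 0 or hi < 0:
        raise ValueError("window must span the 3' end, e.g. (-15, 5)")
    return [k for k in range(lo, hi + 1) if k != 0]


@dataclass
class PIEMatrix:
    """Base-frequency matrix of a pause-inducing element.

    ``counts`` has one row per offset and columns A/C/G/T; every row sums to
    ``n_sites``.  ``background`` holds the base probabilities used in the
    log-likelihood motif score (genomic composition by default).
    """

    offsets: list
    counts: np.ndarray  # (n_offsets, 4) ints
    n_sites: int
    pseudocount: float = 0.25
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.offsets), 4):
            raise ValueError("counts shape must be (n_offsets, 4)")

    def probs(self) -> np.ndarray:
        """Pseudocounted base probabilities per offset (rows sum to 1)."""
        c = self.counts + self.pseudocount
        return c / c.sum(axis=1, keepdims=True)

    def row(self, offset: int) -> np.ndarray:
        return self.counts[self.offsets.index(offset)]

    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.counts.argmax(axis=1))

    def g_fraction(self, offset: int) -> float:
        r = self.row(offset)
        return float(r[BASES.index("G")] / max(r.sum(), 1))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "offset", self.offsets)
        return df


def extract_windows(pauses, genome, window=DEFAULT_WINDOW):
    """Non-template-strand window strings anchored at each pause 3' end.

    Plus-strand sites give the top strand with the pause base at offset -1;
    minus-strand sites the reverse complement (so a motif planted on either
    strand yields the identical string).  Sites whose window would leave the
    sequence are skipped and counted.

    Returns ``(windows, n_skipped)``.
    """
    seq = genome.sequence if hasattr(genome, "sequence") else genome
    n = len(seq)
    lo, hi = window
    up = -lo - 1  # bases upstream of the pause base
    down = hi
    windows, skipped = [], 0
    for p in pauses:
        pos = p.position if hasattr(p, "position") else p[0]
        strand = p.strand if hasattr(p, "strand") else p[1]
        if strand == "+":
            a, b = pos - up, pos + down + 1
            if a < 0 or b > n:
                skipped += 1
                continue
            windows.append(seq[a:b])
        else:
            a, b = pos - down, pos + up + 1
            if a < 0 or b > n:
                skipped += 1
                continue
            windows.append(revcomp(seq[a:b]))
    return windows, skipped


def frequency_matrix(
    windows,
    window=DEFAULT_WINDOW,
    pseudocount: float = 0.25,
    background=None,
) -> PIEMatrix:
    """Tally per-offset base counts over equally long window strings."""
    if not windows:
        raise ValueError("at least one window is required")
    offsets = window_offsets(window)
    width = len(offsets)
    if any(len(w) != width for w in windows):
        raise ValueError("all windows must match the offset grid length")
    mat = np.zeros((width, 4), dtype=float)
    base_idx = {ord(b): j for j, b in enumerate(BASES)}
    for w in windows:
        for i, ch in enumerate(w.encode("ascii")):
            j = base_idx.get(ch)
            if j is None:
                raise ValueError(f"non-ACGT base {chr(ch)!r} in window")
            mat[i, j] += 1
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PIEMatrix(
        offsets=offsets,
        counts=mat,
        n_sites=len(windows),
        pseudocount=pseudocount,
        background=bg,
    )


def information_content(m: PIEMatrix, small_sample_correction: bool = False):
    """Per-offset information content in bits (and the total).

    IC_j = 2 + sum_b p_jb log2 p_jb with pseudocounted probabilities; the
    small-sample correction subtracts 3 / (2 ln2 n), floored at zero.
    """
    if m.n_sites < 1:
        raise ValueError("matrix holds no sites")
    p = m.probs()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    if small_sample_correction:
        ic = np.maximum(ic - 3.0 / (2.0 * np.log(2) * m.n_sites), 0.0)
    return ic, float(ic.sum())


def motif_score(m: PIEMatrix) -> float:
    """Log-likelihood-ratio motif score in bits.

    sum_j sum_b n_jb log2(p_jb / q_b) with pseudocounted p and the matrix's
    background q.  A MAP-like summary of how strongly the site set deviates
    from background composition.
    """
    q = np.asarray(m.background, dtype=float)
    if np.any(q <= 0):
        raise ValueError("background probabilities must be strictly positive")
    p = m.probs()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(m.counts > 0, m.counts * np.log2(p / q), 0.0)
    return float(terms.sum())


def top_ic_offsets(m: PIEMatrix, k: int = 5):
    ic, _ = information_content(m)
    order = np.argsort(ic)[::-1]
    return [m.offsets[i] for i in order[:k]]


def g_position_profile(matrices: dict, candidates=(-9, -10, -11)) -> dict:
    """Per-length-class argmax of the G frequency over upstream offsets.

    The winning offset locates the riboG-dC base pair at the upstream edge
    of the RNA-DNA hybrid: -9 post-translocated, -10 pre-translocated, -11
    1-bp backtracked.  Returns {class: (offset, g_fraction)}.
    """
    out = {}
    for cls, m in matrices.items():
        fracs = {off: m.g_fraction(off) for off in candidates if off in m.offsets}
        if not fracs:
            raise ValueError(f"class {cls}: no candidate offsets in matrix")
        best = max(fracs, key=fracs.get)
        out[cls] = (best, fracs[best])
    return out


def exclude_shared_sites(set_a, set_b):
    """Sites of B not present in A (exact position+strand match)."""
    akeys = {(p.replicon, p.position, p.strand) for p in set_a}
    return [p for p in set_b if (p.replicon, p.position, p.strand) not in akeys]


def split_by_3prime_error(
    pauses,
    alignments,
    genome,
    ref_base: str = "G",
    alt_base: str = "A",
    window=DEFAULT_WINDOW,
    pseudocount: float = 0.25,
):
    """Partition reference-G pause sites by 3'-terminal G-to-A evidence.

    Considers pause sites whose reference base at offset -1 is ``ref_base``;
    a site joins the error group when at least one read ending there carries
    the ``ref_base``->``alt_base`` substitution at -1.  Returns
    ``(error_sites, clean_sites, error_matrix, clean_matrix)``; a matrix is
    None when its group is empty.
    """
    seq = genome.sequence if hasattr(genome, "sequence") else genome
    has_err = set()
    for a in alignments:
        rb, qb = a.ref_bases[-1], a.read_bases[-1]
        if rb == ref_base and qb == alt_base:
            has_err.add((a.replicon, a.pos3, a.strand))

    error_sites, clean_sites = [], []
    for p in pauses:
        base = seq[p.position] if p.strand == "+" else revcomp(seq[p.position])
        if base != ref_base:
            continue
        if (p.replicon, p.position, p.strand) in has_err:
            error_sites.append(p)
        else:
            clean_sites.append(p)

    def matrix(sites):
        if not sites:
            return None
        win, _ = extract_windows(sites, genome, window=window)
        if not win:
            return None
        return frequency_matrix(win, window=window, pseudocount=pseudocount)

    return error_sites, clean_sites, matrix(error_sites), matrix(clean_sites)
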