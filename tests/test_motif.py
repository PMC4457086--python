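"""PIE windows, frequency matrices, information content and motif scores."""

import numpy as np
import pytest

import rnetseq as r
from rnetseq.motif import (
    PIEMatrix,
    exclude_shared_sites,
    extract_windows,
    frequency_matrix,
    g_position_profile,
    information_content,
    motif_score,
    split_by_3prime_error,
    top_ic_offsets,
    window_offsets,
)
from rnetseq.pause import PauseSite
from rnetseq.seqs import revcomp

from conftest import make_read


def test_window_offsets_skip_zero():
    offs = window_offsets((-15, 5))
    assert len(offs) == 20 and 0 not in offs
    assert offs[0] == -15 and offs[-1] == 5


def test_extract_windows_strand_symmetry():
    """A motif planted on either strand yields the identical window string."""
    genome, genes, _ = r.generate_genome(20000, 0.5, 20, seed=1)
    edited, pauses = r.plant_pauses(genome, genes, 20, "WT_PIE", r.WT_PROFILE, seed=5)
    plus = [p for p in pauses if p.strand == "+"]
    minus = [p for p in pauses if p.strand == "-"]
    assert plus and minus
    offs = window_offsets()
    for p in plus + minus:
        (w,), _ = extract_windows([p], edited)
        assert len(w) == 20
        assert w[offs.index(-10)] == "G"
        assert w[offs.index(-1)] == "C" and w[offs.index(1)] == "G"
    # explicit mirror check: reverse-complementing a plus window around a
    # fake minus site at the mirrored coordinate reproduces the string
    p = plus[0]
    (w_plus,), _ = extract_windows([p], edited)
    rc = revcomp(edited.sequence)
    n = len(edited)
    mirrored = PauseSite("simchr", n - 1 - p.position, "-", 1.0, 1, 42.0)
    (w_mirror,), _ = extract_windows(
        [mirrored], type(edited)(edited.replicon_id, rc, True, 0.5)
    )
    assert w_mirror == w_plus


def test_extract_windows_skips_contig_edges():
    genome = r.SimGenome("c", "ACGT" * 20, False, 0.5)
    near_edge = PauseSite("c", 3, "+", 1.0, 1, 42.0)
    inside = PauseSite("c", 40, "+", 1.0, 1, 42.0)
    windows, skipped = extract_windows([near_edge, inside], genome)
    assert skipped == 1 and len(windows) == 1


def test_frequency_matrix_counts_and_validation():
    w = "A" * 15 + "C" * 5  # offsets -15..-1 are A, +1..+5 are C
    m = frequency_matrix([w, w])
    assert m.n_sites == 2
    assert (m.counts.sum(axis=1) == 2).all()
    assert (m.row(-1) == np.array([2, 0, 0, 0])).all()
    assert (m.row(1) == np.array([0, 2, 0, 0])).all()
    with pytest.raises(ValueError):
        frequency_matrix([w, w[:-1]])
    with pytest.raises(ValueError):
        frequency_matrix([])


@pytest.mark.parametrize(
    "counts,expected_bits",
    [
        ((5, 5, 5, 5), 0.0),  # uniform column: maximum entropy
        ((20, 0, 0, 0), 2.0),  # single base: zero entropy
        ((10, 10, 0, 0), 1.0),  # two equiprobable bases: 2 - 1
    ],
)
def test_information_content_closed_forms(counts, expected_bits):
    m = PIEMatrix(offsets=[-1], counts=np.array([counts]), n_sites=sum(counts),
                  pseudocount=0.0)
    ic, total = information_content(m)
    assert ic[0] == pytest.approx(expected_bits)
    assert total == pytest.approx(expected_bits)


def test_small_sample_correction_subtracts_and_floors():
    m = PIEMatrix(offsets=[-1], counts=np.array([[4, 0, 0, 0]]), n_sites=4,
                  pseudocount=0.0)
    ic_raw, _ = information_content(m)
    ic_corr, _ = information_content(m, small_sample_correction=True)
    assert ic_corr[0] == pytest.approx(ic_raw[0] - 3 / (2 * np.log(2) * 4))
    m0 = PIEMatrix(offsets=[-1], counts=np.array([[1, 1, 1, 1]]), n_sites=4,
                   pseudocount=0.0)
    assert information_content(m0, small_sample_correction=True)[0][0] == 0.0


def test_ic_bounds_with_pseudocount():
    rng = np.random.default_rng(0)
    for _ in range(20):
        counts = rng.multinomial(30, rng.dirichlet(np.ones(4)), size=6)
        m = PIEMatrix(offsets=list(range(-6, 0)), counts=counts, n_sites=30)
        ic, _ = information_content(m)
        assert (ic >= 0).all() and (ic <= 2).all()


def test_motif_score_closed_forms():
    # counts exactly matching a uniform background score zero
    m = frequency_matrix(["A" * 20, "C" * 20, "G" * 20, "T" * 20])
    assert motif_score(m) == pytest.approx(0.0, abs=1e-9)
    # single-base columns vs uniform background: 2 bits per count per column
    n, w = 8, 20
    mono = frequency_matrix(["A" * w] * n, pseudocount=0.0)
    assert motif_score(mono) == pytest.approx(2.0 * n * w)
    # replacing a uniform column by a single-base column raises the score
    base = frequency_matrix(["ACGT" * 5, "CGTA" * 5, "GTAC" * 5, "TACG" * 5])
    counts = base.counts.copy()
    counts[0] = [base.n_sites, 0, 0, 0]
    peaked = PIEMatrix(offsets=base.offsets, counts=counts, n_sites=base.n_sites)
    assert motif_score(peaked) > motif_score(base)
    # zero background is rejected
    bad = PIEMatrix(offsets=[-1], counts=np.array([[1, 1, 1, 1]]), n_sites=4,
                    background=np.array([0.5, 0.5, 0.0, 0.0]))
    with pytest.raises(ValueError):
        motif_score(bad)


def test_g_position_profile_null_genome():
    """On random sites of a random genome no upstream offset stands out."""
    genome, _, _ = r.generate_genome(20000, 0.5, 20, seed=77)
    rng = np.random.default_rng(78)
    sites = [
        PauseSite("simchr", int(p), "+-"[int(rng.integers(0, 2))], 1.0, 1, 42.0)
        for p in rng.integers(100, 19900, size=400)
    ]
    windows, _ = extract_windows(sites, genome)
    m = frequency_matrix(windows)
    (off, frac), = g_position_profile({"null": m}).values()
    se = np.sqrt(0.25 * 0.75 / m.n_sites)
    assert frac <= 0.25 + 3 * se + 0.03


def test_exclude_shared_sites():
    def s(pos, strand="+"):
        return PauseSite("c", pos, strand, 1.0, 1, 42.0)

    a = [s(1), s(2)]
    b = [s(3), s(4)]
    assert exclude_shared_sites(a, b) == b
    assert exclude_shared_sites(a, a) == []
    assert len(exclude_shared_sites(a, [s(2), s(5)])) == 1
    # same position on the other strand is not shared
    assert len(exclude_shared_sites(a, [s(1, "-")])) == 1


def test_split_by_3prime_error_degenerate_rates():
    """All sites land in the error group at rate 1, none at rate 0."""
    genome = r.SimGenome("c", "A" * 40 + "CG" + "A" * 38, False, 0.5)
    site = PauseSite("c", 41, "+", 1.0, 100, 42.0)  # reference G at -1, C at -2
    ref = genome.sequence[41 - 17 : 42]  # 18-mer ending at the site
    clean = [make_read(41 - 17, 18, ref=ref, seq=ref, replicon="c") for _ in range(5)]
    err_seq = ref[:-1] + "A"
    witherr = clean[:3] + [
        make_read(41 - 17, 18, ref=ref, seq=err_seq, replicon="c") for _ in range(2)
    ]
    es, cs, em, cm = split_by_3prime_error([site], clean, genome)
    assert es == [] and cs == [site] and em is None
    es, cs, em, cm = split_by_3prime_error([site], witherr, genome)
    assert es == [site] and cs == [] and cm is None
    assert em.row(-2)[1] == 1  # planted C at -2


def test_split_ignores_sites_without_reference_g():
    genome = r.SimGenome("c", "A" * 80, False, 0.5)
    site = PauseSite("c", 41, "+", 1.0, 100, 42.0)
    es, cs, em, cm = split_by_3prime_error([site], [], genome)
    assert es == cs == [] and em is None and cm is None


def test_shuffling_windows_destroys_information(wt_small):
    """Permuting each window's positions drives the total IC to the null."""
    from rnetseq import experiments as X

    m, sites = X.bulk_pie(wt_small)
    _, total_planted = information_content(m, small_sample_correction=True)
    rng = np.random.default_rng(5)
    windows, _ = extract_windows(sites, wt_small.genome)
    shuffled = ["".join(rng.permutation(list(w))) for w in windows]
    _, total_shuffled = information_content(
        frequency_matrix(shuffled), small_sample_correction=True
    )
    # empirical null: matrices of multinomial draws from the pooled
    # composition of the very same windows
    pooled = frequency_matrix(windows).counts.sum(axis=0)
    pvec = pooled / pooled.sum()
    null_totals = []
    for _ in range(30):
        counts = rng.multinomial(m.n_sites, pvec, size=len(m.offsets))
        nm = PIEMatrix(offsets=m.offsets, counts=counts, n_sites=m.n_sites)
        null_totals.append(
            information_content(nm, small_sample_correction=True)[1]
        )
    mu, sd = np.mean(null_totals), np.std(null_totals)
    assert total_shuffled <= mu + 3 * sd + 0.1
    assert total_planted > mu + 10 * sd
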