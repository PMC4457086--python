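"""Pileups, the P(phi, delta) statistic and length-class diagnostics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rnetseq as r
from rnetseq import experiments as X
from rnetseq.pause import (
    BULK_CLASS,
    build_pileup,
    call_pauses,
    call_pauses_all,
    filter_mapq,
    modal_length,
    read_length_histogram,
    rnase_signature_fraction,
    state_from_length,
)

from conftest import make_read

LENGTHS = {"simchr": 500}


def test_single_read_pileup():
    tracks = build_pileup([make_read(100, 21)], LENGTHS, BULK_CLASS)
    t = tracks[("simchr", "+")]
    assert t.depth[100:121].tolist() == [1] * 21
    assert t.depth[99] == 0 and t.depth[121] == 0
    assert t.end3.sum() == 1 and t.end3[120] == 1


def test_minus_strand_three_prime_end_is_ref_start():
    tracks = build_pileup([make_read(100, 21, strand="-")], LENGTHS, BULK_CLASS)
    t = tracks[("simchr", "-")]
    assert t.end3[100] == 1 and t.end3.sum() == 1


def test_two_identical_reads_give_phi_one():
    reads = [make_read(100, 21), make_read(100, 21)]
    t = build_pileup(reads, LENGTHS, BULK_CLASS)[("simchr", "+")]
    assert t.depth[120] == 2 and t.end3[120] == 2
    sites = call_pauses(t, 0.9, 2)
    assert len(sites) == 1 and sites[0].phi == 1.0 and sites[0].delta == 2


def test_phi_mixture_and_thresholds():
    """95 of 100 covering reads end at position 120 -> phi 0.95."""
    reads = [make_read(100, 21) for _ in range(95)]
    reads += [make_read(105, 21) for _ in range(5)]  # cover 120, end at 125
    t = build_pileup(reads, LENGTHS, BULK_CLASS)[("simchr", "+")]
    assert t.depth[120] == 100 and t.end3[120] == 95
    assert call_pauses(t, 0.9, 100)[0].position == 120
    # depth 99 fails the delta threshold
    t99 = build_pileup(reads[1:], LENGTHS, BULK_CLASS)[("simchr", "+")]
    assert all(s.position != 120 for s in call_pauses(t99, 0.9, 100))
    # phi threshold above 0.95 rejects the site
    assert all(s.position != 120 for s in call_pauses(t, 0.96, 50))


def test_call_pauses_validates_thresholds():
    t = build_pileup([make_read(100, 21)], LENGTHS, BULK_CLASS)[("simchr", "+")]
    with pytest.raises(ValueError):
        call_pauses(t, 1.2, 10)
    with pytest.raises(ValueError):
        call_pauses(t, 0.9, 0)


def test_out_of_bounds_alignment_raises():
    with pytest.raises(ValueError, match="outside replicon"):
        build_pileup([make_read(495, 21)], LENGTHS, BULK_CLASS)


@settings(max_examples=25, deadline=None)
@given(st.data())
def test_pileup_conservation_and_monotonicity(data):
    """Sum of 3' ends equals class size; 0 <= end3 <= depth everywhere;
    raising either threshold never adds a pause site."""
    n = data.draw(st.integers(1, 60))
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    reads = [
        make_read(
            int(rng.integers(0, 450)),
            int(rng.integers(21, 31)),
            strand="+-"[int(rng.integers(0, 2))],
        )
        for _ in range(n)
    ]
    tracks = build_pileup(reads, LENGTHS, BULK_CLASS)
    total_end3 = sum(t.end3.sum() for t in tracks.values())
    assert total_end3 == n
    for t in tracks.values():
        assert (t.end3 <= t.depth).all() and (t.end3 >= 0).all()
    loose = {s.key for s in call_pauses_all(tracks, 0.5, 1)}
    tighter_phi = {s.key for s in call_pauses_all(tracks, 0.8, 1)}
    tighter_delta = {s.key for s in call_pauses_all(tracks, 0.5, 3)}
    assert tighter_phi <= loose and tighter_delta <= loose


def test_call_pauses_equals_brute_force_recount(wt_small):
    """Oracle: an independent per-read recount reproduces every call."""
    ds = wt_small
    reads = [a for a in ds.reads if a.length >= 21]
    cover: dict = {}
    ends: dict = {}
    for a in reads:
        for pos in range(a.ref_start, a.ref_end):
            cover[(pos, a.strand)] = cover.get((pos, a.strand), 0) + 1
        ends[(a.pos3, a.strand)] = ends.get((a.pos3, a.strand), 0) + 1
    phi_min, delta_min = 0.7, 100
    expected = {
        key
        for key, c in cover.items()
        if c >= delta_min and ends.get(key, 0) / c >= phi_min
    }
    tracks = build_pileup(ds.reads, ds.replicon_lengths, BULK_CLASS)
    got = {
        (s.position, s.strand)
        for s in call_pauses_all(tracks, phi_min, delta_min)
    }
    assert got == expected and len(got) > 0


def test_filter_mapq_examples():
    def site(mq):
        from rnetseq.pause import PauseSite

        return PauseSite("simchr", 1, "+", 1.0, 100, mq)

    kept, rejected = filter_mapq([site(42.0), site(0.0), site(21.0)], 10.0)
    assert [s.mapq_mean for s in kept] == [42.0, 21.0]
    assert [s.mapq_mean for s in rejected] == [0.0]


def test_mapq_mean_is_arithmetic_mean_of_end_reads():
    reads = [make_read(100, 21, mapq=42), make_read(100, 21, mapq=0)]
    t = build_pileup(reads, LENGTHS, BULK_CLASS)[("simchr", "+")]
    (site,) = call_pauses(t, 0.9, 2)
    assert site.mapq_mean == pytest.approx(21.0)


@pytest.mark.parametrize(
    "L,label",
    [
        (14, "post"),
        (15, "pre"),
        (16, "backtrack1"),
        (17, "backtrack2"),
        (18, "backtrack3"),
        (22, "backtrack7"),
        (12, "sub-footprint"),
        (6, "sub-footprint"),
    ],
)
def test_state_from_length(L, label):
    assert state_from_length(L) == label


@pytest.mark.parametrize("L", [5, 31])
def test_state_from_length_rejects_out_of_range(L):
    with pytest.raises(ValueError):
        state_from_length(L)


def test_read_length_histogram():
    assert all(v == 0 for v in read_length_histogram([]).values())
    reads = [make_read(10, 16) for _ in range(3)]
    h = read_length_histogram(reads)
    assert h[16] == 3 and sum(h.values()) == 3
    assert modal_length(h) == 16


def test_rnase_signature_tracks_the_bias(tiny_genome):
    """G fraction 5' of the read start: genomic at bias 0, strictly higher
    at 0.5, highest at 1."""
    genome, genes, _ = tiny_genome
    fracs = {}
    for bias in (0.0, 0.5, 1.0):
        prof = dataclasses.replace(
            r.WT_PROFILE,
            rnase_t1_bias=bias,
            untrimmed_prob=0.0,
            initiation_prob=0.0,
        )
        sim = r.simulate_reads(genome, genes, [], prof, 15_000, seed=61)
        reads = X.load_sim_alignments(sim)
        fracs[bias] = rnase_signature_fraction(reads, genome)["G"]
    from rnetseq.seqs import base_composition

    g_genomic = base_composition(genome.sequence)[2]
    se = 3 * np.sqrt(0.25 * 0.75 / 15_000)
    assert abs(fracs[0.0] - g_genomic) < se + 0.02
    assert fracs[0.0] < fracs[0.5] < fracs[1.0]


def test_rnase_signature_by_length_sums_to_one(wt_small):
    per_len = rnase_signature_fraction(wt_small.reads, wt_small.genome, by_length=True)
    for L, comp in per_len.items():
        assert sum(comp.values()) == pytest.approx(1.0)
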