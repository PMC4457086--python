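"""Generator contracts: determinism, geometry, planted motifs, length laws."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import rnetseq as r
from rnetseq import experiments as X
from rnetseq.motif import extract_windows
from rnetseq.simulate import STATES, STATE_EXTRA


def test_generate_genome_is_deterministic_and_seed_sensitive():
    g1, genes1, tss1 = r.generate_genome(20000, 0.5, 20, seed=1)
    g2, genes2, tss2 = r.generate_genome(20000, 0.5, 20, seed=1)
    g3, _, _ = r.generate_genome(20000, 0.5, 20, seed=2)
    assert g1.sequence == g2.sequence
    assert [dataclasses.asdict(a) for a in genes1] == [
        dataclasses.asdict(a) for a in genes2
    ]
    pd.testing.assert_frame_equal(tss1, tss2)
    assert g1.sequence != g3.sequence


def test_gc_zero_gives_at_only_sequence():
    g, _, _ = r.generate_genome(2000, 0.0, 1, seed=2)
    assert set(g.sequence) <= {"A", "T"}


def test_gene_geometry_and_convergent_pair():
    g, genes, tss = r.generate_genome(20000, 0.5, 20, seed=1)
    assert {x.strand for x in genes} == {"+", "-"}
    for x in genes:
        assert 0 <= x.tx_lo < x.tx_hi <= len(g)
        # TSS upstream of the start codon in transcription direction
        if x.strand == "+":
            assert x.tx_lo <= x.tss <= x.cds_start <= x.cds_end < x.tx_hi
        else:
            assert x.tx_lo <= x.cds_end <= x.cds_start <= x.tss < x.tx_hi
        assert x.utr5_length >= 0
    # no same-strand overlap; at least one opposite-strand (convergent) overlap
    for s in "+-":
        ivals = sorted((x.tx_lo, x.tx_hi) for x in genes if x.strand == s)
        assert all(a[1] <= b[0] for a, b in zip(ivals, ivals[1:]))
    overlaps = [
        (a, b)
        for a in genes
        for b in genes
        if a.strand == "+" and b.strand == "-" and a.tx_lo < b.tx_hi and b.tx_lo < a.tx_hi
    ]
    assert overlaps, "expected at least one convergent overlapping pair"


def test_generate_genome_rejects_impossible_layout():
    with pytest.raises(ValueError):
        r.generate_genome(2000, 0.5, 30, seed=1)


def test_rrna_copies_are_byte_identical():
    g, genes, _ = r.generate_genome(20000, 0.5, 10, seed=4, rrna_copies=7)
    rr = [x for x in genes if x.biotype == "rRNA"]
    assert len(rr) == 7 and all(x.copy_number == 7 for x in rr)
    seqs = {g.sequence[x.tx_lo : x.tx_hi] for x in rr}
    assert len(seqs) == 1


@pytest.mark.parametrize(
    "motif_class,expected",
    [
        ("WT_PIE", {-10: "G", -3: "T", -2: "G", -1: "C", 1: "G"}),
        ("dGre_PIE", {-11: "G", -7: "T", -4: "T", -1: "G"}),
    ],
)
def test_planted_motif_bases_on_non_template_strand(motif_class, expected):
    genome, genes, _ = r.generate_genome(20000, 0.5, 20, seed=1)
    strain = r.WT_PROFILE if motif_class == "WT_PIE" else r.DGREAB_PROFILE
    edited, pauses = r.plant_pauses(genome, genes, 30, motif_class, strain, seed=5)
    assert len(pauses) == 30
    positions = sorted(p.position for p in pauses)
    assert all(b - a >= 25 for a, b in zip(positions, positions[1:]))
    for p in pauses:
        windows, _ = extract_windows([p], edited)
        w = windows[0]
        offsets = [k for k in range(-15, 6) if k != 0]
        for off, base in expected.items():
            assert w[offsets.index(off)] == base


def test_plant_zero_sites_leaves_genome_unchanged():
    genome, genes, _ = r.generate_genome(20000, 0.5, 20, seed=1)
    edited, pauses = r.plant_pauses(genome, genes, 0, "WT_PIE", r.WT_PROFILE, seed=5)
    assert pauses == [] and edited.sequence == genome.sequence


def test_plant_rejects_when_no_room():
    genome, genes, _ = r.generate_genome(2500, 0.5, 2, seed=1)
    with pytest.raises(ValueError):
        r.plant_pauses(genome, genes, 500, "WT_PIE", r.WT_PROFILE, seed=5)


@pytest.mark.parametrize("state", STATES)
def test_protected_length_is_fourteen_plus_state_offset(state):
    L = X.footprint_length_for_state(state)
    assert L == 14 + STATE_EXTRA[state]


def test_length_law_with_rnase_bias(wt_small):
    """Footprint reads deviate from 14+t by at most the +2 bias shift."""
    t = wt_small.sim.truth
    fp = t[t.category == "footprint"]
    expected = fp.state.map(lambda s: 14 + STATE_EXTRA[s])
    assert (fp.protected_length == expected).all()
    dev = fp.length - fp.protected_length
    assert dev.between(0, 2).all()
    assert (dev == fp.rnase_shift).all()
    assert t.length.between(6, 30).all()


def test_simulation_is_byte_deterministic(tiny_genome):
    genome, genes, _ = tiny_genome
    a = r.simulate_reads(genome, genes, [], r.WT_PROFILE, 2000, seed=11)
    b = r.simulate_reads(genome, genes, [], r.WT_PROFILE, 2000, seed=11)
    c = r.simulate_reads(genome, genes, [], r.WT_PROFILE, 2000, seed=12)
    assert a.fastq_text == b.fastq_text
    assert a.sam_text == b.sam_text
    assert a.truth.equals(b.truth)
    assert a.sam_text != c.sam_text


def test_truth_table_roundtrip(tmp_path, tiny_genome):
    genome, genes, _ = tiny_genome
    sim = r.simulate_reads(genome, genes, [], r.WT_PROFILE, 500, seed=13)
    path = tmp_path / "truth.tsv"
    r.write_truth(sim.truth, path)
    back = r.read_truth(path)
    pd.testing.assert_frame_equal(sim.truth, back)
    # empty table round-trips to a header-only file
    empty = sim.truth.iloc[:0]
    r.write_truth(empty, path)
    assert path.read_text().count("\n") == 1
    assert list(r.read_truth(path).columns) == list(sim.truth.columns)


def test_misincorporation_accounting(dgre_small):
    """3'-terminal G-to-A fraction of 18-nt site reads matches the rate."""
    ds = dgre_small
    rate_cfg = r.DGREAB_PROFILE.default_misincorporation_rate
    site_keys = {
        (p.position, p.strand) for p in ds.pauses if p.misincorporation_rate > 0
    }
    t = ds.sim.truth
    at_site = t.apply(lambda row: (row.pos3, row.strand) in site_keys, axis=1)
    sub = t[at_site & (t.length == 18)]
    n = len(sub)
    assert n > 1000
    frac = sub.misincorporated.mean()
    se = np.sqrt(rate_cfg * (1 - rate_cfg) / n)
    assert abs(frac - rate_cfg) <= 3 * se


def test_modal_length_contrast(wt_small, dgre_small):
    """Without Gre factors the protected fragments run longer (backtracking)."""
    from rnetseq.pause import modal_length, read_length_histogram

    m_wt = modal_length(read_length_histogram(wt_small.reads))
    m_dg = modal_length(read_length_histogram(dgre_small.reads))
    assert m_wt < m_dg


def test_misincorporated_reads_are_backtracked_with_mismatch_md(dgre_small):
    t = dgre_small.sim.truth
    mis = t[t.misincorporated == 1]
    assert len(mis) > 0
    assert mis.state.isin(["backtrack1", "backtrack2", "backtrack3"]).all()
    assert (mis.misinc_offset == "-1").all()
    assert (mis.length >= 16).all()
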