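#!/usr/bin/env python
"""Simulate both strains and characterise their read-length distributions.

Generates the wild-type and Gre-deletion datasets at the default study
conditions (20-kb genome, 40 planted pause motifs, strain-specific
translocation-state occupancies), writes them under results/data/, and
summarises the read-length histograms and the RNase T1 cut signature.

Finding to look for: the deletion strain's protected fragments run longer
(modal 18 nt vs 16 nt), the footprint of an enriched backtracked population,
and the base 5' of the trimmed read starts is G-enriched (T1 cuts GpN).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import BASE_SEED, DATA, N_READS, outpath

from rnetseq import experiments as X
from rnetseq.pause import modal_length, read_length_histogram, rnase_signature_fraction


def main():
    rows, sig_rows = [], []
    for i, strain in enumerate(("WT", "dGreAB")):
        ds = X.strain_dataset(strain, N_READS[strain], seed=BASE_SEED + 11 + 2 * i)
        X.save_dataset(ds, DATA / strain)
        hist = read_length_histogram(ds.reads)
        for L, c in hist.items():
            rows.append({"strain": strain, "length": L, "count": c})
        mode = modal_length(hist)
        comp = rnase_signature_fraction(
            [a for a in ds.reads if a.length < 21], ds.genome
        )
        sig_rows.append({"strain": strain, **comp})
        print(
            f"{strain}: {len(ds.reads)} reads, modal length {mode} nt, "
            f"G 5' of trimmed read starts {comp['G']:.2f}"
        )
    pd.DataFrame(rows).to_csv(outpath("read_length_distributions.tsv"),
                              sep="\t", index=False)
    pd.DataFrame(sig_rows).to_csv(outpath("rnase_cut_signature.tsv"),
                                  sep="\t", index=False, float_format="%.4f")
    print("wrote read_length_distributions.tsv and rnase_cut_signature.tsv")


if __name__ == "__main__":
    main()
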