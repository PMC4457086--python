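"""Shared settings for the numbered analysis drivers.

Every driver reads/writes under ``results/`` relative to the repository
root and uses one base seed, so the whole analysis reruns reproducibly with
``for f in analysis/0*.py; do python "$f"; done``.
"""

from pathlib import Path

BASE_SEED = 173
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
#: bulky intermediate datasets (FASTQ/SAM/truth) live outside the results
#: tables, under scratch/
DATA = ROOT / "scratch" / "analysis_data"

N_READS = {"WT": 150_000, "dGreAB": 400_000}


def outpath(name: str) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS / name
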