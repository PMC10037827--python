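"""Shared plumbing for the numbered analysis drivers.

The study-condition cohort is regenerated deterministically on demand so
each driver can run standalone; the root seed below fixes the cohort all
drivers analyze.
"""

from pathlib import Path

import symnetmap as sn

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

COHORT_SEED = 20260921


def get_cohort() -> sn.Cohort:
    return sn.generate_cohort(sn.study_config(rng_seed=COHORT_SEED))


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
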