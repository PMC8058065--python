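"""Shared access to the analysis cohort.

`01_simulate_cohort.py` writes the fixture under scratch/cohort; later
scripts load it from there, or regenerate it in memory with the same seed if
the scratch copy is missing, so every script can be run on its own.
"""

from pathlib import Path

from enhancerome.synthetic import CohortConfig, load_fixture, simulate_cohort

ANALYSIS_SEED = 17
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def get_cohort():
    if (SCRATCH / "config.json").exists():
        return load_fixture(SCRATCH)
    return simulate_cohort(CohortConfig(rng_seed=ANALYSIS_SEED))
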