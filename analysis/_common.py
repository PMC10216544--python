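"""Shared plumbing for the analysis drivers: one seeded cohort on disk."""

from pathlib import Path

from cdr3profile.io import read_rearrangements
from cdr3profile.simulate import SimulationConfig, simulate_cohort, write_truth
from cdr3profile.io import write_metadata, write_rearrangements
from cdr3profile.translate import translate_cohort

SEED = 20230825
RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_DIR = RESULTS / "cohort"


def ensure_cohort():
    """Generate the default synthetic cohort once; later drivers re-read it
    from disk like any rearrangement export."""
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    tsv = COHORT_DIR / "rearrangements.tsv"
    if not tsv.exists():
        cohort, truth = simulate_cohort(SimulationConfig(seed=SEED))
        write_rearrangements(cohort, tsv)
        write_metadata(cohort, COHORT_DIR / "metadata.tsv")
        write_truth(truth, COHORT_DIR / "truth.json")
    cohort = read_rearrangements(tsv, metadata=COHORT_DIR / "metadata.tsv")
    return translate_cohort(cohort)
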