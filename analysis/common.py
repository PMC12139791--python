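"""Shared cohort definition for the numbered analysis drivers.

Every driver regenerates the same synthetic cohort deterministically from a
seed, so each script is runnable standalone and the chain stays consistent.
The cohort emulates the study design at desk scale: paired MA/placebo
sessions, rest + two doors runs + one MID run per session, per-session task
behavior, and a small planted rate of QC failures.
"""

from pathlib import Path

import connshift as cs

RESULTS = Path(__file__).resolve().parent.parent / "results"
DEFAULT_SEED = 1

N_SUBJECTS = 20
N_NODES = 40


def cohort_config(seed: int = DEFAULT_SEED) -> cs.SynthConfig:
    return cs.SynthConfig(
        n_subjects=N_SUBJECTS,
        n_nodes=N_NODES,
        run_types=("rest", "doors", "mid"),
        include_behavior=True,
        qc_fail_frac=0.05,
        seed=seed,
    )


def make_cohort(seed: int = DEFAULT_SEED) -> cs.GeneratedDataset:
    return cs.gen_condition_dataset(cohort_config(seed))


def ensure_results() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
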