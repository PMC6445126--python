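"""Shared study configuration for the numbered analysis scripts.

One discovery cohort and one validation cohort (300 tumors each) over the
244-gene splicing-factor panel with the 61-gene suppressor and 24-gene
enhancer modules planted, 1000 background genes with graded module
coupling, 114 matched tumor/normal pairs, survival tied to module activity
(gamma = 0.5), and 50 isoform-switch genes.  Everything is deterministic
given STUDY_SEED, so each script can regenerate the cohorts independently.
"""

from pathlib import Path

from sfcomod.synthetic import SyntheticConfig, generate_cohort, generate_validation_cohort

STUDY_SEED = 20260921
RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY_CONFIG = SyntheticConfig(
    n_samples=300,
    n_background=1000,
    n_null_background=200,
    n_matched_pairs=114,
    seed=STUDY_SEED,
)


def get_discovery():
    return generate_cohort(STUDY_CONFIG)


def get_validation(discovery):
    return generate_validation_cohort(discovery.truth, STUDY_CONFIG, n_drop=9)


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
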