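"""Shared study conditions for the analysis drivers.

One exposure (a PM2.5-like continuous trait), three candidate mediators —
two real (a*b of 0.2 and 0.1 on the first outcome) and one null — and two
binary outcomes standing in for the 90th/99th survival-percentile longevity
phenotypes.
"""

from pathlib import Path

from mrkit.simulate import StudyConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
BUNDLE_DIR = RESULTS / "synthetic"

MEDIATORS = ("mediator_strong", "mediator_null", "mediator_weak")
OUTCOMES = ("longevity_90th", "longevity_99th")


def study_config(seed: int) -> StudyConfig:
    return StudyConfig(
        seed=seed,
        a=(0.5, 0.0, 0.4),
        b=((0.4, 0.3), (0.3, 0.2), (0.25, 0.2)),
        c_prime=(0.1, 0.05),
        mediator_labels=MEDIATORS,
        outcome_labels=OUTCOMES,
    )


def bundle_paths() -> dict:
    paths = {label: str(BUNDLE_DIR / f"{label}.tsv")
             for label in ("exposure",) + MEDIATORS + OUTCOMES}
    paths["__ld__"] = str(BUNDLE_DIR / "ld.tsv")
    return paths
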