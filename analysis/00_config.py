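"""Shared settings for the analysis drivers.

The synthetic cohorts stand in for the two study cohorts: a training cohort
of 12 coeliac patients (5 on a gluten-free diet) and 8 controls, and an
independent testing cohort drawing planted sequences from the same
published catalog.  All drivers write under results/.
"""

from pathlib import Path

from ced_tcr.simulate import SyntheticConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

TRAIN_SEED = 20230
TEST_SEED = 20231
ANALYSIS_SEED = 11

CHAIN_SETS = {"TCR-a": ("TRA",), "TCR-b": ("TRB",), "combined": ("TRA", "TRB")}

BOOTSTRAP_B = 1000


def training_config() -> SyntheticConfig:
    return SyntheticConfig(seed=TRAIN_SEED)


def testing_config() -> SyntheticConfig:
    # the published testing cohort: 9 untreated CeD patients, 6 controls
    return SyntheticConfig(
        n_ced_gcd=9, n_ced_gfd=0, n_controls=6, seed=TEST_SEED
    )
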