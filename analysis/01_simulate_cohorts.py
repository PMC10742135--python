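"""Generate the training and testing cohorts used by all later drivers.

Writes AIRR-dialect clonotype tables, manifests, the shared gluten-specific
sequence catalog and the planting ground truth under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import importlib

config = importlib.import_module("00_config")

from ced_tcr.simulate import generate_cohort, write_cohort


def main():
    train, catalog, train_truth = generate_cohort(
        config.training_config(), name="training"
    )
    write_cohort(train, catalog, train_truth, config.DATA / "training")
    test, _, test_truth = generate_cohort(
        config.testing_config(), name="testing", catalog=catalog
    )
    write_cohort(test, catalog, test_truth, config.DATA / "testing")
    for cohort, truth in ((train, train_truth), (test, test_truth)):
        n_ced = sum(1 for v in truth.labels.values() if v == "CeD")
        n_ctl = len(truth.labels) - n_ced
        clones = [r.n_clones for r in cohort.repertoires]
        print(
            f"{cohort.name}: {n_ced} CeD + {n_ctl} controls, "
            f"clones/sample {min(clones)}-{max(clones)} "
            f"(mean {sum(clones) // len(clones)}); "
            f"planted TRA sequences: {len(truth.planted.get('TRA', ()))}"
        )
    print(f"written under {config.DATA}")


if __name__ == "__main__":
    main()
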