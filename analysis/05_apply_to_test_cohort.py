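"""Apply the trained models to the independent testing cohort.

Predictions are made blinded to labels; labels are used afterwards for
evaluation and for per-sequence counts of test CeD samples carrying each
predictive sequence below the threshold.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import importlib

config = importlib.import_module("00_config")

from ced_tcr import apply_model, load_model, read_cohort


def main():
    out = config.RESULTS / "test"
    out.mkdir(parents=True, exist_ok=True)
    test = read_cohort(config.DATA / "testing" / "manifest.tsv", "airr")
    for name in config.CHAIN_SETS:
        model = load_model(config.RESULTS / "train" / f"model_{name}.json")
        report = apply_model(test, model)
        pd.DataFrame(
            [{"sample_id": s, "prediction": p}
             for s, p in report.predictions.items()]
        ).to_csv(out / f"predictions_{name}.tsv", sep="\t", index=False)
        rows = [
            {"chain": ch, "sequence": s, "testing_ced_samples": n,
             "confirmed": s in report.confirmed[ch]}
            for ch, counts in report.testing_counts.items()
            for s, n in sorted(counts.items())
        ]
        pd.DataFrame(rows).to_csv(out / f"testing_counts_{name}.tsv",
                                  sep="\t", index=False)
        ev = report.evaluation
        n_conf = sum(len(v) for v in report.confirmed.values())
        print(
            f"{name}: testing accuracy {ev.accuracy:.2f} "
            f"(sensitivity {ev.sensitivity:.2f}, "
            f"specificity {ev.specificity:.2f}); "
            f"{n_conf} sequences confirmed in test CeD samples only"
        )


if __name__ == "__main__":
    main()
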