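"""Prioritise candidate coeliac-predictive sequences.

Sequences confirmed in the testing cohort (present below threshold in >= 1
test CeD sample, absent from test controls) are ranked by testing CeD count,
then training CeD count, with '='-suffixed shared labels for ties — the
short list with the highest diagnostic potential.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import importlib

config = importlib.import_module("00_config")

from ced_tcr import load_model, rank_candidate_sequences


def main():
    out = config.RESULTS / "prioritise"
    out.mkdir(parents=True, exist_ok=True)
    for name in config.CHAIN_SETS:
        model = load_model(config.RESULTS / "train" / f"model_{name}.json")
        counts = pd.read_csv(
            config.RESULTS / "test" / f"testing_counts_{name}.tsv", sep="\t"
        )
        for ch in model.chains:
            sub = counts[(counts["chain"] == ch) & counts["confirmed"]]
            training = model.metadata["training_counts"][ch]
            fold_counts = {}
            fc_path = config.RESULTS / "cv" / f"fold_counts_{name}.tsv"
            if fc_path.exists():
                fc = pd.read_csv(fc_path, sep="\t")
                fold_counts = dict(
                    fc[fc["chain"] == ch][["sequence", "folds_selected"]].values
                )
            table = rank_candidate_sequences(
                {s: training.get(s, 0) for s in sub["sequence"]},
                {s: int(fold_counts.get(s, 0)) for s in sub["sequence"]},
                dict(sub[["sequence", "testing_ced_samples"]].values),
            )
            frame = table.to_frame()
            frame.to_csv(out / f"ranking_{name}_{ch}.tsv", sep="\t",
                         index=False)
            print(f"{name} / {ch}: {len(frame)} confirmed candidates; top 3:")
            print(frame.head(3).to_string(index=False))


if __name__ == "__main__":
    main()
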