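"""Train the ranked-frequency classifier on the training cohort.

For each chain configuration (TCR-a alone, TCR-b alone, combined) the
threshold grid is scanned, bootstrap CIs computed over the max-accuracy
plateau, the working threshold chosen, and the coeliac-predictive sequence
set selected.  Models and scan tables go to results/train/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import importlib

config = importlib.import_module("00_config")

from ced_tcr import read_catalog, read_cohort, save_model, train_model
from ced_tcr.classifier import motif_matrix


def main():
    out = config.RESULTS / "train"
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(config.DATA / "training" / "manifest.tsv", "airr")
    catalog = read_catalog(config.DATA / "training" / "catalog.tsv")
    for name, chains in config.CHAIN_SETS.items():
        result = train_model(
            cohort, catalog, chains=chains, B=config.BOOTSTRAP_B,
            seed=config.ANALYSIS_SEED,
        )
        save_model(result.model, out / f"model_{name}.json")
        result.scan.to_frame().to_csv(
            out / f"threshold_scan_{name}.tsv", sep="\t", index=False
        )
        n_sel = {ch: len(result.model.sequences[ch]) for ch in chains}
        print(
            f"{name}: plateau {result.scan.plateau[0]:g}-"
            f"{result.scan.plateau[-1]:g}, chosen t={result.model.threshold:g}, "
            f"training accuracy {result.evaluation.accuracy:.2f}, "
            f"selected {n_sel}"
        )
        for ch in chains:
            seqs = result.model.sequences[ch]
            lengths = sorted({len(s) for s in seqs})
            mid = lengths[len(lengths) // 2] if lengths else None
            if mid:
                motif_matrix(seqs, mid).to_csv(
                    out / f"motif_{name}_{ch}_len{mid}.tsv", sep="\t"
                )


if __name__ == "__main__":
    main()
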