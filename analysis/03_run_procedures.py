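"""Run the five decoding procedures on the extracted samples.

Leave-one-block-out cross-validation on identical folds for every
procedure; RFA procedures nest an inner leave-one-block-out loop.  The
top-k filter is scaled to the simulated voxel count (150 of 300 voxels,
mirroring the specific-filter role of 1000 voxels within a brain mask).
Writes per-procedure balanced and class accuracies to results/.
"""

from pathlib import Path

import pandas as pd

from mazemvpa.evaluation import PROCEDURES, run_procedure
from mazemvpa.io import read_sampleset

ROOT = Path(__file__).resolve().parent.parent / "results"
TOPK = 150


def main():
    rows = []
    for name in ("exploration", "imagery"):
        samples = read_sampleset(ROOT / "subject01" / f"{name}_samples")
        for pid, config in PROCEDURES.items():
            res = run_procedure(samples, config, seed=0, topk=TOPK)
            rows.append(
                {
                    "session": name,
                    "procedure": pid,
                    "balanced_accuracy": res.balanced_accuracy,
                    **{f"acc_{c}": v for c, v in res.class_accuracies.items()},
                    "mean_n_features": sum(res.n_features) / len(res.n_features),
                }
            )
            print(
                f"{name} P{pid}: balanced accuracy "
                f"{100 * res.balanced_accuracy:.2f}%, "
                f"~{rows[-1]['mean_n_features']:.0f} features/fold"
            )
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "procedure_accuracies.csv", index=False)
    print(f"\nwrote {ROOT / 'procedure_accuracies.csv'}")


if __name__ == "__main__":
    main()
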