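"""Within-block permutation significance of the decoding accuracies.

For procedure 1 on each session, training labels are permuted within each
block (100 permutations per cross-validation step: 1500 shuffles for the
15-fold exploration session, 900 for the 9-fold imagery session) and the
whole procedure — feature selection included — is rerun to build the null.
"""

import json
from pathlib import Path

from mazemvpa.evaluation import PROCEDURES, permutation_test
from mazemvpa.io import read_sampleset

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    out = {}
    for name in ("exploration", "imagery"):
        samples = read_sampleset(ROOT / "subject01" / f"{name}_samples")
        perm = permutation_test(samples, PROCEDURES[1], n_perm=100, seed=0, topk=150)
        out[name] = {
            "observed_balanced_accuracy": perm.observed,
            "p_value": perm.p_value,
            "null_mean": float(perm.null_values.mean()),
            "n_perm": perm.n_perm,
            "total_shuffles": perm.total_shuffles,
        }
        print(
            f"{name}: observed {100 * perm.observed:.2f}%, "
            f"null mean {100 * out[name]['null_mean']:.2f}%, "
            f"p = {perm.p_value:.4f} ({perm.total_shuffles} shuffles)"
        )
    (ROOT / "permutation_significance.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
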