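"""Simulate one synthetic subject: exploration and imagery sessions.

Writes events (TSV), BOLD series (NIfTI), and motion regressors for both
sessions under results/subject01/.  The exploration session is the paced
maze traversal (15 blocks, 135 events per category); the imagery session
has 54 self-paced recall paths with category-dependent recall probability
(1.0 / 0.65 / 0.93), reproducing the behavioural class imbalance.
"""

from pathlib import Path

import mazemvpa as mz
from mazemvpa.io import write_events, write_motion, write_series
from mazemvpa.synthdata import AcquisitionParams, make_activation_patterns, required_scans

SEED = 0
N_VOXELS = 300
N_INFORMATIVE = 20
OUT = Path(__file__).resolve().parent.parent / "results" / "subject01"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    sessions = {
        "exploration": (mz.make_exploration_design(n_repetitions=5, seed=SEED), 0.05),
        "imagery": (mz.make_imagery_design(n_tests=54, seed=SEED), 0.04),
    }
    for name, (events, effect) in sessions.items():
        params = AcquisitionParams(
            tr=2.04, n_scans=required_scans(events, 2.04), n_voxels=N_VOXELS
        )
        patterns = make_activation_patterns(
            N_VOXELS, N_INFORMATIVE, effect, seed=SEED + 1000
        )
        sim = mz.simulate_bold(events, patterns, params, seed=SEED + 2000)
        write_events(events, OUT / f"{name}_events.tsv")
        write_series(sim.data, params.tr, OUT / f"{name}_bold.nii.gz")
        write_motion(sim.motion, OUT / f"{name}_motion.txt")
        print(
            f"{name}: {len(events)} events, {params.n_scans} scans, "
            f"{events['block'].nunique() if name == 'exploration' else events['path'].nunique()} "
            f"{'blocks' if name == 'exploration' else 'paths'}"
        )


if __name__ == "__main__":
    main()
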