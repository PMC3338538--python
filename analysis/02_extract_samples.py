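"""Confound regression and event-window signal extraction.

Reads the simulated subject from results/subject01/, regresses out motion
and low-frequency drifts (1/128 Hz cutoff), and averages delay-corrected
windows (6 s haemodynamic delay; 3 s windows for paced events, up to 2
scans before each key press for imagery).  Writes SampleSet files.
"""

from pathlib import Path

import mazemvpa as mz
from mazemvpa.io import read_events, read_motion, read_series, write_sampleset

OUT = Path(__file__).resolve().parent.parent / "results" / "subject01"


def main():
    for name in ("exploration", "imagery"):
        events = read_events(OUT / f"{name}_events.tsv")
        series, tr = read_series(OUT / f"{name}_bold.nii.gz")
        motion = read_motion(OUT / f"{name}_motion.txt")
        clean = mz.regress_confounds(series, motion, tr)
        if name == "exploration":
            samples = mz.extract_exploration_samples(clean, events, tr)
        else:
            samples = mz.extract_imagery_samples(clean, events, tr)
        write_sampleset(samples, OUT / f"{name}_samples")
        kept = samples.n_samples
        print(
            f"{name}: {kept}/{len(events)} events kept "
            f"({len(events) - kept} dropped by window/overlap rules)"
        )


if __name__ == "__main__":
    main()
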