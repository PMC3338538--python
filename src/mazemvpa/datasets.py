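"""Published per-subject behavioural tables used as inputs.

Two small tables accompany the study design: the number of events each of
the 16 subjects produced per category during the mental-imagery session
(the class-imbalance data), and each subject's percentage of correct
answers per category in the memory test performed outside the scanner.
They are reproduced here verbatim as package data so the group-level
statistics can be recomputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import CATEGORIES

_SUBJECTS = [f"S{i}" for i in range(1, 17)]

# events per category recalled during mental imagery, per subject
_IMAGERY_EVENT_COUNTS = np.array(
    [
        [69, 30, 57],
        [52, 43, 76],
        [76, 11, 51],
        [47, 58, 50],
        [63, 50, 54],
        [74, 42, 72],
        [65, 43, 57],
        [70, 36, 63],
        [43, 31, 33],
        [67, 44, 64],
        [18, 32, 33],
        [37, 20, 24],
        [69, 31, 68],
        [51, 22, 41],
        [55, 58, 56],
        [77, 53, 68],
    ],
    dtype=float,
)

# % correct answers in the post-scan memory test, per subject
_MEMORY_TEST_SCORES = np.array(
    [
        [48.9, 35.6, 46.7],
        [55.6, 11.1, 28.9],
        [55.6, 42.2, 64.4],
        [75.6, 53.3, 68.9],
        [68.9, 51.1, 73.3],
        [62.2, 31.1, 46.7],
        [77.8, 55.6, 75.6],
        [77.8, 42.2, 68.9],
        [71.1, 57.8, 71.1],
        [51.1, 22.2, 51.1],
        [55.6, 42.2, 64.4],
        [53.3, 8.9, 35.6],
        [55.6, 42.2, 57.8],
        [40.0, 15.6, 48.9],
        [62.2, 42.2, 51.1],
        [64.4, 42.2, 46.7],
    ],
    dtype=float,
)


def load_imagery_event_counts() -> pd.DataFrame:
    """Per-subject event counts by category from the imagery session."""
    return pd.DataFrame(_IMAGERY_EVENT_COUNTS, index=_SUBJECTS, columns=CATEGORIES)


def load_memory_test_scores() -> pd.DataFrame:
    """Per-subject % correct by category in the post-scan memory test."""
    return pd.DataFrame(_MEMORY_TEST_SCORES, index=_SUBJECTS, columns=CATEGORIES)
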