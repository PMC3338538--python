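"""Event-wise signal extraction.

The session time series is first cleaned by regressing out motion estimates
and low-frequency drifts (discrete-cosine high-pass, cutoff 1/128 Hz), once
for the whole session.  Event samples are then formed by averaging scans in
delay-corrected windows: the haemodynamic response peaks roughly 6 s after
stimulus onset, so a window of stimulus duration shifted by that delay is
averaged for paced events, while self-paced events use the interval between
consecutive key presses (at most 2 scans), excluding any scan that two
different events could claim.

Scan-to-window assignment conventions (the acquisition geometry does not
divide evenly into stimulus timing):

* paced (exploration) events: a scan belongs to the window when its
  acquisition *midpoint* k*tr + tr/2 falls in [onset+delay, onset+delay+window);
* self-paced (imagery) events: a scan is a candidate when its acquisition
  *span* [k*tr, (k+1)*tr) overlaps the delay-corrected inter-keypress
  interval; a scan whose span overlaps two events' intervals is excluded
  from both, so no TR ever mixes two stimuli.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_HIGHPASS = 1.0 / 128.0


@dataclass
class SampleSet:
    """Per-event feature matrix with labels, block ids and scan provenance."""

    X: np.ndarray
    labels: np.ndarray
    blocks: np.ndarray
    scan_indices: list = field(default_factory=list)
    event_index: np.ndarray | None = None
    dropped_events: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.blocks = np.asarray(self.blocks, dtype=int)
        n = self.X.shape[0]
        if len(self.labels) != n or len(self.blocks) != n:
            raise ValueError("one label and one block id per sample row required")
        if self.scan_indices:
            seen = {}
            for s, scans in enumerate(self.scan_indices):
                for k in scans:
                    if k in seen:
                        raise ValueError(
                            f"scan {k} assigned to samples {seen[k]} and {s}"
                        )
                    seen[k] = s

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def subset(self, mask: np.ndarray) -> "SampleSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SampleSet(
            X=self.X[idx],
            labels=self.labels[idx],
            blocks=self.blocks[idx],
            scan_indices=[self.scan_indices[i] for i in idx] if self.scan_indices else [],
            event_index=self.event_index[idx] if self.event_index is not None else None,
        )


def dct_highpass_basis(n_scans: int, tr: float, cutoff: float = DEFAULT_HIGHPASS):
    """Discrete-cosine basis spanning frequencies below ``cutoff`` Hz.

    Column k (k = 1..K) is cos(pi*k*(t+0.5)/N); its frequency is k/(2*N*tr),
    so K = floor(2 * N * tr * cutoff) columns are needed to reach the cutoff.
    """
    total = n_scans * tr
    k_max = int(np.floor(2.0 * total * cutoff))
    t = np.arange(n_scans)
    if k_max < 1:
        return np.empty((n_scans, 0))
    return np.column_stack(
        [np.cos(np.pi * k * (t + 0.5) / n_scans) for k in range(1, k_max + 1)]
    )


def regress_confounds(
    series: np.ndarray,
    motion_regressors: np.ndarray | None,
    tr: float,
    highpass_cutoff: float = DEFAULT_HIGHPASS,
) -> np.ndarray:
    """Residualize each voxel on [intercept, motion, DCT high-pass basis].

    Ordinary least squares via a pseudo-inverse, so a rank-deficient confound
    matrix degrades gracefully (with a warning) instead of failing.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    cols = [np.ones((n, 1))]
    if motion_regressors is not None:
        motion_regressors = np.asarray(motion_regressors, dtype=float)
        if motion_regressors.shape[0] != n:
            raise ValueError("motion regressors need one row per scan")
        m = motion_regressors - motion_regressors.mean(axis=0)
        sd = m.std(axis=0)
        sd[sd == 0] = 1.0
        cols.append(m / sd)
    cols.append(dct_highpass_basis(n, tr, highpass_cutoff))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"confound matrix is rank deficient ({rank} < {X.shape[1]}); "
            "using a pseudo-inverse fit",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(X, series, rcond=None)
    return series - X @ beta


def extract_exploration_samples(
    series: np.ndarray,
    events: pd.DataFrame,
    tr: float,
    hrf_delay: float = 6.0,
    window: float = 3.0,
) -> SampleSet:
    """One sample per paced event: average of scans whose midpoints fall in
    [onset + hrf_delay, onset + hrf_delay + window)."""
    series = np.asarray(series, dtype=float)
    n_scans = series.shape[0]
    mid = (np.arange(n_scans) + 0.5) * tr
    rows, labels, blocks, prov, kept, dropped = [], [], [], [], [], []
    for i, ev in events.reset_index(drop=True).iterrows():
        start = ev["onset"] + hrf_delay
        end = start + window
        if end > n_scans * tr:
            logger.warning("event %d window extends past the run; dropped", i)
            dropped.append(i)
            continue
        scans = np.flatnonzero((mid >= start) & (mid < end))
        if len(scans) == 0:
            logger.warning("event %d window contains no scan midpoint; dropped", i)
            dropped.append(i)
            continue
        rows.append(series[scans].mean(axis=0))
        labels.append(ev["trial_type"])
        blocks.append(int(ev["block"]))
        prov.append(list(map(int, scans)))
        kept.append(i)
    return SampleSet(
        X=np.asarray(rows).reshape(len(rows), -1),
        labels=np.asarray(labels),
        blocks=np.asarray(blocks, dtype=int),
        scan_indices=prov,
        event_index=np.asarray(kept, dtype=int),
        dropped_events=dropped,
    )


def _imagery_windows(events: pd.DataFrame, hrf_delay: float):
    """Delay-corrected averaging interval per self-paced event.

    The interval runs from the previous key press of the same path (or the
    event onset for the first event of a path) to this event's key press,
    both shifted by the haemodynamic delay.
    """
    win = []
    prev_kp_by_path: dict = {}
    for _, ev in events.iterrows():
        path = ev["path"]
        start = max(ev["onset"], prev_kp_by_path.get(path, -np.inf))
        win.append((start + hrf_delay, ev["response_time"] + hrf_delay))
        prev_kp_by_path[path] = ev["response_time"]
    return win


def extract_imagery_samples(
    series: np.ndarray,
    events: pd.DataFrame,
    tr: float,
    hrf_delay: float = 6.0,
    max_scans: int = 2,
) -> SampleSet:
    """One sample per recalled image, from scans preceding its key press.

    Candidate scans are those whose acquisition span overlaps the
    delay-corrected interval between consecutive key presses; any scan
    claimed by two events is excluded from both, and at most ``max_scans``
    scans (the last ones before the delay-corrected key press) are averaged.
    Events left without scans yield no sample.
    """
    series = np.asarray(series, dtype=float)
    n_scans = series.shape[0]
    events = events.reset_index(drop=True)
    windows = _imagery_windows(events, hrf_delay)

    candidates = []
    claim_count = np.zeros(n_scans, dtype=int)
    for start, end in windows:
        k_lo = max(int(np.floor(start / tr)), 0)
        k_hi = min(int(np.ceil(end / tr)), n_scans)
        scans = [k for k in range(k_lo, k_hi) if k * tr < end and (k + 1) * tr > start]
        candidates.append(scans)
        for k in scans:
            claim_count[k] += 1

    rows, labels, blocks, prov, kept, dropped = [], [], [], [], [], []
    for i, ev in events.iterrows():
        scans = [k for k in candidates[i] if claim_count[k] == 1]
        scans = scans[-max_scans:]
        if not scans:
            logger.info("imagery event %d has no usable scan; dropped", i)
            dropped.append(i)
            continue
        rows.append(series[scans].mean(axis=0))
        labels.append(ev["trial_type"])
        blocks.append(int(ev["block"]))
        prov.append(scans)
        kept.append(i)
    return SampleSet(
        X=np.asarray(rows).reshape(len(rows), -1),
        labels=np.asarray(labels),
        blocks=np.asarray(blocks, dtype=int),
        scan_indices=prov,
        event_index=np.asarray(kept, dtype=int),
        dropped_events=dropped,
    )
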