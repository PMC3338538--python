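"""Synthetic two-session fMRI generator.

Emulates the statistical structure of the two scanning sessions the decoding
pipeline targets:

* an *exploration* session — a paced traversal of a two-dimensional maze in
  which three blocks of 27 stimuli (9 faces, 9 buildings, 9 animals, always
  in that order) are shown for 3 s each, separated by 15-18 s fixation, the
  whole maze being repeated five times (TR = 2.04 s);
* a *mental imagery* session — 54 self-paced recall paths of 3-6 same-category
  images, each recalled image signalled by a key press, with event durations
  between 200 and 4000 ms.  Class imbalance arises from category-specific
  recall probability (buildings are recalled least reliably).

The forward model is the standard linear BOLD model: per-category boxcars
convolved with a canonical double-gamma haemodynamic response, scaled by
per-voxel category amplitude maps, plus low-frequency drift, motion-coupled
nuisance signal and AR(1) Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .constants import CATEGORIES

EVENT_COLUMNS = ["onset", "duration", "trial_type", "block", "response_time", "path"]

#: mean baseline signal, in scanner units; effect sizes are expressed
#: relative to the noise standard deviation, not to this baseline
BASELINE = 100.0


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner timing and geometry.

    tr is the volume repetition time in seconds (default 2.04 s).  The
    canonical double-gamma response peaks at ``hrf_peak`` seconds with an
    undershoot at ``hrf_undershoot`` seconds.
    """

    tr: float = 2.04
    n_scans: int = 300
    n_voxels: int = 1000
    hrf_peak: float = 6.0
    hrf_undershoot: float = 16.0
    hrf_ratio: float = 1.0 / 6.0

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_scans < 1 or self.n_voxels < 1:
            raise ValueError("n_scans and n_voxels must be >= 1")

    @property
    def duration(self) -> float:
        return self.n_scans * self.tr

    def scan_midpoints(self) -> np.ndarray:
        """Acquisition midpoint of each volume, k*tr + tr/2."""
        return (np.arange(self.n_scans) + 0.5) * self.tr


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise components of the simulated series.

    white_sd is the marginal standard deviation of the AR(1) noise;
    ar1_coef its lag-one autocorrelation.  drift_amp scales slow cosine
    drifts (removed by the 1/128 Hz high-pass), motion_amp scales the
    coupling of the six motion regressors into the voxel signal.
    """

    white_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_amp: float = 2.0
    motion_amp: float = 0.5


@dataclass
class ActivationPatterns:
    """Per-category voxel amplitude maps (voxels x 3, column order CATEGORIES)."""

    maps: np.ndarray
    n_informative: int
    effect_size: float
    overlap_fraction: float

    @property
    def informative(self) -> dict:
        """Indices of nonzero voxels per category."""
        return {
            c: np.flatnonzero(self.maps[:, j]) for j, c in enumerate(CATEGORIES)
        }


def hrf_double_gamma(t, peak=6.0, undershoot=16.0, ratio=1.0 / 6.0):
    """Canonical double-gamma haemodynamic response, unit peak amplitude."""
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak) - ratio * stats.gamma.pdf(t, undershoot)
    peak_val = h.max()
    if peak_val > 0:
        h = h / peak_val
    return h


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_COLUMNS)


def validate_events(events: pd.DataFrame, session_type: str | None = None) -> None:
    """Check the event-table invariants; raise ValueError on violation."""
    missing = {"onset", "duration", "trial_type", "block"} - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if len(events) == 0:
        return
    onsets = events["onset"].to_numpy(float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError("onsets must be non-decreasing")
    if np.any(events["duration"].to_numpy(float) <= 0):
        raise ValueError("durations must be positive")
    bad = set(events["trial_type"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    if session_type == "imagery":
        rt = events["response_time"].to_numpy(float)
        if np.any(~np.isfinite(rt)) or np.any(rt < onsets):
            raise ValueError("imagery events need response_time >= onset")


def make_exploration_design(
    params: AcquisitionParams | None = None,
    fixation_range: tuple[float, float] = (15.0, 18.0),
    n_repetitions: int = 5,
    n_blocks: int = 3,
    n_per_category: int = 9,
    stim_duration: float = 3.0,
    isi: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Event table for the paced maze-exploration session.

    Each traversal of the maze is ``n_blocks`` blocks of consecutive stimuli
    (9 faces, then 9 buildings, then 9 animals by default), 3 s each with no
    gap inside a block; a fixation interval drawn uniformly from
    ``fixation_range`` precedes every block.  The traversal is repeated
    ``n_repetitions`` times and ``block`` enumerates blocks across the whole
    session, so the default design has 3 x 5 = 15 blocks and 135 events of
    each category.

    ``isi`` inserts a gap after each stimulus (0 in the paced design, where
    stimuli follow each other without rest); nonzero values produce a
    slow-event-related variant whose haemodynamic responses do not overlap,
    useful as a separable control condition.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    if n_blocks < 1 or n_per_category < 1:
        raise ValueError("n_blocks and n_per_category must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    block = 0
    for _rep in range(n_repetitions):
        for _b in range(n_blocks):
            t += rng.uniform(*fixation_range)
            for cat in CATEGORIES:
                for _ in range(n_per_category):
                    rows.append((t, stim_duration, cat, block, np.nan, np.nan))
                    t += stim_duration + isi
            block += 1
    ev = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    validate_events(ev, "exploration")
    return ev


def _balanced_path_lengths(n_paths: int, lo: int, hi: int) -> np.ndarray:
    # cycle pairs summing to lo+hi so any even truncation keeps the mean at
    # (lo+hi)/2; for the default (3,6) grid the cycle is 3,6,4,5
    pool = []
    vals = list(range(lo, hi + 1))
    pairs = [(vals[i], vals[-1 - i]) for i in range(len(vals) // 2)]
    if len(vals) % 2:
        pairs.append((vals[len(vals) // 2], vals[len(vals) // 2]))
    while len(pool) < n_paths:
        for a, b in pairs:
            pool.extend([a, b])
    return np.asarray(pool[:n_paths])


def make_imagery_design(
    n_tests: int = 54,
    path_length_range: tuple[int, int] = (3, 6),
    recall_prob: tuple[float, float, float] = (1.0, 0.65, 0.93),
    duration_range: tuple[float, float] = (0.2, 4.0),
    inter_test_interval: float = 6.0,
    jitter_range: tuple[float, float] = (0.0, 0.5),
    paths_per_block: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Event table for the self-paced mental-imagery session.

    ``n_tests`` recall paths are generated, one category per path, categories
    balanced across paths and path lengths cycling through
    ``path_length_range`` so the planned number of images per category is
    equal (mean path length 4.5 for the default 3-6 range).  Each planned
    image is actually recalled — and so emitted as an event — with
    probability ``recall_prob[category]``; this per-image Bernoulli recall is
    the imbalance mechanism (the defaults reproduce the roughly 39/25/36 %
    category proportions observed behaviourally).  Durations are drawn
    log-uniformly from ``duration_range`` (seconds), so most events last less
    than 2 s; the key press falls at the event end, and consecutive events
    within a path are separated by a small uniform jitter.  Paths are grouped
    into blocks of ``paths_per_block`` consecutive paths.
    """
    recall_prob = tuple(float(p) for p in recall_prob)
    if len(recall_prob) != 3 or any(not 0 <= p <= 1 for p in recall_prob):
        raise ValueError("recall_prob must be three probabilities in [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    lo, hi = path_length_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid path_length_range")
    rng = np.random.default_rng(seed)

    n_per_cat = [n_tests // 3 + (1 if i < n_tests % 3 else 0) for i in range(3)]
    cats = []
    lengths = []
    for i, cat in enumerate(CATEGORIES):
        cats.extend([cat] * n_per_cat[i])
        lengths.extend(_balanced_path_lengths(n_per_cat[i], lo, hi))
    order = rng.permutation(n_tests)
    cats = [cats[i] for i in order]
    lengths = np.asarray(lengths)[order]

    p_by_cat = dict(zip(CATEGORIES, recall_prob))
    log_lo, log_hi = np.log(duration_range[0]), np.log(duration_range[1])
    rows = []
    t = inter_test_interval
    for path_id in range(n_tests):
        cat = cats[path_id]
        block = path_id // paths_per_block
        for _img in range(lengths[path_id]):
            recalled = rng.uniform() < p_by_cat[cat]
            if not recalled:
                continue
            dur = float(np.exp(rng.uniform(log_lo, log_hi)))
            onset = t
            keypress = onset + dur
            rows.append((onset, dur, cat, block, keypress, path_id))
            t = keypress + rng.uniform(*jitter_range)
        t += inter_test_interval
    ev = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if len(ev):
        ev["block"] = ev["block"].astype(int)
        ev["path"] = ev["path"].astype(int)
        validate_events(ev, "imagery")
    return ev


def make_activation_patterns(
    n_voxels: int,
    n_informative: int,
    effect_size: float,
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> ActivationPatterns:
    """Category-selective amplitude maps.

    Each category map has exactly ``n_informative`` nonzero voxels of
    amplitude ``effect_size``; each unordered pair of categories shares
    ``round(overlap_fraction * n_informative)`` voxels (no triple overlap).
    Stands in for category-selective cortical regions.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if n_informative < 0:
        raise ValueError("n_informative must be >= 0")
    n_shared = int(round(overlap_fraction * n_informative))
    n_unique = n_informative - 2 * n_shared
    if n_unique < 0:
        raise ValueError("overlap_fraction too large: shared voxels exceed map size")
    total = 3 * n_unique + 3 * n_shared
    if total > n_voxels:
        raise ValueError(
            f"need {total} informative voxels but only {n_voxels} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_voxels, size=total, replace=False)
    maps = np.zeros((n_voxels, 3))
    pos = 0
    # unique voxels per category
    uniq = []
    for j in range(3):
        uniq.append(chosen[pos : pos + n_unique])
        pos += n_unique
    # one shared set per unordered pair
    for (a, b) in [(0, 1), (0, 2), (1, 2)]:
        shared = chosen[pos : pos + n_shared]
        pos += n_shared
        maps[shared, a] = effect_size
        maps[shared, b] = effect_size
    for j in range(3):
        maps[uniq[j], j] = effect_size
    return ActivationPatterns(maps, n_informative, effect_size, overlap_fraction)


@dataclass
class SimulatedSeries:
    """Simulated session: scans x voxels data plus motion regressors."""

    data: np.ndarray
    motion: np.ndarray
    params: AcquisitionParams
    components: dict = field(default_factory=dict)


def _category_boxcars(events: pd.DataFrame, t_grid: np.ndarray) -> np.ndarray:
    box = np.zeros((len(t_grid), 3))
    for j, cat in enumerate(CATEGORIES):
        sub = events[events["trial_type"] == cat]
        for onset, dur in zip(sub["onset"], sub["duration"]):
            box[(t_grid >= onset) & (t_grid < onset + dur), j] = 1.0
    return box


def convolved_regressors(
    events: pd.DataFrame, params: AcquisitionParams, oversample: int = 20
) -> np.ndarray:
    """HRF-convolved category regressors sampled at scan midpoints (scans x 3)."""
    dt = params.tr / oversample
    t_grid = np.arange(0.0, params.duration + dt, dt)
    box = _category_boxcars(events, t_grid)
    t_hrf = np.arange(0.0, 32.0 + dt, dt)
    h = hrf_double_gamma(t_hrf, params.hrf_peak, params.hrf_undershoot, params.hrf_ratio)
    conv = np.column_stack(
        [np.convolve(box[:, j], h)[: len(t_grid)] for j in range(3)]
    )
    idx = np.clip(np.round(params.scan_midpoints() / dt).astype(int), 0, len(t_grid) - 1)
    return conv[idx]


def simulate_bold(
    events: pd.DataFrame,
    patterns: ActivationPatterns,
    params: AcquisitionParams,
    noise: NoiseParams | None = None,
    seed: int = 0,
    baseline: float = BASELINE,
) -> SimulatedSeries:
    """Forward-simulate a session.

    signal = evoked (HRF-convolved category boxcars x amplitude maps)
           + baseline + low-frequency drift + motion-coupled nuisance
           + AR(1) Gaussian noise.

    The six returned motion series play the role of realignment parameters.
    Deterministic given ``seed``; components are returned alongside the sum.
    """
    if noise is None:
        noise = NoiseParams()
    if patterns.maps.shape[0] != params.n_voxels:
        raise ValueError("pattern map size does not match n_voxels")
    if len(events):
        end = (events["onset"] + events["duration"]).max()
        if end > params.duration:
            raise ValueError(
                f"events end at {end:.1f}s but the run lasts {params.duration:.1f}s"
            )
    rng = np.random.default_rng(seed)
    n, v = params.n_scans, params.n_voxels

    evoked = convolved_regressors(events, params) @ patterns.maps.T

    # slow cosine drifts, well below the 1/128 Hz cutoff
    tmid = params.scan_midpoints()
    drift = np.zeros((n, v))
    if noise.drift_amp:
        n_basis = 3
        coef = rng.normal(size=(n_basis, v)) * noise.drift_amp / np.sqrt(n_basis)
        basis = np.column_stack(
            [np.cos(np.pi * k * tmid / params.duration) for k in range(1, n_basis + 1)]
        )
        drift = basis @ coef

    # motion: smooth random walks, coupled into voxels by random loadings
    steps = rng.normal(scale=0.02, size=(n, 6))
    motion = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    motion = np.column_stack(
        [np.convolve(motion[:, j], kernel, mode="same") for j in range(6)]
    )
    motion_effect = np.zeros((n, v))
    if noise.motion_amp:
        loadings = rng.normal(size=(6, v)) * noise.motion_amp
        motion_effect = motion @ loadings

    ar_noise = np.zeros((n, v))
    if noise.white_sd:
        innov_sd = noise.white_sd * np.sqrt(max(1.0 - noise.ar1_coef**2, 1e-12))
        e = rng.normal(scale=innov_sd, size=(n, v))
        ar_noise = sps.lfilter([1.0], [1.0, -noise.ar1_coef], e, axis=0)

    data = baseline + evoked + drift + motion_effect + ar_noise
    return SimulatedSeries(
        data=data,
        motion=motion,
        params=params,
        components={
            "baseline": baseline,
            "evoked": evoked,
            "drift": drift,
            "motion_effect": motion_effect,
            "noise": ar_noise,
        },
    )


def required_scans(events: pd.DataFrame, tr: float, tail: float = 20.0) -> int:
    """Number of scans needed to cover the events plus an HRF tail."""
    if len(events) == 0:
        return int(np.ceil(tail / tr))
    end = float((events["onset"] + events["duration"]).max())
    return int(np.ceil((end + tail) / tr))
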