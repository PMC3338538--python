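"""Two-level voxel selection.

Level one is a univariate GLM filter: an omnibus F statistic per voxel
testing the joint effect of the three stimulus categories, from which either
every voxel above an F-threshold of 0.5 is kept ("global" selection) or the
1000 largest-F voxels are kept ("specific" selection).  The F map can be
computed on the raw time series (HRF-convolved category regressors against a
confound-only null model) or directly on extracted samples (one-way omnibus
F across the three classes), which is the form used inside cross-validation
folds because it restricts cleanly to training samples.

Level two is Recursive Feature Addition (RFA): a forward wrapper that ranks
voxels by the absolute weights of a linear SVM fitted per binary comparison,
grows the per-condition voxel count n through a fixed grid (5, 30, ..., 150),
scores each n by a "global accuracy" — the sum over the three binary
comparisons of held-out accuracy in an inner leave-one-block-out loop — and
stops once the curve has decreased below both of the two preceding
iterations.  The returned voxel set is the one attaining the maximal global
accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classifiers import train_linear_svm, svm_predict
from .constants import CATEGORIES, PAIRS
from .signal_extraction import SampleSet

RFA_GRID = (5, 30, 55, 80, 105, 130, 150)


@dataclass
class FMap:
    """Per-voxel omnibus F statistic with its degrees of freedom."""

    f: np.ndarray
    df: tuple[int, int]

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if np.any(self.f < -1e-10):
            raise ValueError("F statistics must be nonnegative")
        self.f = np.maximum(self.f, 0.0)


@dataclass
class FeatureRanking:
    """Voxels of one binary comparison ordered by decreasing |SVM weight|.

    ``order`` is the full ranking (ties broken by lowest index); the two
    condition lists partition it by weight sign, each kept in rank order.
    Zero-weight voxels go to the positive list (sign convention of the
    decision rule).
    """

    order: np.ndarray
    weights: np.ndarray
    positive: np.ndarray
    negative: np.ndarray

    def top_per_condition(self, n: int) -> np.ndarray:
        """Top-n positive-weight plus top-n negative-weight voxel indices."""
        return np.concatenate([self.positive[:n], self.negative[:n]])


@dataclass
class RFATrace:
    """Audit record of one RFA run."""

    ns: list
    set_sizes: list
    global_acc: list
    selected_iter: int
    stopped_early: bool

    @property
    def selected_n(self) -> int:
        return self.ns[self.selected_iter]


def _omnibus_f(y: np.ndarray, x_full: np.ndarray, x_null: np.ndarray) -> FMap:
    """Vectorized extra-sum-of-squares F over voxels (columns of y)."""
    n = y.shape[0]
    rank_full = np.linalg.matrix_rank(x_full)
    rank_null = np.linalg.matrix_rank(x_null)
    p = rank_full - rank_null
    d2 = n - rank_full
    if p < 1 or d2 < 1:
        raise ValueError("design leaves no degrees of freedom for the omnibus test")
    beta_f, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    rss1 = ((y - x_full @ beta_f) ** 2).sum(axis=0)
    beta_n, *_ = np.linalg.lstsq(x_null, y, rcond=None)
    rss0 = ((y - x_null @ beta_n) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / p) / (rss1 / d2)
    f = np.where(np.isfinite(f), f, 0.0)
    return FMap(f=np.maximum(f, 0.0), df=(p, d2))


def _check_collinear(design: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        culprits = [names[j] for j in np.flatnonzero(bad)]
        raise ValueError(f"singular design matrix; collinear columns: {culprits}")


def fmap_from_series(
    series: np.ndarray,
    condition_regressors: np.ndarray,
    confounds: np.ndarray | None = None,
    scan_mask: np.ndarray | None = None,
) -> FMap:
    """Omnibus F map from the time series.

    ``condition_regressors`` are the three HRF-convolved category regressors
    (scans x 3); the null model contains the confounds and an intercept only.
    ``scan_mask`` restricts the fit to a subset of scans (e.g. training
    blocks).
    """
    series = np.asarray(series, dtype=float)
    cond = np.asarray(condition_regressors, dtype=float)
    n = series.shape[0]
    parts = [np.ones((n, 1))]
    names = ["intercept"]
    if confounds is not None and confounds.size:
        parts.append(np.asarray(confounds, dtype=float))
        names += [f"confound_{j}" for j in range(confounds.shape[1])]
    x_null = np.column_stack(parts)
    x_full = np.column_stack([cond, x_null])
    full_names = [f"condition_{c}" for c in CATEGORIES[: cond.shape[1]]] + names
    _check_collinear(x_full, full_names)
    if scan_mask is not None:
        series, x_full, x_null = series[scan_mask], x_full[scan_mask], x_null[scan_mask]
    return _omnibus_f(series, x_full, x_null)


def fmap_from_samples(samples: SampleSet, mask: np.ndarray | None = None) -> FMap:
    """Omnibus F map from extracted samples: one-way F across the classes.

    Equivalent to regressing each voxel on class-indicator columns against an
    intercept-only null; used inside cross-validation folds, where it is
    fitted on the training samples only.
    """
    X, labels = samples.X, samples.labels
    if mask is not None:
        mask = np.asarray(mask)
        X, labels = X[mask], labels[mask]
    classes = [c for c in CATEGORIES if c in labels]
    if len(classes) < 2:
        raise ValueError("need at least two classes for an omnibus F map")
    indic = np.column_stack([(labels == c).astype(float) for c in classes])
    n = X.shape[0]
    return _omnibus_f(X, indic, np.ones((n, 1)))


def select_global(fmap: FMap, f_threshold: float = 0.5) -> np.ndarray:
    """All voxels strictly above the F threshold."""
    return np.flatnonzero(fmap.f > f_threshold)


def select_topk(fmap: FMap, k: int = 1000) -> np.ndarray:
    """The k largest-F voxels (boundary ties broken by lowest index)."""
    v = len(fmap.f)
    if k >= v:
        if k > v:
            warnings.warn(
                f"k={k} exceeds the {v} available voxels; returning all",
                stacklevel=2,
            )
        return np.arange(v)
    order = np.lexsort((np.arange(v), -fmap.f))
    return np.sort(order[:k])


def rank_by_svm_weights(
    samples: SampleSet, pair: tuple[str, str], C: float = 1.0
) -> FeatureRanking:
    """Rank voxels by their linear-SVM weight magnitude for one comparison.

    The SVM is trained on all provided samples of the two classes, with the
    first-named class coded +1.  Positive weights favour the first class.
    """
    mask = np.isin(samples.labels, pair)
    X = samples.X[mask]
    y = np.where(samples.labels[mask] == pair[0], 1, -1)
    if len(np.unique(y)) < 2:
        raise ValueError(f"both classes of {pair} must be present")
    model = train_linear_svm(X, y, C=C)
    w = model.w
    v = len(w)
    order = np.lexsort((np.arange(v), -np.abs(w)))
    positive = order[w[order] >= 0]
    negative = order[w[order] < 0]
    return FeatureRanking(order=order, weights=w, positive=positive, negative=negative)


def _rfa_stopping(global_acc: list[float]) -> bool:
    """True when the last value sits strictly below both of the two before it."""
    if len(global_acc) < 3:
        return False
    return global_acc[-1] < global_acc[-2] and global_acc[-1] < global_acc[-3]


def rfa_select(
    samples: SampleSet,
    grid: tuple[int, ...] = RFA_GRID,
    C: float = 1.0,
    pairs: tuple = PAIRS,
) -> tuple[np.ndarray, RFATrace]:
    """Recursive Feature Addition over the provided (training) samples.

    Inner leave-one-block-out: for every inner fold, each comparison's voxels
    are ranked on the inner-training blocks and an SVM restricted to the
    top-n voxels per condition is scored on the left-out block.  The global
    accuracy at n is the sum of the three binary accuracies, averaged over
    inner folds.  The grid is traversed in order until the stopping rule
    fires (strictly below both of the two preceding values) or the grid is
    exhausted; the voxel set returned is re-ranked on all provided samples at
    the best n, as the union over comparisons of n positive plus n negative
    voxels each.

    Returns (selected voxel indices, trace).
    """
    blocks = np.unique(samples.blocks)
    if len(blocks) < 3:
        raise ValueError(
            "RFA needs at least 3 blocks (use a filter-only procedure otherwise)"
        )
    # rankings per inner fold, each fitted on the inner-training blocks only
    fold_rankings = []
    for b in blocks:
        train = samples.subset(samples.blocks != b)
        test = samples.subset(samples.blocks == b)
        rankings = {}
        for pair in pairs:
            try:
                rankings[pair] = rank_by_svm_weights(train, pair, C=C)
            except ValueError:
                rankings[pair] = None
        fold_rankings.append((train, test, rankings))
    full_rankings = {pair: rank_by_svm_weights(samples, pair, C=C) for pair in pairs}

    ns, accs, sizes = [], [], []
    for n in grid:
        fold_accs = []
        for train, test, rankings in fold_rankings:
            total = 0.0
            for pair in pairs:
                ranking = rankings[pair]
                if ranking is None:
                    continue
                vox = ranking.top_per_condition(n)
                tr_mask = np.isin(train.labels, pair)
                te_mask = np.isin(test.labels, pair)
                if not te_mask.any():
                    continue
                y_tr = np.where(train.labels[tr_mask] == pair[0], 1, -1)
                y_te = np.where(test.labels[te_mask] == pair[0], 1, -1)
                model = train_linear_svm(train.X[np.ix_(tr_mask, vox)], y_tr, C=C)
                pred = svm_predict(model, test.X[np.ix_(te_mask, vox)])
                total += float(np.mean(pred == y_te))
            fold_accs.append(total)
        ns.append(n)
        accs.append(float(np.mean(fold_accs)))
        union = np.unique(
            np.concatenate([full_rankings[p].top_per_condition(n) for p in pairs])
        )
        sizes.append(int(len(union)))
        if _rfa_stopping(accs):
            break

    selected_iter = int(np.argmax(accs))
    best_n = ns[selected_iter]
    selected = np.unique(
        np.concatenate([full_rankings[p].top_per_condition(best_n) for p in pairs])
    )
    trace = RFATrace(
        ns=ns,
        set_sizes=sizes,
        global_acc=accs,
        selected_iter=selected_iter,
        stopped_early=len(ns) < len(grid),
    )
    return selected, trace
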