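"""Procedure orchestration, accuracy measures and permutation testing.

Five procedures combine the two GLM filters, the RFA wrapper and the two
classifiers:

====  ========  =======  ==========
P     filter    wrapper  classifier
====  ========  =======  ==========
1     specific  --       SVM
2     specific  --       GP
3     global    RFA      GP
4     specific  RFA      GP
5     specific  RFA      SVM
====  ========  =======  ==========

Cross-validation is leave-one-block-out over temporally contiguous blocks
(27 consecutive paced stimuli, or the events of 6 consecutive recall paths);
procedures with RFA nest an inner leave-one-block-out loop inside each outer
training set so that feature selection never sees the test block.  Accuracy
is summarized as balanced accuracy, the unweighted mean of per-class
accuracies, with chance at 1/3 for three classes.  Significance is assessed
by permuting training labels within each block — preserving per-block class
frequencies — and re-running the full procedure (selection included).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import (
    KernelSpec,
    gp_ep_train,
    gp_predict_prob,
    svm_predict,
    train_linear_svm,
)
from .constants import CATEGORIES, PAIRS
from .ecoc import assign_class, codeword_table
from .feature_selection import (
    RFA_GRID,
    fmap_from_samples,
    rfa_select,
    select_global,
    select_topk,
)
from .signal_extraction import SampleSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProcedureConfig:
    """One row of the procedure table."""

    procedure_id: int
    filter: str  # "specific_top1000" | "global_F0.5"
    wrapper: str  # "none" | "RFA"
    classifier: str  # "SVM" | "GP"

    def __post_init__(self):
        if self.filter not in ("specific_top1000", "global_F0.5"):
            raise ValueError(f"unknown filter {self.filter!r}")
        if self.wrapper not in ("none", "RFA"):
            raise ValueError(f"unknown wrapper {self.wrapper!r}")
        if self.classifier not in ("SVM", "GP"):
            raise ValueError(f"unknown classifier {self.classifier!r}")


PROCEDURES = {
    1: ProcedureConfig(1, "specific_top1000", "none", "SVM"),
    2: ProcedureConfig(2, "specific_top1000", "none", "GP"),
    3: ProcedureConfig(3, "global_F0.5", "RFA", "GP"),
    4: ProcedureConfig(4, "specific_top1000", "RFA", "GP"),
    5: ProcedureConfig(5, "specific_top1000", "RFA", "SVM"),
}


@dataclass
class ProcedureResult:
    config: ProcedureConfig
    fold_ids: list
    fold_confusions: list
    confusion: np.ndarray
    balanced_accuracy: float
    class_accuracies: dict
    fold_balanced: list
    n_features: list
    rfa_traces: list
    skipped_folds: list
    records: pd.DataFrame
    seed: int


def make_blocks(
    events: pd.DataFrame, session_type: str, paths_per_block: int = 6
) -> np.ndarray:
    """Fold label per event.

    Exploration folds are the maze blocks (one per block per repetition);
    imagery folds group 6 consecutive recall paths.  A trailing group of
    fewer paths forms a smaller final fold, with a warning.
    """
    if session_type == "exploration":
        folds = events["block"].to_numpy(int)
    elif session_type == "imagery":
        paths = events["path"].to_numpy(int)
        folds = (np.unique(paths, return_inverse=True)[1]) // paths_per_block
        n_paths = len(np.unique(paths))
        if n_paths % paths_per_block:
            warnings.warn(
                f"{n_paths} paths do not divide into groups of {paths_per_block}; "
                "the final fold is smaller",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown session type {session_type!r}")
    if len(np.unique(folds)) < 2:
        raise ValueError("cannot cross-validate with a single block")
    return folds


def balanced_accuracy(confusion: np.ndarray) -> float:
    """Mean of per-class accuracies from a 3x3 confusion (rows = truth)."""
    confusion = np.asarray(confusion, dtype=float)
    row_sums = confusion.sum(axis=1)
    present = row_sums > 0
    if not present.any():
        raise ValueError("confusion matrix has no test instances")
    if not present.all():
        warnings.warn(
            "classes absent from the test set are excluded from the mean",
            stacklevel=2,
        )
    acc = np.diag(confusion)[present] / row_sums[present]
    return float(acc.mean())


def _class_accuracies(confusion: np.ndarray) -> dict:
    out = {}
    for j, c in enumerate(CATEGORIES):
        total = confusion[j].sum()
        out[c] = float(confusion[j, j] / total) if total > 0 else np.nan
    return out


def _select_features(
    samples_train_labels: SampleSet,
    train_mask: np.ndarray,
    config: ProcedureConfig,
    rfa_grid,
    C: float,
    topk: int,
    f_threshold: float,
):
    """Filter (and, if configured, RFA) fitted strictly on training samples."""
    fmap = fmap_from_samples(samples_train_labels, mask=train_mask)
    if config.filter == "specific_top1000":
        voxels0 = select_topk(fmap, k=topk)
    else:
        voxels0 = select_global(fmap, f_threshold=f_threshold)
        if len(voxels0) == 0:
            logger.warning("global filter selected no voxels; falling back to all")
            voxels0 = np.arange(samples_train_labels.n_voxels)
    trace = None
    if config.wrapper == "RFA":
        train = samples_train_labels.subset(train_mask)
        train_restricted = SampleSet(
            X=train.X[:, voxels0], labels=train.labels, blocks=train.blocks
        )
        sel, trace = rfa_select(train_restricted, grid=tuple(rfa_grid), C=C)
        voxels = voxels0[sel]
    else:
        voxels = voxels0
    return voxels, trace


def run_procedure(
    samples: SampleSet,
    config: ProcedureConfig,
    seed: int = 0,
    train_labels: np.ndarray | None = None,
    topk: int = 1000,
    f_threshold: float = 0.5,
    rfa_grid=RFA_GRID,
    C: float = 1.0,
    kernel_spec: KernelSpec | None = None,
    optimize_sigma: bool = True,
) -> ProcedureResult:
    """Run one procedure under leave-one-block-out cross-validation.

    The outer fold sequence is the sorted block order, identical for every
    configuration given the same samples, so procedures are comparable fold
    by fold.  ``train_labels`` optionally overrides the labels used for
    feature selection and model fitting (the permutation-test hook); test
    scoring always uses the true labels.
    """
    blocks = np.unique(samples.blocks)
    min_folds = 3 if config.wrapper == "RFA" else 2
    if len(blocks) < min_folds:
        raise ValueError(
            f"procedure {config.procedure_id} needs at least {min_folds} blocks"
        )
    eff_labels = samples.labels if train_labels is None else np.asarray(train_labels)
    if eff_labels.shape != samples.labels.shape:
        raise ValueError("train_labels must match the sample count")
    samples_eff = SampleSet(X=samples.X, labels=eff_labels, blocks=samples.blocks)
    if kernel_spec is None:
        kernel_spec = KernelSpec()

    scheme = "prediction" if config.classifier == "SVM" else "probability"
    table = codeword_table(scheme)
    rng = np.random.default_rng(seed)

    fold_ids, fold_confusions, fold_bal = [], [], []
    n_features, traces, skipped = [], [], []
    rec_rows = []
    for b in blocks:
        train_mask = samples.blocks != b
        test_mask = ~train_mask
        train_classes = set(eff_labels[train_mask])
        if not set(CATEGORIES) <= train_classes:
            logger.warning("fold %s: training set missing a class; skipped", b)
            skipped.append(int(b))
            continue
        voxels, trace = _select_features(
            samples_eff, train_mask, config, rfa_grid, C, topk, f_threshold
        )
        n_features.append(int(len(voxels)))
        traces.append(trace)

        X_train = samples.X[np.ix_(train_mask, voxels)]
        X_test = samples.X[np.ix_(test_mask, voxels)]
        y_train_all = eff_labels[train_mask]

        votes = np.zeros((X_test.shape[0], 3))
        for j, pair in enumerate(PAIRS):
            pm = np.isin(y_train_all, pair)
            y_pm = np.where(y_train_all[pm] == pair[0], 1, -1)
            if config.classifier == "SVM":
                model = train_linear_svm(X_train[pm], y_pm, C=C)
                votes[:, j] = svm_predict(model, X_test)
            else:
                model = gp_ep_train(
                    X_train[pm], y_pm, spec=kernel_spec,
                    optimize_sigma=optimize_sigma,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # non-convergence is logged in the model
                    votes[:, j] = gp_predict_prob(model, X_test)

        conf = np.zeros((3, 3))
        true_test = samples.labels[test_mask]
        test_idx = np.flatnonzero(test_mask)
        for i in range(X_test.shape[0]):
            predicted, distances, tie = assign_class(votes[i], table, rng=rng)
            conf[CATEGORIES.index(true_test[i]), CATEGORIES.index(predicted)] += 1
            rec_rows.append(
                {
                    "fold": int(b),
                    "sample": int(test_idx[i]),
                    "true": true_test[i],
                    "predicted": predicted,
                    "tie": tie,
                    **{f"vote_{k}": votes[i, k] for k in range(3)},
                }
            )
        fold_ids.append(int(b))
        fold_confusions.append(conf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_bal.append(balanced_accuracy(conf))

    if not fold_confusions:
        raise ValueError("every fold was skipped; cannot evaluate")
    pooled = np.sum(fold_confusions, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bal = balanced_accuracy(pooled)
    return ProcedureResult(
        config=config,
        fold_ids=fold_ids,
        fold_confusions=fold_confusions,
        confusion=pooled,
        balanced_accuracy=bal,
        class_accuracies=_class_accuracies(pooled),
        fold_balanced=fold_bal,
        n_features=n_features,
        rfa_traces=traces,
        skipped_folds=skipped,
        records=pd.DataFrame(rec_rows),
        seed=seed,
    )


def permute_within_blocks(
    labels: np.ndarray, blocks: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute labels independently within each block (class counts preserved)."""
    out = np.array(labels, copy=True)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        out[idx] = out[rng.permutation(idx)]
    return out


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    total_shuffles: int
    result: ProcedureResult = field(repr=False, default=None)


def permutation_test(
    samples: SampleSet,
    config: ProcedureConfig,
    n_perm: int = 100,
    seed: int = 0,
    observed_result: ProcedureResult | None = None,
    **run_kwargs,
) -> PermutationResult:
    """Within-block permutation test of the balanced accuracy.

    Each of the ``n_perm`` replicates draws one label permutation per block,
    reruns the full procedure — feature selection included — with the
    permuted labels on the training side of every outer fold (test labels
    untouched), and pools the fold confusions into one subject-level null
    balanced accuracy.  p = (1 + #{null >= observed}) / (1 + n_perm);
    ``total_shuffles`` counts label shufflings across cross-validation steps
    (n_perm x number of outer folds).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed_result is None:
        observed_result = run_procedure(samples, config, seed=seed, **run_kwargs)
    observed = observed_result.balanced_accuracy
    ss = np.random.SeedSequence([seed, 0x7E57])
    child_seeds = ss.spawn(n_perm)
    nulls = np.empty(n_perm)
    for r in range(n_perm):
        rng = np.random.default_rng(child_seeds[r])
        permuted = permute_within_blocks(samples.labels, samples.blocks, rng)
        res = run_procedure(
            samples, config, seed=seed, train_labels=permuted, **run_kwargs
        )
        nulls[r] = res.balanced_accuracy
    p = (1.0 + np.sum(nulls >= observed)) / (1.0 + n_perm)
    n_folds = len(observed_result.fold_ids) + len(observed_result.skipped_folds)
    return PermutationResult(
        observed=observed,
        null_values=nulls,
        p_value=float(p),
        n_perm=n_perm,
        total_shuffles=n_perm * n_folds,
        result=observed_result,
    )
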