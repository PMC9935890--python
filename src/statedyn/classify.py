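"""Decoding the stimulation condition from latent-state posteriors.

A linear support-vector machine is trained on per-timepoint state posterior
vectors, evaluated with leave-one-subject-out cross-validation (timepoint
folds would leak temporal autocorrelation across train/test), and scored by
balanced accuracy: stimulation-ON samples are a minority of the blocked
design, so raw accuracy would reward the majority predictor while the
chance level of interest is 50%.  Significance comes from a permutation
test that shuffles condition labels at the block level within subject,
preserving block structure and the block-label counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations, product

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.svm import LinearSVC

from .design import BlockDesign, ON

logger = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    C: float = 1.0
    n_permutations: int = 500
    seed: int = 0
    max_iter: int = 5000


@dataclass
class ClassificationResult:
    """Leave-one-subject-out decoding result.

    Accuracies are percentages.  ``block_accuracies`` score majority-vote
    predictions per stimulation block (a coarser unit than timepoints).
    The permutation fields are filled by :func:`permutation_test`.
    """

    fold_accuracies: list
    mean_accuracy: float
    block_accuracies: list
    mean_block_accuracy: float
    n_folds: int
    config: ClassifierConfig
    permutation_null: np.ndarray = None
    permutation_p: float = None

    def as_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "mean_block_accuracy": self.mean_block_accuracy,
            "fold_accuracies": list(self.fold_accuracies),
            "n_folds": self.n_folds,
            "permutation_p": self.permutation_p,
            "n_permutations": (None if self.permutation_null is None
                               else int(len(self.permutation_null))),
        }


def _as_label_lists(labels, n_subjects):
    if isinstance(labels, (list, tuple)) and len(labels) == n_subjects \
            and np.ndim(labels[0]) == 1:
        return [np.asarray(l) for l in labels]
    lab = np.asarray(labels)
    return [lab] * n_subjects


def _block_segments(labels):
    """Maximal constant runs of a label vector as (start, stop, label)."""
    segs = []
    t, n = 0, len(labels)
    while t < n:
        u = t
        while u < n and labels[u] == labels[t]:
            u += 1
        segs.append((t, u, labels[t]))
        t = u
    return segs


def classify_blocks(features: list, labels, config: ClassifierConfig = None
                    ) -> ClassificationResult:
    """Leave-one-subject-out linear-SVM decoding of the condition labels.

    Parameters
    ----------
    features : list of (T_s, F) arrays
        Per-subject feature matrices (state posterior vectors).
    labels : array or list of arrays
        Per-sample condition labels, shared across subjects or per subject.
    """
    config = config or ClassifierConfig()
    n_sub = len(features)
    if n_sub < 3:
        raise ValueError(f"leave-one-subject-out needs >= 3 subjects, got {n_sub}")
    label_lists = _as_label_lists(labels, n_sub)
    for i, (X, y) in enumerate(zip(features, label_lists)):
        if X.shape[0] != y.size:
            raise ValueError(f"subject {i}: {X.shape[0]} samples vs {y.size} labels")
        if len(np.unique(y)) < 2:
            raise ValueError(f"subject {i} is missing a condition class")
    pooled = np.vstack(features)
    if np.all(pooled.std(axis=0) < 1e-12):
        raise ValueError("degenerate (constant) features")

    fold_acc, block_acc = [], []
    for i in range(n_sub):
        X_tr = np.vstack([features[j] for j in range(n_sub) if j != i])
        y_tr = np.concatenate([label_lists[j] for j in range(n_sub) if j != i])
        clf = LinearSVC(C=config.C, class_weight="balanced",
                        max_iter=config.max_iter, random_state=0)
        clf.fit(X_tr, y_tr)
        pred = clf.predict(features[i])
        y_te = label_lists[i]
        fold_acc.append(100.0 * balanced_accuracy_score(y_te, pred))
        seg_true, seg_pred = [], []
        for s, e, lab in _block_segments(list(y_te)):
            seg_true.append(lab)
            vals, cnt = np.unique(pred[s:e], return_counts=True)
            seg_pred.append(vals[np.argmax(cnt)])
        block_acc.append(100.0 * balanced_accuracy_score(seg_true, seg_pred))
    return ClassificationResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        block_accuracies=block_acc,
        mean_block_accuracy=float(np.mean(block_acc)),
        n_folds=n_sub,
        config=config,
    )


def _permute_block_labels(labels, rng=None, order=None):
    """Reassign the multiset of block labels to block positions."""
    segs = _block_segments(list(labels))
    block_labels = [lab for _, _, lab in segs]
    if order is None:
        order = rng.permutation(len(block_labels))
    out = np.empty(len(labels), dtype=np.asarray(labels).dtype)
    for (s, e, _), lab in zip(segs, [block_labels[o] for o in order]):
        out[s:e] = lab
    return out


def _distinct_block_permutations(labels):
    """All distinct permuted label vectors of one subject (tiny inputs only)."""
    segs = _block_segments(list(labels))
    block_labels = tuple(lab for _, _, lab in segs)
    seen, out = set(), []
    for perm in permutations(range(len(block_labels))):
        assigned = tuple(block_labels[o] for o in perm)
        if assigned in seen:
            continue
        seen.add(assigned)
        vec = np.empty(len(labels), dtype=np.asarray(labels).dtype)
        for (s, e, _), lab in zip(segs, assigned):
            vec[s:e] = lab
        out.append(vec)
    return out


def permutation_test(
    features: list,
    labels,
    config: ClassifierConfig = None,
    observed: ClassificationResult = None,
    exhaustive: bool = False,
) -> ClassificationResult:
    """Block-label permutation test of the LOOCV decoding accuracy.

    Each permutation shuffles entire condition blocks within every subject
    (preserving block structure and block-label counts) and re-runs the full
    leave-one-subject-out analysis.  Sampled mode reports
    ``p = (1 + #{null >= observed}) / (1 + n_permutations)``; with
    ``exhaustive=True`` every distinct within-subject assignment is
    enumerated and ``p = #{null >= observed} / N``.
    """
    config = config or ClassifierConfig()
    if not exhaustive and config.n_permutations < 100:
        logger.warning("n_permutations = %d is small; the attainable p-value "
                       "floor is %.3f", config.n_permutations,
                       1.0 / (1 + config.n_permutations))
    n_sub = len(features)
    label_lists = _as_label_lists(labels, n_sub)
    if observed is None:
        observed = classify_blocks(features, label_lists, config)
    obs = observed.mean_accuracy

    null = []
    if exhaustive:
        per_subject = [_distinct_block_permutations(l) for l in label_lists]
        n_total = int(np.prod([len(p) for p in per_subject]))
        if n_total > 100_000:
            raise ValueError(f"{n_total} exhaustive permutations is too many; "
                             "use sampled mode")
        for combo in product(*per_subject):
            null.append(classify_blocks(features, list(combo), config)
                        .mean_accuracy)
        null = np.array(null)
        p = float(np.sum(null >= obs - 1e-12) / null.size)
    else:
        rng = np.random.default_rng(config.seed)
        for _ in range(config.n_permutations):
            permed = [_permute_block_labels(l, rng) for l in label_lists]
            null.append(classify_blocks(features, permed, config).mean_accuracy)
        null = np.array(null)
        p = float((1 + np.sum(null >= obs - 1e-12)) / (1 + null.size))
    observed.permutation_null = null
    observed.permutation_p = p
    return observed


def posterior_features(posteriors, states=None):
    """Feature matrices (per-timepoint posterior vectors) from posteriors."""
    out = []
    for p in posteriors:
        g = p.gamma
        out.append(g[:, list(states)] if states is not None else g)
    return out
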