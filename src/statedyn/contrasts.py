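"""State-specific activation and functional-connectivity contrasts.

Per-subject estimates are posterior-weighted: each state's activation is the
gamma-weighted mean of the ROI signal, its connectivity the correlation form
of the gamma-weighted covariance, so all evidence contributes in proportion
to the state posterior.  Group contrasts between two states use paired
two-tailed t-tests across subjects with Benjamini-Hochberg FDR correction
(over ROIs for activation, over all unordered ROI pairs for connectivity;
connectivity differences are tested on Fisher-z transformed correlations).
A hard-assignment counterpart (plain correlation over dominant-state
samples) validates the soft estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import RoiTimeSeries
from .model import StatePosterior

logger = logging.getLogger(__name__)


@dataclass
class SubjectStateEstimates:
    """Posterior-weighted per-state activation and connectivity for one subject.

    States with posterior mass below the threshold are missing (NaN) for
    this subject.
    """

    subject_id: str
    activation: np.ndarray      # (K, d)
    connectivity: np.ndarray    # (K, d, d)
    mass: np.ndarray            # (K,)
    mass_threshold: float

    def has_state(self, k: int) -> bool:
        return self.mass[k] >= self.mass_threshold


def subject_state_estimates(
    subject: RoiTimeSeries,
    posterior: StatePosterior,
    mass_threshold: float = 5.0,
) -> SubjectStateEstimates:
    """Gamma-weighted state mean and correlation estimates for one subject."""
    gamma = posterior.gamma
    if gamma.shape[0] != subject.n_timepoints:
        raise ValueError("posterior length does not match the subject run")
    y = subject.data
    K = gamma.shape[1]
    d = y.shape[1]
    mass = gamma.sum(axis=0)
    if np.all(mass < mass_threshold):
        raise ValueError(f"subject {subject.subject_id}: no state reaches "
                         f"posterior mass {mass_threshold}")
    activation = np.full((K, d), np.nan)
    connectivity = np.full((K, d, d), np.nan)
    for k in range(K):
        if mass[k] < mass_threshold:
            continue
        w = gamma[:, k]
        mu = (w[:, None] * y).sum(axis=0) / mass[k]
        activation[k] = mu
        r = y - mu
        cov = (w[:, None] * r).T @ r / mass[k]
        sd = np.sqrt(np.diag(cov))
        if np.any(sd == 0):
            logger.warning("subject %s state %d: zero weighted variance; "
                           "connectivity undefined", subject.subject_id, k)
            continue
        corr = cov / np.outer(sd, sd)
        np.fill_diagonal(corr, 1.0)
        connectivity[k] = np.clip(corr, -1.0, 1.0)
    return SubjectStateEstimates(subject.subject_id, activation, connectivity,
                                 mass, mass_threshold)


@dataclass
class ContrastResult:
    """Group contrast between two states: per-target statistics table."""

    table: pd.DataFrame         # mean_diff, t, p, q, significant per target
    state_a: int
    state_b: int
    alpha: float
    kind: str                   # "activation" | "connectivity"

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def _paired_tests(values_a, values_b, targets, alpha, state_a, state_b, kind):
    diffs = np.asarray(values_a) - np.asarray(values_b)
    n = diffs.shape[0]
    if n < 3:
        raise ValueError(f"paired contrast needs >= 3 subjects with both "
                         f"states, got {n}")
    mean_diff = diffs.mean(axis=0)
    tstat, pval = stats.ttest_rel(values_a, values_b, axis=0)
    pval = np.where(np.isnan(pval), 1.0, pval)
    tstat = np.where(np.isnan(tstat), 0.0, tstat)
    reject, qval, _, _ = multipletests(pval, alpha=alpha, method="fdr_bh")
    table = pd.DataFrame({
        "target": targets,
        "mean_diff": mean_diff,
        "t": tstat,
        "p": pval,
        "q": qval,
        "significant": reject,
    }).set_index("target")
    return ContrastResult(table, state_a, state_b, alpha, kind)


def activation_contrast(
    estimates: list,
    state_a: int,
    state_b: int,
    roi_labels,
    alpha: float = 0.01,
) -> ContrastResult:
    """Per-ROI paired t-test of activation(state_a) - activation(state_b)
    across subjects, BH-FDR corrected over ROIs."""
    rows_a, rows_b = [], []
    for est in estimates:
        if est.has_state(state_a) and est.has_state(state_b):
            rows_a.append(est.activation[state_a])
            rows_b.append(est.activation[state_b])
    return _paired_tests(rows_a, rows_b, list(roi_labels), alpha,
                         state_a, state_b, "activation")


def _fisher_z(r):
    clipped = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    if np.any(np.abs(np.asarray(r)) >= 1):
        logger.warning("correlation(s) of +/-1 clipped before Fisher z")
    return np.arctanh(clipped)


def connectivity_contrast(
    estimates: list,
    state_a: int,
    state_b: int,
    roi_labels,
    alpha: float = 0.01,
) -> ContrastResult:
    """Per-link paired t-test of Fisher-z connectivity differences,
    BH-FDR corrected over all unordered ROI pairs."""
    labels = list(roi_labels)
    pairs = list(combinations(range(len(labels)), 2))
    rows_a, rows_b = [], []
    for est in estimates:
        if est.has_state(state_a) and est.has_state(state_b):
            ca, cb = est.connectivity[state_a], est.connectivity[state_b]
            if np.any(np.isnan(ca)) or np.any(np.isnan(cb)):
                continue
            rows_a.append(_fisher_z([ca[i, j] for i, j in pairs]))
            rows_b.append(_fisher_z([cb[i, j] for i, j in pairs]))
    targets = [f"{labels[i]}-{labels[j]}" for i, j in pairs]
    return _paired_tests(rows_a, rows_b, targets, alpha,
                         state_a, state_b, "connectivity")


def direct_fc_validation(
    cohort: list,
    sequences: dict,
    states: list,
    min_samples: int = 10,
):
    """Hard-assignment functional connectivity per subject and state.

    Plain correlation over the samples whose dominant state matches;
    states with fewer than ``min_samples`` assigned samples in a subject
    are skipped with a flag.

    Returns ``(matrices, flags)``: ``matrices[sid][k]`` is the ROI x ROI
    correlation matrix.
    """
    matrices, flags = {}, {}
    for ts in cohort:
        seq = np.asarray(sequences[ts.subject_id])
        matrices[ts.subject_id] = {}
        for k in states:
            sel = seq == k
            if sel.sum() < min_samples:
                flags.setdefault(ts.subject_id, []).append(k)
                continue
            sub = ts.data[sel]
            if np.any(sub.std(axis=0) == 0):
                flags.setdefault(ts.subject_id, []).append(k)
                continue
            matrices[ts.subject_id][k] = np.corrcoef(sub, rowvar=False)
    return matrices, flags


def fc_agreement(direct: dict, estimates: list, states: list) -> float:
    """Median per-link absolute difference between hard-assignment and
    posterior-weighted connectivity across subjects and states."""
    by_sid = {e.subject_id: e for e in estimates}
    diffs = []
    for sid, per_state in direct.items():
        est = by_sid.get(sid)
        if est is None:
            continue
        for k, mat in per_state.items():
            soft = est.connectivity[k]
            if np.any(np.isnan(soft)):
                continue
            iu = np.triu_indices_from(mat, k=1)
            diffs.extend(np.abs(mat[iu] - soft[iu]).tolist())
    return float(np.median(diffs)) if diffs else float("nan")
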