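"""Temporal statistics of fitted latent states.

Occupancy rates by stimulation condition, identification of the OFF / ON /
Transition roles of model states, switching probabilities and path counting
at stimulation boundaries, and the mutual-inhibition (anticorrelation) check
between the ON- and OFF-state posterior time courses.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BlockDesign, OFF_TO_ON, ON_TO_OFF, ON, OFF

logger = logging.getLogger(__name__)


def occupancy_rates(
    sequences: dict,
    design: BlockDesign,
    n_states: int,
    include_rest: bool = True,
) -> pd.DataFrame:
    """Fraction of condition samples in which each state is dominant.

    Parameters
    ----------
    sequences : mapping subject_id -> integer dominant-state sequence
    design : BlockDesign
    n_states : int
        Number of model states (table covers all, including never-dominant).
    include_rest : bool
        Whether the rest prefix counts toward the OFF condition.

    Returns
    -------
    DataFrame with columns subject, state, condition, occupancy; for every
    subject x condition the occupancies sum to 1 over states.
    """
    labels = design.condition_labels
    mask = np.ones(labels.size, bool)
    if not include_rest:
        mask[: design.rest_samples] = False
    rows = []
    for sid, seq in sequences.items():
        seq = np.asarray(seq)
        if seq.size != labels.size:
            raise ValueError(f"subject {sid}: sequence length {seq.size} != "
                             f"design length {labels.size}")
        for cond in (OFF, ON):
            sel = mask & (labels == cond)
            denom = int(sel.sum())
            if denom == 0:
                raise ValueError(f"condition {cond} has zero samples")
            counts = np.bincount(seq[sel], minlength=n_states)
            for k in range(n_states):
                rows.append({"subject": sid, "state": k, "condition": cond,
                             "occupancy": counts[k] / denom})
    return pd.DataFrame(rows)


@dataclass
class StateRoleMap:
    """Mapping from functional roles to model state indices."""

    off_state: int = None
    on_state: int = None
    transition_state: int = None
    flags: dict = field(default_factory=dict)

    def assigned(self) -> dict:
        out = {}
        if self.off_state is not None:
            out["OFF"] = self.off_state
        if self.on_state is not None:
            out["ON"] = self.on_state
        if self.transition_state is not None:
            out["Transition"] = self.transition_state
        return out


def _runs(seq):
    """Maximal constant runs of ``seq`` as (start, stop, value)."""
    runs = []
    t = 0
    n = len(seq)
    while t < n:
        u = t
        while u < n and seq[u] == seq[t]:
            u += 1
        runs.append((t, u, seq[t]))
        t = u
    return runs


def _traversal(seq_window, boundary_offset, source, target):
    """Intermediate states on the source->target traversal around a boundary.

    Returns (intermediates tuple, completed flag).  The traversal starts at
    the last source-state run beginning at or before the boundary offset and
    ends at the first target-state run after it.
    """
    runs = _runs(list(seq_window))
    src_idx = None
    for i, (s, e, v) in enumerate(runs):
        if v == source and s <= boundary_offset:
            src_idx = i
    if src_idx is None:
        return (), False
    for j in range(src_idx + 1, len(runs)):
        if runs[j][2] == target:
            inter = tuple(runs[i][2] for i in range(src_idx + 1, j))
            return inter, True
    return (), False


@dataclass
class BoundarySwitchStats:
    """Per-subject boundary switching matrices and traversal path counts.

    ``matrices[sid][direction]`` holds raw one-step transition counts and the
    row-normalised probabilities within the boundary windows; rows with no
    observed successor remain zero.  ``paths[sid][direction]`` counts
    completed OFF<->ON traversals classified as direct, via the Transition
    state, or multi-hop; incomplete traversals are tallied separately.
    """

    matrices: dict
    paths: dict
    n_states: int
    window: float

    def group_path_counts(self, direction=None) -> dict:
        total = Counter()
        for sid in self.paths:
            dirs = [direction] if direction else list(self.paths[sid])
            for d in dirs:
                total.update(self.paths[sid][d])
        return dict(total)


def boundary_switching(
    sequences: dict,
    design: BlockDesign,
    roles: StateRoleMap,
    n_states: int,
    window: float = 10.0,
) -> BoundarySwitchStats:
    """Switching statistics of dominant sequences around stimulation boundaries.

    Within +/- ``window`` seconds of every boundary, one-step transitions of
    the dominant sequence are tallied into a per-direction switching matrix
    (each transition counted once even if covered by several windows).  Each
    boundary's OFF->ON (or ON->OFF) traversal is classified as ``direct``
    (no intermediate state), ``via_transition``, or ``multi_hop``;
    traversals that do not complete inside the window are ``incomplete``.
    ``window=None`` pools every transition in the run (no boundary
    restriction).
    """
    if window is not None:
        if window <= 0:
            raise ValueError("window must be > 0")
        shortest = min(design.on_duration, design.off_duration,
                       design.rest_duration or np.inf)
        if window >= shortest:
            logger.info("boundary window %.1f s is not shorter than the "
                        "shortest block; windows will overlap/truncate", window)
        w = int(round(window / design.tr))
    matrices, paths = {}, {}
    for sid, seq in sequences.items():
        seq = np.asarray(seq)
        T = seq.size
        matrices[sid], paths[sid] = {}, {}
        for direction in (OFF_TO_ON, ON_TO_OFF):
            bnds = [b for b, d in design.boundaries if d == direction]
            trans_idx = set()
            path_counts = Counter(direct=0, via_transition=0, multi_hop=0,
                                  incomplete=0)
            for b in bnds:
                if window is None:
                    lo, hi = 0, T
                else:
                    lo, hi = max(0, b - w), min(T, b + w)
                    if b - w < 0 or b + w > T:
                        logger.info("subject %s: window at boundary %d "
                                    "truncated at run edge", sid, b)
                trans_idx.update(range(lo, min(hi, T) - 1))
                src, tgt = ((roles.off_state, roles.on_state)
                            if direction == OFF_TO_ON
                            else (roles.on_state, roles.off_state))
                if src is None or tgt is None:
                    continue
                inter, completed = _traversal(seq[lo:hi], b - lo, src, tgt)
                if not completed:
                    path_counts["incomplete"] += 1
                elif len(inter) == 0:
                    path_counts["direct"] += 1
                elif (len(set(inter)) == 1
                      and inter[0] == roles.transition_state
                      and roles.transition_state is not None):
                    path_counts["via_transition"] += 1
                else:
                    path_counts["multi_hop"] += 1
            counts = np.zeros((n_states, n_states))
            for t in sorted(trans_idx):
                counts[seq[t], seq[t + 1]] += 1
            probs = np.zeros_like(counts)
            rowsum = counts.sum(axis=1)
            nz = rowsum > 0
            probs[nz] = counts[nz] / rowsum[nz, None]
            matrices[sid][direction] = {"counts": counts, "probs": probs}
            paths[sid][direction] = dict(path_counts)
    return BoundarySwitchStats(matrices, paths, n_states, window)


def assign_state_roles(
    occupancy: pd.DataFrame,
    sequences: dict = None,
    design: BlockDesign = None,
    window: float = 10.0,
) -> StateRoleMap:
    """Name model states by their relationship to the stimulation design.

    The OFF state is the group-mean occupancy argmax during OFF, the ON
    state the argmax during ON.  If the same state wins both conditions
    (control-like regime) the ON role is left unassigned and flagged.  When
    dominant ``sequences`` and the ``design`` are supplied, the Transition
    role goes to the state most often traversed between the OFF and ON
    states at stimulation boundaries (path dominance).
    """
    group_mean = occupancy.groupby(["state", "condition"])["occupancy"].mean()
    off_state = int(group_mean.xs(OFF, level="condition").idxmax())
    on_candidate = int(group_mean.xs(ON, level="condition").idxmax())
    roles = StateRoleMap(off_state=off_state)
    if on_candidate == off_state:
        roles.flags["on_unassigned"] = (
            "the same state dominates both conditions (design-independent "
            "regime); ON role not assigned")
        return roles
    roles.on_state = on_candidate

    if sequences is not None and design is not None:
        inter_counter = Counter()
        w = int(round(window / design.tr))
        for sid, seq in sequences.items():
            seq = np.asarray(seq)
            T = seq.size
            for b, direction in design.boundaries:
                lo, hi = max(0, b - w), min(T, b + w)
                src, tgt = ((off_state, on_candidate) if direction == OFF_TO_ON
                            else (on_candidate, off_state))
                inter, completed = _traversal(seq[lo:hi], b - lo, src, tgt)
                if completed and len(set(inter)) == 1:
                    inter_counter[inter[0]] += 1
        inter_counter.pop(off_state, None)
        inter_counter.pop(on_candidate, None)
        if inter_counter:
            roles.transition_state = int(inter_counter.most_common(1)[0][0])
        else:
            roles.flags["transition_unassigned"] = (
                "no single-state traversals between OFF and ON states at "
                "the boundaries")
    return roles


def posterior_anticorrelation(posteriors, roles: StateRoleMap):
    """Pearson correlation between ON- and OFF-state posterior time courses.

    With only two states the correlation is exactly -1 (the rows of the
    posterior matrix sum to 1); with more states a negative group mean
    indicates mutual inhibition between the two condition-locked states.

    Returns ``(per_subject: dict, group_mean: float)``; subjects with a
    constant posterior column get NaN and a flag entry.
    """
    if roles.on_state is None or roles.off_state is None:
        raise ValueError("both ON and OFF roles must be assigned")
    per_subject = {}
    vals = []
    for p in posteriors:
        a = p.gamma[:, roles.on_state]
        b = p.gamma[:, roles.off_state]
        if a.std() == 0 or b.std() == 0:
            logger.warning("subject %s: constant posterior column; "
                           "correlation undefined", p.subject_id)
            per_subject[p.subject_id] = float("nan")
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        per_subject[p.subject_id] = r
        vals.append(r)
    group_mean = float(np.mean(vals)) if vals else float("nan")
    return per_subject, group_mean
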