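"""Blocked-stimulation experimental designs.

A run consists of an initial rest period (no stimulation, labelled OFF)
followed by ``n_epochs`` repetitions of a stimulation-ON block and a
recovery-OFF block.  All timing is expressed in seconds; sampling is
uniform with repetition time ``tr``.  Sample indices are 0-based and
stimulus intervals are half-open ``[onset, onset + duration)`` in
seconds: a sample carries the label of the interval containing its start
time, so block boundaries are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

OFF = "OFF"
ON = "ON"

#: boundary directions
OFF_TO_ON = "OFF->ON"
ON_TO_OFF = "ON->OFF"


def _check_divisible(duration: float, tr: float, name: str) -> int:
    n = duration / tr
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"repetition time {tr} s does not divide {name} ({duration} s) exactly"
        )
    return int(round(n))


@dataclass(frozen=True)
class BlockDesign:
    """Stimulation timeline of a blocked optogenetic-fMRI run.

    Attributes
    ----------
    rest_duration, on_duration, off_duration : float
        Durations in seconds of the initial rest period and of each
        ON / OFF block.
    n_epochs : int
        Number of ON/OFF epoch repetitions.
    tr : float
        Repetition time (seconds per sample).
    condition_labels : np.ndarray of str
        Per-sample condition, ``"OFF"`` or ``"ON"``; the rest prefix is
        labelled OFF.
    boundaries : list of (int, str)
        Sample index of the first sample after each condition change,
        paired with the direction (``"OFF->ON"`` or ``"ON->OFF"``).
    """

    rest_duration: float
    n_epochs: int
    on_duration: float
    off_duration: float
    tr: float
    total_duration: float = field(init=False)
    condition_labels: np.ndarray = field(init=False, repr=False)
    boundaries: list = field(init=False, repr=False)

    def __post_init__(self):
        for name, value in [
            ("rest_duration", self.rest_duration),
            ("on_duration", self.on_duration),
            ("off_duration", self.off_duration),
            ("tr", self.tr),
        ]:
            if value < 0 or (value <= 0 and name != "rest_duration"):
                raise ValueError(f"{name} must be positive (got {value})")
        if self.n_epochs < 1:
            raise ValueError(f"n_epochs must be >= 1 (got {self.n_epochs})")

        n_rest = _check_divisible(self.rest_duration, self.tr, "rest_duration")
        n_on = _check_divisible(self.on_duration, self.tr, "on_duration")
        n_off = _check_divisible(self.off_duration, self.tr, "off_duration")

        total = self.rest_duration + self.n_epochs * (self.on_duration + self.off_duration)
        labels = [OFF] * n_rest
        boundaries = []
        for _ in range(self.n_epochs):
            boundaries.append((len(labels), OFF_TO_ON))
            labels += [ON] * n_on
            boundaries.append((len(labels), ON_TO_OFF))
            labels += [OFF] * n_off
        object.__setattr__(self, "total_duration", total)
        object.__setattr__(self, "condition_labels", np.array(labels))
        object.__setattr__(self, "boundaries", boundaries)

    @property
    def n_timepoints(self) -> int:
        return self.condition_labels.size

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_duration / self.tr))

    def block_segments(self, include_rest: bool = True):
        """Maximal constant-condition segments as (start, stop, label) triples."""
        labels = self.condition_labels
        edges = [0] + [i for i, _ in self.boundaries] + [labels.size]
        segs = [
            (edges[j], edges[j + 1], labels[edges[j]])
            for j in range(len(edges) - 1)
            if edges[j] < edges[j + 1]
        ]
        if not include_rest and self.rest_samples > 0:
            segs = segs[1:]
        return segs

    def relabel_subblocks(self, subblock_duration: float):
        """Split every block into consecutive sub-blocks of equal duration.

        Returns a list of ``(condition, ordinal)`` per sample, ordinals
        starting at 1 within each block.  The coarse condition labels are
        recovered by dropping the ordinal.  ``subblock_duration`` must
        divide the rest, ON and OFF durations exactly.
        """
        n_sub = _check_divisible(subblock_duration, self.tr, "subblock_duration")
        for name, dur in [
            ("on_duration", self.on_duration),
            ("off_duration", self.off_duration),
            ("rest_duration", self.rest_duration),
        ]:
            if dur > 0:
                k = dur / subblock_duration
                if abs(k - round(k)) > 1e-9:
                    raise ValueError(
                        f"subblock_duration {subblock_duration} s does not divide "
                        f"{name} ({dur} s)"
                    )
        fine = []
        for start, stop, label in self.block_segments():
            for i in range(start, stop):
                fine.append((label, (i - start) // n_sub + 1))
        return fine


def build_block_design(
    rest_duration: float,
    n_epochs: int,
    on_duration: float,
    off_duration: float,
    tr: float = 1.0,
) -> BlockDesign:
    """Construct a :class:`BlockDesign`.

    With the study defaults ``(360, 8, 20, 80, tr=1)`` this yields a
    1160-sample timeline with an 800 s stimulation segment.
    """
    return BlockDesign(rest_duration, n_epochs, on_duration, off_duration, tr)
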