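"""ROI time-series containers, delimited-text I/O and CBV normalization.

Time series are stored as plain delimited text (TSV or CSV, auto-detected
from the header line): one header row of ROI labels, one row per sample.
The normalization pipeline follows iron-oxide contrast-agent (CBV-weighted)
fMRI conventions: percent change from a pre-stimulation baseline, sign
inversion (a signal decrease indexes an activity increase), then per-ROI
z-scoring over the whole run.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import BlockDesign

EXPERIMENTAL = "experimental"
CONTROL = "control"

#: canonical 9-node ROI set: anterior insula, prelimbic, cingulate and six
#: retrosplenial subdivisions ordered anterior to posterior.
DEFAULT_ROI_LABELS = (
    "AI", "PrL", "Cg", "RSC1", "RSC2", "RSC3", "RSC4", "RSC5", "RSC6",
)


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's (timepoints x ROIs) signal matrix."""

    subject_id: str
    group: str
    data: np.ndarray
    roi_labels: tuple
    tr: float = 1.0

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (timepoints x ROIs)")
        if data.shape[0] == 0:
            raise ValueError("time series has zero timepoints")
        if not np.all(np.isfinite(data)):
            bad = np.argwhere(~np.isfinite(data))[0]
            raise ValueError(
                f"non-finite value at row {bad[0]}, column {bad[1]}"
            )
        labels = tuple(self.roi_labels)
        if len(labels) != data.shape[1]:
            raise ValueError(
                f"{len(labels)} ROI labels for {data.shape[1]} columns"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate ROI labels: {dupes}")
        if self.group not in (EXPERIMENTAL, CONTROL):
            raise ValueError(f"group must be experimental or control, got {self.group!r}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "roi_labels", labels)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def check_design(self, design: BlockDesign) -> None:
        if self.n_timepoints != design.n_timepoints:
            raise ValueError(
                f"subject {self.subject_id}: {self.n_timepoints} samples but the "
                f"design specifies {design.n_timepoints}"
            )


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_roi_timeseries(
    path, subject_id: str = None, group: str = EXPERIMENTAL, tr: float = 1.0
) -> RoiTimeSeries:
    """Read a delimited-text time-series table (header = ROI labels)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        sep = _detect_sep(header)
        body = fh.read()
    labels = [c.strip() for c in header.rstrip("\n").split(sep)]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"{path}: duplicate ROI labels {dupes}")
    if not body.strip():
        raise ValueError(f"{path}: header only, zero timepoints")
    try:
        frame = pd.read_csv(_io.StringIO(body), sep=sep, header=None,
                            dtype=float, float_precision="round_trip")
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric or ragged table ({err})") from err
    if frame.isna().any().any():
        r, c = np.argwhere(frame.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing/ragged cell at data row {r}, column {c}")
    if frame.shape[1] != len(labels):
        raise ValueError(
            f"{path}: {frame.shape[1]} data columns but {len(labels)} header labels"
        )
    return RoiTimeSeries(
        subject_id=subject_id or path.stem,
        group=group,
        data=frame.to_numpy(),
        roi_labels=tuple(labels),
        tr=tr,
    )


def save_roi_timeseries(ts: RoiTimeSeries, path, sep: str = "\t", decimals: int = 17):
    """Write a time series as delimited text; round-trips through
    :func:`load_roi_timeseries` at the stated decimal precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(sep.join(ts.roi_labels) + "\n")
        np.savetxt(fh, ts.data, fmt=f"%.{decimals}g", delimiter=sep)
    return path


def zscore(data: np.ndarray) -> np.ndarray:
    """Per-column z-score (population SD); rejects constant columns."""
    data = np.asarray(data, dtype=float)
    sd = data.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"zero-variance column(s) at index {np.where(sd == 0)[0].tolist()}")
    return (data - data.mean(axis=0)) / sd


def cbv_normalize(
    raw: RoiTimeSeries, baseline_window: tuple, design: BlockDesign = None
) -> RoiTimeSeries:
    """CBV-contrast normalization of a raw ROI time series.

    Per ROI: percent change from the baseline-window mean, sign-inverted
    (CBV contrast: signal decrease <-> activity increase), then z-scored
    over the full run, so the output has per-ROI mean 0 and unit variance.

    Parameters
    ----------
    baseline_window : (start, stop)
        Half-open sample-index range inside the rest prefix.
    design : BlockDesign, optional
        When given, the window is checked to lie inside the rest prefix.
    """
    start, stop = baseline_window
    if not (0 <= start < stop <= raw.n_timepoints):
        raise ValueError(f"empty or out-of-range baseline window ({start}, {stop})")
    if design is not None and stop > design.rest_samples:
        raise ValueError(
            f"baseline window extends to sample {stop}, beyond the "
            f"{design.rest_samples}-sample rest prefix"
        )
    baseline = raw.data[start:stop].mean(axis=0)
    zero = np.where(baseline == 0)[0]
    if zero.size:
        raise ValueError(
            f"zero baseline mean for ROI(s) {[raw.roi_labels[i] for i in zero]}"
        )
    pct = 100.0 * (raw.data - baseline) / baseline
    inverted = -pct
    try:
        normalized = zscore(inverted)
    except ValueError as err:
        raise ValueError(f"subject {raw.subject_id}: {err}") from err
    return replace(raw, data=normalized)


def default_baseline_window(design: BlockDesign, duration: float = 60.0) -> tuple:
    """Final ``duration`` seconds of the rest prefix (pre-stimulation)."""
    n = design.rest_samples
    w = min(n, int(round(duration / design.tr)))
    if w < 1:
        raise ValueError("design has no rest prefix to take a baseline from")
    return (n - w, n)
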