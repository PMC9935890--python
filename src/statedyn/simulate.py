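"""Synthetic multi-subject ROI time series with known latent-state ground truth.

The generator mirrors the statistical structure the switching-state analysis
assumes: each subject's run is a sequence of discrete latent states; within a
state run the ROI signal fluctuates around the state's activation mean as a
stationary AR(1) process with the state's covariance; white observation noise,
a hemodynamic lag and temporal Gaussian smoothing are then applied, and the
series is z-scored per ROI as real runs are after CBV normalization.

Experimental subjects express an OFF state throughout no-stimulation periods,
a short-lived Transition state after every stimulation boundary (both
directions), and an ON state for the remainder of each stimulation block.
Control subjects express design-independent states with slow Markov switching.

Hemodynamic realism is a lag plus Gaussian smoothing rather than a full
haemodynamic response model: the analysis operates at state timescales of
tens of seconds, where this suffices and keeps ground truth analytically
checkable.  The lag is applied to the state sequence itself, and the stored
ground truth is the lag-shifted sequence actually expressed in the signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .design import BlockDesign, build_block_design, ON, OFF
from .io import (
    CONTROL,
    DEFAULT_ROI_LABELS,
    EXPERIMENTAL,
    RoiTimeSeries,
    save_roi_timeseries,
)

STATE_OFF = "OFF"
STATE_ON = "ON"
STATE_TRANSITION = "Transition"


@dataclass(frozen=True)
class StateSpec:
    """Generative description of one latent brain state."""

    name: str
    mean: np.ndarray        # per-ROI activation level, z-units
    cov: np.ndarray         # ROI x ROI stationary covariance, positive definite
    dynamics: float = 0.6   # latent AR(1) coefficient, |a| < 1

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (mean.size, mean.size):
            raise ValueError(f"state {self.name}: covariance shape {cov.shape} "
                             f"does not match {mean.size} ROIs")
        if not np.allclose(cov, cov.T):
            raise ValueError(f"state {self.name}: covariance not symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError(f"state {self.name}: covariance not positive definite")
        if not abs(self.dynamics) < 1:
            raise ValueError(f"state {self.name}: |dynamics| must be < 1")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)


def _base_correlation(n: int) -> np.ndarray:
    """Baseline (OFF) correlation: positive AI<->RSC coupling, smooth
    neighbour structure along the RSC anterior-posterior axis."""
    r = np.eye(n)
    n_rsc = n - 3
    for j in range(3, n):          # AI with every RSC subdivision
        r[0, j] = r[j, 0] = 0.35
    r[0, 1] = r[1, 0] = 0.15       # AI-PrL
    r[0, 2] = r[2, 0] = 0.15       # AI-Cg
    r[1, 2] = r[2, 1] = 0.20       # PrL-Cg
    for i in range(3, n):          # within-RSC smoothness
        for j in range(i + 1, n):
            d = j - i
            r[i, j] = r[j, i] = 0.4 if d == 1 else (0.2 if d == 2 else 0.1)
    # guard positive definiteness for small n_rois
    lam = np.linalg.eigvalsh(r).min()
    if lam <= 1e-6:
        r = r + (1e-6 - lam) * np.eye(n)
        r = r / r[0, 0]
    assert n_rsc >= 0
    return r


def default_state_specs(n_rois: int = 9) -> list:
    """OFF / ON / Transition state specifications for the canonical node set.

    Conventions: the first three ROIs are AI, PrL, Cg; the remainder are RSC
    subdivisions ordered anterior to posterior.  The ON state elevates AI and
    PrL, suppresses anterior-to-mid RSC, decouples AI from anterior RSC and
    strengthens PrL-Cg coupling; the Transition state strongly suppresses
    anterior-mid RSC, activates posterior RSC, and strengthens AI coupling to
    mid RSC.  Magnitudes are free generative parameters.
    """
    if n_rois < 3:
        raise ValueError(f"n_rois must be >= 3 (got {n_rois})")
    n_rsc = n_rois - 3
    # within-state fluctuation variance (z-units squared): state contrasts
    # (means up to ~0.8) clearly dominate within-state noise, mirroring the
    # near-saturated state posteriors blocked stimulation elicits
    var = 0.2

    r_off = _base_correlation(n_rois)
    off_mean = np.zeros(n_rois)

    on_mean = np.zeros(n_rois)
    on_mean[0] = 0.8          # AI activation
    on_mean[1] = 0.6          # PrL activation
    on_mean[2] = 0.3          # Cg
    rsc_profile = [-0.6, -0.5, -0.4, -0.2, -0.1, 0.0]
    for k in range(n_rsc):
        on_mean[3 + k] = rsc_profile[k] if k < 6 else 0.0
    r_on = r_off.copy()
    if n_rsc > 0:
        r_on[0, 3] = r_on[3, 0] = 0.05    # AI decoupled from anterior RSC
    r_on[1, 2] = r_on[2, 1] = 0.55        # PrL-Cg strengthened

    tr_mean = np.zeros(n_rois)
    tr_mean[0] = 0.3
    tr_profile = [-0.8, -0.8, -0.8, 0.0, 0.4, 0.4]
    for k in range(n_rsc):
        tr_mean[3 + k] = tr_profile[k] if k < 6 else 0.0
    r_tr = r_off.copy()
    if n_rsc > 0:
        mid = 3 + min(3, n_rsc - 1)   # mid-RSC subdivision
        r_tr[0, mid] = r_tr[mid, 0] = 0.60

    return [
        StateSpec(STATE_OFF, off_mean, var * r_off, dynamics=0.6),
        StateSpec(STATE_ON, on_mean, var * r_on, dynamics=0.6),
        StateSpec(STATE_TRANSITION, tr_mean, var * r_tr, dynamics=0.4),
    ]


def default_control_specs(n_rois: int = 9) -> list:
    """Design-independent states for the control group: the baseline OFF
    state plus two generic nuisance states (3 states, matching the number
    typically resolved in unstimulated animals)."""
    specs = default_state_specs(n_rois)
    off = specs[0]
    m1 = np.full(n_rois, 0.4)
    m2 = 0.4 * np.array([(-1) ** i for i in range(n_rois)], dtype=float)
    return [
        off,
        StateSpec("nuisance1", m1, off.cov, dynamics=0.6),
        StateSpec("nuisance2", m2, off.cov, dynamics=0.6),
    ]


@dataclass
class SyntheticConfig:
    """Conditions of the emulated study.

    Defaults follow the study design: a 1160 s run at 1 s repetition time
    (360 s rest, then 8 epochs of 20 s ON / 80 s OFF), 9 ROIs, 9
    experimental and 7 control subjects, a ~5 s Transition dwell after each
    stimulation boundary, 2 s hemodynamic lag, 2 s FWHM temporal smoothing
    and 0.1 z-units of white observation noise.
    """

    n_experimental: int = 9
    n_control: int = 7
    n_rois: int = 9
    rest_duration: float = 360.0
    n_epochs: int = 8
    on_duration: float = 20.0
    off_duration: float = 80.0
    tr: float = 1.0
    transition_dwell: float = 5.0
    hemodynamic_lag: float = 2.0
    smoothing_fwhm: float = 2.0
    observation_noise_sd: float = 0.1
    seed: int = 0
    states: list = None
    control_states: list = None
    roi_labels: tuple = None

    def __post_init__(self):
        if self.n_experimental < 0 or self.n_control < 0:
            raise ValueError("subject counts must be >= 0")
        if self.n_experimental + self.n_control < 1:
            raise ValueError("at least one subject required")
        if self.states is None:
            self.states = default_state_specs(self.n_rois)
        if self.control_states is None:
            self.control_states = default_control_specs(self.n_rois)
        if self.roi_labels is None:
            if self.n_rois == len(DEFAULT_ROI_LABELS):
                self.roi_labels = DEFAULT_ROI_LABELS
            else:
                self.roi_labels = tuple(f"ROI{i+1}" for i in range(self.n_rois))
        for spec in list(self.states) + list(self.control_states):
            if spec.mean.size != self.n_rois:
                raise ValueError(f"state {spec.name} has {spec.mean.size} ROIs, "
                                 f"config says {self.n_rois}")

    def design(self) -> BlockDesign:
        return build_block_design(
            self.rest_duration, self.n_epochs, self.on_duration,
            self.off_duration, self.tr,
        )

    def state_names(self, group: str) -> list:
        specs = self.states if group == EXPERIMENTAL else self.control_states
        return [s.name for s in specs]


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one synthetic subject.

    ``sequence`` is the per-sample state name actually expressed in the
    signal (hemodynamic lag already applied).  ``loc``/``scale`` are the
    per-ROI affine normalization applied at the end of generation, so any
    planted mean ``m`` appears in the output at ``(m - loc) / scale``.
    """

    subject_id: str
    sequence: np.ndarray
    specs: list
    seed: int
    loc: np.ndarray = None
    scale: np.ndarray = None

    def mean_in_output_units(self, spec: StateSpec) -> np.ndarray:
        return (spec.mean - self.loc) / self.scale

    def cov_in_output_units(self, spec: StateSpec) -> np.ndarray:
        d = 1.0 / self.scale
        return spec.cov * np.outer(d, d)


def _truncated_geometric(rng, mean_samples: float, upper: int, lower: int = 3) -> int:
    """Jittered dwell on {lower, ..., upper} with mean ~ mean_samples.

    A geometric tail shifted to start at ``lower``: truncating below keeps
    the jitter small relative to the mean and ensures the planted state
    outlives the temporal smoothing kernel instead of being erased by it.
    """
    lower = max(1, min(lower, upper))
    tail_mean = max(mean_samples - lower + 1.0, 1.0)
    d = lower + rng.geometric(1.0 / tail_mean) - 1
    return int(min(max(d, lower), upper))


def plant_state_sequence(
    design: BlockDesign,
    group: str,
    transition_dwell: float = 5.0,
    rng=None,
    control_state_names=("OFF", "nuisance1", "nuisance2"),
    jitter: bool = True,
) -> np.ndarray:
    """Per-sample planted state names for one subject.

    Experimental: OFF through rest and OFF blocks, a Transition dwell after
    every boundary (both directions), ON for the remainder of ON blocks.
    Dwell lengths are jittered (truncated geometric, mean ``transition_dwell``)
    unless ``jitter`` is False.  Control: a slow design-independent Markov
    chain over ``control_state_names`` biased toward its first state.
    """
    rng = np.random.default_rng(rng)
    n = design.n_timepoints
    if group == CONTROL:
        k = len(control_state_names)
        pi = np.zeros(k)
        pi[0] = 1.0
        trans = np.full((k, k), 0.0)
        for i in range(k):
            trans[i, i] = 0.98
            leak = 0.02
            others = [j for j in range(k) if j != i]
            for j in others:
                # bias re-entry into the first (baseline) state
                trans[i, j] = leak * (0.7 if j == 0 else 0.3 / (k - 2 if k > 2 else 1)) \
                    if k > 2 else leak
        trans = trans / trans.sum(axis=1, keepdims=True)
        seq = np.empty(n, dtype=object)
        z = rng.choice(k, p=pi)
        for t in range(n):
            seq[t] = control_state_names[z]
            z = rng.choice(k, p=trans[z])
        return seq.astype(str)

    dwell_samples = transition_dwell / design.tr
    if transition_dwell >= design.on_duration:
        raise ValueError(
            f"transition_dwell ({transition_dwell} s) must be shorter than "
            f"on_duration ({design.on_duration} s)"
        )
    seq = np.empty(n, dtype=object)
    for start, stop, label in design.block_segments():
        state = STATE_ON if label == ON else STATE_OFF
        seq[start:stop] = state
        if start == 0:      # rest prefix: no preceding boundary
            continue
        if dwell_samples > 0:
            upper = stop - start - 1
            if upper >= 1:
                d = (_truncated_geometric(rng, dwell_samples, upper)
                     if jitter else int(min(round(dwell_samples), upper)))
                seq[start:start + d] = STATE_TRANSITION
    return seq.astype(str)


def simulate_state_run(spec: StateSpec, n_samples: int, rng) -> np.ndarray:
    """Stationary AR(1) fluctuation around a state's mean (no noise/filtering)."""
    rng = np.random.default_rng(rng)
    d = spec.mean.size
    chol = np.linalg.cholesky(spec.cov)
    a = spec.dynamics
    x = np.empty((n_samples, d))
    x[0] = chol @ rng.standard_normal(d)
    innov_scale = np.sqrt(1.0 - a * a)
    eps = rng.standard_normal((n_samples - 1, d)) if n_samples > 1 else None
    for t in range(1, n_samples):
        x[t] = a * x[t - 1] + innov_scale * (chol @ eps[t - 1])
    return spec.mean + x


def generate_subject(
    config: SyntheticConfig, group: str, subject_seed, subject_id: str = None
):
    """Generate one subject: returns ``(RoiTimeSeries, GroundTruth)``."""
    rng = np.random.default_rng(subject_seed)
    design = config.design()
    specs = config.states if group == EXPERIMENTAL else config.control_states
    by_name = {s.name: s for s in specs}

    seq = plant_state_sequence(
        design, group, config.transition_dwell, rng,
        control_state_names=tuple(s.name for s in config.control_states),
    )
    lag = int(round(config.hemodynamic_lag / config.tr))
    if lag > 0:
        seq = np.concatenate([np.repeat(seq[0], lag), seq[:-lag]])

    n = design.n_timepoints
    data = np.empty((n, config.n_rois))
    t = 0
    while t < n:
        run_end = t
        while run_end < n and seq[run_end] == seq[t]:
            run_end += 1
        data[t:run_end] = simulate_state_run(by_name[seq[t]], run_end - t, rng)
        t = run_end
    if config.observation_noise_sd > 0:
        data = data + config.observation_noise_sd * rng.standard_normal(data.shape)
    if config.smoothing_fwhm > 0:
        sigma = config.smoothing_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / config.tr
        data = gaussian_filter1d(data, sigma=sigma, axis=0, mode="nearest")

    loc = data.mean(axis=0)
    scale = data.std(axis=0)
    if np.any(scale == 0):
        raise ValueError("degenerate zero-variance channel in generated data")
    data = (data - loc) / scale

    if isinstance(subject_seed, np.random.SeedSequence):
        seed_repr = int(subject_seed.generate_state(1)[0] % (2**31 - 1))
    else:
        seed_repr = int(subject_seed)
    sid = subject_id or f"{group[:3]}-{seed_repr & 0xFFFF:04x}"
    ts = RoiTimeSeries(subject_id=sid, group=group, data=data,
                       roi_labels=config.roi_labels, tr=config.tr)
    truth = GroundTruth(subject_id=sid, sequence=seq, specs=list(specs),
                        seed=seed_repr, loc=loc, scale=scale)
    return ts, truth


def generate_cohort(config: SyntheticConfig):
    """Generate the full cohort; returns a list of ``(RoiTimeSeries, GroundTruth)``.

    Subject seeds derive deterministically from ``config.seed`` so the whole
    cohort is reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_experimental + config.n_control)
    out = []
    for i in range(config.n_experimental):
        out.append(generate_subject(config, EXPERIMENTAL, children[i],
                                    subject_id=f"exp{i+1:02d}"))
    for j in range(config.n_control):
        out.append(generate_subject(config, CONTROL,
                                    children[config.n_experimental + j],
                                    subject_id=f"ctl{j+1:02d}"))
    return out


def write_cohort(cohort, out_dir, config: SyntheticConfig = None):
    """Write per-subject TSV files plus a ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_doc = {}
    for ts, gt in cohort:
        save_roi_timeseries(ts, out_dir / f"{ts.subject_id}.tsv")
        truth_doc[ts.subject_id] = {
            "group": ts.group,
            "sequence": gt.sequence.tolist(),
            "seed": gt.seed,
            "loc": gt.loc.tolist(),
            "scale": gt.scale.tolist(),
        }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
    return out_dir
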