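"""End-to-end orchestration: simulate/ingest -> fit -> dynamics -> contrasts
-> classify, with deterministic seeding and a single machine-readable report.

Every stochastic stage derives its seed from the master seed, so a config
run twice produces byte-identical reports.  Arrays are serialized to one
hierarchical HDF5 container per run; statistics to JSON; tables to TSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .classify import ClassifierConfig, classify_blocks, permutation_test, posterior_features
from .contrasts import (
    activation_contrast,
    connectivity_contrast,
    direct_fc_validation,
    fc_agreement,
    subject_state_estimates,
)
from .design import BlockDesign, build_block_design
from .dynamics import (
    assign_state_roles,
    boundary_switching,
    occupancy_rates,
    posterior_anticorrelation,
)
from .io import CONTROL, EXPERIMENTAL, RoiTimeSeries
from .model import ModelConfig, SwitchingStateModel
from .simulate import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "fit", "dynamics", "contrasts", "classify")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    seed: int = 0
    stages: tuple = ALL_STAGES
    synthetic: SyntheticConfig = None
    model: ModelConfig = None
    classifier: ClassifierConfig = None
    boundary_window: float = 10.0
    contrast_alpha: float = 0.01
    occupancy_alpha: float = 0.05
    mass_threshold: float = 5.0
    include_rest: bool = True
    input_dir: str = None       # ingest instead of simulate when set
    run_permutation: bool = True

    def __post_init__(self):
        if self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        if self.model is None:
            self.model = ModelConfig()
        if self.classifier is None:
            self.classifier = ClassifierConfig()
        self.stages = tuple(self.stages)

    # -- serialization round-trip ------------------------------------------
    _SYN_SCALARS = ("n_experimental", "n_control", "n_rois", "rest_duration",
                    "n_epochs", "on_duration", "off_duration", "tr",
                    "transition_dwell", "hemodynamic_lag", "smoothing_fwhm",
                    "observation_noise_sd", "seed")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": list(self.stages),
            "synthetic": {k: getattr(self.synthetic, k) for k in self._SYN_SCALARS},
            "model": dataclasses.asdict(self.model),
            "classifier": dataclasses.asdict(self.classifier),
            "boundary_window": self.boundary_window,
            "contrast_alpha": self.contrast_alpha,
            "occupancy_alpha": self.occupancy_alpha,
            "mass_threshold": self.mass_threshold,
            "include_rest": self.include_rest,
            "input_dir": self.input_dir,
            "run_permutation": self.run_permutation,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        if "synthetic" in doc and isinstance(doc["synthetic"], dict):
            doc["synthetic"] = SyntheticConfig(**doc["synthetic"])
        if "model" in doc and isinstance(doc["model"], dict):
            doc["model"] = ModelConfig(**doc["model"])
        if "classifier" in doc and isinstance(doc["classifier"], dict):
            doc["classifier"] = ClassifierConfig(**doc["classifier"])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


@dataclass
class PipelineRun:
    """Outputs of one pipeline execution: the JSON-ready report plus the
    in-memory objects each stage produced."""

    report: dict
    config: PipelineConfig
    cohort: list = None                 # list of (RoiTimeSeries, GroundTruth|None)
    results: dict = field(default_factory=dict)       # group -> SwitchingStateResults
    roles: dict = field(default_factory=dict)
    occupancy: dict = field(default_factory=dict)
    switching: dict = field(default_factory=dict)
    contrasts: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as err:
                raise PipelineError(f"stage '{name}' failed: {err}") from err
        return wrapped
    return deco


def _derive_seeds(master: int, names):
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1))
            for n, c in zip(names, children)}


def _group_analysis(group, cohort_ts, results, design, cfg, seeds, report, run):
    """Dynamics + classification for one group; contrasts for experimental."""
    k = results.config.k_max
    sequences = {p.subject_id: p.dominant for p in results.posteriors}
    occ = occupancy_rates(sequences, design, k, include_rest=cfg.include_rest)
    roles = assign_state_roles(occ, sequences, design, window=cfg.boundary_window)
    run.occupancy[group] = occ
    run.roles[group] = roles

    section = report[group]
    section["effective_state_count"] = results.effective_state_count()
    section["effective_states"] = results.effective_states()
    section["state_weights"] = results.state_weights.round(6)
    section["converged"] = results.converged
    section["elbo"] = round(results.elbo, 6)
    section["roles"] = {**{r: int(s) for r, s in roles.assigned().items()},
                        "flags": roles.flags}
    mean_occ = (occ.groupby(["state", "condition"])["occupancy"]
                .mean().unstack())
    section["group_mean_occupancy"] = {
        cond: mean_occ[cond].round(6).to_dict() for cond in mean_occ.columns}

    if "dynamics" in cfg.stages:
        stats = boundary_switching(sequences, design, roles, k,
                                   window=cfg.boundary_window)
        run.switching[group] = stats
        section["boundary_path_counts"] = stats.group_path_counts()
        if roles.on_state is not None:
            per_subj, group_mean = posterior_anticorrelation(
                results.posteriors, roles)
            section["on_off_anticorrelation"] = {
                "per_subject": {s: round(v, 6) for s, v in per_subj.items()},
                "group_mean": round(group_mean, 6)}

    if "classify" in cfg.stages:
        clf_cfg = replace(cfg.classifier, seed=seeds[f"classify_{group}"])
        feats = posterior_features(results.posteriors)
        try:
            res = classify_blocks(feats, design.condition_labels, clf_cfg)
            if cfg.run_permutation:
                res = permutation_test(feats, design.condition_labels, clf_cfg,
                                       observed=res)
            run.classification[group] = res
            section["classification"] = _jsonable(res.as_dict())
        except ValueError as err:
            # e.g. a fully collapsed fit yields constant posterior features;
            # record the rejection rather than aborting the other stages
            logger.warning("classification rejected for %s group: %s", group, err)
            section["classification"] = {"error": str(err)}
    return roles


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineRun:
    """Execute the enabled stages in order and assemble the report."""
    cfg = config
    seeds = _derive_seeds(cfg.seed, ["simulate", "fit_experimental",
                                     "fit_control", "classify_experimental",
                                     "classify_control"])
    report = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "config": cfg.to_dict(),
        EXPERIMENTAL: {},
        CONTROL: {},
    }
    run = PipelineRun(report=report, config=cfg)

    # ---- cohort ----------------------------------------------------------
    if cfg.input_dir:
        cohort = _stage("ingest")(load_cohort_dir)(cfg.input_dir, tr=cfg.synthetic.tr)
        design = cfg.synthetic.design()
    else:
        if "simulate" not in cfg.stages:
            raise PipelineError("stage 'simulate' disabled and no input_dir given")
        syn = replace(cfg.synthetic, seed=seeds["simulate"])
        cohort = _stage("simulate")(generate_cohort)(syn)
        design = syn.design()
    run.cohort = cohort
    report["design"] = {
        "total_duration": design.total_duration,
        "n_timepoints": design.n_timepoints,
        "n_epochs": design.n_epochs,
        "n_on_samples": int((design.condition_labels == "ON").sum()),
    }

    if "fit" not in cfg.stages:
        return run

    groups = {}
    for group in (EXPERIMENTAL, CONTROL):
        ts_list = [ts for ts, _ in cohort if ts.group == group]
        if not ts_list:
            continue
        for ts in ts_list:
            ts.check_design(design)
        mdl_cfg = replace(cfg.model, seed=seeds[f"fit_{group}"])
        results = _stage("fit")(
            lambda tl, mc: SwitchingStateModel(tl, mc).fit())(ts_list, mdl_cfg)
        run.results[group] = results
        groups[group] = ts_list
        _stage("dynamics")(_group_analysis)(
            group, ts_list, results, design, cfg, seeds, report, run)

    # ---- contrasts (experimental group) ----------------------------------
    if "contrasts" in cfg.stages and EXPERIMENTAL in run.results:
        results = run.results[EXPERIMENTAL]
        roles = run.roles[EXPERIMENTAL]
        report[EXPERIMENTAL]["contrasts"] = _stage("contrasts")(_contrast_stage)(
            groups[EXPERIMENTAL], results, roles, cfg, run)

    if out_dir is not None:
        write_run(run, out_dir)
    return run


def _contrast_stage(ts_list, results, roles, cfg, run):
    estimates = [subject_state_estimates(ts, p, cfg.mass_threshold)
                 for ts, p in zip(ts_list, results.posteriors)]
    out = {}
    assigned = roles.assigned()
    pairs = []
    if "ON" in assigned and "OFF" in assigned:
        pairs.append(("ON", "OFF"))
    if "Transition" in assigned and "OFF" in assigned:
        pairs.append(("Transition", "OFF"))
    if "ON" in assigned and "Transition" in assigned:
        pairs.append(("ON", "Transition"))
    labels = results.roi_labels
    for ra, rb in pairs:
        a, b = assigned[ra], assigned[rb]
        act = activation_contrast(estimates, a, b, labels, cfg.contrast_alpha)
        con = connectivity_contrast(estimates, a, b, labels, cfg.contrast_alpha)
        run.contrasts[(ra, rb)] = (act, con)
        out[f"{ra}_vs_{rb}"] = {
            "activation": _jsonable(act.table.round(6).reset_index()
                                    .to_dict(orient="records")),
            "connectivity_significant": _jsonable(
                con.significant().round(6).reset_index()
                .to_dict(orient="records")),
        }
    seqs = {p.subject_id: p.dominant for p in results.posteriors}
    direct, flagged = direct_fc_validation(
        ts_list, seqs, list(assigned.values()))
    out["direct_fc_median_abs_diff"] = fc_agreement(
        direct, estimates, list(assigned.values()))
    out["direct_fc_skipped"] = _jsonable(flagged)
    return out


def compare_groups(report_experimental: dict, report_control: dict) -> dict:
    """Side-by-side group comparison and the stimulation-specificity flag:
    condition-locked (distinct ON/OFF) states in the experimental group only,
    with above-control decoding accuracy."""
    for key in ("design",):
        if report_experimental.get(key) != report_control.get(key):
            raise ValueError("mismatched designs between reports")
    exp = report_experimental[EXPERIMENTAL]
    ctl = report_control[CONTROL]
    if not exp or not ctl:
        raise ValueError("both reports must contain fitted group sections")
    exp_roles = exp.get("roles", {})
    ctl_roles = ctl.get("roles", {})
    exp_locked = "ON" in exp_roles and "OFF" in exp_roles
    ctl_locked = "ON" in ctl_roles and "OFF" in ctl_roles
    acc_exp = (exp.get("classification") or {}).get("mean_accuracy")
    acc_ctl = (ctl.get("classification") or {}).get("mean_accuracy")
    specificity = bool(
        exp_locked and not ctl_locked
        and acc_exp is not None and acc_ctl is not None
        and acc_exp > acc_ctl)
    return {
        "effective_state_count": {
            "experimental": exp.get("effective_state_count"),
            "control": ctl.get("effective_state_count")},
        "condition_locked_states": {
            "experimental": exp_locked, "control": ctl_locked},
        "classification_accuracy": {
            "experimental": acc_exp, "control": acc_ctl},
        "specificity_flag": specificity,
    }


# ----------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------

def write_run(run: PipelineRun, out_dir):
    """Write report.json, per-table TSVs and one HDF5 array container."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_jsonable(run.report), fh, indent=1, sort_keys=True)
    for group, occ in run.occupancy.items():
        occ.to_csv(out_dir / f"occupancy_{group}.tsv", sep="\t", index=False)
    for (ra, rb), (act, con) in run.contrasts.items():
        act.table.to_csv(out_dir / f"contrast_{ra}_vs_{rb}_activation.tsv", sep="\t")
        con.table.to_csv(out_dir / f"contrast_{ra}_vs_{rb}_connectivity.tsv", sep="\t")
    with h5py.File(out_dir / "arrays.h5", "w") as h5:
        for group, results in run.results.items():
            g = h5.create_group(group)
            g.create_dataset("state_means", data=results.state_means)
            g.create_dataset("state_covs", data=results.state_covs)
            g.create_dataset("transition_matrix", data=results.transition_matrix)
            g.create_dataset("state_weights", data=results.state_weights)
            g.create_dataset("elbo_trace", data=results.elbo_trace)
            for p in results.posteriors:
                sg = g.create_group(f"posterior/{p.subject_id}")
                sg.create_dataset("gamma", data=p.gamma)
                sg.create_dataset("dominant", data=p.dominant)
    logger.info("run written to %s (seeds %s)", out_dir, run.report["stage_seeds"])
    return out_dir


def save_cohort_h5(cohort, path, design: BlockDesign = None):
    """Normalized cohort in one hierarchical container."""
    with h5py.File(path, "w") as h5:
        if design is not None:
            h5.attrs["rest_duration"] = design.rest_duration
            h5.attrs["n_epochs"] = design.n_epochs
            h5.attrs["on_duration"] = design.on_duration
            h5.attrs["off_duration"] = design.off_duration
            h5.attrs["tr"] = design.tr
        for item in cohort:
            ts = item[0] if isinstance(item, tuple) else item
            g = h5.create_group(ts.subject_id)
            g.create_dataset("data", data=ts.data)
            g.attrs["group"] = ts.group
            g.attrs["tr"] = ts.tr
            g.attrs["roi_labels"] = ",".join(ts.roi_labels)
    return path


def load_cohort_h5(path):
    cohort, design = [], None
    with h5py.File(path, "r") as h5:
        if "rest_duration" in h5.attrs:
            design = build_block_design(
                float(h5.attrs["rest_duration"]), int(h5.attrs["n_epochs"]),
                float(h5.attrs["on_duration"]), float(h5.attrs["off_duration"]),
                float(h5.attrs["tr"]))
        for sid in sorted(h5.keys()):
            g = h5[sid]
            cohort.append(RoiTimeSeries(
                subject_id=sid, group=str(g.attrs["group"]),
                data=g["data"][()],
                roi_labels=tuple(str(g.attrs["roi_labels"]).split(",")),
                tr=float(g.attrs["tr"])))
    return cohort, design


def load_cohort_dir(path, tr: float = 1.0):
    """Load a cohort directory written by :func:`statedyn.simulate.write_cohort`."""
    from .io import load_roi_timeseries

    path = Path(path)
    meta_path = path / "ground_truth.json"
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    cohort = []
    for tsv in sorted(path.glob("*.tsv")):
        sid = tsv.stem
        group = meta.get(sid, {}).get("group", EXPERIMENTAL)
        cohort.append((load_roi_timeseries(tsv, subject_id=sid, group=group,
                                           tr=tr), None))
    if not cohort:
        raise ValueError(f"no subject TSV files found in {path}")
    return cohort
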