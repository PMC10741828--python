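"""End-to-end run: simulate/load -> preprocess -> laterality -> states -> stats.

Every stage draws its seed from a master seed via a counter scheme so
identical config + seed reproduce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import RoiAtlas
from .io import (bandpass, detrend_and_regress, discard_initial_volumes,
                 read_roi_timeseries)
from .laterality import (WindowSpec, laterality_series, metric_table,
                         state_laterality_correlation)
from .states import fit_states
from .stats import clinical_correlations, demographics_table, group_compare
from .synthetic import SimulationSpec, simulate_cohort, write_cohort

log = logging.getLogger("dynlat")


@dataclass
class RunConfig:
    """Analysis configuration; defaults follow the reference protocol
    (50/1 windows, resolution grid 0.1-1.5 step 0.1, alpha 0.05)."""

    mode: str = "simulate"  # simulate | tsv
    input_dir: str | None = None
    window_length: int = 50
    window_step: int = 1
    gs_exclude_self: bool = False
    lf_ddof: int = 1
    aggregate_first: bool = True
    preprocess: bool = False
    n_discard: int = 10
    bandpass_low: float = 0.01
    bandpass_high: float = 0.1
    k1: int = 5
    r_min: float = 0.1
    r_max: float = 1.5
    r_step: float = 0.1
    afg_restarts: int = 8
    alpha: float = 0.05
    correlation_sidedness: str = "two-sided"
    patient_group: str = "BD"
    control_group: str = "NC"
    seed: int = 0
    n_per_group: int = 12
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(d) - known)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seed(cfg: RunConfig, stage: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stage,))


def load_tsv_cohort(input_dir, tr_seconds: float = 2.0):
    """Load atlas.tsv, subjects/*.tsv, manifest.csv and optional scores.csv."""
    root = Path(input_dir)
    atlas = RoiAtlas.read_tsv(root / "atlas.tsv")
    manifest = pd.read_csv(root / "manifest.csv")
    subjects = []
    for sid in manifest["subject_id"]:
        subjects.append(
            read_roi_timeseries(root / "subjects" / f"{sid}.tsv",
                                tr_seconds=tr_seconds, subject_id=str(sid))
        )
    groups = dict(zip(manifest["subject_id"].astype(str), manifest["group"]))
    scores_path = root / "scores.csv"
    scores = (
        pd.read_csv(scores_path).set_index("subject_id")
        if scores_path.exists()
        else pd.DataFrame()
    )
    return atlas, subjects, groups, manifest, scores


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Execute all stages and write artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---------------------------------------------------------- stage 0: data
    if cfg.mode == "simulate":
        sim_spec = SimulationSpec(**{"seed": cfg.seed, **cfg.simulation})
        cohort = simulate_cohort(sim_spec, cfg.n_per_group,
                                 seed=_stage_seed(cfg, 0),
                                 patient_group=cfg.patient_group,
                                 control_group=cfg.control_group)
        write_cohort(cohort, out / "cohort")
        atlas = cohort.atlas
        groups = cohort.groups
        scores = cohort.scores
        demographics = cohort.demographics
        subjects = [
            discard_initial_volumes(ts, sim_spec.n_discard)
            for ts in cohort.subjects
        ]
        log.info("simulated %d subjects (%d per group)", len(subjects),
                 cfg.n_per_group)
    elif cfg.mode == "tsv":
        if not cfg.input_dir:
            raise ValueError("mode=tsv requires input_dir")
        atlas, subjects, groups, demographics, scores = load_tsv_cohort(cfg.input_dir)
        log.info("loaded %d subjects from %s", len(subjects), cfg.input_dir)
        if cfg.preprocess:
            staged = []
            for ts in subjects:
                ts = discard_initial_volumes(ts, cfg.n_discard)
                ts = detrend_and_regress(ts)
                ts = bandpass(ts, cfg.bandpass_low, cfg.bandpass_high)
                staged.append(ts)
            subjects = staged
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")

    # ----------------------------------------------------- stage 1: laterality
    wspec = WindowSpec(cfg.window_length, cfg.window_step)
    lat_dir = out / "laterality"
    lat_dir.mkdir(exist_ok=True)
    ls_all = []
    for ts in subjects:
        try:
            ls = laterality_series(ts, wspec, atlas,
                                   gs_exclude_self=cfg.gs_exclude_self)
        except Exception as exc:
            raise RuntimeError(
                f"laterality stage failed for subject {ts.subject_id!r}: {exc}"
            ) from exc
        ls_all.append(ls)
        pd.DataFrame(ls.values, columns=[str(c) for c in ls.column_ids]).to_csv(
            lat_dir / f"{ts.subject_id}.tsv", sep="\t", index=False
        )
    with open(lat_dir / "windows.json", "w") as fh:
        json.dump({"length": wspec.length, "step": wspec.step,
                   "n_windows": ls_all[0].n_windows}, fh, indent=2)
    log.info("laterality: %d subjects x %d windows", len(ls_all),
             ls_all[0].n_windows)

    # --------------------------------------------------------- stage 2: states
    try:
        model = fit_states(ls_all, k1=cfg.k1,
                           seed=_stage_seed(cfg, 2),
                           r_min=cfg.r_min, r_max=cfg.r_max, r_step=cfg.r_step,
                           n_restarts=cfg.afg_restarts)
    except Exception as exc:
        raise RuntimeError(f"states stage failed: {exc}") from exc
    states_dir = out / "states"
    states_dir.mkdir(exist_ok=True)
    pd.DataFrame(model.centroids,
                 columns=[str(c) for c in ls_all[0].column_ids]).to_csv(
        states_dir / "centroids.tsv", sep="\t", index=False
    )
    assign_rows = [
        {"subject_id": sid, "window_index": w, "state": int(s)}
        for sid, lab in model.assignments.items()
        for w, s in enumerate(lab)
    ]
    pd.DataFrame(assign_rows).to_csv(states_dir / "assignments.tsv",
                                     sep="\t", index=False)
    with open(states_dir / "sweep.json", "w") as fh:
        json.dump({"k": model.k, "occupancy": model.occupancy.tolist(),
                   **model.sweep.to_dict()}, fh, indent=2)
    log.info("states: k=%d, occupancy=%s", model.k,
             np.round(model.occupancy, 3).tolist())

    for s in range(1, model.k + 1):
        try:
            corr = state_laterality_correlation(ls_all, model.assignments, s)
        except ValueError as exc:
            log.warning("state %d correlation skipped: %s", s, exc)
            continue
        pd.DataFrame(corr).to_csv(states_dir / f"state{s}_correlation.tsv",
                                  sep="\t", index=False, header=False)

    # -------------------------------------------------------- stage 3: metrics
    ls_by_subject = {ls.subject_id: ls for ls in ls_all}
    metrics = metric_table(
        ls_by_subject, atlas, groups, assignments=model.assignments,
        levels=("node", "subnetwork", "hemisphere"), n_states=model.k,
        ddof=cfg.lf_ddof, aggregate_first=cfg.aggregate_first,
    )
    metrics.to_csv(out / "metrics.csv", index=False)

    # ---------------------------------------------------------- stage 4: stats
    results = group_compare(metrics, cfg.patient_group, cfg.control_group,
                            alpha=cfg.alpha)
    results.to_csv(out / "group_results.csv", index=False)
    n_sig = int(results["significant"].sum()) if len(results) else 0
    log.info("group comparisons: %d tests, %d significant", len(results), n_sig)

    if len(scores) and len(results):
        selected = results[results["significant"]]
        corr_results = clinical_correlations(
            metrics, scores, selected, cfg.patient_group,
            alternative=cfg.correlation_sidedness,
        )
        corr_results.to_csv(out / "correlations.csv", index=False)

    if demographics is not None and "age" in getattr(demographics, "columns", ()):
        demo = demographics_table(demographics, cfg.patient_group,
                                  cfg.control_group)
        demo.to_csv(out / "demographics.csv", index=False)

    provenance = {
        "config": cfg.to_dict(),
        "dynlat_version": __version__,
        "numpy_version": np.__version__,
        "n_subjects": len(subjects),
        "k": model.k,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return out
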