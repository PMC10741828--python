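"""Synthetic cohorts with planted laterality states and group effects.

Each ROI is a mixture of two latent hemisphere drivers (smoothed Gaussian
noise) whose loadings switch with a hidden first-order Markov state
sequence:

    ROI_i(t) = a_i(s_t) * D_L(t) + b_i(s_t) * D_R(t) + noise

State-specific loading patterns are sign-structured per
subnetwork-by-hemisphere unit so the planted states have well-separated
window-laterality directions.  A "patient" group can receive an additive
coupling-asymmetry shift in one designated unit, and clinical scores are
generated correlated with each patient's realised shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import DEFAULT_SUBNETWORKS, AtlasError, RoiAtlas
from .io import SubjectTimeSeries, write_roi_timeseries


class SimulationError(ValueError):
    pass


def generate_atlas(n_rois: int = 90, subnetworks=DEFAULT_SUBNETWORKS) -> RoiAtlas:
    """Homologous left/right atlas: first half L, second half R.

    Within each hemisphere ROIs are split into contiguous, near-equal
    subnetwork blocks, so every subnetwork is present in both
    hemispheres.
    """
    if n_rois % 2 != 0:
        raise AtlasError(f"n_rois must be even, got {n_rois}")
    if not subnetworks:
        raise AtlasError("subnetwork list must be non-empty")
    half = n_rois // 2
    if half < len(subnetworks):
        raise AtlasError(
            f"{half} ROIs per hemisphere cannot cover {len(subnetworks)} subnetworks"
        )
    blocks = np.array_split(np.arange(half), len(subnetworks))
    sub_of = np.empty(half, dtype=object)
    for name, idx in zip(subnetworks, blocks):
        sub_of[idx] = name
    roi_ids = tuple(range(1, n_rois + 1))
    hemis = tuple(["L"] * half + ["R"] * half)
    subs = tuple(sub_of.tolist() * 2)
    names = tuple(
        f"{subs[i]}_{hemis[i]}_{(i % half) + 1}" for i in range(n_rois)
    )
    return RoiAtlas(roi_ids=roi_ids, names=names, hemispheres=hemis, subnetworks=subs)


# Hand-designed unit sign patterns for the canonical 3-state, 5-subnetwork
# case, in block order (5 left-hemisphere units, then 5 right).  Per
# hemisphere the signs sum to +1 (L) / -1 (R) so each hemisphere global
# signal keeps a stable driver preference, and every pairwise dot product
# is -2 so the planted state directions are nearly orthogonal.
_CANONICAL_PATTERNS = np.array(
    [
        [+1, +1, +1, -1, -1, +1, +1, -1, -1, -1],
        [+1, +1, -1, +1, -1, -1, -1, +1, +1, -1],
        [+1, -1, -1, +1, +1, +1, -1, -1, -1, +1],
    ],
    dtype=float,
)


def state_unit_patterns(n_states: int, n_subnetworks: int, seed=0) -> np.ndarray:
    """Per-state sign pattern over the 2 * n_subnetworks units.

    Unit order is all left-hemisphere subnetworks then all right.  Each
    row sums to +1 over the left block and -1 over the right block (odd
    subnetwork counts; as balanced as possible otherwise).
    """
    n_units = 2 * n_subnetworks
    if n_states <= 3 and n_subnetworks == 5:
        return _CANONICAL_PATTERNS[:n_states].copy()
    rng = np.random.default_rng(seed)

    def draw_half(target_sum: int) -> np.ndarray:
        n_pos = (n_subnetworks + target_sum) // 2
        signs = np.array([1.0] * n_pos + [-1.0] * (n_subnetworks - n_pos))
        return rng.permutation(signs)

    best, best_score = None, np.inf
    for _ in range(500):
        cand = np.array(
            [np.concatenate([draw_half(+1), draw_half(-1)]) for _ in range(n_states)]
        )
        dots = cand @ cand.T
        np.fill_diagonal(dots, 0.0)
        score = np.abs(dots).max()
        if score < best_score:
            best, best_score = cand, score
    return best


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the generative model; consumed reproducibly from seed."""

    n_rois: int = 90
    n_timepoints: int = 152
    n_discard: int = 10
    tr_seconds: float = 2.0
    n_states: int = 3
    state_dwell_mean: float = 60.0
    subnetworks: tuple = DEFAULT_SUBNETWORKS
    coupling: np.ndarray | None = None
    coupling_delta: float = 0.7
    driver_smooth: int = 5
    noise_sd: float = 1.0
    group_effect: float = 0.0
    effect_unit: str | None = "AN_R"
    subject_effect_sd: float = 0.0
    clinical_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois % 2 != 0 or self.n_rois < 2:
            raise SimulationError("n_rois must be even and >= 2")
        if self.state_dwell_mean < 1:
            raise SimulationError("state_dwell_mean must be >= 1")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be positive")
        if self.n_states < 1:
            raise SimulationError("n_states must be >= 1")
        if not (0 <= self.n_discard < self.n_timepoints):
            raise SimulationError("n_discard must lie in [0, n_timepoints)")
        if self.coupling is not None:
            c = np.asarray(self.coupling, dtype=float)
            if c.shape != (self.n_states, self.n_rois, 2):
                raise SimulationError(
                    f"coupling must have shape ({self.n_states}, {self.n_rois}, 2)"
                )
            object.__setattr__(self, "coupling", c)

    @property
    def n_retained(self) -> int:
        return self.n_timepoints - self.n_discard

    def resolved_effect_unit(self) -> str:
        """Effect unit, falling back to the third subnetwork's right-side
        unit when the configured one does not exist for this atlas."""
        if self.effect_unit is not None:
            candidates = {f"{s}_{h}" for s in self.subnetworks for h in "LR"}
            if self.effect_unit in candidates:
                return self.effect_unit
        sub = self.subnetworks[2] if len(self.subnetworks) > 2 else self.subnetworks[0]
        return f"{sub}_R"


def build_atlas(spec: SimulationSpec) -> RoiAtlas:
    return generate_atlas(spec.n_rois, spec.subnetworks)


def build_coupling(spec: SimulationSpec, atlas: RoiAtlas) -> np.ndarray:
    """Default (n_states, n_rois, 2) loadings from the unit sign patterns.

    ROI i in a unit with sign sigma gets loadings (1 + delta*sigma,
    1 - delta*sigma) on (D_L, D_R).
    """
    if spec.coupling is not None:
        return spec.coupling
    patterns = state_unit_patterns(spec.n_states, len(spec.subnetworks), spec.seed)
    units = atlas.units("subnetwork")
    n_sub = len(spec.subnetworks)
    sub_pos = {name: i for i, name in enumerate(atlas.subnetwork_labels)}
    coupling = np.empty((spec.n_states, spec.n_rois, 2))
    for s in range(spec.n_states):
        sigma = np.empty(spec.n_rois)
        for uid, idx in units:
            name, side = uid.rsplit("_", 1)
            # pattern columns are block-ordered: left units then right units
            col = sub_pos[name] + (0 if side == "L" else n_sub)
            sigma[idx] = patterns[s, col]
        coupling[s, :, 0] = 1.0 + spec.coupling_delta * sigma
        coupling[s, :, 1] = 1.0 - spec.coupling_delta * sigma
    return coupling


def _smoothed_driver(rng: np.random.Generator, n: int, width: int) -> np.ndarray:
    """Moving-average-smoothed unit-variance Gaussian noise."""
    width = max(1, int(width))
    raw = rng.standard_normal(n + width - 1)
    kernel = np.ones(width) / np.sqrt(width)
    return np.convolve(raw, kernel, mode="valid")


def _markov_states(rng: np.random.Generator, n: int, n_states: int,
                   dwell_mean: float) -> np.ndarray:
    stay = 1.0 - 1.0 / dwell_mean if dwell_mean > 1 else 0.0
    seq = np.empty(n, dtype=int)
    seq[0] = rng.integers(1, n_states + 1)
    for t in range(1, n):
        if n_states == 1 or rng.random() < stay:
            seq[t] = seq[t - 1]
        else:
            others = [s for s in range(1, n_states + 1) if s != seq[t - 1]]
            seq[t] = others[rng.integers(len(others))]
    return seq


def simulate_subject(spec: SimulationSpec, group: str, seed,
                     subject_id: str = "", atlas: RoiAtlas | None = None,
                     coupling: np.ndarray | None = None,
                     effect: float = 0.0) -> tuple[SubjectTimeSeries, np.ndarray]:
    """One subject's raw ROI-by-time matrix plus its hidden state sequence.

    ``effect`` shifts the designated unit's loading asymmetry by
    (+effect on D_L, -effect on D_R); deterministic given ``seed``.
    """
    atlas = atlas if atlas is not None else build_atlas(spec)
    coupling = coupling if coupling is not None else build_coupling(spec, atlas)
    rng = np.random.default_rng(seed)
    T = spec.n_timepoints
    states = _markov_states(rng, T, spec.n_states, spec.state_dwell_mean)
    d_left = _smoothed_driver(rng, T, spec.driver_smooth)
    d_right = _smoothed_driver(rng, T, spec.driver_smooth)
    a = coupling[states - 1, :, 0]
    b = coupling[states - 1, :, 1]
    if effect != 0.0:
        unit_ids = dict(atlas.units("subnetwork"))
        effect_unit = spec.resolved_effect_unit()
        if effect_unit not in unit_ids:
            raise SimulationError(f"unknown effect unit {effect_unit!r}")
        members = unit_ids[effect_unit]
        side = effect_unit.rsplit("_", 1)[1]
        hemi_idx = atlas.hemisphere_indices(side)
        rest = np.setdiff1d(hemi_idx, members)
        # shift the unit's loading asymmetry toward D_L while compensating
        # the rest of its hemisphere, so the hemisphere global signal keeps
        # its driver composition and the response stays monotone in effect
        shift = np.zeros(spec.n_rois)
        shift[members] = effect
        if rest.size:
            shift[rest] = -effect * members.size / rest.size
        a = a + shift
        b = b - shift
    values = (
        a * d_left[:, None]
        + b * d_right[:, None]
        + spec.noise_sd * rng.standard_normal((T, spec.n_rois))
    )
    ts = SubjectTimeSeries(
        values=values,
        tr_seconds=spec.tr_seconds,
        roi_ids=atlas.roi_ids,
        subject_id=subject_id or f"{group}-{seed}",
    )
    return ts, states


SCORE_SCALES = {
    # scale -> (mean, sd, lower, upper), plausible instrument ranges
    "BPRS": (44.7, 10.9, 18.0, 80.0),
    "SANS": (21.6, 14.1, 0.0, 80.0),
    "YMRS": (12.0, 11.0, 0.0, 50.0),
}


@dataclass(frozen=True)
class SyntheticCohort:
    subjects: list[SubjectTimeSeries]
    groups: dict[str, str]
    true_states: dict[str, np.ndarray]
    scores: pd.DataFrame
    demographics: pd.DataFrame
    atlas: RoiAtlas
    spec: SimulationSpec
    subject_effects: dict[str, float] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return [ts.subject_id for ts in self.subjects]


def simulate_cohort(spec: SimulationSpec, n_per_group: int, seed=None,
                    patient_group: str = "BD", control_group: str = "NC") -> SyntheticCohort:
    """Simulate n_per_group controls and patients with planted effects.

    Patient j receives coupling shift ``group_effect + subject_effect_sd
    * z_j`` in the designated unit; clinical scores share the z_j draw
    with weight ``clinical_coupling`` so score-metric correlations are
    planted at a controlled strength.
    """
    if n_per_group < 2:
        raise SimulationError("n_per_group must be >= 2")
    if seed is None:
        seed = spec.seed
    master = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
    atlas = build_atlas(spec)
    coupling = build_coupling(spec, atlas)
    subj_seeds = master.spawn(2 * n_per_group)
    aux_rng = np.random.default_rng(master.spawn(1)[0])

    subjects, groups, true_states, effects = [], {}, {}, {}
    demo_rows, score_rows = [], []
    plan = [(control_group, i) for i in range(n_per_group)] + [
        (patient_group, i) for i in range(n_per_group)
    ]
    for (grp, i), s in zip(plan, subj_seeds):
        sid = f"{grp}{i + 1:03d}"
        if grp == patient_group:
            z = float(aux_rng.standard_normal())
            effect = spec.group_effect + spec.subject_effect_sd * z
        else:
            z, effect = 0.0, 0.0
        ts, states = simulate_subject(
            spec, grp, s, subject_id=sid, atlas=atlas, coupling=coupling,
            effect=effect,
        )
        subjects.append(ts)
        groups[sid] = grp
        true_states[sid] = states
        effects[sid] = effect
        demo_rows.append(
            {
                "subject_id": sid,
                "group": grp,
                "age": float(np.clip(aux_rng.normal(34.5, 9.0), 18, 65)),
                "gender": "M" if aux_rng.random() < 0.55 else "F",
                "education": float(np.clip(aux_rng.normal(14.8, 1.7), 8, 22)),
                "handscore": float(np.clip(aux_rng.normal(0.93, 0.1), -1.0, 1.0)),
            }
        )
        if grp == patient_group:
            cc = spec.clinical_coupling
            row = {"subject_id": sid}
            for name, (mean, sd, lo, hi) in SCORE_SCALES.items():
                noise = aux_rng.standard_normal()
                latent = cc * z + np.sqrt(max(0.0, 1.0 - cc * cc)) * noise
                row[name] = float(np.clip(mean + sd * latent, lo, hi))
            score_rows.append(row)

    scores = pd.DataFrame(score_rows).set_index("subject_id")
    demographics = pd.DataFrame(demo_rows)
    return SyntheticCohort(
        subjects=subjects,
        groups=groups,
        true_states=true_states,
        scores=scores,
        demographics=demographics,
        atlas=atlas,
        spec=spec,
        subject_effects=effects,
    )


def window_majority_states(state_seq: np.ndarray, windows) -> np.ndarray:
    """Majority planted state within each window range (ties -> lower id)."""
    out = np.empty(len(windows), dtype=int)
    for w, (a, b) in enumerate(windows):
        counts = np.bincount(np.asarray(state_seq[a:b], dtype=int))
        out[w] = int(np.argmax(counts))
    return out


# ----------------------------------------------------------------- export


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write atlas, per-subject TSVs, manifest, scores, true states."""
    out = Path(out_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    cohort.atlas.write_tsv(out / "atlas.tsv")
    for ts in cohort.subjects:
        write_roi_timeseries(ts, out / "subjects" / f"{ts.subject_id}.tsv")
    cohort.demographics.to_csv(out / "manifest.csv", index=False)
    cohort.scores.to_csv(out / "scores.csv")
    states = pd.DataFrame(
        {sid: seq for sid, seq in cohort.true_states.items()}
    )
    states.to_csv(out / "true_states.tsv", sep="\t", index=False)


def write_toy_nifti(ts: SubjectTimeSeries, atlas: RoiAtlas, image_path,
                    label_path, voxels_per_roi: int = 2) -> None:
    """Toy 4D volume + integer label volume exercising ROI extraction.

    Each ROI occupies ``voxels_per_roi`` voxels along one axis, all
    carrying the ROI's series, so extracted means round-trip exactly.
    """
    import nibabel as nib

    n = atlas.n_rois * voxels_per_roi
    labels = np.zeros((n, 1, 1), dtype=np.int16)
    data = np.zeros((n, 1, 1, ts.n_timepoints), dtype=np.float64)
    for i, rid in enumerate(atlas.roi_ids):
        sl = slice(i * voxels_per_roi, (i + 1) * voxels_per_roi)
        labels[sl, 0, 0] = rid
        data[sl, 0, 0, :] = ts.values[:, i]
    affine = np.eye(4)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, ts.tr_seconds))
    nib.save(img, str(image_path))
    nib.save(nib.Nifti1Image(labels, affine), str(label_path))


# ------------------------------------------------------------- calibration


def calibrate_group_effect(spec: SimulationSpec, cohens_d: float,
                           n_calibration: int = 24, seed: int = 1234,
                           probe: float = 0.8) -> float:
    """Coupling shift giving roughly Cohen's d on the effect unit's MLI.

    Simulates matched subject panels with and without candidate shifts,
    measures the realised d on the effect unit's all-window MLI, and runs
    one secant refinement (the response saturates, so a single linear
    scale overshoots).
    """
    from .laterality import WindowSpec, aggregate_units, laterality_series

    atlas = build_atlas(spec)
    coupling = build_coupling(spec, atlas)
    wspec = WindowSpec(50, 1)
    unit_names = [uid for uid, _ in atlas.units("subnetwork")]
    u = unit_names.index(spec.resolved_effect_unit())
    seeds = np.random.SeedSequence(seed).spawn(n_calibration)

    def unit_mli(effect: float) -> np.ndarray:
        out = np.empty(n_calibration)
        for i, s in enumerate(seeds):
            ts, _ = simulate_subject(spec, "CAL", s, atlas=atlas,
                                     coupling=coupling, effect=effect)
            ts = SubjectTimeSeries(
                values=ts.values[spec.n_discard:], tr_seconds=ts.tr_seconds,
                roi_ids=ts.roi_ids, subject_id=ts.subject_id,
            )
            ls = aggregate_units(laterality_series(ts, wspec, atlas), atlas,
                                 "subnetwork")
            out[i] = ls.values[:, u].mean()
        return out

    base = unit_mli(0.0)

    def d_at(effect: float) -> float:
        probed = unit_mli(effect)
        pooled = np.sqrt((base.var(ddof=1) + probed.var(ddof=1)) / 2.0)
        if pooled <= 0:
            raise SimulationError("degenerate calibration panel")
        return float((probed.mean() - base.mean()) / pooled)

    d1 = d_at(probe)
    if abs(d1) < 1e-6:
        raise SimulationError("MLI is insensitive to the coupling shift")
    e2 = float(np.clip(probe * cohens_d / d1, 0.05, 4.0))
    d2 = d_at(e2)
    if abs(d2 - d1) > 1e-9 and abs(e2 - probe) > 1e-9:
        e3 = e2 + (cohens_d - d2) * (e2 - probe) / (d2 - d1)
        if 0.0 < e3 < 4.0:
            return float(e3)
    return e2
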