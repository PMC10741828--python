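"""Sliding-window dynamic laterality index and its summary metrics.

For each window the laterality of ROI i is

    DLI_i = atanh(r(ROI_i, GS_L)) - atanh(r(ROI_i, GS_R))

where GS_L / GS_R are the hemisphere global signals (unweighted ROI means)
computed within the same window and r is the Pearson correlation.  Per
window-set summaries are the mean laterality index (MLI) and the
laterality fluctuation (LF, sample standard deviation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RoiAtlas
from .io import SubjectTimeSeries


class LateralityError(ValueError):
    """Degenerate windows: zero variance or |r| = 1."""


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters (defaults: 50-sample windows, step 1)."""

    length: int = 50
    step: int = 1

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ValueError("window length must be >= 3")
        if not (1 <= self.step <= self.length):
            raise ValueError("step must satisfy 1 <= step <= length")

    def n_windows(self, n_timepoints: int) -> int:
        if self.length > n_timepoints:
            raise ValueError(
                f"window length {self.length} exceeds series length {n_timepoints}"
            )
        return (n_timepoints - self.length) // self.step + 1


@dataclass(frozen=True)
class LateralitySeries:
    """W x N matrix of per-window DLI values for one subject.

    ``column_ids`` are roi_ids (node level) or unit labels after
    aggregation.
    """

    values: np.ndarray
    window_starts: np.ndarray
    column_ids: tuple
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (window x column)")
        if v.shape[1] != len(self.column_ids):
            raise ValueError("column_ids do not match value columns")
        if v.shape[0] != len(self.window_starts):
            raise ValueError("window_starts do not match value rows")
        if not np.all(np.isfinite(v)):
            raise ValueError("laterality series contains non-finite values")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "window_starts", np.asarray(self.window_starts, dtype=int))

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def sliding_windows(n_timepoints: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open index ranges [s, s + length), s = 0, step, 2*step, ...

    The count obeys floor((T - length) / step) + 1.
    """
    n = spec.n_windows(n_timepoints)
    return [(s, s + spec.length) for s in range(0, n * spec.step, spec.step)]


def hemisphere_global_signal(ts: SubjectTimeSeries, atlas: RoiAtlas, side: str) -> np.ndarray:
    """Unweighted mean across one hemisphere's ROI columns at each time point."""
    idx = atlas.hemisphere_indices(side)
    if idx.size == 0:
        raise LateralityError(f"hemisphere {side} has no ROIs")
    return ts.values[:, idx].mean(axis=1)


def _window_correlations(x: np.ndarray, gs: np.ndarray, roi_ids, what: str) -> np.ndarray:
    """Pearson r of every column of ``x`` with ``gs`` (both within-window)."""
    xc = x - x.mean(axis=0)
    gc = gs - gs.mean()
    xn = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    gn = np.sqrt(gc @ gc)
    if gn <= 0.0:
        raise LateralityError(f"{what} global signal has zero variance in window")
    zero = np.flatnonzero(xn <= 0.0)
    if zero.size:
        raise LateralityError(
            f"ROI {roi_ids[zero[0]]} has zero variance in window"
        )
    r = (xc.T @ gc) / (xn * gn)
    capped = np.flatnonzero(np.abs(r) >= 1.0 - 1e-15)
    if capped.size:
        raise LateralityError(
            f"|r| = 1 between ROI {roi_ids[capped[0]]} and GS_{what}: "
            "Fisher z is infinite"
        )
    return r


def dli_window(window: np.ndarray, atlas: RoiAtlas, roi_ids=None,
               gs_exclude_self: bool = False) -> np.ndarray:
    """Per-ROI DLI for a single window (length x N, atlas column order).

    With ``gs_exclude_self`` the target ROI is removed from its own
    hemisphere's mean before correlating.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] < 3:
        raise LateralityError("window must be 2-D with length >= 3")
    if window.shape[1] != atlas.n_rois:
        raise LateralityError(
            f"window has {window.shape[1]} columns, atlas has {atlas.n_rois} ROIs"
        )
    if roi_ids is None:
        roi_ids = atlas.roi_ids
    z = np.empty((2, window.shape[1]))
    for k, side in enumerate(("L", "R")):
        idx = atlas.hemisphere_indices(side)
        gs = window[:, idx].mean(axis=1)
        if not gs_exclude_self:
            r = _window_correlations(window, gs, roi_ids, side)
        else:
            r = _window_correlations(window, gs, roi_ids, side)
            if idx.size > 1:
                # leave-one-out mean for ROIs belonging to this hemisphere
                total = window[:, idx].sum(axis=1)
                for i in idx:
                    loo = (total - window[:, i]) / (idx.size - 1)
                    r[i] = _window_correlations(
                        window[:, [i]], loo, (roi_ids[i],), side
                    )[0]
        z[k] = np.arctanh(r)
    return z[0] - z[1]


def _batched_dli(values: np.ndarray, spec: WindowSpec, atlas: RoiAtlas,
                 roi_ids) -> np.ndarray:
    """All windows at once via a strided view; equals per-window dli_window."""
    from numpy.lib.stride_tricks import sliding_window_view

    view = sliding_window_view(values, spec.length, axis=0)[::spec.step]
    xc = view - view.mean(axis=-1, keepdims=True)  # (W, N, L), centred
    xn = np.sqrt(np.einsum("wnl,wnl->wn", xc, xc))
    z = []
    for side in ("L", "R"):
        idx = atlas.hemisphere_indices(side)
        gc = xc[:, idx, :].mean(axis=1)
        gn = np.sqrt(np.einsum("wl,wl->w", gc, gc))
        bad = np.flatnonzero(gn <= 0.0)
        if bad.size:
            raise LateralityError(
                f"window {bad[0]}: {side} global signal has zero variance"
            )
        zero = np.argwhere(xn <= 0.0)
        if zero.size:
            w, i = zero[0]
            raise LateralityError(
                f"window {w}: ROI {roi_ids[i]} has zero variance"
            )
        r = np.einsum("wnl,wl->wn", xc, gc) / (xn * gn[:, None])
        capped = np.argwhere(np.abs(r) >= 1.0 - 1e-15)
        if capped.size:
            w, i = capped[0]
            raise LateralityError(
                f"window {w}: |r| = 1 between ROI {roi_ids[i]} and GS_{side}: "
                "Fisher z is infinite"
            )
        z.append(np.arctanh(r))
    return z[0] - z[1]


def laterality_series(ts: SubjectTimeSeries, spec: WindowSpec, atlas: RoiAtlas,
                      gs_exclude_self: bool = False) -> LateralitySeries:
    """Stack :func:`dli_window` over all sliding windows of ``ts``.

    The default path computes all windows in one batched pass; the
    leave-one-out variant falls back to the per-window routine.
    """
    if ts.n_rois != atlas.n_rois:
        raise LateralityError("time series columns do not match atlas")
    ranges = sliding_windows(ts.n_timepoints, spec)
    if not gs_exclude_self:
        rows = _batched_dli(ts.values, spec, atlas, ts.roi_ids)
    else:
        rows = np.empty((len(ranges), ts.n_rois))
        for w, (a, b) in enumerate(ranges):
            try:
                rows[w] = dli_window(ts.values[a:b], atlas, ts.roi_ids,
                                     gs_exclude_self)
            except LateralityError as exc:
                raise LateralityError(f"window {w} [{a}, {b}): {exc}") from exc
    return LateralitySeries(
        values=rows,
        window_starts=np.array([a for a, _ in ranges]),
        column_ids=ts.roi_ids,
        subject_id=ts.subject_id,
    )


def compute_metrics(ls: LateralitySeries, window_subset=None, ddof: int = 1) -> pd.DataFrame:
    """MLI (mean) and LF (sample SD) per column over a window subset.

    ``window_subset=None`` means all windows.  An empty subset yields
    NaN metrics flagged by ``n_windows_used = 0``; LF needs >= 2 windows
    and is NaN otherwise.
    """
    if window_subset is None:
        sub = np.arange(ls.n_windows)
    else:
        sub = np.asarray(window_subset, dtype=int)
    n = int(sub.size)
    cols = list(ls.column_ids)
    if n == 0:
        mli = np.full(len(cols), np.nan)
        lf = np.full(len(cols), np.nan)
    else:
        x = ls.values[sub]
        mli = x.mean(axis=0)
        lf = x.std(axis=0, ddof=ddof) if n > ddof else np.full(len(cols), np.nan)
    return pd.DataFrame(
        {"unit_id": [str(c) for c in cols], "mli": mli, "lf": lf, "n_windows_used": n}
    )


def aggregate_units(ls: LateralitySeries, atlas: RoiAtlas, level: str) -> LateralitySeries:
    """Average member-ROI DLI columns into unit columns per window.

    ``level`` is ``"hemisphere"`` (2 units) or ``"subnetwork"``
    (#subnetworks x 2 units).
    """
    if len(ls.column_ids) != atlas.n_rois:
        raise LateralityError("laterality columns do not match atlas")
    units = atlas.units(level)
    cols = np.column_stack([ls.values[:, idx].mean(axis=1) for _, idx in units])
    return LateralitySeries(
        values=cols,
        window_starts=ls.window_starts,
        column_ids=tuple(uid for uid, _ in units),
        subject_id=ls.subject_id,
    )


def state_laterality_correlation(ls_all: list[LateralitySeries], assignments: dict,
                                 state: int) -> np.ndarray:
    """Pearson correlation between DLI columns over a state's pooled windows.

    ``assignments`` maps subject_id to a per-window vector of 1-based
    state ids.  Requires at least 3 pooled windows.
    """
    blocks = []
    for ls in ls_all:
        lab = np.asarray(assignments[ls.subject_id])
        if lab.shape[0] != ls.n_windows:
            raise ValueError(f"assignment length mismatch for {ls.subject_id}")
        rows = ls.values[lab == state]
        if rows.size:
            blocks.append(rows)
    if not blocks:
        raise ValueError(f"state {state} has no assigned windows")
    pooled = np.vstack(blocks)
    if pooled.shape[0] < 3:
        raise ValueError(
            f"state {state} has only {pooled.shape[0]} windows; need >= 3"
        )
    return np.corrcoef(pooled, rowvar=False)


# ------------------------------------------------------------ metric table

METRIC_LEVELS = ("node", "subnetwork", "hemisphere")


def metric_table(ls_by_subject: dict[str, LateralitySeries], atlas: RoiAtlas,
                 groups: dict[str, str], assignments: dict | None = None,
                 levels=("subnetwork", "hemisphere"), n_states: int = 0,
                 ddof: int = 1, aggregate_first: bool = True) -> pd.DataFrame:
    """Tidy per-subject metric table across levels and (optionally) states.

    One row per (subject, unit, state) with columns ``mli``, ``lf`` and
    ``n_windows_used``; ``state`` is ``"ALL"`` or the 1-based state id.
    With ``aggregate_first`` (default) unit metrics summarise the
    unit-mean DLI series; otherwise per-ROI metrics are averaged.
    """
    records = []
    for sid, ls in ls_by_subject.items():
        subsets: list[tuple[str, np.ndarray | None]] = [("ALL", None)]
        if assignments is not None and n_states:
            lab = np.asarray(assignments[sid])
            subsets += [
                (str(s), np.flatnonzero(lab == s)) for s in range(1, n_states + 1)
            ]
        for level in levels:
            if level == "node":
                series = ls
            elif aggregate_first:
                series = aggregate_units(ls, atlas, level)
            else:
                series = None
            for state, sub in subsets:
                if series is not None:
                    df = compute_metrics(series, sub, ddof=ddof)
                else:
                    per_roi = compute_metrics(ls, sub, ddof=ddof)
                    rows = []
                    for uid, idx in atlas.units(level):
                        rows.append(
                            {
                                "unit_id": uid,
                                "mli": per_roi["mli"].values[idx].mean(),
                                "lf": per_roi["lf"].values[idx].mean(),
                                "n_windows_used": per_roi["n_windows_used"].iloc[0],
                            }
                        )
                    df = pd.DataFrame(rows)
                df = df.assign(
                    subject_id=sid,
                    group=groups[sid],
                    unit_level=level,
                    state=state,
                )
                records.append(df)
    out = pd.concat(records, ignore_index=True)
    return out[
        ["subject_id", "group", "unit_id", "unit_level", "state",
         "mli", "lf", "n_windows_used"]
    ]
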