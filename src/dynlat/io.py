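"""BOLD input handling and in-scope preprocessing.

Covers reading ROI-by-time matrices from TSV, extracting ROI means from a
labelled 4D volume, initial volume discard, linear detrending with
nuisance regression, and zero-phase band-pass filtering.  Scanner-level
steps (slice timing, realignment, normalisation, smoothing) are assumed
done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .atlas import RoiAtlas


class ParseError(ValueError):
    """Malformed tabular input."""


class PreprocessError(ValueError):
    """Invalid preprocessing request (bad band, rank-deficient design, ...)."""


@dataclass(frozen=True)
class SubjectTimeSeries:
    """A T x N matrix of ROI signals sampled every ``tr_seconds``.

    Columns are ordered by ascending roi_id and must align with the atlas
    used downstream.
    """

    values: np.ndarray
    tr_seconds: float
    roi_ids: tuple
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (time x ROI)")
        if v.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if v.shape[1] != len(self.roi_ids):
            raise ValueError(
                f"{v.shape[1]} columns but {len(self.roi_ids)} roi_ids"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


# --------------------------------------------------------------------- TSV


def read_roi_timeseries(path, tr_seconds: float = 2.0, subject_id: str | None = None) -> SubjectTimeSeries:
    """Read a TSV with a header row of ROI ids and one row per time point.

    Raises :class:`ParseError` naming the offending row for ragged or
    non-numeric input.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().strip()
        if not header:
            raise ParseError(f"{path}: empty file")
        roi_ids = tuple(int(tok) for tok in header.split("\t"))
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            toks = line.split("\t")
            if len(toks) != len(roi_ids):
                raise ParseError(
                    f"{path}: row {lineno} has {len(toks)} cells, expected {len(roi_ids)}"
                )
            try:
                rows.append([float(t) for t in toks])
            except ValueError as exc:
                raise ParseError(f"{path}: row {lineno}: {exc}") from None
    values = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.all(np.isfinite(values), axis=1))[0]) + 2
        raise ParseError(f"{path}: row {bad} contains a non-finite value")
    return SubjectTimeSeries(
        values=values,
        tr_seconds=tr_seconds,
        roi_ids=roi_ids,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_roi_timeseries(ts: SubjectTimeSeries, path) -> None:
    """Write the matrix as TSV with ROI ids in the header."""
    df = pd.DataFrame(ts.values, columns=[str(r) for r in ts.roi_ids])
    df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- NIfTI


def extract_roi_means(image4d, labels, atlas: RoiAtlas, tr_seconds: float | None = None,
                      subject_id: str = "") -> SubjectTimeSeries:
    """Average voxel time courses within each labelled ROI.

    ``image4d`` and ``labels`` may be nibabel images or file paths; the
    label volume holds integer roi_ids on the same spatial grid.  Column i
    of the result is the unweighted mean over voxels carrying
    ``atlas.roi_ids[i]``, per time point.
    """
    import nibabel as nib

    if isinstance(image4d, (str, Path)):
        image4d = nib.load(str(image4d))
    if isinstance(labels, (str, Path)):
        labels = nib.load(str(labels))

    data = np.asarray(image4d.get_fdata(), dtype=float)
    lab = np.asarray(labels.get_fdata())
    lab_int = np.rint(lab).astype(int)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D image, got shape {data.shape}")
    if lab_int.shape != data.shape[:3]:
        raise ValueError(
            f"label grid {lab_int.shape} does not match image grid {data.shape[:3]}"
        )
    present = set(np.unique(lab_int).tolist())
    missing = [rid for rid in atlas.roi_ids if rid not in present]
    if missing:
        raise ValueError(f"label volume lacks roi_ids: {missing}")

    if tr_seconds is None:
        zooms = image4d.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0

    flat = data.reshape(-1, data.shape[3])
    lab_flat = lab_int.ravel()
    cols = []
    for rid in atlas.roi_ids:
        mask = lab_flat == rid
        cols.append(flat[mask].mean(axis=0))
    return SubjectTimeSeries(
        values=np.column_stack(cols),
        tr_seconds=float(tr_seconds),
        roi_ids=atlas.roi_ids,
        subject_id=subject_id,
    )


# ----------------------------------------------------------- preprocessing


def discard_initial_volumes(ts: SubjectTimeSeries, n_discard: int) -> SubjectTimeSeries:
    """Drop the first ``n_discard`` time points."""
    if n_discard < 0:
        raise PreprocessError("n_discard must be >= 0")
    if n_discard >= ts.n_timepoints:
        raise PreprocessError(
            f"cannot discard {n_discard} of {ts.n_timepoints} time points"
        )
    if n_discard == 0:
        return ts
    return replace(ts, values=ts.values[n_discard:])


def detrend_and_regress(ts: SubjectTimeSeries, confounds: np.ndarray | None = None) -> SubjectTimeSeries:
    """OLS-residualise each column on [intercept, linear ramp, confounds]."""
    T = ts.n_timepoints
    cols = [np.ones(T), np.linspace(-1.0, 1.0, T)]
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.size and confounds.shape[0] != T:
            raise PreprocessError(
                f"confounds have {confounds.shape[0]} rows, series has {T}"
            )
        if confounds.size:
            cols.extend(confounds.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PreprocessError(
            "rank-deficient design matrix; remove collinear confound columns"
        )
    beta, *_ = np.linalg.lstsq(X, ts.values, rcond=None)
    return replace(ts, values=ts.values - X @ beta)


def bandpass(ts: SubjectTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1,
             order: int = 4) -> SubjectTimeSeries:
    """Zero-phase Butterworth band-pass applied per column.

    Forward-backward filtering with odd-symmetric edge padding; the band
    must sit strictly inside (0, Nyquist).
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise PreprocessError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist:g} Hz at TR={ts.tr_seconds}s)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / ts.tr_seconds, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.values, axis=0, padtype="odd")
    return replace(ts, values=np.ascontiguousarray(filtered))
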