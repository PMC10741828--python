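"""ROI atlas: hemisphere and subnetwork labels for a parcellation.

The atlas is the single source of truth for column alignment: every
time-series matrix in the package orders its columns by ascending
``roi_id`` and aggregation units (hemispheres, subnetwork-by-hemisphere
blocks) are derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical within-hemisphere subnetwork labels (somatosensory/motor and
#: auditory, visual, attention, default-mode, limbic/subcortical).
DEFAULT_SUBNETWORKS: tuple[str, ...] = ("MAN", "VN", "AN", "DMN", "LSN")

HEMISPHERES = ("L", "R")

ATLAS_COLUMNS = ("roi_id", "name", "hemisphere", "subnetwork")


class AtlasError(ValueError):
    """Raised for structurally invalid atlases."""


@dataclass(frozen=True)
class RoiAtlas:
    """Immutable table of ROI labels.

    Parameters
    ----------
    roi_ids
        Unique integer labels, one per ROI.  External files use these
        1-based ids; positional (0-based) indices are internal.
    names
        Human-readable ROI names.
    hemispheres
        ``"L"`` or ``"R"`` per ROI; both hemispheres must be non-empty.
    subnetworks
        Subnetwork label per ROI.
    """

    roi_ids: tuple[int, ...]
    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    subnetworks: tuple[str, ...]
    _index: dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.roi_ids)
        if not (len(self.names) == len(self.hemispheres) == len(self.subnetworks) == n):
            raise AtlasError("atlas fields must have equal length")
        if n == 0:
            raise AtlasError("atlas is empty")
        if len(set(self.roi_ids)) != n:
            raise AtlasError("roi_ids must be unique")
        bad = sorted(set(self.hemispheres) - set(HEMISPHERES))
        if bad:
            raise AtlasError(f"hemisphere labels must be L or R, got {bad}")
        for side in HEMISPHERES:
            if side not in self.hemispheres:
                raise AtlasError(f"hemisphere {side!r} has no ROIs")
        object.__setattr__(self, "_index", {rid: i for i, rid in enumerate(self.roi_ids)})

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def subnetwork_labels(self) -> tuple[str, ...]:
        """Distinct subnetwork labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.subnetworks:
            seen.setdefault(s)
        return tuple(seen)

    def position(self, roi_id: int) -> int:
        """0-based column position of ``roi_id``."""
        try:
            return self._index[roi_id]
        except KeyError:
            raise AtlasError(f"roi_id {roi_id} not in atlas") from None

    def hemisphere_indices(self, side: str) -> np.ndarray:
        """Positions of all ROIs in hemisphere ``side``."""
        if side not in HEMISPHERES:
            raise AtlasError(f"side must be L or R, got {side!r}")
        return np.flatnonzero(np.asarray(self.hemispheres) == side)

    def units(self, level: str) -> list[tuple[str, np.ndarray]]:
        """Aggregation units at ``level``.

        ``"hemisphere"`` yields 2 units (``HEM_L``, ``HEM_R``);
        ``"subnetwork"`` yields one unit per subnetwork per hemisphere
        (e.g. ``AN_L``); ``"node"`` yields one unit per ROI keyed by its
        roi_id.  Each unit is (unit_id, member positions).
        """
        hemi = np.asarray(self.hemispheres)
        if level == "hemisphere":
            return [(f"HEM_{s}", np.flatnonzero(hemi == s)) for s in HEMISPHERES]
        if level == "subnetwork":
            sub = np.asarray(self.subnetworks)
            out = []
            for name in self.subnetwork_labels:
                for s in HEMISPHERES:
                    idx = np.flatnonzero((sub == name) & (hemi == s))
                    if idx.size == 0:
                        raise AtlasError(f"subnetwork {name!r} empty in hemisphere {s}")
                    out.append((f"{name}_{s}", idx))
            return out
        if level == "node":
            return [(str(rid), np.array([i])) for i, rid in enumerate(self.roi_ids)]
        raise AtlasError(f"unknown aggregation level {level!r}")

    def relabeled_swapped(self) -> "RoiAtlas":
        """Atlas with hemisphere labels L and R exchanged (for symmetry tests)."""
        flip = {"L": "R", "R": "L"}
        return RoiAtlas(
            roi_ids=self.roi_ids,
            names=self.names,
            hemispheres=tuple(flip[h] for h in self.hemispheres),
            subnetworks=self.subnetworks,
        )

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "name": self.names,
                "hemisphere": self.hemispheres,
                "subnetwork": self.subnetworks,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RoiAtlas":
        missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
        if missing:
            raise AtlasError(f"atlas table missing columns {missing}")
        df = df.sort_values("roi_id")
        return cls(
            roi_ids=tuple(int(r) for r in df["roi_id"]),
            names=tuple(str(x) for x in df["name"]),
            hemispheres=tuple(str(x) for x in df["hemisphere"]),
            subnetworks=tuple(str(x) for x in df["subnetwork"]),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "RoiAtlas":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
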