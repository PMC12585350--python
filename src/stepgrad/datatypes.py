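"""Shared domain types for the stepwise-connectivity / gradient pipeline.

The coordinate frame for every map in the package is an :class:`ROIAtlas`:
a fixed, 0-based contiguous ordering of regions of interest with hemisphere
and network labels and at least one designated seed region per hemisphere
(the entorhinal cortex in the disease application this package targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("A-CN", "A+CN", "CI")
HEMISPHERES = ("left", "right")
MODALITIES = ("functional", "structural")

#: tolerance for declaring a stored connectome matrix symmetric
SYMMETRY_TOL = 1e-10
#: asymmetry up to this level is repaired by averaging with the transpose
SYMMETRY_REPAIR_TOL = 1e-8


def canonical_group(label: str) -> str:
    """Map spelling variants (unicode minus, missing hyphen) onto GROUPS."""
    norm = label.strip().replace("−", "-").replace(" ", "")
    aliases = {"A-CN": "A-CN", "ACN": "A-CN", "A+CN": "A+CN", "CI": "CI"}
    if norm not in aliases:
        raise ValueError(f"unknown diagnostic group label: {label!r}")
    return aliases[norm]


@dataclass(frozen=True)
class ROIAtlas:
    """Region-of-interest atlas: identities, hemisphere, network, seed flags."""

    names: tuple
    hemisphere: np.ndarray  # array of {"left","right"}
    network: np.ndarray  # array of network labels
    is_seed: np.ndarray  # boolean

    def __post_init__(self):
        n = len(self.names)
        for attr in ("hemisphere", "network", "is_seed"):
            arr = np.asarray(getattr(self, attr))
            if arr.shape != (n,):
                raise ValueError(f"atlas field {attr} has wrong length")
            object.__setattr__(self, attr, arr)
        bad = set(self.hemisphere) - set(HEMISPHERES)
        if bad:
            raise ValueError(f"unknown hemisphere labels: {bad}")
        if any(not str(lab) for lab in self.network):
            raise ValueError("every ROI needs a network label")
        for hemi in HEMISPHERES:
            mask = self.hemisphere == hemi
            if mask.any() and not self.is_seed[mask].any():
                raise ValueError(f"no seed ROI flagged in {hemi} hemisphere")

    @property
    def n_rois(self) -> int:
        return len(self.names)

    @property
    def roi_ids(self) -> np.ndarray:
        return np.arange(self.n_rois)

    def seed(self, hemisphere: str) -> int:
        """First flagged seed ROI of a hemisphere."""
        mask = (self.hemisphere == hemisphere) & self.is_seed
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"no seed in hemisphere {hemisphere!r}")
        return int(idx[0])

    def hemisphere_rois(self, hemisphere: str) -> np.ndarray:
        if hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {hemisphere!r}")
        return np.flatnonzero(self.hemisphere == hemisphere)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "name": list(self.names),
                "hemisphere": self.hemisphere,
                "network": self.network,
                "is_seed": self.is_seed.astype(int),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ROIAtlas":
        ids = df["roi_id"].to_numpy()
        if not np.array_equal(np.sort(ids), np.arange(len(ids))):
            raise ValueError("roi_id must be 0-based, unique, contiguous")
        df = df.sort_values("roi_id")
        return cls(
            names=tuple(str(x) for x in df["name"]),
            hemisphere=df["hemisphere"].to_numpy(dtype=object),
            network=df["network"].to_numpy(dtype=object),
            is_seed=df["is_seed"].astype(bool).to_numpy(),
        )


@dataclass
class Connectome:
    """One subject's square connectivity matrix bound to an atlas.

    Functional matrices hold Pearson correlations in [-1, 1]; structural
    matrices hold non-negative streamline counts. The diagonal is stored as
    exactly zero in both cases.
    """

    modality: str
    matrix: np.ndarray
    atlas: ROIAtlas

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        m = np.asarray(self.matrix, dtype=float)
        n = self.atlas.n_rois
        if m.shape != (n, n):
            raise ValueError(
                f"matrix shape {m.shape} does not match atlas size {n}"
            )
        if not np.isfinite(m).all():
            raise ValueError("connectome contains non-finite values")
        asym = np.abs(m - m.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"connectome asymmetry {asym:g} above tolerance")
        if np.abs(np.diag(m)).max(initial=0.0) != 0.0:
            raise ValueError("connectome diagonal must be exactly zero")
        if self.modality == "functional":
            if np.abs(m).max(initial=0.0) > 1.0:
                raise ValueError("functional connectome values outside [-1, 1]")
        else:
            if m.min(initial=0.0) < 0.0:
                raise ValueError("structural connectome has negative counts")
        self.matrix = m

    def submatrix(self, rois: np.ndarray) -> np.ndarray:
        return self.matrix[np.ix_(rois, rois)]


@dataclass
class SubjectRecord:
    """One participant: group, covariates, both connectomes, optional tau."""

    subject_id: str
    group: str
    age: float
    sex: str  # {"F", "M"}
    apoe4_carrier: bool
    functional: Connectome
    structural: Connectome
    tau_suvr: np.ndarray | None = None

    def __post_init__(self):
        self.group = canonical_group(self.group)
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.tau_suvr is not None:
            tau = np.asarray(self.tau_suvr, dtype=float)
            if tau.shape != (self.functional.atlas.n_rois,):
                raise ValueError("tau vector length does not match atlas")
            self.tau_suvr = tau

    @property
    def has_tau(self) -> bool:
        return self.tau_suvr is not None


@dataclass
class CohortTable:
    """All subjects of a study sharing one atlas."""

    subjects: list
    atlas: ROIAtlas = field(default=None)

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate subject_id(s): {sorted(dupes)}")
        if self.atlas is None and self.subjects:
            self.atlas = self.subjects[0].functional.atlas
        for s in self.subjects:
            if s.functional.atlas is not self.atlas and (
                s.functional.atlas.n_rois != self.atlas.n_rois
            ):
                raise ValueError("all subjects must share one atlas")

    def __len__(self) -> int:
        return len(self.subjects)

    def group_subjects(self, group: str) -> list:
        group = canonical_group(group)
        return [s for s in self.subjects if s.group == group]

    def covariate_frame(self, subjects=None) -> pd.DataFrame:
        """Covariates as numeric columns (sex: M=1, APOE-e4 carrier: 1)."""
        subs = self.subjects if subjects is None else subjects
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subs],
                "group": [s.group for s in subs],
                "age": [s.age for s in subs],
                "sex": [1.0 if s.sex == "M" else 0.0 for s in subs],
                "apoe4": [1.0 if s.apoe4_carrier else 0.0 for s in subs],
            }
        )
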