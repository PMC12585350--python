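"""Delimited-text I/O for connectomes, atlases, cohorts and result tables.

All interchange formats are TSV:

* connectome: n rows x n columns of numbers, no header, row order = atlas order
* atlas: header ``roi_id  name  hemisphere  network  is_seed``
* cohort manifest: header ``subject_id  group  age  sex  apoe4
  functional_path  structural_path  tau_path`` (paths relative to the
  manifest's directory; an empty ``tau_path`` marks tau as missing)
* result tables: header row; floats printed to 12 significant digits so a
  write/read round trip is lossless at that precision.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    SYMMETRY_REPAIR_TOL,
    CohortTable,
    Connectome,
    ROIAtlas,
    SubjectRecord,
    canonical_group,
)

FLOAT_FMT = "%.12g"


def read_connectome(path, modality: str, atlas: ROIAtlas) -> Connectome:
    """Read and validate one TSV connectivity matrix.

    Asymmetry up to 1e-8 (e.g. from printed precision) is repaired by
    averaging the matrix with its transpose; anything larger is an error.
    """
    try:
        m = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in connectome {path}: {exc}") from exc
    n = atlas.n_rois
    if m.shape != (n, n):
        raise ValueError(
            f"connectome {path} has shape {m.shape}, atlas expects ({n}, {n})"
        )
    asym = np.abs(m - m.T).max()
    if asym > SYMMETRY_REPAIR_TOL:
        raise ValueError(f"connectome {path} asymmetry {asym:g} above 1e-08")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return Connectome(modality=modality, matrix=m, atlas=atlas)


def write_connectome(conn: Connectome, path) -> None:
    np.savetxt(path, conn.matrix, delimiter="\t", fmt=FLOAT_FMT)


def read_atlas(path) -> ROIAtlas:
    return ROIAtlas.from_dataframe(pd.read_csv(path, sep="\t"))


def write_atlas(atlas: ROIAtlas, path) -> None:
    atlas.to_dataframe().to_csv(path, sep="\t", index=False)


def read_tau(path, atlas: ROIAtlas) -> np.ndarray:
    tau = np.loadtxt(path, delimiter="\t", ndmin=1)
    if tau.shape != (atlas.n_rois,):
        raise ValueError(f"tau vector {path} length does not match atlas")
    return tau


def read_cohort(manifest_path) -> CohortTable:
    """Load a full cohort from a manifest TSV.

    Subjects whose ``tau_path`` is blank are loaded with tau marked missing;
    only the tau-association analyses drop them.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t", dtype={"subject_id": str})
    atlas = read_atlas(base / "atlas.tsv")
    subjects = []
    for row in df.itertuples(index=False):
        group = canonical_group(str(row.group))
        func = read_connectome(base / row.functional_path, "functional", atlas)
        struct = read_connectome(base / row.structural_path, "structural", atlas)
        tau = None
        tau_path = getattr(row, "tau_path", None)
        if isinstance(tau_path, str) and tau_path.strip():
            full = base / tau_path
            if not os.path.exists(full):
                raise FileNotFoundError(f"missing tau file {full}")
            tau = read_tau(full, atlas)
        subjects.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=group,
                age=float(row.age),
                sex=str(row.sex),
                apoe4_carrier=bool(int(row.apoe4)),
                functional=func,
                structural=struct,
                tau_suvr=tau,
            )
        )
    return CohortTable(subjects=subjects, atlas=atlas)


def write_cohort(cohort: CohortTable, out_dir) -> Path:
    """Write a cohort as manifest + atlas + per-subject TSVs; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(cohort.atlas, out / "atlas.tsv")
    rows = []
    for s in cohort.subjects:
        fpath = f"{s.subject_id}_functional.tsv"
        spath = f"{s.subject_id}_structural.tsv"
        write_connectome(s.functional, out / fpath)
        write_connectome(s.structural, out / spath)
        tpath = ""
        if s.has_tau:
            tpath = f"{s.subject_id}_tau.tsv"
            np.savetxt(out / tpath, s.tau_suvr, delimiter="\t", fmt=FLOAT_FMT)
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "apoe4": int(s.apoe4_carrier),
                "functional_path": fpath,
                "structural_path": spath,
                "tau_path": tpath,
            }
        )
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def write_table(result: pd.DataFrame, path) -> None:
    """Write a result table as TSV with header, 12-significant-digit floats."""
    result.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
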