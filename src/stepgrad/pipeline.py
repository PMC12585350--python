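"""End-to-end seed-based stepwise connectivity analysis in gradient space.

One :func:`run_analysis` call takes a cohort and produces, for one
modality and one hemisphere:

1. per-subject thresholded graphs and stepwise walk-count profiles,
2. the reference-group convergence curve across step sizes,
3. group-template diffusion gradients (min-max scaled g1/g2 coordinates),
4. covariate-adjusted ROI-wise group comparison of summed normalized
   stepwise connectivity with permutation FWER,
5. the binned gradient-space t-statistic grids (full and thresholded),
6. the tau-vs-connectivity-shift association for the analysis group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinnedGrid, assign_bins, grid_mean, grid_stat
from .datatypes import CohortTable, canonical_group
from .gradients import GradientEmbedding, group_template, minmax_scale
from .prep import prep_connectome
from .stats import roi_group_comparison, tau_association
from .stepwise import ConvergenceCurve, convergence_curve, stepwise_profile


@dataclass
class AnalysisResult:
    modality: str
    hemisphere: str
    rois: np.ndarray  # atlas indices analyzed
    profiles: dict  # subject_id -> StepwiseProfile
    sum_maps: dict  # subject_id -> summed normalized map (len(rois),)
    convergence: ConvergenceCurve
    template: GradientEmbedding
    scaled_coords: np.ndarray  # (len(rois), 2) in [0, 1]
    group_stats: pd.DataFrame
    grid_full: BinnedGrid
    grid_thresholded: BinnedGrid
    group_mean_grids: dict  # group -> BinnedGrid of mean summed maps
    tau_stats: pd.DataFrame | None


def run_analysis(
    cohort: CohortTable,
    modality: str = "functional",
    hemisphere: str = "left",
    contrast=("A-CN", "CI"),
    reference_group: str = "A-CN",
    fraction: float = 0.20,
    max_step: int = 7,
    steps: tuple[int, int] | None = None,
    n_bins: int = 15,
    n_perm: int = 5000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    tau_group: str | None = "CI",
    exclude_seed: bool = False,
) -> AnalysisResult:
    atlas = cohort.atlas
    rois = atlas.hemisphere_rois(hemisphere)
    seed_global = atlas.seed(hemisphere)
    seed_local = int(np.flatnonzero(rois == seed_global)[0])
    reference_group = canonical_group(reference_group)

    # walk counting always happens on the full hemisphere graph; the seed's
    # own (self-walk) value can optionally be dropped from maps and statistics
    keep = np.ones(rois.size, dtype=bool)
    if exclude_seed:
        keep[seed_local] = False

    profiles, sum_maps, prepped_weighted = {}, {}, {}
    for s in cohort.subjects:
        conn = s.functional if modality == "functional" else s.structural
        graph = prep_connectome(conn, fraction=fraction, binary=True, rois=rois)
        prof = stepwise_profile(graph, seed_local, max_step)
        profiles[s.subject_id] = prof
        sum_maps[s.subject_id] = prof.sum_normalized(steps)[keep]
        prepped_weighted[s.subject_id] = prep_connectome(
            conn, fraction=fraction, binary=False, rois=rois
        ).matrix

    ref_subjects = cohort.group_subjects(reference_group)
    curve = convergence_curve([profiles[s.subject_id] for s in ref_subjects])

    template = group_template(
        [prepped_weighted[s.subject_id] for s in ref_subjects], reference_group
    )
    scaled = minmax_scale(template, components=(0, 1))
    rois_kept = rois[keep]
    coords_kept = scaled.coordinates[keep]
    bins = assign_bins(coords_kept, n_bins)

    contrast = tuple(canonical_group(g) for g in contrast)
    contrast_subjects = [s for s in cohort.subjects if s.group in contrast]
    values = np.array([sum_maps[s.subject_id] for s in contrast_subjects])
    roi_names = [atlas.names[i] for i in rois_kept]
    stats = roi_group_comparison(
        values,
        cohort,
        contrast,
        n_perm=n_perm,
        alpha=alpha,
        rng_seed=rng_seed,
        roi_names=roi_names,
    )
    stats["roi_id"] = rois_kept
    stats["network"] = [atlas.network[i] for i in rois_kept]
    grid_full, grid_thr = grid_stat(
        stats["t"].to_numpy(),
        stats["significant"].to_numpy(),
        bins,
        n_bins,
    )

    group_mean_grids = {}
    for group in sorted({s.group for s in cohort.subjects}):
        subs = cohort.group_subjects(group)
        mean_map = np.mean([sum_maps[s.subject_id] for s in subs], axis=0)
        group_mean_grids[group] = grid_mean(mean_map, bins, n_bins)

    tau_stats = None
    if tau_group is not None:
        tau_stats = tau_association(
            cohort,
            sum_maps,
            analysis_group=tau_group,
            reference_group=reference_group,
            rois=rois_kept,
            n_perm=n_perm,
            alpha=alpha,
            rng_seed=rng_seed + 1,
        )
        tau_stats["network"] = [atlas.network[i] for i in rois_kept]

    return AnalysisResult(
        modality=modality,
        hemisphere=hemisphere,
        rois=rois_kept,
        profiles=profiles,
        sum_maps=sum_maps,
        convergence=curve,
        template=template,
        scaled_coords=coords_kept,
        group_stats=stats,
        grid_full=grid_full,
        grid_thresholded=grid_thr,
        group_mean_grids=group_mean_grids,
        tau_stats=tau_stats,
    )
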