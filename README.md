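# stepgrad

Seed-based **stepwise connectivity** of brain connectomes, integrated with
**connectome gradient** space — a reusable pipeline for studying how direct
and indirect (multi-step) connections from a seed region reorganize in
disease, and how that reorganization relates to regional tau pathology.

The package is aimed at researchers analyzing cohorts of subject-level
functional (Pearson-correlation) and structural (streamline-count)
connectomes with a region-of-interest atlas, diagnostic group labels,
covariates, and optional tau-PET SUVR maps. Because such clinical cohorts
are rarely public, the package ships a first-class synthetic-cohort
generator with planted, recoverable effects, so every stage of the pipeline
is testable end to end.

## The method

For a seed ROI *s* (e.g. the entorhinal cortex, one of the earliest sites
of tau tangle deposition in Alzheimer's disease) and a binarized,
proportionally thresholded connectome with adjacency matrix **A**, the
stepwise connectivity of target ROI *j* at step size *x* is the number of
walks of edge length *x* from the seed to the target,

> S_x(j) = (A^x)_{s,j},

computed iteratively as vector–matrix products. Because walk counts grow
exponentially in *x*, each step's map is standardized within subject
(z-scored across ROIs, population SD). Consecutive-step maps are compared
by spatial Pearson correlation; maps saturate toward the leading
eigenvector of **A** (convergence by step 7 at default settings).

Connectome **gradients** are obtained by diffusion-map embedding of a
cosine-similarity affinity (anisotropic normalization α = 0.5, diffusion
time t = 0, i.e. components scaled by λ/(1−λ)) of the group-averaged
thresholded connectome; subject embeddings are realigned to their group
template by orthogonal Procrustes. The first two gradients, min-max scaled
to [0, 1], span a 2-D coordinate system in which ROI-level values and
statistics are summarized as 15 × 15 equal-width binned heatmaps.

Group comparisons of summed normalized stepwise connectivity are ROI-wise
OLS regressions adjusted for age, sex and APOE-ε4 carriage, with
family-wise error across the ROI map controlled by permutation maxT
(Freedman–Lane residual permutation). The tau stage regresses each ROI's
baseline tau SUVR on the subject's connectivity shift
Δ_s(r) = Σ_x z_x(r) − ⟨Σ_x z_x(r)⟩_controls, with the same covariates.

## Worked example

```python
import numpy as np
import stepgrad as sg

cfg = sg.SimulationConfig(rng_seed=1)     # default world: 80 ROIs, 8 networks,
cohort = sg.simulate_cohort(cfg)          # 30/20/30 subjects, planted CI effects
res = sg.run_analysis(cohort, modality="functional", hemisphere="left",
                      contrast=("A-CN", "CI"), n_perm=2000, rng_seed=1)

print(res.convergence.r(6, 7))                       # 0.9996
print(int(res.group_stats["significant"].sum()))     # 16
sig = res.group_stats[res.group_stats.significant]
print(sig.groupby("network")["t"].mean().round(1))
#   DMN              -7.9   <- planted hypoconnectivity, recovered negative
#   frontoparietal   -3.5   <- propagated via walks through the DMN
#   somatomotor      +7.4   <- planted hyperconnectivity, recovered positive
#   visual           +4.7   <- propagated via walks through somatomotor
print(float(np.nanmedian(res.tau_stats["slope"])))   # 0.0992  (truth: 0.1)
```

The step-map convergence (0.9996 at steps 6–7) shows the walk-count maps
have topologically stabilized; the significant-ROI table recovers the
planted group effects with the correct signs; and the tau regression
recovers the generator's tau–connectivity slope of 0.1 SUVR per z-unit to
within 1%. `res.grid_thresholded` holds the FWER-thresholded gradient-space
heatmap of the group t-statistics.

The same pipeline is available from a shell:

```bash
stepgrad simulate --out data/                 # write manifest + TSVs
stepgrad run --manifest data/manifest.tsv --out results/
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch — it simulates the default cohort from the given seed, executes the
full left- and right-hemisphere functional analyses (thresholding, walk
counts, convergence, gradients, permutation-FWER group statistics,
gradient-space grids, tau association) and writes its result JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module | contents |
| --- | --- |
| `stepgrad.datatypes` | `ROIAtlas`, `Connectome`, `SubjectRecord`, `CohortTable` |
| `stepgrad.io` | TSV readers/writers for matrices, atlases, cohorts, result tables |
| `stepgrad.simulate` | `SimulationConfig`, planted-effect cohort generator, ground-truth maps |
| `stepgrad.prep` | Fisher z, top-fraction thresholding, union symmetrization, `ConnectomeThresholder` |
| `stepgrad.stepwise` | walk counts, within-subject normalization, convergence, `StepwiseConnectivity` |
| `stepgrad.gradients` | cosine affinity, diffusion embedding, Procrustes, `DiffusionGradients` |
| `stepgrad.binning` | gradient-space bin assignment, cell means, FWER-thresholded grids |
| `stepgrad.stats` | ROI-wise OLS, permutation maxT FWER, tau association |
| `stepgrad.pipeline` | `run_analysis` end-to-end orchestration |
| `stepgrad.cli` | `stepgrad` console script (`simulate`/`prep`/`sfc`/`gradients`/`stats`/`tau`/`run`) |

See `docs/methods.md` for the model, parameter choices, and limitations.
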