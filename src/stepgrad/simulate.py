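"""Synthetic cohort generator with known planted seed-centric effects.

Stands in for a non-public clinical cohort: three diagnostic groups
(amyloid-negative controls A-CN, preclinical A+CN, impaired CI) with
network-block-structured functional and structural connectomes, covariates
(age, sex, APOE-e4), and regional tau maps.

Functional connectomes are Pearson correlations of simulated time series
from a unit-variance latent-factor model (shared network factor + global
factor + planted seed-coupling factors + white noise), which guarantees a
valid (positive semidefinite) correlation matrix. A planted hypo/hyper
effect of magnitude m shifts the expected seed-to-target-network
correlation by exactly -/+ m: the plant's variance is taken out of the
residual noise budget so every series keeps unit variance.

Structural connectomes are symmetric Poisson count matrices with
within-network mean ``mu_within`` and between-network means decaying with
block distance along the network ordering (emulating posterior-to-anterior
propagation structure); planted effects multiply the seed-to-target-network
means by (1 +/- m).

Tau is linked to each subject's realized stepwise-connectivity shift (their
sum-normalized seed walk-count map minus the A-CN group mean) with slope
``tau_link_slope``, plus Gaussian noise, so the tau-association stage has a
recoverable ground-truth slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .datatypes import GROUPS, CohortTable, Connectome, ROIAtlas, SubjectRecord
from .prep import prep_connectome
from .stepwise import stepwise_profile

DEFAULT_NETWORKS = (
    ("medial-temporal", 10),
    ("visual", 10),
    ("dorsal-attention", 10),
    ("somatomotor", 10),
    ("limbic", 10),
    ("cingulo-opercular", 10),
    ("DMN", 10),
    ("frontoparietal", 10),
)

#: hierarchy position of each default network along the unimodal-to-transmodal
#: chain (somatomotor pole 0 ... DMN pole 7, medial-temporal seed mid-chain)
DEFAULT_POSITIONS = (5.0, 1.0, 2.0, 0.0, 4.0, 3.0, 7.0, 6.0)


@dataclass(frozen=True)
class Effect:
    """One planted group effect on seed-to-target-network connectivity."""

    group: str
    target_network: str
    modality: str  # {"functional", "structural"}
    direction: str  # {"hypo", "hyper"}
    magnitude: float

    def __post_init__(self):
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"direction must be hypo/hyper, got {self.direction!r}")
        if self.magnitude < 0:
            raise ValueError("effect magnitude must be >= 0")

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "hyper" else -1.0


# Functional magnitudes are balanced for realized strength: the DMN sits two
# hierarchy steps from the seed and expresses a plant far more strongly than
# the distal somatomotor pole, so equal magnitudes would leave a net
# normalization imbalance. These defaults give group t-statistics at planted
# networks in the 4-8 range typical of cohort studies of this size.
DEFAULT_EFFECTS = (
    Effect("CI", "DMN", "functional", "hypo", 0.12),
    Effect("CI", "somatomotor", "functional", "hyper", 0.18),
    Effect("CI", "visual", "structural", "hypo", 0.40),
    Effect("CI", "frontoparietal", "structural", "hyper", 0.40),
)


@dataclass
class SimulationConfig:
    """Full specification of a synthetic cohort; outputs are a pure function of it."""

    n_rois: int = 80
    networks: tuple = DEFAULT_NETWORKS
    group_sizes: dict = field(
        default_factory=lambda: {"A-CN": 30, "A+CN": 20, "CI": 30}
    )
    seed_roi: int = 0
    effects: tuple = DEFAULT_EFFECTS
    timeseries_length: int = 400
    #: variance fraction carried by the shared network factor
    network_coupling: float = 0.35
    #: variance fraction carried by the global factor (baseline between-network r)
    global_coupling: float = 0.10
    #: correlation of neighboring network factors decays as rho^|block distance|,
    #: ordering networks along a posterior-to-anterior / unimodal-to-transmodal chain
    network_corr_decay: float = 0.5
    #: between-subject heterogeneity: per-subject per-ROI lognormal jitter on the
    #: network-factor variance fraction (0 = identical loadings for all subjects)
    loading_jitter_sd: float = 0.35
    #: per-network positions along the connectivity hierarchy; factor correlation
    #: and structural streamline decay follow |position| distance. None = block order.
    network_positions: tuple | None = None
    #: half-width of the within-network spread of per-ROI hierarchy positions;
    #: 0 collapses each network to a point (all members share one profile)
    within_network_spread: float = 0.3
    #: idiosyncratic noise SD; default sqrt(1 - w - v) gives unit total variance
    noise_sd: float | None = None
    mu_within: float = 100.0
    mu_between: float = 30.0
    distance_decay: float = 0.6
    tau_baseline: dict = field(
        default_factory=lambda: {"A-CN": 1.0, "A+CN": 1.1, "CI": 1.3}
    )
    tau_link_slope: float = 0.1
    tau_noise_sd: float = 0.1
    apoe4_rates: dict = field(
        default_factory=lambda: {"A-CN": 0.265, "A+CN": 0.257, "CI": 0.569}
    )
    female_rate: float = 0.6
    n_missing_tau: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        self.networks = tuple((str(l), int(s)) for l, s in self.networks)
        if sum(s for _, s in self.networks) != self.n_rois:
            raise ValueError("network sizes must sum to n_rois")
        if not 0 <= self.seed_roi < self.n_rois:
            raise ValueError(f"seed_roi {self.seed_roi} outside 0..{self.n_rois - 1}")
        if self.seed_roi >= self.networks[0][1]:
            raise ValueError("seed_roi must lie in the first (medial-temporal) block")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in group_sizes")
            if n < 1:
                raise ValueError("group sizes must be >= 1")
        self.effects = tuple(
            e if isinstance(e, Effect) else Effect(**e) for e in self.effects
        )
        labels = {label for label, _ in self.networks}
        for e in self.effects:
            if e.target_network not in labels:
                raise ValueError(
                    f"effect targets unknown network {e.target_network!r}"
                )
            if e.group not in GROUPS:
                raise ValueError(f"effect names unknown group {e.group!r}")
            if e.modality not in ("functional", "structural"):
                raise ValueError(f"effect names unknown modality {e.modality!r}")
        if self.noise_sd is None:
            self.noise_sd = float(
                np.sqrt(1.0 - self.network_coupling - self.global_coupling)
            )
        if self.network_coupling + self.global_coupling > 1.0:
            raise ValueError("network_coupling + global_coupling must be <= 1")
        if self.network_positions is None:
            if self.networks == DEFAULT_NETWORKS:
                self.network_positions = DEFAULT_POSITIONS
            else:
                self.network_positions = tuple(float(i) for i in range(len(self.networks)))
        else:
            self.network_positions = tuple(float(p) for p in self.network_positions)
        if len(self.network_positions) != len(self.networks):
            raise ValueError("network_positions must match networks in length")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["effects"] = [asdict(e) for e in self.effects]
        data["networks"] = [list(nw) for nw in self.networks]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def make_atlas(config: SimulationConfig) -> ROIAtlas:
    """Atlas with contiguous network blocks, split half-left / half-right.

    The configured seed ROI (first block) is flagged, together with the
    first ROI of the first block in the opposite hemisphere, so each
    hemisphere has a seed.
    """
    names, hemi, network = [], [], []
    start = 0
    block_bounds = []
    for label, size in config.networks:
        if size < 2:
            raise ValueError(f"network {label!r} needs >= 2 ROIs for both hemispheres")
        n_left = (size + 1) // 2
        for j in range(size):
            side = "left" if j < n_left else "right"
            names.append(f"{label}_{side[0].upper()}{j if j < n_left else j - n_left}")
            hemi.append(side)
            network.append(label)
        block_bounds.append((start, start + size, n_left))
        start += size
    hemi = np.array(hemi, dtype=object)
    is_seed = np.zeros(config.n_rois, dtype=bool)
    is_seed[config.seed_roi] = True
    first_lo, first_hi, n_left0 = block_bounds[0]
    seed_hemi = hemi[config.seed_roi]
    other = "right" if seed_hemi == "left" else "left"
    block0 = np.arange(first_lo, first_hi)
    is_seed[block0[hemi[block0] == other][0]] = True
    return ROIAtlas(
        names=tuple(names),
        hemisphere=hemi,
        network=np.array(network, dtype=object),
        is_seed=is_seed,
    )


def roi_positions(config: SimulationConfig, atlas: ROIAtlas) -> np.ndarray:
    """Continuous per-ROI hierarchy positions.

    Each ROI sits at its network's position plus an evenly spaced
    within-network offset (mirrored across hemispheres, so homotopic pairs
    share a position). The functional factor correlation decays with
    distance on this axis, giving a continuous connectivity gradient
    rather than a set of point-mass communities.
    """
    net_labels = [label for label, _ in config.networks]
    base = np.asarray(config.network_positions)
    pos = np.empty(config.n_rois)
    spread = config.within_network_spread
    for k, lab in enumerate(net_labels):
        members = np.flatnonzero(atlas.network == lab)
        for hemi in ("left", "right"):
            sub = members[atlas.hemisphere[members] == hemi]
            if sub.size == 0:
                continue
            offsets = (
                np.linspace(-spread, spread, sub.size) if sub.size > 1 else np.zeros(1)
            )
            pos[sub] = base[k] + offsets
    return pos


def _plant_loadings(config: SimulationConfig, atlas: ROIAtlas, group: str):
    """Per-effect loading vectors (sqrt-variance) for functional plants.

    A *hyper* effect adds a seed-target coupling factor to the affected
    group only; a *hypo* effect adds it to every group EXCEPT the affected
    one, so hypoconnectivity is the loss of a coupling the other groups
    have (rather than an anti-correlation appearing in patients). Either
    way the expected seed-to-target correlation of the affected group
    differs from the others by +/- magnitude.
    """
    loadings = []
    seeds = np.flatnonzero(atlas.is_seed)
    for e in config.effects:
        if e.modality != "functional" or e.magnitude == 0:
            continue
        carried = (group == e.group) if e.direction == "hyper" else (group != e.group)
        if not carried:
            continue
        load = np.zeros(config.n_rois)
        root = np.sqrt(e.magnitude)
        for s in seeds:
            load[s] = root
        targets = np.flatnonzero(atlas.network == e.target_network)
        load[targets] = root
        loadings.append((e, load))
    return loadings


def simulate_functional(
    config: SimulationConfig, group: str, rng: np.random.Generator
) -> Connectome:
    """One subject's functional connectome (Pearson r of latent-factor series)."""
    if config.timeseries_length < config.n_rois + 1:
        raise ValueError(
            "timeseries_length must exceed n_rois to avoid rank deficiency"
        )
    atlas = make_atlas(config)
    n, t = config.n_rois, config.timeseries_length
    w, v = config.network_coupling, config.global_coupling
    # per-ROI factors correlated along the hierarchy axis (Ornstein-Uhlenbeck
    # kernel rho^|p_i - p_j|, positive semidefinite for any positions)
    rho = config.network_corr_decay
    pos = roi_positions(config, atlas)
    corr_f = rho ** np.abs(np.subtract.outer(pos, pos))
    chol = np.linalg.cholesky(corr_f + 1e-10 * np.eye(n))
    factors = chol @ rng.standard_normal((n, t))
    global_factor = rng.standard_normal(t)
    plant_var = np.zeros(n)
    plant_terms = []
    for e, load in _plant_loadings(config, atlas, group):
        h = rng.standard_normal(t)
        plant_terms.append(load[:, None] * h)
        plant_var += load**2
    budget = w + config.noise_sd**2 - plant_var  # variance left for factor + noise
    if (budget <= 0.0).any():
        raise ValueError(
            "planted effect magnitudes exceed the noise variance budget "
            f"(w + noise_sd^2 = {w + config.noise_sd**2:.3f})"
        )
    # per-subject per-ROI heterogeneity in how strongly each region expresses
    # its network's factor; jitter 0 reproduces identical loadings. The jitter
    # trades variance against the residual so total variance stays fixed.
    if config.loading_jitter_sd > 0:
        net_var = w * rng.lognormal(0.0, config.loading_jitter_sd, size=n)
        net_var = np.clip(net_var, 0.05 * w, budget - 1e-3)
    else:
        net_var = np.full(n, w)  # resid is then exactly noise_sd^2 - plant
    x = np.sqrt(net_var)[:, None] * factors + np.sqrt(v) * global_factor
    for term in plant_terms:
        x += term
    resid_var = budget - net_var
    if (resid_var < 0.0).any():
        raise ValueError(
            "planted effect magnitudes exceed the noise variance budget "
            f"(noise_sd^2 = {config.noise_sd**2:.4f})"
        )
    x += np.sqrt(resid_var)[:, None] * rng.standard_normal((n, t))
    corr = np.corrcoef(x)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return Connectome(modality="functional", matrix=corr, atlas=atlas)


def structural_rates(config: SimulationConfig, group: str) -> np.ndarray:
    """Expected streamline counts (Poisson means) for one group."""
    atlas = make_atlas(config)
    pos = roi_positions(config, atlas)
    dist = np.abs(pos[:, None] - pos[None, :])
    same_net = np.equal.outer(atlas.network, atlas.network)
    mu = np.where(
        same_net,
        config.mu_within,
        config.mu_between * config.distance_decay ** np.maximum(dist - 1.0, 0.0),
    ).astype(float)
    seeds = np.flatnonzero(atlas.is_seed)
    for e in config.effects:
        if e.modality != "structural" or e.group != group:
            continue
        targets = np.flatnonzero(atlas.network == e.target_network)
        factor = 1.0 + e.sign * e.magnitude
        for s in seeds:
            mu[s, targets] *= factor
            mu[targets, s] *= factor
    np.fill_diagonal(mu, 0.0)
    return mu


def simulate_structural(
    config: SimulationConfig, group: str, rng: np.random.Generator
) -> Connectome:
    """One subject's structural connectome: symmetric Poisson counts."""
    atlas = make_atlas(config)
    mu = structural_rates(config, group)
    iu = np.triu_indices(config.n_rois, k=1)
    counts = np.zeros_like(mu)
    counts[iu] = rng.poisson(mu[iu])
    counts = counts + counts.T
    return Connectome(modality="structural", matrix=counts, atlas=atlas)


def _sum_normalized_map(subject: SubjectRecord, atlas: ROIAtlas, max_step: int = 7):
    """Full-length sum-normalized seed walk-count map, per hemisphere."""
    out = np.zeros(atlas.n_rois)
    for hemi in ("left", "right"):
        rois = atlas.hemisphere_rois(hemi)
        graph = prep_connectome(subject.functional, rois=rois)
        seed_local = int(np.flatnonzero(rois == atlas.seed(hemi))[0])
        profile = stepwise_profile(graph, seed_local, max_step)
        out[rois] = profile.sum_normalized()
    return out


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Generate the full cohort; fully reproducible from ``config.rng_seed``."""
    atlas = make_atlas(config)
    seq = np.random.SeedSequence(config.rng_seed)
    rng_cov, rng_conn, rng_tau = (
        np.random.default_rng(s) for s in seq.spawn(3)
    )
    subjects = []
    for group in GROUPS:
        size = config.group_sizes.get(group, 0)
        for i in range(size):
            age = float(rng_cov.normal(70.0, 9.0))
            while not 50.0 <= age <= 95.0:
                age = float(rng_cov.normal(70.0, 9.0))
            sex = "F" if rng_cov.random() < config.female_rate else "M"
            apoe = bool(rng_cov.random() < config.apoe4_rates[group])
            func = simulate_functional(config, group, rng_conn)
            struct = simulate_structural(config, group, rng_conn)
            subjects.append(
                SubjectRecord(
                    subject_id=f"{group}_{i:03d}",
                    group=group,
                    age=age,
                    sex=sex,
                    apoe4_carrier=apoe,
                    functional=func,
                    structural=struct,
                )
            )
    # tau: baseline + slope * (subject's realized connectivity shift) + noise
    maps = {s.subject_id: _sum_normalized_map(s, atlas) for s in subjects}
    ref = [s for s in subjects if s.group == "A-CN"]
    ref_mean = np.mean([maps[s.subject_id] for s in ref], axis=0)
    for s in subjects:
        shift = maps[s.subject_id] - ref_mean
        tau = (
            config.tau_baseline[s.group]
            + config.tau_link_slope * shift
            + rng_tau.normal(0.0, config.tau_noise_sd, size=atlas.n_rois)
        )
        s.tau_suvr = tau
    for s in ref[: config.n_missing_tau]:
        s.tau_suvr = None
    return CohortTable(subjects=subjects, atlas=atlas)


def expected_functional_matrix(config: SimulationConfig, group: str) -> np.ndarray:
    """Noise-free expected functional correlation matrix for one group.

    The latent-factor model implies corr(i, j) = w * rho^|p_i - p_j| + v
    plus the planted seed-coupling contributions; this is the generator's
    analytic ground truth (loading jitter averages out across subjects).
    """
    atlas = make_atlas(config)
    w, v = config.network_coupling, config.global_coupling
    pos = roi_positions(config, atlas)
    corr = w * config.network_corr_decay ** np.abs(np.subtract.outer(pos, pos)) + v
    for _, load in _plant_loadings(config, atlas, group):
        corr += np.outer(load, load)
    np.fill_diagonal(corr, 0.0)
    return np.clip(corr, -1.0, 1.0)


def true_effect_map(
    config: SimulationConfig,
    contrast=("A-CN", "CI"),
    hemisphere: str = "left",
    max_step: int = 7,
    steps: tuple[int, int] | None = None,
) -> np.ndarray:
    """Ground-truth propagated effect of the plants on summed normalized maps.

    Runs the deterministic pipeline (threshold, walk counts, normalization,
    summation) on each group's expected connectome and returns the
    difference (second minus first contrast group) over the hemisphere's
    ROIs. This is the direction a correct analysis should recover, including
    the walk-propagation and normalization-compensation structure that a
    seed-coupling plant induces away from its target network.
    """
    atlas = make_atlas(config)
    rois = atlas.hemisphere_rois(hemisphere)
    seed_local = int(np.flatnonzero(rois == atlas.seed(hemisphere))[0])
    maps = []
    for group in contrast:
        m = expected_functional_matrix(config, group)
        conn = Connectome(modality="functional", matrix=m, atlas=atlas)
        graph = prep_connectome(conn, rois=rois)
        prof = stepwise_profile(graph, seed_local, max_step)
        maps.append(prof.sum_normalized(steps))
    return maps[1] - maps[0]


def null_config(**overrides) -> SimulationConfig:
    """A no-effect configuration (exchangeable groups) for calibration studies."""
    defaults = dict(effects=(), tau_link_slope=0.0)
    defaults.update(overrides)
    return SimulationConfig(**defaults)
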