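"""Generator checks: degenerate limits, planted-effect expectations, determinism."""

import numpy as np
import pytest

import stepgrad as sg
from stepgrad.simulate import (
    Effect,
    SimulationConfig,
    expected_functional_matrix,
    make_atlas,
    simulate_cohort,
    simulate_functional,
    simulate_structural,
)


def _seed_target_mean(conn, atlas, network):
    seeds = np.flatnonzero(atlas.is_seed)
    targets = np.flatnonzero(atlas.network == network)
    return conn.matrix[np.ix_(seeds, targets)].mean()


class TestMakeAtlas:
    def test_blocks_and_sizes(self):
        cfg = SimulationConfig(
            n_rois=10,
            networks=(("medial-temporal", 4), ("DMN", 3), ("visual", 3)),
            timeseries_length=20,
            effects=(),
        )
        atlas = make_atlas(cfg)
        assert atlas.n_rois == 10
        assert list(atlas.network[:4]) == ["medial-temporal"] * 4
        assert list(atlas.network[4:7]) == ["DMN"] * 3
        # one seed per hemisphere, both in the first block
        seeds = np.flatnonzero(atlas.is_seed)
        assert len(seeds) == 2 and all(s < 4 for s in seeds)
        assert {atlas.hemisphere[s] for s in seeds} == {"left", "right"}

    def test_seed_roi_out_of_range(self):
        with pytest.raises(ValueError, match="seed_roi"):
            SimulationConfig(
                n_rois=10, networks=(("medial-temporal", 10),), seed_roi=10, effects=()
            )

    def test_deterministic(self):
        cfg = SimulationConfig()
        a1, a2 = make_atlas(cfg), make_atlas(cfg)
        assert a1.names == a2.names
        assert np.array_equal(a1.is_seed, a2.is_seed)


class TestFunctionalGenerator:
    def test_single_network_low_noise_corr_one(self):
        cfg = SimulationConfig(
            n_rois=6,
            networks=(("medial-temporal", 6),),
            noise_sd=1e-4,
            loading_jitter_sd=0.0,
            within_network_spread=0.0,
            timeseries_length=50,
            effects=(),
        )
        conn = simulate_functional(cfg, "A-CN", np.random.default_rng(0))
        off = conn.matrix[~np.eye(6, dtype=bool)]
        assert np.all(np.abs(off - 1.0) < 1e-6)

    def test_independent_networks_low_noise(self):
        cfg = SimulationConfig(
            n_rois=8,
            networks=(("medial-temporal", 4), ("DMN", 4)),
            global_coupling=0.0,
            network_corr_decay=0.0,
            loading_jitter_sd=0.0,
            noise_sd=1e-3,
            timeseries_length=2000,
            effects=(),
        )
        conn = simulate_functional(cfg, "A-CN", np.random.default_rng(1))
        atlas = make_atlas(cfg)
        between = conn.matrix[np.ix_(atlas.network == "medial-temporal", atlas.network == "DMN")]
        assert np.abs(between).max() < 0.1

    def test_hyper_effect_shifts_seed_correlation_by_magnitude(self):
        """Monte-Carlo check of the generator's own expectation: +0.3 +/- 0.05."""
        eff = (Effect("CI", "DMN", "functional", "hyper", 0.3),)
        cfg = SimulationConfig(effects=eff, rng_seed=0)
        atlas = make_atlas(cfg)
        rng = np.random.default_rng(42)
        diffs = []
        for _ in range(50):
            ci = simulate_functional(cfg, "CI", rng)
            cn = simulate_functional(cfg, "A-CN", rng)
            diffs.append(
                _seed_target_mean(ci, atlas, "DMN") - _seed_target_mean(cn, atlas, "DMN")
            )
        assert abs(np.mean(diffs) - 0.3) < 0.05

    def test_valid_correlation_matrix(self, default_cohort):
        for s in default_cohort.subjects[::17]:
            m = s.functional.matrix.copy()
            assert np.abs(m - m.T).max() == 0.0
            assert np.abs(m).max() <= 1.0
            np.fill_diagonal(m, 1.0)
            assert np.linalg.eigvalsh(m).min() >= -1e-10

    def test_short_timeseries_rejected(self):
        cfg = SimulationConfig(timeseries_length=50)
        with pytest.raises(ValueError, match="timeseries_length"):
            simulate_functional(cfg, "A-CN", np.random.default_rng(0))

    def test_expected_matrix_matches_empirical(self):
        cfg = SimulationConfig(loading_jitter_sd=0.0, rng_seed=0)
        rng = np.random.default_rng(5)
        emp = np.mean(
            [simulate_functional(cfg, "CI", rng).matrix for _ in range(40)], axis=0
        )
        exp = expected_functional_matrix(cfg, "CI")
        off = ~np.eye(cfg.n_rois, dtype=bool)
        assert np.abs(emp[off] - exp[off]).mean() < 0.02


class TestStructuralGenerator:
    def test_block_diagonal_when_between_zero(self):
        cfg = SimulationConfig(
            n_rois=8,
            networks=(("medial-temporal", 4), ("DMN", 4)),
            mu_between=0.0,
            timeseries_length=20,
            effects=(),
        )
        conn = simulate_structural(cfg, "A-CN", np.random.default_rng(0))
        atlas = make_atlas(cfg)
        cross = conn.matrix[np.ix_(atlas.network == "medial-temporal", atlas.network == "DMN")]
        assert cross.max() == 0.0

    def test_exchangeable_when_no_effects(self):
        cfg = SimulationConfig(effects=(), rng_seed=0)
        rng = np.random.default_rng(3)
        a = np.mean([simulate_structural(cfg, "A-CN", rng).matrix for _ in range(30)], axis=0)
        b = np.mean([simulate_structural(cfg, "CI", rng).matrix for _ in range(30)], axis=0)
        off = ~np.eye(cfg.n_rois, dtype=bool)
        # SE of a difference of 30-subject Poisson means at mu<=100 is ~2.6;
        # the max over ~6400 entries stays within 5 SE
        assert np.abs(a[off] - b[off]).max() < 13.0

    def test_hypo_effect_halves_seed_target_counts(self):
        eff = (Effect("CI", "DMN", "structural", "hypo", 0.5),)
        cfg = SimulationConfig(effects=eff)
        atlas = make_atlas(cfg)
        rng = np.random.default_rng(11)
        ci = np.mean(
            [_seed_target_mean(simulate_structural(cfg, "CI", rng), atlas, "DMN") for _ in range(50)]
        )
        cn = np.mean(
            [_seed_target_mean(simulate_structural(cfg, "A-CN", rng), atlas, "DMN") for _ in range(50)]
        )
        assert abs(ci / cn - 0.5) < 0.1


class TestCohort:
    def test_reproducible_from_seed(self):
        cfg = SimulationConfig(
            n_rois=16,
            networks=(("medial-temporal", 8), ("DMN", 8)),
            group_sizes={"A-CN": 3, "A+CN": 2, "CI": 3},
            timeseries_length=40,
            effects=(),
            rng_seed=9,
        )
        c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
        for a, b in zip(c1.subjects, c2.subjects):
            assert a.age == b.age and a.sex == b.sex and a.apoe4_carrier == b.apoe4_carrier
            assert np.array_equal(a.functional.matrix, b.functional.matrix)
            assert np.array_equal(a.structural.matrix, b.structural.matrix)
            if a.has_tau:
                assert np.array_equal(a.tau_suvr, b.tau_suvr)

    def test_zero_link_slope_decouples_tau(self):
        cfg = sg.null_config(
            group_sizes={"A-CN": 10, "A+CN": 2, "CI": 10},
            timeseries_length=120,
            n_missing_tau=0,
            rng_seed=21,
        )
        cohort = simulate_cohort(cfg)
        from stepgrad.simulate import _sum_normalized_map

        subs = cohort.group_subjects("A-CN")
        maps = np.array([_sum_normalized_map(s, cohort.atlas) for s in subs])
        taus = np.array([s.tau_suvr for s in subs])
        rs = [
            np.corrcoef(maps[:, r], taus[:, r])[0, 1]
            for r in range(0, cohort.atlas.n_rois, 4)
        ]
        assert np.abs(np.mean(rs)) < 0.1

    def test_noiseless_tau_tracks_connectivity_shift(self):
        cfg = SimulationConfig(
            group_sizes={"A-CN": 8, "A+CN": 2, "CI": 8},
            timeseries_length=120,
            tau_link_slope=0.5,
            tau_noise_sd=1e-9,
            n_missing_tau=0,
            rng_seed=2,
        )
        cohort = simulate_cohort(cfg)
        from stepgrad.simulate import _sum_normalized_map

        maps = {s.subject_id: _sum_normalized_map(s, cohort.atlas) for s in cohort.subjects}
        ref = np.mean(
            [maps[s.subject_id] for s in cohort.group_subjects("A-CN")], axis=0
        )
        subs = cohort.group_subjects("CI")
        shift = np.array([maps[s.subject_id] - ref for s in subs])
        tau = np.array([s.tau_suvr for s in subs])
        for r in range(0, cohort.atlas.n_rois, 7):
            if shift[:, r].std() > 1e-12:
                assert np.corrcoef(shift[:, r], tau[:, r])[0, 1] > 0.999

    def test_missing_tau_marked(self, default_cohort):
        missing = [s for s in default_cohort.subjects if not s.has_tau]
        assert len(missing) == 1
        assert missing[0].group == "A-CN"


class TestConfig:
    def test_network_sizes_must_sum(self):
        with pytest.raises(ValueError, match="sum to n_rois"):
            SimulationConfig(n_rois=10, networks=(("medial-temporal", 4),), effects=())

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(rng_seed=5)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = SimulationConfig.from_yaml(p)
        assert back == cfg

    def test_unknown_yaml_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_roist: 80\n")
        with pytest.raises(ValueError, match="unknown config key"):
            SimulationConfig.from_yaml(p)
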