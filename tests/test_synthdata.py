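"""Generator correctness: determinism, rendering, visibility, trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tightrope.detection import stack_frames
from tightrope.synthdata import (SimulationConfig, Species,
                                 expected_observed_composition,
                                 generate_livecell_movie,
                                 generate_survival_counts,
                                 generate_tightrope_movie, reflected_brownian,
                                 tightrope_geometry)


class TestTightropeMovie:
    def test_noiseless_static_argmax_matches_truth(self, noiseless_config):
        movie, truth = generate_tightrope_movie(noiseless_config, seed=7)
        geom, _ = tightrope_geometry(noiseless_config)
        mol = truth.molecules[0]
        x, y = geom.point_at_px(mol.positions_um[0] / noiseless_config.um_per_px)
        stack = movie.channels["565"]
        for frame in stack:
            r, c = np.unravel_index(np.argmax(frame), frame.shape)
            assert abs(c - x) <= 0.5 and abs(r - y) <= 0.5

    def test_all_dark_movie_is_pure_background(self, noiseless_config):
        noiseless_config.species[0].dark_fraction = 1.0
        noiseless_config.species[0].count = 5
        movie, truth = generate_tightrope_movie(noiseless_config, seed=3)
        assert np.all(movie.channels["565"] == 0.0)
        assert all(not any(m.visible.values()) for m in truth.molecules)

    def test_uniform_placement_mean_position(self):
        cfg = SimulationConfig(species=[Species(composition=("A",), count=1000)],
                               n_frames=1, background_mean=0, read_noise_sigma=0,
                               shot_noise=False)
        _, truth = generate_tightrope_movie(cfg, seed=11)
        positions = [m.mean_position_um for m in truth.molecules]
        L = cfg.tightrope_length_um
        se = (L / math.sqrt(12)) / math.sqrt(1000)
        assert abs(np.mean(positions) - L / 2) < 3 * se

    def test_determinism_bit_identical(self, snr10_config):
        m1, t1 = generate_tightrope_movie(snr10_config, seed=42)
        m2, t2 = generate_tightrope_movie(snr10_config, seed=42)
        for ch in m1.channels:
            np.testing.assert_array_equal(m1.channels[ch], m2.channels[ch])
        assert [m.positions_um.tolist() for m in t1.molecules] == \
               [m.positions_um.tolist() for m in t2.molecules]

    def test_photon_conservation_noiseless(self, noiseless_config):
        movie, _ = generate_tightrope_movie(noiseless_config, seed=1)
        amp = noiseless_config.species[0].amplitude
        sigma = noiseless_config.psf_sigma_px
        expected = amp * 2 * math.pi * sigma**2
        for frame in movie.channels["565"]:
            assert frame.sum() == pytest.approx(expected, rel=0.01)

    def test_damage_bound_molecule_sits_on_damage_coordinate(self):
        cfg = SimulationConfig(
            species=[Species(composition=("A",), count=1, damage_bound_fraction=1.0)],
            damage_positions_kbp=[24.25], background_mean=0, read_noise_sigma=0,
            shot_noise=False)
        _, truth = generate_tightrope_movie(cfg, seed=5)
        mol = truth.molecules[0]
        assert mol.damage_bound
        assert mol.mean_position_um == pytest.approx(cfg.kbp_to_um(24.25))

    def test_trajectories_confined_to_tightrope(self):
        cfg = SimulationConfig(
            species=[Species(composition=("A",), count=20,
                             diffusion_constant_um2_s=0.5)],
            n_frames=200, background_mean=0, read_noise_sigma=0, shot_noise=False)
        _, truth = generate_tightrope_movie(cfg, seed=9)
        for m in truth.molecules:
            assert np.all(m.positions_um >= 0)
            assert np.all(m.positions_um <= cfg.tightrope_length_um)

    def test_angled_tightrope_renders_along_its_axis(self):
        cfg = SimulationConfig(species=[Species(composition=("A",), count=1)],
                               angle_deg=30.0, n_frames=2, background_mean=0,
                               read_noise_sigma=0, shot_noise=False)
        movie, truth = generate_tightrope_movie(cfg, seed=4)
        geom, shape = tightrope_geometry(cfg)
        assert movie.frame_shape == shape
        x, y = geom.point_at_px(truth.molecules[0].positions_um[0]
                                / cfg.um_per_px)
        frame = movie.channels["565"][0]
        r, c = np.unravel_index(np.argmax(frame), frame.shape)
        assert abs(c - x) <= 0.5 and abs(r - y) <= 0.5

    def test_invalid_config_names_field(self):
        cfg = SimulationConfig(species=[Species(composition=())])
        with pytest.raises(ValueError, match="composition"):
            generate_tightrope_movie(cfg, seed=0)
        cfg2 = SimulationConfig(species=[Species(composition=("A",),
                                                 dark_fraction=1.5)])
        with pytest.raises(ValueError, match="dark_fraction"):
            generate_tightrope_movie(cfg2, seed=0)
        cfg3 = SimulationConfig(damage_positions_kbp=[60.0])
        with pytest.raises(ValueError, match="damage_positions_kbp"):
            generate_tightrope_movie(cfg3, seed=0)


class TestReflectedBrownian:
    def test_stays_in_bounds(self):
        rng = np.random.default_rng(0)
        x = reflected_brownian(10000, 0.1, 0.5, 4.0, 2.0, rng)
        assert np.all(x >= 0) and np.all(x <= 4.0)

    def test_msd_slope_recovers_diffusion_constant(self):
        d, dt, L = 0.05, 0.1, 16.0
        x = reflected_brownian(10000, dt, d, L, L / 2, np.random.default_rng(1))
        d_hat = np.mean(np.diff(x) ** 2) / (2 * dt)
        assert d_hat == pytest.approx(d, rel=0.10)


class TestLivecellMovie:
    def test_static_fraction_one_labels_all_cells(self):
        cfg = SimulationConfig(n_frames=3)
        _, truth = generate_livecell_movie(cfg, n_cells=20, static_fraction=1.0,
                                           seed=2)
        assert all(c.has_static_spot for c in truth.cells)

    def test_static_fraction_zero_has_no_persistent_maxima(self):
        cfg = SimulationConfig(n_frames=10, background_mean=0,
                               read_noise_sigma=0, shot_noise=False)
        movie, truth = generate_livecell_movie(cfg, n_cells=9, static_fraction=0.0,
                                               seed=2, cell_fluorescence=50.0)
        assert not any(c.has_static_spot for c in truth.cells)
        # noiseless diffuse cells are flat: no pixel exceeds the body level
        assert movie.channels["egfp"].max() <= 50.0 + 1e-9

    def test_static_count_within_binomial_bounds(self):
        cfg = SimulationConfig(n_frames=2)
        _, truth = generate_livecell_movie(cfg, n_cells=200, static_fraction=0.3,
                                           seed=8)
        n_static = sum(c.has_static_spot for c in truth.cells)
        sd = math.sqrt(200 * 0.3 * 0.7)
        assert abs(n_static - 60) <= 3 * sd

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError, match="n_cells"):
            generate_livecell_movie(SimulationConfig(), n_cells=0,
                                    static_fraction=0.5, seed=0)


class TestExpectedObservedComposition:
    def test_no_dark_dots_fully_observed(self):
        dist = expected_observed_composition({"A", "B", "C"}, 0.0)
        assert dist[frozenset("ABC")] == pytest.approx(1.0)

    def test_half_dark_pair_uniform_over_subsets(self):
        dist = expected_observed_composition({"A", "B"}, 0.5)
        for subset in (frozenset(), frozenset("A"), frozenset("B"),
                       frozenset("AB")):
            assert dist[subset] == pytest.approx(0.25)

    def test_triple_all_visible_probability(self):
        dist = expected_observed_composition({"A", "B", "C"}, 0.1)
        assert dist[frozenset("ABC")] == pytest.approx(0.729)

    @given(st.sets(st.sampled_from("ABC"), min_size=1),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_distribution_sums_to_one_and_matches_enumeration(self, comp, d):
        dist = expected_observed_composition(comp, d)
        assert len(dist) == 2 ** len(comp)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        # independent-Bernoulli oracle: brute-force product per subset
        for subset, p in dist.items():
            p_ref = 1.0
            for member in comp:
                p_ref *= (1 - d) if member in subset else d
            assert p == pytest.approx(p_ref, abs=1e-12)


class TestSurvivalCounts:
    def test_poisson_mean_at_zero_dose(self):
        recs = generate_survival_counts([0.0], [1.0], n0=1000, dilutions=(1.0,),
                                        seed=4, n_replicates=500)
        counts = [r.colony_count for r in recs]
        assert np.mean(counts) == pytest.approx(1000, rel=0.01)

    def test_poisson_mean_scales_with_fraction(self):
        recs = generate_survival_counts([5.0], [0.05], n0=1000, dilutions=(1.0,),
                                        seed=4, n_replicates=500)
        mean = np.mean([r.colony_count for r in recs])
        assert abs(mean - 50) <= 3 * math.sqrt(50 / 500)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="n0"):
            generate_survival_counts([0.0], [1.0], n0=0)
        with pytest.raises(ValueError, match="equal length"):
            generate_survival_counts([0.0, 5.0], [1.0], n0=10)
        with pytest.raises(ValueError, match="fractions"):
            generate_survival_counts([0.0], [0.0], n0=10)
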