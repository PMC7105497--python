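"""Surrogate generators: discrete chains, gap Langevin dynamics, loop embedding."""

import numpy as np
import pytest
from scipy.stats import norm

from _oracles import hand_count_transitions

from loopmsm.geometry import min_group_distance, rmsd
from loopmsm.synthetic import (
    LoopModelSpec,
    PotentialSpec,
    default_surrogate,
    embed_loop_frames,
    reference_slow_modes,
    reference_timescales,
    sample_discrete_chain,
    simulate_langevin_gap,
    simulate_langevin_gap_batch,
    well_of_gap,
)


class TestDiscreteChain:
    def test_identity_matrix_is_absorbing(self):
        d = sample_discrete_chain(np.eye(2), 100, seed=0, initial=0)
        assert np.all(d.labels == 0)

    def test_determinism(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        a = sample_discrete_chain(T, 5000, seed=42)
        b = sample_discrete_chain(T, 5000, seed=42)
        assert np.array_equal(a.labels, b.labels)

    def test_empirical_frequencies_match_generator(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        n = 10**6
        d = sample_discrete_chain(T, n, seed=1, initial=0)
        C = hand_count_transitions(d.labels, 1, 2)
        for i in range(2):
            row_n = C[i].sum()
            for j in range(2):
                p = T[i, j]
                se = np.sqrt(p * (1 - p) / row_n)
                assert abs(C[i, j] / row_n - p) < 3 * se

    def test_non_stochastic_matrix_names_offending_row(self):
        T = np.array([[0.9, 0.1], [0.3, 0.3]])
        with pytest.raises(ValueError, match="row 1"):
            sample_discrete_chain(T, 10, seed=0)


@pytest.fixture()
def single_well():
    return PotentialSpec(wells=((4.0, 2.0, 0.8),), kT=1.0)


class TestLangevin:
    def test_cold_start_at_minimum_stays_put(self):
        # vanishing temperature: gradient is exactly zero at the well center
        pot = PotentialSpec(wells=((4.0, 2.0, 0.8),), kT=1e-30)
        g = simulate_langevin_gap(pot, 1000, dt=0.01, friction=1.0, seed=0, x0=4.0)
        assert np.allclose(g, 4.0, atol=1e-9)

    def test_determinism_bitwise(self, single_well):
        a = simulate_langevin_gap(single_well, 500, 0.01, 1.0, seed=9, x0=4.0)
        b = simulate_langevin_gap(single_well, 500, 0.01, 1.0, seed=9, x0=4.0)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("n_frames,tol", [(400, 0.05), (2000, 0.02)])
    def test_harmonic_well_matches_boltzmann(self, single_well, n_frames, tol):
        """Gaussian-well stationary density is N(center, width); KS sup-norm
        against the closed form shrinks with run length."""
        gaps = simulate_langevin_gap_batch(
            single_well, n_frames * 10, 0.01, 1.0, seed=3,
            x0=np.full(50, 4.0), record_stride=10,
        ).ravel()
        gaps = gaps[5000:]  # discard equilibration
        xs = np.sort(gaps)
        ecdf = np.arange(1, xs.size + 1) / xs.size
        ks = np.max(np.abs(ecdf - norm.cdf(xs, loc=4.0, scale=0.8)))
        assert ks < tol

    def test_three_well_ergodicity(self):
        pot, _, _ = default_surrogate()
        gaps = simulate_langevin_gap_batch(
            pot, 10**5, 0.01, 1.0, seed=5, x0=np.full(10, 4.0), record_stride=10
        )
        occ = np.bincount(well_of_gap(pot, gaps).ravel(), minlength=3)
        assert np.all(occ > 0)

    def test_divergence_raises_with_dt_advice(self, single_well):
        steep = PotentialSpec(wells=((4.0, 2.0, 0.05),), kT=1.0)
        with pytest.raises(FloatingPointError, match="smaller dt"):
            simulate_langevin_gap(steep, 1000, dt=10.0, friction=1.0, seed=0, x0=4.5)


class TestEmbedding:
    def test_zero_jitter_min_distance_equals_gap(self):
        _, loops, _ = default_surrogate()
        spec = LoopModelSpec(loops.sel_template, loops.lel_template, jitter_sd=0.0)
        traj = embed_loop_frames(np.array([10.0]), spec, seed=0)
        d = min_group_distance(traj.frame(0), traj.groups, "SEL", "LEL")
        assert d == pytest.approx(10.0, abs=1e-12)

    def test_zero_jitter_constant_gap_gives_identical_frames(self):
        _, loops, _ = default_surrogate()
        spec = LoopModelSpec(loops.sel_template, loops.lel_template, jitter_sd=0.0)
        traj = embed_loop_frames(np.full(4, 7.0), spec, seed=0)
        for i in range(1, 4):
            assert rmsd(traj.frame(0), traj.frame(i), superpose=False) == 0.0

    def test_min_distance_affine_increasing_in_gap(self):
        _, loops, _ = default_surrogate()
        spec = LoopModelSpec(loops.sel_template, loops.lel_template, jitter_sd=0.0)
        gaps = np.linspace(2.0, 16.0, 8)
        traj = embed_loop_frames(gaps, spec, seed=0)
        d = [min_group_distance(traj.frame(i), traj.groups, "SEL", "LEL") for i in range(8)]
        diffs = np.diff(d) / np.diff(gaps)
        assert np.all(diffs > 0)
        assert np.allclose(diffs, diffs[0], atol=1e-9)  # affine

    def test_kernel_features_separate_two_gap_levels(self):
        """Frames at gaps 4 A apart are linearly separable in kernel-feature
        space (nearest-centroid check)."""
        from loopmsm.featurize import ReferenceSet, rmsd_kernel_features

        _, loops, _ = default_surrogate()
        spec = LoopModelSpec(loops.sel_template, loops.lel_template, jitter_sd=0.2)
        rng = np.random.default_rng(0)
        g = np.concatenate([np.full(30, 6.0), np.full(30, 10.0)])
        traj = embed_loop_frames(g, spec, seed=1)
        refs = ReferenceSet(
            structures=traj.coords[[0, 59]],
            source_frame_indices=np.array([[0, 0], [0, 59]]),
        )
        F = rmsd_kernel_features(traj, refs, sigma=0.5).values
        mu0, mu1 = F[:30].mean(axis=0), F[30:].mean(axis=0)
        d0 = np.linalg.norm(F - mu0, axis=1)
        d1 = np.linalg.norm(F - mu1, axis=1)
        pred = (d1 < d0).astype(int)
        truth = np.repeat([0, 1], 30)
        assert np.array_equal(pred, truth)

    def test_validation(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        good = np.column_stack([np.arange(4.0), np.array([0, 1, 0, 1.0]), np.zeros(4)])
        with pytest.raises(ValueError, match="degenerate"):
            LoopModelSpec(sel_template=line, lel_template=good)
        with pytest.raises(ValueError):
            LoopModelSpec(sel_template=good, lel_template=good, jitter_sd=-0.1)


class TestPotentialSpec:
    def test_well_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            PotentialSpec(wells=((5.0, 1.0, 0.5), (4.0, 1.0, 0.5)))
        with pytest.raises(ValueError, match="width"):
            PotentialSpec(wells=((5.0, 1.0, -0.5),))
        with pytest.raises(ValueError):
            PotentialSpec(wells=())

    def test_stationary_density_normalised(self, single_well):
        g = np.linspace(-2, 10, 4001)
        z = np.trapezoid(single_well.stationary_density(g), g)
        assert z == pytest.approx(1.0, abs=1e-6)


class TestDefaultSurrogate:
    def test_three_wells(self, surrogate):
        potential, _, _ = surrogate
        assert len(potential.wells) == 3

    def test_ground_truth_contract(self, surrogate):
        _, _, truth = surrogate
        ts = truth.timescales
        assert np.all(np.isfinite(ts)) and np.all(np.diff(ts) <= 0)
        assert np.allclose(truth.transition_matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_brute_force_relaxation_matches_ground_truth(self, surrogate):
        """Long ensemble simulation, projected onto the exact slow mode:
        the fitted autocorrelation decay agrees with the stored generator
        timescale within 20%."""
        potential, _, truth = surrogate
        grid, modes, _ = reference_slow_modes(potential)
        _, _, pi = reference_timescales(potential)
        cdf = np.cumsum(pi)
        cdf /= cdf[-1]
        fits = []
        n_frames = 4000
        for seed in range(1, 6):
            rng = np.random.default_rng(seed)
            x0 = np.interp(rng.random(100), cdf, grid)
            gaps = simulate_langevin_gap_batch(
                potential, n_frames * 10, 0.01, 1.0, seed, x0, record_stride=10
            )
            u = np.interp(gaps, grid, modes[0])
            u -= u.mean()
            f = np.fft.rfft(u, n=2 * n_frames, axis=0)
            acf = np.fft.irfft(f * np.conj(f), axis=0)[:n_frames].mean(axis=1)
            acf /= np.arange(n_frames, 0, -1)
            acf /= acf[0]
            lags = np.arange(n_frames) * 0.1
            win = (lags >= 20) & (lags <= 150) & (acf > 0)
            slope, _ = np.polyfit(lags[win], np.log(acf[win]), 1)
            fits.append(-1.0 / slope)
        assert np.mean(fits) == pytest.approx(truth.timescales[0], rel=0.20)
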