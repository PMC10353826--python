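"""Forward simulator: rescaling, transmission, conditioning, footprints."""

from dataclasses import replace

import numpy as np
import pytest

from selfingpop.diversity import WindowStat
from selfingpop.sweep_sim import (
    SimParams,
    desk_preset,
    footprint_preset,
    full_scale_params,
    pi_profile,
    rescale,
    run_forward,
    run_neutral,
    sweep_extent_windows,
    sweep_size_piecewise,
)


def tiny_params(**kw):
    defaults = dict(
        N=30,
        L=10_000,
        rec_map=[(1, 10_000, 1e-6)],
        mu=1e-6,
        sel_pos=5_000,
        s=0.5,
        t_intro=20,
        burn_in=50,
        pi_window=2_000,
        pi_stride=2_000,
    )
    defaults.update(kw)
    return SimParams(**defaults)


class TestRescale:
    def test_identity(self):
        p = full_scale_params()
        assert rescale(p, 1.0) == p

    def test_q10_definition(self):
        p = replace(full_scale_params(s=0.01), N=10_000)
        p2 = rescale(p, 10)
        assert p2.N == 1_000 and p2.s == pytest.approx(0.1)
        assert p2.mu == pytest.approx(p.mu * 10)

    @pytest.mark.parametrize("Q", [2.0, 5.0, 40.0])
    def test_theta_rho_invariant(self, Q):
        p = full_scale_params()
        p2 = rescale(p, Q)
        assert p2.N * p2.mu == pytest.approx(p.N * p.mu, rel=1e-3)
        for (a, b, r), (a2, b2, r2) in zip(p.rec_map, p2.rec_map):
            assert p2.N * r2 == pytest.approx(p.N * r, rel=1e-3)

    def test_too_large_q_rejected(self):
        with pytest.raises(ValueError, match="N/Q"):
            rescale(full_scale_params(), 10_000)


class TestRunForward:
    def test_deterministic_given_seed(self):
        p = tiny_params()
        pop1, traj1, _ = run_forward(p, seed=11)
        pop2, traj2, _ = run_forward(p, seed=11)
        np.testing.assert_array_equal(traj1, traj2)
        np.testing.assert_array_equal(pop1.positions, pop2.positions)
        np.testing.assert_array_equal(pop1.geno, pop2.geno)

    def test_conditioned_replicates_end_above_threshold(self):
        p = tiny_params(freq_threshold=0.7931)
        for seed in (1, 2, 3):
            _, traj, _ = run_forward(p, seed=seed)
            assert traj[-1] >= 0.7931

    def test_neutral_single_copy_martingale(self):
        # s = 0, no conditioning: E[final frequency] = 1/(2N)
        p = tiny_params(N=20, s=0.0, t_intro=8, burn_in=0, mu=0.0)
        finals = []
        for seed in range(800):
            _, traj, _ = run_forward(p, seed=seed, condition=False)
            finals.append(traj[-1])
        mean = np.mean(finals)
        se = np.std(finals) / np.sqrt(len(finals))
        assert abs(mean - 1 / (2 * p.N)) <= 3 * se + 1e-9

    def test_full_selfing_heterozygosity_halves(self):
        # sigma = 1, one individual: a heterozygous site stays heterozygous
        # in the selfed offspring with probability 1/2
        from selfingpop.sweep_sim import _Engine

        p = tiny_params(N=1, selfing=1.0, mu=0.0, s=0.0)
        stay = 0
        reps = 600
        for seed in range(reps):
            eng = _Engine(p, np.random.default_rng(seed))
            positions = np.array([1234.5])
            geno = np.array([[True], [False]])
            sel = np.zeros(2, dtype=bool)
            _, g2, _ = eng.step(positions, geno, sel, select=False)
            stay += g2[0, 0] != g2[1, 0]
        frac = stay / reps
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / reps)

    def test_zero_recombination_hitchhiking(self):
        # with r = 0 a fixed sweep carries its background marker to fixation
        from selfingpop.sweep_sim import _Engine

        p = tiny_params(N=50, rec_map=[(1, 10_000, 0.0)], mu=0.0, s=1.0)
        for trial in range(60):
            eng = _Engine(p, np.random.default_rng(trial))
            geno = np.zeros((100, 1), dtype=bool)
            sel = np.zeros(100, dtype=bool)
            sel[7] = True
            geno[7, 0] = True
            positions = np.array([2_000.0])
            f = 0.0
            for _ in range(300):
                positions, geno, sel = eng.step(positions, geno, sel, select=True)
                f = sel.mean()
                if f in (0.0, 1.0):
                    break
            if f == 1.0:
                assert geno[:, 0].all()
                return
        pytest.fail("no sweep fixed in 60 trials")

    def test_watterson_equilibrium(self):
        # segregating sites in a sample after a 10N neutral burn-in match
        # Watterson's expectation with the selfing-adjusted N_e
        p = tiny_params(N=100, L=50_000, mu=2e-6, selfing=0.95, burn_in=None, s=0.0)
        counts = []
        n_sample = 10
        a1 = sum(1.0 / i for i in range(1, n_sample))
        expected = 4 * p.n_effective * p.mu * p.L * a1
        for seed in range(4):
            pop = run_neutral(p, np.random.default_rng(seed))
            H = pop.sample_haplotypes(n_sample, np.random.default_rng(seed + 50))
            c = H.sum(axis=0)
            counts.append(int(((c > 0) & (c < n_sample)).sum()))
        assert np.mean(counts) == pytest.approx(expected, rel=0.4)


class TestPresets:
    def test_desk_preset_scales_coordinates(self):
        p = desk_preset(L=2_000_000)
        assert p.N == 500
        assert p.L == 2_000_000
        assert 0 < p.sel_pos < p.L
        assert p.freq_threshold == pytest.approx(0.7931)

    def test_full_scale_defaults(self):
        p = full_scale_params()
        assert p.L == 18_747_412
        assert p.sel_pos == 11_100_000
        assert p.selfing == 0.95 and p.h == 0.0

    def test_pi_profile_default_windows_full_scale(self):
        p = full_scale_params()
        assert p.pi_window == 200_000 and p.pi_stride == 25_000

    def test_footprint_preset_centred(self):
        p = footprint_preset()
        assert p.sel_pos == p.L // 2


def _flat_profile(value, L=100_000, window=5_000):
    out = []
    start = 1
    while start <= L:
        end = min(start + window - 1, L)
        out.append(WindowStat("sim", start, end, 0, window, value))
        start += window
    return out


def _trapezoid(L=200_000, window=5_000, left=70_000, right=130_000, ramp=20_000,
               base=4e-4, depth=3.5e-4, noise=0.0, rng=None):
    out = []
    start = 1
    while start <= L:
        end = min(start + window - 1, L)
        mid = (start + end) / 2
        if left <= mid <= right:
            v = base - depth
        elif left - ramp <= mid < left:
            v = base - depth * (mid - (left - ramp)) / ramp
        elif right < mid <= right + ramp:
            v = base - depth * ((right + ramp) - mid) / ramp
        else:
            v = base
        if noise and rng is not None:
            v += rng.normal(0, noise)
        out.append(WindowStat("sim", start, end, 0, window, float(v)))
        start += window
    return out


class TestSweepExtentWindows:
    def test_flat_profile_not_detected(self):
        ext = sweep_extent_windows(_flat_profile(1e-4), 50_000, (90_000, 100_000))
        assert not ext.detected and ext.size == 0

    def test_trapezoid_boundaries(self):
        prof = _trapezoid()
        ext = sweep_extent_windows(prof, 100_000, (180_000, 200_000))
        assert ext.detected
        # run of sub-baseline windows spans shoulders (50k..150k)
        assert ext.left == pytest.approx(50_001, abs=5_000)
        assert ext.right == pytest.approx(150_000, abs=5_000)

    def test_monomorphic_pop_profile_all_zero(self):
        from selfingpop.sweep_sim import HaplotypePopulation

        p = tiny_params()
        pop = HaplotypePopulation(
            params=p,
            positions=np.empty(0),
            geno=np.empty((2 * p.N, 0), dtype=bool),
            sel=np.zeros(2 * p.N, dtype=bool),
        )
        prof = pi_profile(pop, sample_size=5)
        assert all(w.value == 0 for w in prof)


class TestSweepSizePiecewise:
    def test_exact_trapezoid_recovery_within_one_window(self):
        prof = _trapezoid()
        ext = sweep_size_piecewise(prof, 100_000)
        assert ext.detected
        assert abs(ext.size - 100_000) <= 5_000

    def test_flat_profile_flagged_chromosome_length(self):
        prof = _flat_profile(2e-4, L=200_000)
        ext = sweep_size_piecewise(prof, 100_000)
        assert not ext.detected
        assert ext.size == pytest.approx(200_000, rel=0.01)

    def test_noisy_trapezoid_median_error_two_windows(self):
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(20):
            prof = _trapezoid(noise=0.1 * 3.5e-4, rng=rng)
            ext = sweep_size_piecewise(prof, 100_000)
            errs.append(abs(ext.size - 100_000))
        assert np.median(errs) <= 2 * 5_000


class TestGridExperiment:
    def test_defaults_match_study_grid(self):
        import inspect

        from selfingpop.sweep_sim import grid_experiment

        sig = inspect.signature(grid_experiment)
        assert sig.parameters["s_values"].default == (0.001, 0.01, 0.1)
        assert sig.parameters["t_values"].default == (
            16_030,
            13_030,
            10_030,
            7_030,
            4_030,
            1_030,
        )
        assert sig.parameters["replicates"].default == 12

    def test_tiny_grid_runs_and_tabulates(self):
        from selfingpop.sweep_sim import grid_experiment

        def preset(s, t_intro):
            return tiny_params(
                N=40, L=20_000, s=s * 100, t_intro=max(2, t_intro // 500),
                sel_pos=10_000, burn_in=80, mu=5e-6,
                pi_window=1_000, pi_stride=1_000, retry_cap=200,
            )

        df = grid_experiment(
            s_values=(0.01,), t_values=(2_000,), replicates=2, preset=preset,
            seed=3, sample_size=8,
        )
        assert len(df) == 2
        assert {"s", "t_intro", "final_freq", "extent_windows"} <= set(df.columns)
        assert (df["final_freq"].dropna() >= 0.7931).all()
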