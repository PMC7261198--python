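"""Bias deposition, temperature ladders, replica exchange, umbrella windows."""

import math

import numpy as np
import pytest

from h1ntd.constants import KB
from h1ntd.sampling import (
    GaussianKernel,
    MetaBias,
    MetadParams,
    ReplicaState,
    UmbrellaWindow,
    WTEParams,
    exchange_probability,
    run_metad,
    run_tremd,
    run_umbrella,
    run_wte_stage,
    temperature_ladder,
)
from h1ntd.toys import DoubleWell1D, HarmonicND


class TestDeposition:
    def test_first_kernel_peaks_at_its_height(self):
        bias = MetaBias(("x",))
        bias.deposit([0.3], base_height=1.5, temperature=300.0, time=10, sigma=[0.1])
        assert bias.evaluate([0.3]) == pytest.approx(1.5)

    def test_plain_deposition_sums_heights(self):
        bias = MetaBias(("x",), bias_factor=math.inf)
        for t in (10, 20):
            bias.deposit([0.0], 1.0, 300.0, t, [0.1])
        assert bias.evaluate([0.0]) == pytest.approx(2.0)

    def test_well_tempered_decay_closed_form(self):
        gamma, w, t_kelvin = 50.0, 1.0, 300.0
        bias = MetaBias(("x",), bias_factor=gamma)
        bias.deposit([0.0], w, t_kelvin, 10, [0.1])
        k2 = bias.deposit([0.0], w, t_kelvin, 20, [0.1])
        expected = w * math.exp(-w / (KB * (gamma - 1) * t_kelvin))
        assert k2.height == pytest.approx(expected)
        assert k2.height < w

    def test_gaussian_shape_and_time_masking(self):
        bias = MetaBias(("x",))
        bias.deposit([1.0], 2.0, 300.0, 100, [0.25])
        assert bias.evaluate([1.25]) == pytest.approx(2.0 * math.exp(-0.5))
        assert bias.evaluate([1.0], t=50) == 0.0

    def test_dimension_mismatch_rejected(self):
        bias = MetaBias(("a", "b"))
        with pytest.raises(ValueError, match="dimension"):
            bias.evaluate([1.0])

    def test_grid_evaluation_matches_pointwise(self, rng):
        bias = MetaBias(("x",), bias_factor=8.0)
        for t in range(1, 40):
            bias.deposit([float(rng.normal())], 0.7, 300.0, t, [0.3])
        grid = np.linspace(-3, 3, 101)
        pointwise = np.array([bias.evaluate([x]) for x in grid])
        np.testing.assert_allclose(bias.evaluate_grid(grid), pointwise, atol=1e-12)

    def test_2d_kernels_are_products(self):
        bias = MetaBias(("a", "b"))
        bias.deposit([0.0, 0.0], 1.0, 300.0, 1, [1.0, 2.0])
        v = bias.evaluate([1.0, 2.0])
        assert v == pytest.approx(math.exp(-0.5) * math.exp(-0.5))


class TestTemperatureLadder:
    def test_endpoints_and_geometric_spacing(self):
        ladder = temperature_ladder(298.0, 400.0, 8)
        assert ladder[0] == pytest.approx(298.0)
        assert ladder[7] == pytest.approx(400.0)
        assert ladder[1] == pytest.approx(298.0 * (400.0 / 298.0) ** (1 / 7))
        ratios = np.diff(np.log(ladder.temperatures))
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    def test_two_replica_ladder(self):
        assert temperature_ladder(300.0, 450.0, 2).temperatures == (300.0, 450.0)

    def test_degenerate_ladders_rejected(self):
        with pytest.raises(ValueError):
            temperature_ladder(300.0, 450.0, 1)
        with pytest.raises(ValueError):
            temperature_ladder(450.0, 300.0, 4)


class TestExchangeProbability:
    def _replica(self, rid, t_kelvin, u):
        return ReplicaState(rid, t_kelvin, None, u)

    def test_zero_bias_reduces_to_tremd_metropolis(self):
        a = self._replica(0, 300.0, -50.0)
        b = self._replica(1, 350.0, -20.0)
        expected = min(1.0, math.exp((a.beta - b.beta) * (-50.0 - -20.0)))
        assert exchange_probability(a, b) == pytest.approx(expected)

    def test_identical_replicas_always_swap(self):
        a = self._replica(0, 300.0, -30.0)
        b = self._replica(1, 300.0, -30.0)
        assert exchange_probability(a, b) == 1.0

    def test_symmetric_bias_terms_cancel(self):
        a = self._replica(0, 320.0, -10.0)
        b = self._replica(1, 320.0, -10.0)
        v = lambda r: 3.7  # noqa: E731 - constant bias everywhere
        assert exchange_probability(a, b, v, v) == 1.0

    def test_detailed_balance_of_swap_factors(self):
        a = self._replica(0, 300.0, -42.0)
        b = self._replica(1, 360.0, -17.0)
        p_fwd = exchange_probability(a, b)
        arg = (a.beta - b.beta) * (a.potential_energy - b.potential_energy)
        assert p_fwd == pytest.approx(min(1.0, math.exp(arg)))
        # reverse move: the same swap applied to the already-swapped pair;
        # detailed balance requires p_fwd = exp(arg) * p_reverse
        a_sw = self._replica(0, 300.0, b.potential_energy)
        b_sw = self._replica(1, 360.0, a.potential_energy)
        p_rev = exchange_probability(a_sw, b_sw)
        assert p_fwd == pytest.approx(math.exp(arg) * p_rev)


class TestTremd:
    def test_equal_temperatures_always_accept(self):
        system = HarmonicND(n_dim=4)
        res = run_tremd(system, [300.0, 300.0, 300.0], 20, 10, seed=1)
        assert res.exchange.mean_rate == 1.0

    def test_acceptance_decreases_with_ladder_width(self):
        system = HarmonicND(n_dim=64, step=0.08)
        narrow = run_tremd(system, temperature_ladder(300.0, 330.0, 3), 60, 50, seed=2)
        wide = run_tremd(system, temperature_ladder(300.0, 500.0, 3), 60, 50, seed=2)
        assert wide.exchange.mean_rate < narrow.exchange.mean_rate

    def test_seeded_rerun_reproduces_exchange_log(self):
        system = HarmonicND(n_dim=8)
        runs = [run_tremd(system, [300.0, 340.0, 380.0], 30, 20, seed=9)
                for _ in range(2)]
        assert runs[0].exchange.log == runs[1].exchange.log

    def test_swaps_conserve_pooled_energies(self):
        """Exchange relabels temperatures; the configuration pool is unchanged."""
        system = HarmonicND(n_dim=16)
        res = run_tremd(system, [300.0, 400.0], 40, 25, seed=3)
        # energies recorded per temperature slot across a swap-heavy run stay
        # finite and the replica states remain distinct objects
        pooled = sorted(r.potential_energy for r in res.replicas)
        assert all(np.isfinite(pooled))


class TestWte:
    def test_zero_height_stage_leaves_plain_dynamics(self):
        system = HarmonicND(n_dim=8)
        ladder = temperature_ladder(300.0, 360.0, 2)
        biases, series, _ = run_wte_stage(
            system, ladder, WTEParams(height=0.0, sigma=5.0, stride=50), 2000, seed=4)
        assert all(b.n_kernels == 0 for b in biases)

    def test_wte_broadens_energy_distribution(self):
        system = HarmonicND(n_dim=64, step=0.08)
        ladder = temperature_ladder(300.0, 400.0, 2)
        plain = run_tremd(system, ladder, 40, 50, seed=5)
        u_plain = plain.energies(0)[10:]
        biases, series, _ = run_wte_stage(
            system, ladder, WTEParams(height=3.0, sigma=20.0, stride=50,
                                      bias_factor=50.0), 15000, seed=5)
        u_wte = series[0][len(series[0]) // 3:]
        assert u_wte.var() > 2.0 * u_plain.var()


class TestUmbrella:
    def test_stiff_spring_concentrates_samples(self):
        dw = DoubleWell1D()
        (window,) = run_umbrella(dw, [0.5], force_constant=5e4, n_steps=4000,
                                 seed=6, record_stride=2)
        assert abs(window.series.mean() - 0.5) < 0.02
        assert window.series.std() < 0.01

    def test_flat_potential_window_means_track_centers(self):
        class Flat:
            cv_names = ("x",)

            def initial_state(self, rng):
                return 0.0

            def propose(self, s, rng):
                return float(s + rng.normal(0, 0.2))

            def energy(self, s):
                return 0.0

            def cvs(self, s):
                return np.array([s])

        centers = [0.0, 0.5, 1.0]
        windows = run_umbrella(Flat(), centers, 400.0, 4000, seed=7)
        for w in windows:
            assert abs(w.series.mean() - w.center) < 0.05

    def test_default_protocol_spans_twenty_windows(self):
        centers = list(np.round(np.arange(0.1, 2.1, 0.1), 3))
        assert len(centers) == 20
        assert centers[-1] - centers[0] == pytest.approx(1.9)

    def test_unsorted_centers_rejected(self):
        with pytest.raises(ValueError):
            run_umbrella(DoubleWell1D(), [1.0, 0.5], 100.0, 10, seed=0)

    def test_short_window_warns(self):
        with pytest.warns(UserWarning, match="retained"):
            run_umbrella(DoubleWell1D(), [0.0], 100.0, 100, seed=0)


class TestMetadRunner:
    def test_zero_height_equals_unbiased_sampling(self):
        dw = DoubleWell1D()
        run = run_metad(dw, MetadParams(height=0.0, sigma=(0.1,), stride=10),
                        500, seed=8)
        assert run.bias.n_kernels == 0
        assert np.all(run.bias_series == 0.0)

    def test_bias_history_reproducible_from_kernels(self):
        from h1ntd.reweighting import BiasHistory

        dw = DoubleWell1D()
        run = run_metad(dw, MetadParams(height=0.8, sigma=(0.15,), stride=20,
                                        bias_factor=10.0), 2000, seed=9)
        hist = BiasHistory.from_run(run)
        assert hist.validate(tol=1e-9) < 1e-9


class TestPtmetadWte:
    def test_two_stage_protocol_runs_and_freezes_wte(self):
        from h1ntd.sampling import run_ptmetad_wte
        from h1ntd.toys import SixResidueSystem

        system = SixResidueSystem().system(("n_h",))
        ladder = temperature_ladder(300.0, 450.0, 3)
        result = run_ptmetad_wte(
            system, ladder,
            WTEParams(height=0.5, sigma=2.0, stride=50, bias_factor=10.0),
            MetadParams(height=0.4, sigma=(0.6,), stride=100, bias_factor=8.0),
            production_cv_indices=(0,),
            n_wte_steps=2000, n_production_cycles=30, steps_per_cycle=50, seed=3)
        assert len(result.wte_biases) == 3
        assert all(b.n_kernels > 0 for b in result.wte_biases)
        n_wte_after = [b.n_kernels for b in result.wte_biases]
        assert all(b.n_kernels > 0 for b in result.production_biases)
        # frozen: production did not grow the WTE biases
        assert [b.n_kernels for b in result.wte_biases] == n_wte_after
        for bias in result.production_biases:
            times = bias.arrays()[3]
            assert np.all(np.diff(times) >= 0)
        assert result.production.exchange.attempts.sum() > 0

    def test_zero_height_wte_stage_reduces_to_plain_ptmetad(self):
        from h1ntd.sampling import run_ptmetad_wte
        from h1ntd.toys import SixResidueSystem

        system = SixResidueSystem().system(("n_h",))
        ladder = temperature_ladder(300.0, 400.0, 2)
        result = run_ptmetad_wte(
            system, ladder,
            WTEParams(height=0.0, sigma=2.0, stride=50),
            MetadParams(height=0.4, sigma=(0.6,), stride=100, bias_factor=8.0),
            production_cv_indices=(0,),
            n_wte_steps=500, n_production_cycles=10, steps_per_cycle=50, seed=4)
        assert all(b.n_kernels == 0 for b in result.wte_biases)
        # the effective bias is then the production CV bias alone
        rep = result.production.replicas[0]
        assert result.wte_biases[0].evaluate([rep.potential_energy]) == 0.0


class TestHelixDnaBinding:
    def test_umbrella_pmf_of_rigid_helix_shows_bound_well(self):
        """A charged pre-formed helix binds the DNA rod: interior PMF minimum."""
        from h1ntd.model import ModelParameters, make_dna_rod
        from h1ntd.toys import RigidHelixDNASystem
        from h1ntd.wham import wham, well_depth

        system = RigidHelixDNASystem("KAKKAKAKKA", ModelParameters(dna_on=True),
                                     make_dna_rod(20), start_distance=1.2)
        centers = list(np.round(np.arange(0.7, 2.01, 0.1), 3))
        windows = run_umbrella(system, centers, force_constant=400.0,
                               n_steps=6000, seed=6, record_stride=2)
        profile = wham(windows, bins=30)
        depth = well_depth(profile)
        assert depth.bound
        assert depth.depth_kj_per_mol > 1.0
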