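"""Helix-coil model: geometry, energies, DNA rod, MC sampler vs exact oracle."""

import math

import numpy as np
import pytest

from h1ntd.constants import KB
from h1ntd.cvs import s_alpha, kabsch_rmsd
from h1ntd.model import (
    REFERENCE_TEMPERATURE,
    ChargedParametersError,
    ModelParameters,
    build_coordinates,
    energy,
    enumerate_state_probabilities,
    expected_fractional_helicity,
    helix_coil_energy,
    ideal_helix_ca,
    make_dna_rod,
    mc_sample,
    screened_pair_energy,
    transfer_matrix_helicity,
)


class TestParameters:
    @pytest.mark.parametrize("field,value", [
        ("w_other", 0.0), ("v", -1.0), ("debye_length", 0.0), ("temperature", 0.0),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            ModelParameters(**{field: value})

    def test_neutralization_zeroes_basic_charges_only(self):
        p = ModelParameters(neutralized=True)
        assert p.charge("K") == 0.0 and p.charge("R") == 0.0
        assert p.charge("E") == -1.0
        assert ModelParameters().charge("K") == 1.0
        assert ModelParameters().charge("H") == 0.0  # His neutral


class TestGeometry:
    def test_all_helical_chain_matches_ideal_template_exactly(self, neutral_params):
        conf = build_coordinates("A" * 12, np.ones(12, bool), neutral_params,
                                 coil_dihedrals=np.zeros((12, 2)))
        assert kabsch_rmsd(conf.ca_coords, ideal_helix_ca(12)) < 1e-6

    def test_consecutive_calpha_distances_in_peptide_range(self, neutral_params, rng):
        states = rng.random(20) < 0.5
        conf = build_coordinates("A" * 20, states, neutral_params, rng=rng)
        d = np.linalg.norm(np.diff(conf.ca_coords, axis=0), axis=1)
        assert d.min() > 0.36 and d.max() < 0.40

    def test_coil_coordinates_reproducible_under_seed(self, neutral_params):
        confs = [
            build_coordinates("A" * 12, np.zeros(12, bool), neutral_params,
                              rng=np.random.default_rng(7))
            for _ in range(2)
        ]
        np.testing.assert_allclose(confs[0].ca_coords, confs[1].ca_coords)

    def test_all_helical_11mer_scores_six_windows(self, neutral_params):
        conf = build_coordinates("A" * 11, np.ones(11, bool), neutral_params,
                                 coil_dihedrals=np.zeros((11, 2)))
        assert s_alpha(conf) == pytest.approx(6.0, abs=1e-9)

    def test_empty_state_vector_rejected(self, neutral_params):
        with pytest.raises(ValueError):
            build_coordinates("", np.zeros(0, bool), neutral_params)


class TestEnergy:
    def test_all_coil_uncharged_energy_is_zero(self, neutral_params):
        conf = build_coordinates("A" * 8, np.zeros(8, bool), neutral_params,
                                 rng=np.random.default_rng(0))
        assert energy(conf, neutral_params) == 0.0

    def test_two_unit_charges_at_debye_length(self):
        p = ModelParameters()
        sites = np.array([[0.0, 0, 0], [p.debye_length, 0, 0]])
        e = screened_pair_energy(sites, np.array([1.0, 1.0]), p)
        assert e == pytest.approx(p.elec_prefactor * math.exp(-1.0) / p.debye_length)

    def test_neutralization_switches_off_repulsion(self, subregions):
        seq = subregions["H1.0"].residues
        states = np.ones(len(seq), bool)
        charged = ModelParameters()
        neutral = ModelParameters(neutralized=True)
        conf_c = build_coordinates(seq, states, charged, coil_dihedrals=np.zeros((len(seq), 2)))
        conf_n = build_coordinates(seq, states, neutral, coil_dihedrals=np.zeros((len(seq), 2)))
        energy(conf_c, charged)
        energy(conf_n, neutral)
        assert conf_c.energy_terms["electrostatic"] > 0
        assert conf_n.energy_terms["electrostatic"] == 0.0

    def test_hard_core_overlap_rejected(self):
        p = ModelParameters()
        sites = np.array([[0.0, 0, 0], [0.005, 0, 0]])
        assert screened_pair_energy(sites, np.array([1.0, 1.0]), p) == pytest.approx(1e6)

    def test_energy_extensive_and_reproducible(self, neutral_params, rng):
        states = rng.random(14) < 0.5
        conf = build_coordinates("AKAAKAAKAAKAAK", states, neutral_params, rng=rng)
        e1, e2 = energy(conf, neutral_params), energy(conf, neutral_params)
        assert e1 == e2
        # doubling a helix run doubles its propagation contribution
        p = neutral_params
        e_four = helix_coil_energy("AAAA", np.ones(4, bool), p)
        e_eight = helix_coil_energy("AAAAAAAA", np.ones(8, bool), p)
        kt = KB * REFERENCE_TEMPERATURE
        assert e_eight - e_four == pytest.approx(-4 * kt * math.log(p.w_other))


class TestDnaRod:
    def test_default_rod_20bp_with_11_central(self):
        rod = make_dna_rod(20)
        assert rod.n_bp == 20
        assert len(rod.central_bp_indices) == 11
        assert len(rod.phosphate_coords) == 40  # two strands

    def test_minimal_rod_all_central(self):
        rod = make_dna_rod(11)
        assert len(rod.central_bp_indices) == rod.n_bp

    def test_too_short_rod_rejected(self):
        with pytest.raises(ValueError):
            make_dna_rod(10)

    def test_rise_per_bp(self):
        rod = make_dna_rod(12)
        z = np.unique(np.round(rod.phosphate_coords[:, 2], 9))
        assert np.diff(z) == pytest.approx(0.34)


class TestTransferMatrixOracle:
    def test_refuses_charged_parameters(self):
        with pytest.raises(ChargedParametersError):
            transfer_matrix_helicity("KAK", ModelParameters())

    def test_single_residue_closed_form(self, neutral_params):
        # Z = 1 + v*w; p(h) = v*w / (1 + v*w)
        p = neutral_params
        vw = p.v * p.w_other
        assert transfer_matrix_helicity("A", p)[0] == pytest.approx(vw / (1 + vw))

    def test_vanishing_weights_give_zero_helicity(self):
        p = ModelParameters(w_other=1e-12, w_basic=1e-12, w_pro=1e-12,
                            w_gly=1e-12, neutralized=True)
        assert transfer_matrix_helicity("AAAAA", p).max() < 1e-10

    def test_interior_exceeds_terminal_helicity_in_homopolymer(self):
        p = ModelParameters(w_other=1.5, v=0.05, neutralized=True)
        h = transfer_matrix_helicity("A" * 20, p)
        assert h[10] > h[0] and h[10] > h[-1]

    @pytest.mark.parametrize("seq", ["AKAGKA", "PKRAKA", "AAKKPG"])
    def test_matches_brute_force_enumeration(self, seq, neutral_params):
        probs = enumerate_state_probabilities(seq, neutral_params)
        L = len(seq)
        p_enum = np.zeros(L)
        for code, pr in enumerate(probs):
            for i in range(L):
                if (code >> i) & 1:
                    p_enum[i] += pr
        np.testing.assert_allclose(
            transfer_matrix_helicity(seq, neutral_params), p_enum, atol=1e-12)

    def test_window_probability_matches_enumeration(self, neutral_params):
        seq = "AKAGKAK"
        probs = enumerate_state_probabilities(seq, neutral_params)
        from h1ntd.model import helix_window_probabilities

        expected = np.zeros(2)
        for code, pr in enumerate(probs):
            bits = [(code >> i) & 1 for i in range(len(seq))]
            for j in range(2):
                if all(bits[j:j + 6]):
                    expected[j] += pr
        np.testing.assert_allclose(
            helix_window_probabilities(seq, neutral_params), expected, atol=1e-12)


class TestMonteCarlo:
    def test_same_seed_gives_identical_trajectories(self, neutral_params):
        runs = [mc_sample("AKAAKA", neutral_params, 50, seed=3) for _ in range(2)]
        np.testing.assert_array_equal(runs[0].states_matrix, runs[1].states_matrix)
        np.testing.assert_allclose(runs[0].energies, runs[1].energies)

    def test_infinite_temperature_samples_states_uniformly(self):
        p = ModelParameters(temperature=1e9, neutralized=True)
        traj = mc_sample("A" * 10, p, 3000, seed=5, record_stride=2)
        frac = traj.states_matrix[200:].mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_per_residue_helicity_matches_transfer_matrix(self, neutral_params):
        # unit-weight case plus the shipped defaults, both against the oracle
        for p in (ModelParameters(w_other=1.0, w_basic=1.0, w_pro=1.0,
                                  w_gly=1.0, v=1.0, neutralized=True),
                  neutral_params):
            seq = "AKAGKAAK"
            traj = mc_sample(seq, p, 6000, seed=11, record_stride=2)
            mc_h = traj.states_matrix[300:].mean(axis=0)
            exact = transfer_matrix_helicity(seq, p)
            n_eff = len(traj.states_matrix) - 300
            sigma = np.sqrt(exact * (1 - exact) / n_eff) * 3  # ~3x autocorrelation
            assert np.all(np.abs(mc_h - exact) < 3 * sigma + 0.02)

    def test_detailed_balance_on_enumerable_system(self, neutral_params):
        """Flip-move acceptance satisfies P(a->b) pi(a) = P(b->a) pi(b)."""
        seq = "AKAGKA"
        beta = 1.0 / (KB * neutral_params.temperature)
        rng = np.random.default_rng(0)
        for _ in range(50):
            states = rng.random(6) < 0.5
            i = rng.integers(6)
            flipped = states.copy()
            flipped[i] = ~flipped[i]
            e_a = helix_coil_energy(seq, states, neutral_params)
            e_b = helix_coil_energy(seq, flipped, neutral_params)
            acc_ab = min(1.0, math.exp(-beta * (e_b - e_a)))
            acc_ba = min(1.0, math.exp(-beta * (e_a - e_b)))
            assert acc_ab * math.exp(-beta * e_a) == pytest.approx(
                acc_ba * math.exp(-beta * e_b), rel=1e-12)

    def test_neutralization_increases_helicity(self, subregions):
        """Removing Lys/Arg repulsion can only stabilize the helical state."""
        seq = subregions["H1.0"].residues
        f = {}
        for label, neut in (("neutral", True), ("charged", False)):
            traj = mc_sample(seq, ModelParameters(neutralized=neut), 1500,
                             seed=21, record_stride=5)
            frames = traj.frames[len(traj.frames) // 5:]
            f[label] = np.mean([s_alpha(fr.ca_coords) for fr in frames])
        assert f["neutral"] > f["charged"]
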