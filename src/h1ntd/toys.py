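"""Analytic toy systems and peptide adapters for the samplers.

The toys provide exact references: a 1D double well whose free-energy
profile is known in closed form (the metadynamics recovery oracle), harmonic
wells for replica-exchange and WTE checks, and a six-residue helix-coil
peptide small enough to enumerate all 64 micro-states exactly (the
reweighting oracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from . import model as _model
from .model import (
    ModelParameters,
    DNARod,
    build_coordinates,
    draw_coil_dihedrals,
    helix_coil_energy,
    ideal_helix_ca,
)
from . import cvs as _cvs


class DoubleWell1D:
    """U(x) = barrier ((x/x0)^2 - 1)^2: two minima at +-x0, barrier at 0."""

    cv_names = ("x",)

    def __init__(self, barrier: float = 8.0, x0: float = 1.0, step: float = 0.25):
        self.barrier = barrier
        self.x0 = x0
        self.step = step

    def potential(self, x):
        x = np.asarray(x, dtype=float)
        return self.barrier * ((x / self.x0) ** 2 - 1.0) ** 2

    def initial_state(self, rng):
        return float(-self.x0)

    def propose(self, state, rng):
        return float(state + rng.normal(0.0, self.step))

    def energy(self, state):
        return float(self.potential(state))

    def cvs(self, state):
        return np.array([state])

    def free_energy_reference(self, grid: np.ndarray) -> np.ndarray:
        """Exact F(x) = U(x) - min U on the grid (1D: no entropic term)."""
        f = self.potential(grid)
        return f - f.min()


class HarmonicND:
    """Independent harmonic wells U = 0.5 k sum x_i^2 (first coordinate is the CV)."""

    cv_names = ("x0",)

    def __init__(self, n_dim: int = 16, k: float = 100.0, step: float = 0.15,
                 init_temperature: float = 300.0):
        self.n_dim = n_dim
        self.k = k
        self.step = step
        self.init_temperature = init_temperature

    def initial_state(self, rng):
        # draw from the 300 K equilibrium so runs start thermalized
        sd = math.sqrt(KB * self.init_temperature / self.k)
        return rng.normal(0.0, sd, size=self.n_dim)

    def propose(self, state, rng):
        out = state.copy()
        i = int(rng.integers(self.n_dim))
        out[i] += rng.normal(0.0, self.step)
        return out

    def energy(self, state):
        return float(0.5 * self.k * np.dot(state, state))

    def cvs(self, state):
        return np.array([state[0]])


class PeptideSystem:
    """MC-system adapter around the helix-coil peptide model.

    State is a ``(helix_flags, coil_dihedrals)`` pair; proposals mirror the
    move set of :func:`h1ntd.model.mc_sample` (single-residue flips and coil
    dihedral redraws).  Available CVs: ``n_h`` (helical residue count,
    cheap), ``frac_windows`` (fraction of all-helical six-residue windows),
    ``s_alpha`` and ``s_rg`` (geometric, via coordinate realization).
    """

    def __init__(
        self,
        sequence: str,
        params: ModelParameters,
        cv_names: tuple[str, ...] = ("n_h",),
        rod: DNARod | None = None,
    ):
        self.sequence = sequence
        self.params = params
        self.cv_names = cv_names
        self.rod = rod
        if params.dna_on and rod is None:
            raise ValueError("dna_on requires a rod")
        charges = params.charges_for(sequence)
        self._charged_idx = [int(i) for i in np.nonzero(charges != 0.0)[0]]
        self._qvals = [float(charges[i]) for i in self._charged_idx]
        self._coords_needed = (
            bool(self._charged_idx)
            or params.dna_on
            or any(n in ("s_alpha", "s_rg") for n in cv_names)
        )
        self._phos = ([tuple(p) for p in rod.phosphate_coords] if params.dna_on else None)
        self._template = ideal_helix_ca(_cvs.S_ALPHA_WINDOW)

    def initial_state(self, rng):
        L = len(self.sequence)
        return (np.zeros(L, dtype=bool), draw_coil_dihedrals(L, rng))

    def propose(self, state, rng):
        states, dih = state
        states, dih = states.copy(), dih.copy()
        i = int(rng.integers(len(states)))
        if rng.random() < 0.5:
            states[i] = ~states[i]
        else:
            dih[i] = draw_coil_dihedrals(1, rng)[0]
        return (states, dih)

    def _conformation(self, state):
        states, dih = state
        return build_coordinates(self.sequence, states, self.params,
                                 coil_dihedrals=dih)

    def energy(self, state):
        states, dih = state
        e = helix_coil_energy(self.sequence, states, self.params)
        if self._charged_idx or self.params.dna_on:
            eff = _model._effective_dihedrals(states, dih)
            _, ca, _ = _model._build_backbone_scalar(list(eff[:, 0]), list(eff[:, 1]))
            sites = _model._charge_sites_scalar(ca, self._charged_idx)
            e += _model._pair_energy_scalar(sites, self._qvals,
                                            self.params.elec_prefactor,
                                            self.params.debye_length)
            if self._phos:
                e += _model._dna_energy_scalar(sites, self._qvals, self._phos,
                                               self.params.dna_strength,
                                               self.params.debye_length)
        return float(e)

    def cvs(self, state):
        states, _ = state
        out = []
        conf = self._conformation(state) if any(
            n in ("s_alpha", "s_rg") for n in self.cv_names) else None
        for name in self.cv_names:
            if name == "n_h":
                out.append(float(states.sum()))
            elif name == "frac_windows":
                L = len(states)
                wins = [states[j:j + 6].all() for j in range(L - 5)]
                out.append(float(np.mean(wins)))
            elif name == "s_alpha":
                out.append(_cvs.s_alpha(conf, self._template))
            elif name == "s_rg":
                out.append(_cvs.s_rg(conf))
            else:
                raise ValueError(f"unknown CV {name!r}")
        return np.array(out)


class RigidHelixDNASystem:
    """A pre-formed helical peptide rigid-body-translating near a DNA rod.

    The peptide conformation is frozen (all-helical); the state is its
    in-plane displacement from the rod axis.  Energy is the screened
    charge-phosphate attraction plus a soft cylindrical excluded-volume wall
    at the duplex radius (without it the discrete phosphate sites let the
    helix thread into the rod and the profile falls monotonically to
    contact); the CV is the radial binding distance.  Supports umbrella
    sampling of the binding profile, which exhibits an interior bound-state
    minimum at surface contact.
    """

    cv_names = ("radial_distance",)
    #: cylinder radius (nm) of the r^-12 excluded-volume wall (B-DNA duplex)
    cylinder_sigma = 1.0
    cylinder_epsilon = 1.0  # kJ/mol per Calpha at the wall radius

    def __init__(
        self,
        sequence: str,
        params: ModelParameters,
        rod: DNARod,
        start_distance: float = 2.0,
        step: float = 0.08,
    ):
        if not params.dna_on:
            raise ValueError("RigidHelixDNASystem requires dna_on parameters")
        self.sequence = sequence
        self.params = params
        self.rod = rod
        self.step = step
        self.start_distance = start_distance
        L = len(sequence)
        conf = build_coordinates(sequence, np.ones(L, dtype=bool), params,
                                 coil_dihedrals=np.zeros((L, 2)))
        # orient the helix axis along z (parallel to the rod) and centre it
        ca = conf.ca_coords - conf.ca_coords.mean(axis=0)
        u, s, vt = np.linalg.svd(ca)
        rot = _rotation_onto_z(vt[0])
        self._ca0 = ca @ rot.T
        self._charges = params.charges_for(sequence)

    def initial_state(self, rng):
        return np.array([self.start_distance, 0.0])

    def propose(self, state, rng):
        return state + rng.normal(0.0, self.step, size=2)

    def _sites(self, state):
        shift = np.array([state[0], state[1], 0.0])
        sites, values, _ = _model._charge_sites(self._ca0 + shift, self._charges)
        return sites, values

    def energy(self, state):
        sites, values = self._sites(state)
        e = _model.screened_pair_energy(sites, values, self.params)
        diff = sites[:, None, :] - self.rod.phosphate_coords[None, :, :]
        r = np.sqrt((diff * diff).sum(axis=-1))
        if np.any(r < _model.HARD_CORE_DISTANCE):
            return _model.HARD_CORE_ENERGY
        e += float((values[:, None] * (-1.0) * self.params.dna_strength
                    * np.exp(-r / self.params.debye_length) / r).sum())
        ca = self._ca0 + np.array([state[0], state[1], 0.0])
        r_axis = np.hypot(ca[:, 0], ca[:, 1])
        r_axis = np.maximum(r_axis, 0.05)
        e += float(self.cylinder_epsilon
                   * ((self.cylinder_sigma / r_axis) ** 12).sum())
        return e

    def cvs(self, state):
        return np.array([float(np.hypot(state[0], state[1]))])


def _rotation_onto_z(axis: np.ndarray) -> np.ndarray:
    """Proper rotation matrix sending ``axis`` to the +z direction."""
    a = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    c = float(np.dot(a, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


# ---------------------------------------------------------------------------
# enumerable six-residue fixture

SIX_RESIDUE_SEQUENCE = "AKAGKA"


@dataclass(frozen=True)
class SixResidueSystem:
    """The enumerable six-residue helix-coil test system.

    Charge-free (neutralized) by construction so the 2^6 = 64 state
    probabilities are exactly the Boltzmann weights of the helix-coil
    Hamiltonian.
    """

    sequence: str = SIX_RESIDUE_SEQUENCE
    params: ModelParameters = field(
        default_factory=lambda: ModelParameters(neutralized=True))

    def system(self, cv_names: tuple[str, ...] = ("n_h",)) -> PeptideSystem:
        return PeptideSystem(self.sequence, self.params, cv_names)

    def exact_state_probabilities(self) -> np.ndarray:
        return _model.enumerate_state_probabilities(self.sequence, self.params)

    def exact_nh_probabilities(self) -> np.ndarray:
        """Exact P(n_h = k), k = 0..6."""
        probs = self.exact_state_probabilities()
        out = np.zeros(len(self.sequence) + 1)
        for code, p in enumerate(probs):
            out[bin(code).count("1")] += p
        return out
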