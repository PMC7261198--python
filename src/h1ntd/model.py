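"""Coarse-grained helix-coil peptide model with screened electrostatics.

This is the package's synthetic-data generator and desk-scale simulator.  A
peptide is a chain of residues, each in a helix (``h``) or coil (``c``)
micro-state.  The Hamiltonian has three parts:

1. *Helix-coil term* (Zimm-Bragg-type nearest-neighbour cooperativity):
   ``E_hc = -k_B T_ref * (sum_{i in h} ln w_i + n_runs * ln v)`` where
   ``w_i`` is a per-residue propagation weight keyed on residue class
   (Pro, Gly, basic Lys/Arg, other), ``v`` < 1 is the nucleation weight paid
   once per contiguous helical run, and ``T_ref`` = 300 K is a fixed
   reference so that the Hamiltonian is temperature-independent (sampling at
   temperature T then tempers it by the usual Boltzmann factor).
2. *Screened electrostatics*: Debye-Hueckel pair repulsion between sidechain
   charge pseudo-atoms, ``q_i q_j A exp(-r/lambda_D)/r``; the ``neutralized``
   flag zeroes Lys/Arg charges (the model analogue of charge neutralization).
3. *Optional DNA field*: attraction of positive charges to the phosphate
   sites of a rigid 20-bp B-DNA rod.

Coordinates are realized from the micro-states: helical residues take ideal
alpha dihedrals (phi = -57, psi = -47), coil residues carry dihedrals drawn
uniformly from a broad extended basin (phi in [-150, -60], psi in
[60, 180]); backbone atoms are placed by standard internal-coordinate (NeRF)
construction and the Calpha trace is extracted.

An exact transfer-matrix solver provides per-residue helix probabilities and
six-residue-window (helicity CV) expectations for the charge-free part of
the Hamiltonian, serving as the oracle for the Monte-Carlo sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB, COULOMB_K, DEBYE_LENGTH_150MM, WATER_EPS_R

# ---------------------------------------------------------------------------
# parameters

#: Reference temperature (K) at which ln-weight energies are defined.
REFERENCE_TEMPERATURE = 300.0

HELIX_PHI = -57.0
HELIX_PSI = -47.0
#: Coil dihedral basin (degrees): broad extended/PPII-like region.
COIL_PHI_RANGE = (-150.0, -60.0)
COIL_PSI_RANGE = (60.0, 180.0)

# backbone internal coordinates (nm / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 0.1458, 0.1525, 0.1329
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.0, 116.2, 121.7
_OMEGA = 180.0

#: Distance of the sidechain charge pseudo-atom from Calpha (nm).
CHARGE_SITE_OFFSET = 0.35

#: Hard-core distance (nm) and rejection energy (kJ/mol).
HARD_CORE_DISTANCE = 0.01
HARD_CORE_ENERGY = 1.0e6


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the coarse-grained helix-coil Hamiltonian.

    Propagation weights are dimensionless Zimm-Bragg ``w`` values per
    residue class; ``v`` is the nucleation weight.  The defaults were set by
    the bundled calibration script (``scripts/calibrate_model.py``) so that
    the charge-neutralized helicity of the three bundled NTD basic
    subregions orders H1.0 > H1.2 > H1.1, the qualitative behaviour the
    model is meant to emulate; see docs/methods.md.
    """

    w_other: float = 0.5
    w_basic: float = 3.5
    w_pro: float = 0.05
    w_gly: float = 0.10
    v: float = 0.05
    debye_length: float = DEBYE_LENGTH_150MM
    elec_prefactor: float = COULOMB_K / WATER_EPS_R
    dna_strength: float = COULOMB_K / WATER_EPS_R
    dna_on: bool = False
    temperature: float = 300.0
    neutralized: bool = False

    def __post_init__(self) -> None:
        for name in ("w_other", "w_basic", "w_pro", "w_gly", "v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.debye_length <= 0:
            raise ValueError("debye_length must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    def propagation_weight(self, aa: str) -> float:
        if aa == "P":
            return self.w_pro
        if aa == "G":
            return self.w_gly
        if aa in ("K", "R"):
            return self.w_basic
        return self.w_other

    def charge(self, aa: str) -> float:
        if aa in ("K", "R"):
            return 0.0 if self.neutralized else 1.0
        if aa in ("D", "E"):
            return -1.0
        return 0.0

    def weights_for(self, sequence: str) -> np.ndarray:
        return np.array([self.propagation_weight(aa) for aa in sequence])

    def charges_for(self, sequence: str) -> np.ndarray:
        return np.array([self.charge(aa) for aa in sequence])

    @property
    def has_charges_disabled(self) -> bool:
        """True when no electrostatic term can contribute (oracle regime)."""
        return self.neutralized and not self.dna_on


# ---------------------------------------------------------------------------
# geometry

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d from a-b-c with given bond length, angle and torsion.

    Scalar-tuple implementation: this sits in the Monte-Carlo inner loop, so
    per-call numpy overhead matters more than vectorization.
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    dx = -bond * math.cos(ang)
    sin_ang = math.sin(ang)
    dy = bond * sin_ang * math.cos(tor)
    dz = bond * sin_ang * math.sin(tor)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx * inv, ny * inv, nz * inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    return (
        c[0] + bcx * dx + mx * dy + nx * dz,
        c[1] + bcy * dx + my * dy + ny * dz,
        c[2] + bcz * dx + mz * dy + nz * dz,
    )


def _build_backbone_scalar(phi, psi):
    """N, CA, C positions as lists of tuples; phi[0]/psi[-1] unused."""
    L = len(phi)
    N = [(0.0, 0.0, 0.0)]
    CA = [(_B_N_CA, 0.0, 0.0)]
    ang = math.radians(_ANG_N_CA_C)
    C = [(_B_N_CA - _B_CA_C * math.cos(ang), _B_CA_C * math.sin(ang), 0.0)]
    for i in range(1, L):
        n_i = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _ANG_CA_C_N, psi[i - 1])
        ca_i = _place_atom(CA[i - 1], C[i - 1], n_i, _B_N_CA, _ANG_C_N_CA, _OMEGA)
        c_i = _place_atom(C[i - 1], n_i, ca_i, _B_CA_C, _ANG_N_CA_C, phi[i])
        N.append(n_i)
        CA.append(ca_i)
        C.append(c_i)
    return N, CA, C


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """N, CA, C coordinates (nm) from per-residue phi/psi (degrees).

    phi[0] and psi[-1] are ignored (no preceding C / following N).
    """
    N, CA, C = _build_backbone_scalar(list(map(float, phi)), list(map(float, psi)))
    return np.array(N), np.array(CA), np.array(C)


def ideal_helix_ca(n_residues: int) -> np.ndarray:
    """Calpha trace of an ideal alpha helix with n_residues residues."""
    phi = np.full(n_residues, HELIX_PHI)
    psi = np.full(n_residues, HELIX_PSI)
    return build_backbone(phi, psi)[1]


def draw_coil_dihedrals(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform (phi, psi) draws from the documented coil basin, shape (n, 2)."""
    phi = rng.uniform(*COIL_PHI_RANGE, size=n)
    psi = rng.uniform(*COIL_PSI_RANGE, size=n)
    return np.column_stack([phi, psi])


def helix_runs(states: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive helical residues as (start, stop) slices."""
    runs = []
    i, L = 0, len(states)
    while i < L:
        if states[i]:
            j = i
            while j < L and states[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


@dataclass
class Conformation:
    """A single peptide configuration.

    ``states`` is the per-residue helix/coil boolean vector, ``dihedrals``
    the (phi, psi) pairs in degrees actually used to realize the chain
    (helical residues hold the ideal values), ``ca_coords`` the Calpha trace
    in nm, and ``charge_sites``/``charge_values`` the sidechain pseudo-atoms
    of charged residues.
    """

    sequence: str
    states: np.ndarray
    dihedrals: np.ndarray
    ca_coords: np.ndarray
    charge_sites: np.ndarray
    charge_values: np.ndarray
    charge_residues: np.ndarray
    energy_terms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ca_coords) != len(self.sequence):
            raise ValueError("coordinate count must equal residue count")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def total_energy(self) -> float:
        return sum(self.energy_terms.values()) if self.energy_terms else 0.0


def _effective_dihedrals(states: np.ndarray, coil_dihedrals: np.ndarray) -> np.ndarray:
    out = np.array(coil_dihedrals, dtype=float, copy=True)
    out[states, 0] = HELIX_PHI
    out[states, 1] = HELIX_PSI
    return out


def _charge_sites(ca: np.ndarray, charges: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.nonzero(charges != 0.0)[0]
    if len(idx) == 0:
        return np.zeros((0, 3)), np.zeros(0), idx
    L = len(ca)
    sites = np.empty((len(idx), 3))
    for k, i in enumerate(idx):
        if 0 < i < L - 1:
            ref = 0.5 * (ca[i - 1] + ca[i + 1])
        elif i == 0:
            ref = ca[1] if L > 1 else ca[0] + np.array([1.0, 0, 0])
        else:
            ref = ca[i - 1]
        u = ca[i] - ref
        norm = np.linalg.norm(u)
        if norm < 1e-9:  # collinear fallback
            u = np.array([0.0, 0.0, 1.0])
            norm = 1.0
        sites[k] = ca[i] + CHARGE_SITE_OFFSET * u / norm
    return sites, charges[idx], idx


def build_coordinates(
    sequence: str,
    states: np.ndarray,
    params: ModelParameters,
    coil_dihedrals: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Conformation:
    """Realize a helix/coil state vector as a 3D Calpha conformation.

    Helical residues take ideal alpha dihedrals (so that maximal runs of
    >= 4 helical residues reproduce the ideal helix exactly); coil residues
    use ``coil_dihedrals`` or fresh draws from the coil basin.
    """
    states = np.asarray(states, dtype=bool)
    if len(states) == 0 or len(states) != len(sequence):
        raise ValueError("state vector must be non-empty and match the sequence")
    if coil_dihedrals is None:
        if rng is None:
            rng = np.random.default_rng(0)
        coil_dihedrals = draw_coil_dihedrals(len(states), rng)
    dih = _effective_dihedrals(states, coil_dihedrals)
    _, ca, _ = build_backbone(dih[:, 0], dih[:, 1])
    charges = params.charges_for(sequence)
    sites, values, idx = _charge_sites(ca, charges)
    return Conformation(sequence, states, dih, ca, sites, values, idx)


# ---------------------------------------------------------------------------
# energies

def helix_coil_energy(sequence: str, states: np.ndarray, params: ModelParameters) -> float:
    """-kT_ref [sum_h ln w_i + (number of helical runs) ln v], kJ/mol."""
    states = np.asarray(states, dtype=bool)
    if not states.any():
        return 0.0
    w = params.weights_for(sequence)
    n_runs = len(helix_runs(states))
    log_weight = float(np.sum(np.log(w[states]))) + n_runs * math.log(params.v)
    return -KB * REFERENCE_TEMPERATURE * log_weight


def screened_pair_energy(
    sites: np.ndarray, values: np.ndarray, params: ModelParameters
) -> float:
    """Debye-Hueckel pair sum over charge pseudo-atoms, kJ/mol."""
    m = len(sites)
    if m < 2:
        return 0.0
    diff = sites[:, None, :] - sites[None, :, :]
    r = np.sqrt((diff * diff).sum(axis=-1))
    iu = np.triu_indices(m, k=1)
    r = r[iu]
    if np.any(r < HARD_CORE_DISTANCE):
        return HARD_CORE_ENERGY
    qq = (values[:, None] * values[None, :])[iu]
    return float(np.sum(qq * params.elec_prefactor * np.exp(-r / params.debye_length) / r))


def dna_field_energy(conf: Conformation, rod: "DNARod", params: ModelParameters) -> float:
    """Screened attraction between positive sites and rod phosphates, kJ/mol."""
    if len(conf.charge_sites) == 0:
        return 0.0
    diff = conf.charge_sites[:, None, :] - rod.phosphate_coords[None, :, :]
    r = np.sqrt((diff * diff).sum(axis=-1))
    if np.any(r < HARD_CORE_DISTANCE):
        return HARD_CORE_ENERGY
    contrib = conf.charge_values[:, None] * (-1.0) * params.dna_strength \
        * np.exp(-r / params.debye_length) / r
    return float(contrib.sum())


def energy(conf: Conformation, params: ModelParameters, rod: "DNARod | None" = None) -> float:
    """Total model energy of a conformation; also stores the term breakdown."""
    terms = {
        "helix_coil": helix_coil_energy(conf.sequence, conf.states, params),
        "electrostatic": screened_pair_energy(conf.charge_sites, conf.charge_values, params),
    }
    if params.dna_on:
        if rod is None:
            raise ValueError("dna_on requires a DNARod")
        terms["dna_field"] = dna_field_energy(conf, rod, params)
    conf.energy_terms = terms
    return sum(terms.values())


# ---------------------------------------------------------------------------
# DNA rod

BDNA_RISE = 0.34   # nm per bp
BDNA_TWIST = 36.0  # degrees per bp
BDNA_PHOSPHATE_RADIUS = 0.89  # nm
BDNA_STRAND_OFFSET = 154.0    # degrees between strand phosphates


@dataclass(frozen=True)
class DNARod:
    """Rigid straight B-DNA rod along z with one phosphate site per bp per strand."""

    n_bp: int
    phosphate_coords: np.ndarray      # (2*n_bp, 3) nm
    phosphate_bp_index: np.ndarray    # (2*n_bp,) bp index of each site
    central_bp_indices: np.ndarray    # indices of the central 11 bp
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def central_phosphate_coords(self) -> np.ndarray:
        mask = np.isin(self.phosphate_bp_index, self.central_bp_indices)
        return self.phosphate_coords[mask]

    @property
    def central_bp_coord(self) -> np.ndarray:
        """Axis point of the central base pair."""
        mid = self.central_bp_indices[len(self.central_bp_indices) // 2]
        z = (mid - (self.n_bp - 1) / 2.0) * BDNA_RISE
        return np.array([0.0, 0.0, z])


def make_dna_rod(n_bp: int = 20) -> DNARod:
    """Build a straight rod; the central 11 bp are flagged for contact CVs."""
    if n_bp < 11:
        raise ValueError("n_bp must be >= 11 (central 11-bp subset undefined)")
    z = (np.arange(n_bp) - (n_bp - 1) / 2.0) * BDNA_RISE
    coords, bp_idx = [], []
    for i in range(n_bp):
        for strand_offset in (0.0, BDNA_STRAND_OFFSET):
            ang = math.radians(BDNA_TWIST * i + strand_offset)
            coords.append([
                BDNA_PHOSPHATE_RADIUS * math.cos(ang),
                BDNA_PHOSPHATE_RADIUS * math.sin(ang),
                z[i],
            ])
            bp_idx.append(i)
    start = (n_bp - 11) // 2
    central = np.arange(start, start + 11)
    return DNARod(n_bp, np.array(coords), np.array(bp_idx), central)


# ---------------------------------------------------------------------------
# exact transfer-matrix oracle (charge terms off)

class ChargedParametersError(ValueError):
    """Transfer-matrix oracle requested with electrostatics active."""


def _check_oracle_valid(sequence: str, params: ModelParameters) -> None:
    charges = params.charges_for(sequence)
    if np.any(charges != 0.0) or params.dna_on:
        raise ChargedParametersError(
            "transfer-matrix oracle covers the nearest-neighbour helix-coil "
            "Hamiltonian only; disable charges (neutralized, no acidic "
            "residues, dna_on=False)"
        )


def _tempered_weights(sequence: str, params: ModelParameters) -> tuple[np.ndarray, float]:
    """Per-residue w and nucleation v, tempered to the sampling temperature."""
    x = REFERENCE_TEMPERATURE / params.temperature
    return params.weights_for(sequence) ** x, params.v ** x


def _transfer_vectors(a: np.ndarray, v: float) -> tuple[np.ndarray, np.ndarray]:
    """Forward/backward DP vectors over (coil, helix) states.

    Returns f (L, 2) prefix weights and b (L, 2) suffix weights such that
    Z = sum_s f[L-1, s] and p_i(h) = f[i, 1] * b[i, 1] / Z.
    """
    L = len(a)
    f = np.zeros((L, 2))
    f[0] = (1.0, v * a[0])
    for i in range(1, L):
        f[i, 0] = f[i - 1, 0] + f[i - 1, 1]
        f[i, 1] = f[i - 1, 0] * v * a[i] + f[i - 1, 1] * a[i]
    b = np.zeros((L, 2))
    b[L - 1] = (1.0, 1.0)
    for i in range(L - 2, -1, -1):
        b[i, 0] = b[i + 1, 0] + v * a[i + 1] * b[i + 1, 1]
        b[i, 1] = b[i + 1, 0] + a[i + 1] * b[i + 1, 1]
    return f, b


def transfer_matrix_helicity(sequence: str, params: ModelParameters) -> np.ndarray:
    """Exact equilibrium per-residue helix probability (charges off)."""
    _check_oracle_valid(sequence, params)
    a, v = _tempered_weights(sequence, params)
    f, b = _transfer_vectors(a, v)
    Z = f[-1].sum()
    return f[:, 1] * b[:, 1] / Z


def helix_window_probabilities(
    sequence: str, params: ModelParameters, window: int = 6
) -> np.ndarray:
    """Exact P(residues j..j+window-1 all helical) for every window (charges off)."""
    _check_oracle_valid(sequence, params)
    a, v = _tempered_weights(sequence, params)
    L = len(a)
    if L < window:
        return np.zeros(0)
    f, b = _transfer_vectors(a, v)
    Z = f[-1].sum()
    probs = np.empty(L - window + 1)
    for j in range(L - window + 1):
        if j == 0:
            amount = v * a[0]
        else:
            amount = (f[j - 1, 0] * v + f[j - 1, 1]) * a[j]
        for k in range(j + 1, j + window):
            amount *= a[k]
        probs[j] = amount * b[j + window - 1, 1] / Z
    return probs


def expected_fractional_helicity(
    sequence: str, params: ModelParameters, window: int = 6
) -> float:
    """Exact expectation of the per-window helicity fraction (charges off).

    This is the transfer-matrix analogue of the geometric helicity CV: a
    six-residue window contributes 1 when fully helical (its coordinates are
    then the ideal helix) and essentially 0 otherwise, so the mean
    fractional CV equals the mean fraction of all-helical windows.
    """
    probs = helix_window_probabilities(sequence, params, window)
    if len(probs) == 0:
        raise ValueError(f"sequence shorter than window ({window})")
    return float(probs.mean())


def enumerate_state_probabilities(sequence: str, params: ModelParameters) -> np.ndarray:
    """Brute-force Boltzmann probabilities over all 2^L state vectors.

    Independent oracle for small systems (L <= 16); index bit i of the state
    integer is residue i's helix flag.
    """
    _check_oracle_valid(sequence, params)
    L = len(sequence)
    if L > 16:
        raise ValueError("enumeration limited to L <= 16")
    beta = 1.0 / (KB * params.temperature)
    weights = np.empty(2 ** L)
    for code in range(2 ** L):
        states = np.array([(code >> i) & 1 for i in range(L)], dtype=bool)
        weights[code] = math.exp(-beta * helix_coil_energy(sequence, states, params))
    return weights / weights.sum()


# ---------------------------------------------------------------------------
# Monte Carlo sampler

@dataclass
class TrajectoryFrame:
    step: int
    states: np.ndarray
    energy: float
    energy_terms: dict
    ca_coords: np.ndarray | None = None


@dataclass
class Trajectory:
    """Ordered MC frames with full provenance (seed, parameters)."""

    sequence: str
    frames: list[TrajectoryFrame]
    rng_seed: int
    params: ModelParameters
    acceptance_rate: float = float("nan")

    def __post_init__(self) -> None:
        steps = [f.step for f in self.frames]
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValueError("frame step indices must be strictly increasing")

    @property
    def states_matrix(self) -> np.ndarray:
        return np.array([f.states for f in self.frames])

    @property
    def energies(self) -> np.ndarray:
        return np.array([f.energy for f in self.frames])


def _charge_sites_scalar(ca, charged_idx):
    """Sidechain pseudo-atom positions for the given residues (tuple math)."""
    L = len(ca)
    sites = []
    for i in charged_idx:
        if 0 < i < L - 1:
            rx = 0.5 * (ca[i - 1][0] + ca[i + 1][0])
            ry = 0.5 * (ca[i - 1][1] + ca[i + 1][1])
            rz = 0.5 * (ca[i - 1][2] + ca[i + 1][2])
        elif i == 0:
            rx, ry, rz = ca[1] if L > 1 else (ca[0][0] + 1.0, ca[0][1], ca[0][2])
        else:
            rx, ry, rz = ca[i - 1]
        ux, uy, uz = ca[i][0] - rx, ca[i][1] - ry, ca[i][2] - rz
        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
        if norm < 1e-9:
            ux, uy, uz, norm = 0.0, 0.0, 1.0, 1.0
        f = CHARGE_SITE_OFFSET / norm
        sites.append((ca[i][0] + f * ux, ca[i][1] + f * uy, ca[i][2] + f * uz))
    return sites


def _pair_energy_scalar(sites, qvals, prefactor, lam):
    total = 0.0
    m = len(sites)
    for a in range(m):
        xa, ya, za = sites[a]
        qa = qvals[a]
        for b in range(a + 1, m):
            dx, dy, dz = xa - sites[b][0], ya - sites[b][1], za - sites[b][2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r < HARD_CORE_DISTANCE:
                return HARD_CORE_ENERGY
            total += qa * qvals[b] * prefactor * math.exp(-r / lam) / r
    return total


def _dna_energy_scalar(sites, qvals, phos, strength, lam):
    total = 0.0
    for (x, y, z), q in zip(sites, qvals):
        for px, py, pz in phos:
            dx, dy, dz = x - px, y - py, z - pz
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r < HARD_CORE_DISTANCE:
                return HARD_CORE_ENERGY
            total += q * (-1.0) * strength * math.exp(-r / lam) / r
    return total


def _delta_helix_coil(sequence: str, states: np.ndarray, i: int,
                      params: ModelParameters) -> float:
    """Energy change of flipping residue i's helix flag, O(1)."""
    L = len(states)
    left = states[i - 1] if i > 0 else False
    right = states[i + 1] if i < L - 1 else False
    w_i = params.propagation_weight(sequence[i])
    # run-count change when residue i turns helical
    if left and right:
        d_runs = -1
    elif left or right:
        d_runs = 0
    else:
        d_runs = 1
    d_log = math.log(w_i) + d_runs * math.log(params.v)
    dE_on = -KB * REFERENCE_TEMPERATURE * d_log
    return dE_on if not states[i] else -dE_on


def mc_sample(
    sequence: str,
    params: ModelParameters,
    n_sweeps: int,
    seed: int,
    record_stride: int = 10,
    rod: DNARod | None = None,
    initial_states: np.ndarray | None = None,
) -> Trajectory:
    """Metropolis sampling of the peptide at ``params.temperature``.

    One sweep is L elementary moves; each move either flips a residue's
    helix/coil flag or redraws a coil residue's dihedrals from the coil
    basin (both proposals are symmetric).  When the parameter set has no
    active charges and no DNA field, the energy is a pure function of the
    state vector and coordinates are only realized at recording times (their
    coil dihedrals are equilibrium-independent uniform draws).
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(sequence)
    charges = params.charges_for(sequence)
    charged_idx = [int(i) for i in np.nonzero(charges != 0.0)[0]]
    qvals = [float(charges[i]) for i in charged_idx]
    coords_needed = bool(charged_idx) or params.dna_on
    beta = 1.0 / (KB * params.temperature)
    phos = ([tuple(p) for p in rod.phosphate_coords]
            if (params.dna_on and rod is not None) else None)
    if params.dna_on and rod is None:
        raise ValueError("dna_on requires a DNARod")

    states = (np.zeros(L, dtype=bool) if initial_states is None
              else np.asarray(initial_states, dtype=bool).copy())
    coil_dih = draw_coil_dihedrals(L, rng)

    def charge_energies(states_, dih_) -> tuple[float, float]:
        eff = _effective_dihedrals(states_, dih_)
        _, ca, _ = _build_backbone_scalar(list(eff[:, 0]), list(eff[:, 1]))
        sites = _charge_sites_scalar(ca, charged_idx)
        e_el = _pair_energy_scalar(sites, qvals, params.elec_prefactor,
                                   params.debye_length)
        e_dna = (_dna_energy_scalar(sites, qvals, phos, params.dna_strength,
                                    params.debye_length) if phos else 0.0)
        return e_el, e_dna

    e_hc = helix_coil_energy(sequence, states, params)
    e_el, e_dna = charge_energies(states, coil_dih) if coords_needed else (0.0, 0.0)

    frames: list[TrajectoryFrame] = []
    n_acc = n_try = 0
    for sweep in range(n_sweeps):
        for _ in range(L):
            i = int(rng.integers(L))
            flip = rng.random() < 0.5
            n_try += 1
            if flip:
                d_hc = _delta_helix_coil(sequence, states, i, params)
                if coords_needed:
                    states[i] = ~states[i]
                    new_el, new_dna = charge_energies(states, coil_dih)
                    dE = d_hc + (new_el - e_el) + (new_dna - e_dna)
                    if dE <= 0 or rng.random() < math.exp(-beta * dE):
                        e_hc += d_hc
                        e_el, e_dna = new_el, new_dna
                        n_acc += 1
                    else:
                        states[i] = ~states[i]
                else:
                    if d_hc <= 0 or rng.random() < math.exp(-beta * d_hc):
                        states[i] = ~states[i]
                        e_hc += d_hc
                        n_acc += 1
            else:
                new_dih = draw_coil_dihedrals(1, rng)[0]
                if coords_needed and not states[i]:
                    old = coil_dih[i].copy()
                    coil_dih[i] = new_dih
                    new_el, new_dna = charge_energies(states, coil_dih)
                    dE = (new_el - e_el) + (new_dna - e_dna)
                    if dE <= 0 or rng.random() < math.exp(-beta * dE):
                        e_el, e_dna = new_el, new_dna
                        n_acc += 1
                    else:
                        coil_dih[i] = old
                else:
                    # latent or energy-free coordinate: always accepted
                    coil_dih[i] = new_dih
                    n_acc += 1
        if (sweep + 1) % record_stride == 0:
            ca = build_coordinates(sequence, states, params,
                                   coil_dihedrals=coil_dih).ca_coords
            frames.append(TrajectoryFrame(
                step=sweep + 1,
                states=states.copy(),
                energy=e_hc + e_el + e_dna,
                energy_terms={"helix_coil": e_hc, "electrostatic": e_el,
                              "dna_field": e_dna},
                ca_coords=ca,
            ))
    return Trajectory(sequence, frames, seed, params, n_acc / max(n_try, 1))
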