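"""Collective variables: helicity (S_alpha), compaction (S_rg), protein-DNA
contacts (S_cont) and the radial binding distance.

S_alpha sums a rational switching function of the best-fit RMSD between every
contiguous six-residue window and an ideal alpha-helix template, so an
L-residue chain scores between 0 (no helical window) and L-5 (every window
ideal).  S_rg is the mass-weighted radius of gyration of the Calpha trace.
S_cont counts screened electrostatic protein-DNA contacts through the same
switching function applied to donor-acceptor distances.  The radial distance
is the in-plane (normal to the DNA axis) distance between the central base
pair and the peptide centroid, the reaction coordinate used for binding free
energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .model import DNARod, Conformation, ideal_helix_ca

_SINGULARITY_GUARD = 1e-9


@dataclass(frozen=True)
class SwitchParams:
    """Rational switch (1 - x^n) / (1 - x^m) parameters."""

    r0: float
    n: int
    m: int

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("R0 must be > 0")
        if not (0 < self.n < self.m):
            raise ValueError("require m > n > 0")


#: Switch for the helicity CV (RMSD to the ideal helix template).
S_ALPHA_SWITCH = SwitchParams(r0=0.08, n=8, m=12)
#: Switch for the protein-DNA contact CV.
S_CONT_SWITCH = SwitchParams(r0=0.2, n=8, m=10)

S_ALPHA_WINDOW = 6


def rational_switch(x: float | np.ndarray, sp: SwitchParams) -> float | np.ndarray:
    """(1 - x^n)/(1 - x^m) with the x = 1 singularity evaluated as n/m.

    Continuous and monotonically decreasing on [0, inf): 1 at x = 0,
    n/m at x = 1, -> 0 as x -> inf.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("switch argument must be >= 0")
    near_one = np.abs(x - 1.0) < _SINGULARITY_GUARD
    safe = np.where(near_one, 2.0, x)
    with np.errstate(over="ignore", invalid="ignore"):
        val = (1.0 - safe**sp.n) / (1.0 - safe**sp.m)
    val = np.where(near_one, sp.n / sp.m, val)
    return float(val) if val.ndim == 0 else val


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Best-fit (proper-rotation) RMSD between two coordinate sets, nm."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    import warnings

    with warnings.catch_warnings():
        # collinear coordinate sets make the optimal rotation degenerate;
        # the residual (all we use) is still well defined
        warnings.simplefilter("ignore", UserWarning)
        _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(len(a)))


def _coords_of(conf: Conformation | np.ndarray) -> np.ndarray:
    if isinstance(conf, Conformation):
        return conf.ca_coords
    return np.asarray(conf, dtype=float)


def s_alpha(
    conf: Conformation | np.ndarray,
    template: np.ndarray | None = None,
    sp: SwitchParams = S_ALPHA_SWITCH,
) -> float:
    """Helical content: switched window-RMSD sum over all L-5 six-residue windows."""
    coords = _coords_of(conf)
    L = len(coords)
    if L < S_ALPHA_WINDOW:
        raise ValueError(f"S_alpha needs >= {S_ALPHA_WINDOW} residues, got {L}")
    if template is None:
        template = ideal_helix_ca(S_ALPHA_WINDOW)
    total = 0.0
    for j in range(L - S_ALPHA_WINDOW + 1):
        rmsd = kabsch_rmsd(coords[j : j + S_ALPHA_WINDOW], template)
        total += float(rational_switch(rmsd / sp.r0, sp))
    return total


def s_rg(conf: Conformation | np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration of the Calpha trace, nm."""
    coords = _coords_of(conf)
    if len(coords) == 0:
        raise ValueError("S_rg needs at least one atom")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    com = np.average(coords, axis=0, weights=masses)
    d2 = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt(np.average(d2, weights=masses)))


#: Contact-CV distance cutoff (nm): the n=8, m=10 rational switch decays
#: only as x^-2, so the tail is stretched to reach exactly zero here.
S_CONT_CUTOFF = 2.0


def _stretched_switch(r: np.ndarray, sp: SwitchParams, r_cut: float):
    """Switch of r/R0, rescaled to hit 0 at the cutoff (1 at r = 0)."""
    s_cut = float(rational_switch(r_cut / sp.r0, sp))
    raw = rational_switch(np.minimum(r, r_cut) / sp.r0, sp)
    return np.where(r >= r_cut, 0.0, (raw - s_cut) / (1.0 - s_cut))


def s_cont(
    conf: Conformation,
    rod: DNARod,
    sp: SwitchParams = S_CONT_SWITCH,
    donor_sites: np.ndarray | None = None,
    acceptor_sites: np.ndarray | None = None,
    r_cut: float = S_CONT_CUTOFF,
) -> float:
    """Number of screened protein-DNA contacts.

    Donors are the positive sidechain pseudo-atoms (Lys/Arg); acceptors are
    the phosphate sites of the rod's central 11 bp.  Contributions vanish
    (continuously) beyond ``r_cut``.
    """
    if donor_sites is None:
        mask = conf.charge_values > 0
        donor_sites = conf.charge_sites[mask]
    acceptors = (rod.central_phosphate_coords if acceptor_sites is None
                 else np.asarray(acceptor_sites, dtype=float))
    if len(donor_sites) == 0:
        import warnings

        warnings.warn("empty donor set: S_cont = 0", stacklevel=2)
        return 0.0
    diff = donor_sites[:, None, :] - acceptors[None, :, :]
    r = np.sqrt((diff * diff).sum(axis=-1))
    return float(np.sum(_stretched_switch(r, sp, r_cut)))


def s_cont_bruteforce(
    conf: Conformation,
    rod: DNARod,
    sp: SwitchParams = S_CONT_SWITCH,
    r_cut: float = S_CONT_CUTOFF,
) -> float:
    """Naive double loop over donor/acceptor pairs (implementation oracle)."""
    donors = conf.charge_sites[conf.charge_values > 0]
    total = 0.0
    for d in donors:
        for a in rod.central_phosphate_coords:
            r = float(np.linalg.norm(d - a))
            total += float(_stretched_switch(np.array(r), sp, r_cut))
    return total


def radial_distance(conf: Conformation | np.ndarray, rod: DNARod) -> float:
    """In-plane distance between the central bp and the Calpha centroid, nm.

    The rod axis is re-aligned to z internally; axial displacement is
    ignored.
    """
    coords = _coords_of(conf)
    axis = rod.axis / np.linalg.norm(rod.axis)
    centroid = coords.mean(axis=0)
    delta = centroid - rod.central_bp_coord
    in_plane = delta - np.dot(delta, axis) * axis
    return float(np.linalg.norm(in_plane))
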