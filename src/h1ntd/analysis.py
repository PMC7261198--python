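"""Observable extraction from (weighted) conformational ensembles.

Secondary-structure assignment (state- or dihedral-based, counting both
alpha-like and 3-10-like runs toward helicity), radius-of-gyration
distributions against globular and random-coil power-law baselines,
single-linkage RMSD clustering with reweighted populations, per-residue
DNA-contact fractions, free-energy surfaces over collective variables, and
block-based convergence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .constants import KB, NM_PER_ANGSTROM
from .cvs import kabsch_rmsd
from .model import DNARod, Trajectory, helix_runs

#: Clustering cutoff (Angstrom) on pairwise Calpha RMSD.
CLUSTER_CUTOFF_ANGSTROM = 2.5
#: Heavy-atom DNA-contact cutoff (Angstrom).
CONTACT_CUTOFF_ANGSTROM = 3.2
#: Maximum frames entering the O(n^2) clustering (strided above this).
MAX_CLUSTER_FRAMES = 2000

HELIX_PHI_WINDOW = (-57.0, 30.0)  # centre, half-width (degrees)
HELIX_PSI_WINDOW = (-47.0, 30.0)


def assign_secondary_structure(
    states_or_dihedrals: np.ndarray, mode: str = "states"
) -> np.ndarray:
    """Per-frame, per-residue labels in {"H", "C"}.

    ``states`` mode (coarse-grained): a residue is helical iff its helix
    flag sits in a run of >= 3 consecutive helical residues -- runs of 3
    count as 3-10-like, runs of >= 4 as alpha-like; both count toward
    helicity, mirroring the convention of counting alpha and 3-10 motifs
    together.

    ``dihedrals`` mode (atomistic input): a residue is helical iff its
    (phi, psi) lie within +-30 degrees of (-57, -47) over a run of >= 3
    consecutive residues.
    """
    arr = np.asarray(states_or_dihedrals)
    if mode == "states":
        frames = np.atleast_2d(arr).astype(bool)
        in_window = frames
    elif mode == "dihedrals":
        if arr.ndim == 2:
            arr = arr[None, ...]
        phi_ok = np.abs(arr[..., 0] - HELIX_PHI_WINDOW[0]) <= HELIX_PHI_WINDOW[1]
        psi_ok = np.abs(arr[..., 1] - HELIX_PSI_WINDOW[0]) <= HELIX_PSI_WINDOW[1]
        in_window = phi_ok & psi_ok
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = np.full(in_window.shape, "C", dtype="U1")
    for f in range(in_window.shape[0]):
        for start, stop in helix_runs(in_window[f]):
            if stop - start >= 3:
                out[f, start:stop] = "H"
    return out


def helix_indicator(states_matrix: np.ndarray) -> np.ndarray:
    """(n_frames, L) 0/1 helicity matrix from raw state vectors."""
    return (assign_secondary_structure(states_matrix, "states") == "H").astype(float)


@dataclass(frozen=True)
class RgBaselines:
    """Power-law radius-of-gyration baselines (Angstrom) for N residues.

    Globular: 2.2 N^0.38; random coil: 2.02 N^0.60.
    """

    n_residues: int
    rg_glob: float
    rg_coil: float

    @property
    def rg_glob_nm(self) -> float:
        return self.rg_glob * NM_PER_ANGSTROM

    @property
    def rg_coil_nm(self) -> float:
        return self.rg_coil * NM_PER_ANGSTROM


def rg_baselines(n_residues: int) -> RgBaselines:
    if n_residues < 1:
        raise ValueError("N must be >= 1")
    return RgBaselines(
        n_residues,
        2.2 * n_residues**0.38,
        2.02 * n_residues**0.60,
    )


@dataclass
class RgDistribution:
    bin_centers: np.ndarray
    density: np.ndarray
    mean_rg: float
    baselines: RgBaselines
    fraction_below_glob: float
    fraction_above_coil: float


def rg_distribution(
    rg_values: np.ndarray,
    n_residues: int,
    weights: np.ndarray | None = None,
    bins: int = 40,
) -> RgDistribution:
    """Weighted histogram of Rg (nm) with compaction-baseline mass fractions."""
    rg_values = np.asarray(rg_values, dtype=float)
    if weights is None:
        weights = np.full(len(rg_values), 1.0 / len(rg_values))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    base = rg_baselines(n_residues)
    lo = min(rg_values.min(), base.rg_glob_nm) * 0.9
    hi = max(rg_values.max(), base.rg_coil_nm) * 1.1
    density, edges = np.histogram(rg_values, bins=bins, range=(lo, hi),
                                  weights=weights, density=True)
    return RgDistribution(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        density=density,
        mean_rg=float(np.sum(weights * rg_values)),
        baselines=base,
        fraction_below_glob=float(weights[rg_values < base.rg_glob_nm].sum()),
        fraction_above_coil=float(weights[rg_values > base.rg_coil_nm].sum()),
    )


@dataclass
class ClusterSet:
    assignments: np.ndarray        # frame -> cluster id (by descending population)
    populations: np.ndarray        # normalized reweighted population per cluster
    representatives: np.ndarray    # frame index of highest-weight member
    cutoff_angstrom: float
    stride: int = 1


def single_linkage_cluster(
    coords: np.ndarray | list[np.ndarray],
    cutoff_angstrom: float = CLUSTER_CUTOFF_ANGSTROM,
    weights: np.ndarray | None = None,
) -> ClusterSet:
    """Single-linkage clustering on pairwise best-fit Calpha RMSD.

    Structures closer than the cutoff are linked; clusters are the
    transitive closure (connected components) of that relation.  Frame sets
    larger than ``MAX_CLUSTER_FRAMES`` are strided down and the stride
    recorded.
    """
    coords = [np.asarray(c, dtype=float) for c in coords]
    n = len(coords)
    if n == 0:
        raise ValueError("need at least one frame")
    stride = max(1, -(-n // MAX_CLUSTER_FRAMES))
    idx = np.arange(0, n, stride)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    weights = np.asarray(weights, dtype=float)
    sub_w = weights[idx]
    sub = [coords[i] for i in idx]
    cutoff_nm = cutoff_angstrom * NM_PER_ANGSTROM
    m = len(sub)
    rows, cols = [], []
    for i in range(m):
        for j in range(i + 1, m):
            if kabsch_rmsd(sub[i], sub[j]) < cutoff_nm:
                rows.append(i)
                cols.append(j)
    graph = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    n_comp, labels = connected_components(graph, directed=False)
    pops = np.array([sub_w[labels == k].sum() for k in range(n_comp)])
    pops_norm = pops / pops.sum()
    order = np.argsort(-pops_norm)
    rank = np.empty_like(order)
    rank[order] = np.arange(n_comp)
    assignments = rank[labels]
    reps = np.empty(n_comp, dtype=int)
    for new_k in range(n_comp):
        members = idx[assignments == new_k]
        reps[new_k] = members[np.argmax(weights[members])]
    return ClusterSet(assignments, pops_norm[order], reps, cutoff_angstrom, stride)


@dataclass
class ContactReport:
    per_residue_fraction: np.ndarray
    bound_fraction: float
    cutoff_angstrom: float


def contact_fraction(
    frames_coords: list[np.ndarray],
    rod: DNARod,
    cutoff_angstrom: float = CONTACT_CUTOFF_ANGSTROM,
    weights: np.ndarray | None = None,
) -> ContactReport:
    """Per-residue fraction of frames with any site within the cutoff of DNA."""
    n = len(frames_coords)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    cutoff_nm = cutoff_angstrom * NM_PER_ANGSTROM
    L = len(frames_coords[0])
    per_res = np.zeros(L)
    bound = 0.0
    for w, ca in zip(weights, frames_coords):
        diff = np.asarray(ca)[:, None, :] - rod.phosphate_coords[None, :, :]
        r = np.sqrt((diff * diff).sum(axis=-1))
        in_contact = (r < cutoff_nm).any(axis=1)
        per_res += w * in_contact
        bound += w * float(in_contact.any())
    return ContactReport(per_res, bound, cutoff_angstrom)


@dataclass
class FreeEnergySurface:
    """Gridded free-energy surface with located minima (kJ/mol, min = 0)."""

    grid: tuple[np.ndarray, ...]
    free_energy: np.ndarray        # masked (nan) where unsampled
    minima: list[tuple[tuple[float, ...], float]]
    delta_e: float | None          # depth difference of the two lowest minima
    mode: str


def _local_minima_1d(x: np.ndarray, f: np.ndarray) -> list[tuple[tuple[float, ...], float]]:
    minima = []
    valid = np.isfinite(f)
    for i in range(len(f)):
        if not valid[i]:
            continue
        left = f[i - 1] if i > 0 and valid[i - 1] else np.inf
        right = f[i + 1] if i < len(f) - 1 and valid[i + 1] else np.inf
        if f[i] <= left and f[i] <= right and (f[i] < left or f[i] < right):
            minima.append(((float(x[i]),), float(f[i])))
    return sorted(minima, key=lambda m: m[1])


def _local_minima_2d(gx, gy, f) -> list[tuple[tuple[float, ...], float]]:
    minima = []
    nx, ny = f.shape
    for i in range(nx):
        for j in range(ny):
            if not np.isfinite(f[i, j]):
                continue
            neigh = []
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and np.isfinite(f[a, b]):
                    neigh.append(f[a, b])
            if neigh and f[i, j] <= min(neigh) and f[i, j] < max(neigh):
                minima.append(((float(gx[i]), float(gy[j])), float(f[i, j])))
    return sorted(minima, key=lambda m: m[1])


def fes(
    cv_samples: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    bias=None,
    grid: np.ndarray | tuple[np.ndarray, np.ndarray] | None = None,
    mode: str = "from-weights",
    temperature: float = 300.0,
    bins: int = 50,
) -> FreeEnergySurface:
    """Free-energy surface over 1 or 2 CVs.

    ``from-weights``: -kT ln of the weighted CV histogram, empty bins masked
    (never imputed).  ``from-bias``: -gamma/(gamma-1) V on the grid.  The
    global minimum is shifted to zero and local minima are located; the
    depth difference of the two lowest minima is reported when both exist on
    the sampled (finite) region.
    """
    if mode == "from-bias":
        if bias is None or grid is None:
            raise ValueError("from-bias mode needs bias and grid")
        from .reweighting import free_energy_estimate

        if isinstance(grid, tuple):
            gx, gy = grid
            pts = np.array([(a, b) for a in gx for b in gy])
            f = free_energy_estimate(bias, pts).reshape(len(gx), len(gy))
            minima = _local_minima_2d(gx, gy, f)
            g = (gx, gy)
        else:
            f = free_energy_estimate(bias, grid)
            minima = _local_minima_1d(grid, f)
            g = (grid,)
    elif mode == "from-weights":
        samples = np.asarray(cv_samples, dtype=float)
        if samples.ndim == 1:
            samples = samples[:, None]
        elif samples.shape[1] not in (1, 2) and samples.shape[0] in (1, 2):
            samples = samples.T
        n = samples.shape[0]
        if weights is None:
            weights = np.full(n, 1.0 / n)
        weights = np.asarray(weights, dtype=float)
        kt = KB * temperature
        if samples.shape[1] == 1:
            hist, edges = np.histogram(samples[:, 0], bins=bins, weights=weights)
            centers = 0.5 * (edges[:-1] + edges[1:])
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(hist > 0, -kt * np.log(np.where(hist > 0, hist, 1.0)), np.nan)
            f = f - np.nanmin(f)
            minima = _local_minima_1d(centers, f)
            g = (centers,)
        else:
            hist, ex, ey = np.histogram2d(samples[:, 0], samples[:, 1],
                                          bins=bins, weights=weights)
            cx, cy = 0.5 * (ex[:-1] + ex[1:]), 0.5 * (ey[:-1] + ey[1:])
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(hist > 0, -kt * np.log(np.where(hist > 0, hist, 1.0)), np.nan)
            f = f - np.nanmin(f)
            minima = _local_minima_2d(cx, cy, f)
            g = (cx, cy)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    f = f - np.nanmin(f)
    delta_e = minima[1][1] - minima[0][1] if len(minima) >= 2 else None
    return FreeEnergySurface(g, f, minima, delta_e, mode)


@dataclass
class ConvergenceReport:
    block_means: np.ndarray
    max_drift: float
    threshold: float
    converged: bool


def convergence_check(
    series: np.ndarray,
    block_length: int,
    discard: int = 0,
    threshold: float = 0.05,
) -> ConvergenceReport:
    """Block-mean stability of an observable series.

    The initial ``discard`` points are dropped; the rest is cut into blocks
    of ``block_length``; the verdict is converged when the maximum absolute
    difference between consecutive block means is below the threshold.
    """
    series = np.asarray(series, dtype=float)[discard:]
    n_blocks = len(series) // block_length
    if n_blocks < 2:
        raise ValueError("trajectory too short: need >= 2 blocks after discard")
    blocks = series[: n_blocks * block_length].reshape(n_blocks, block_length)
    means = blocks.mean(axis=1)
    drift = float(np.max(np.abs(np.diff(means)))) if n_blocks > 1 else 0.0
    return ConvergenceReport(means, drift, threshold, drift < threshold)


def trajectory_helicity_series(traj: Trajectory) -> np.ndarray:
    """Mean helix fraction (assignment-based) per recorded frame."""
    ind = helix_indicator(traj.states_matrix)
    return ind.mean(axis=1)
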