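"""Potential-of-mean-force estimation from umbrella windows (WHAM).

The weighted histogram analysis method combines biased histograms from
harmonic umbrella windows into one unbiased profile by self-consistent
iteration over the per-window free-energy constants f_i:

    P(b) = sum_i n_i(b) / sum_i N_i exp(-beta [w_i(b) - f_i])
    exp(-beta f_i) = sum_b P(b) exp(-beta w_i(b))

where w_i(b) = 0.5 k (x_b - c_i)^2 is window i's restraint at bin centre
x_b.  Uncertainties come from Bayesian bootstrapping: windows are
re-weighted with unit-mean Dirichlet weights (the trajectory, not the
sample, is the resampling unit) and WHAM is re-run per replicate.  Profiles
follow the large-distance zero convention: the mean of the two outermost
sampled bins is shifted to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import KB
from .sampling import UmbrellaWindow

WHAM_TOL = 1e-6
WHAM_MAX_ITER = 100_000


class WindowOverlapError(ValueError):
    """Adjacent umbrella windows share no sampled bins."""


@dataclass
class PMFProfile:
    """Binned potential of mean force with bootstrap uncertainties."""

    bin_centers: np.ndarray
    free_energy: np.ndarray
    bootstrap_sd: np.ndarray | None
    n_bootstrap: int
    temperature: float

    def __post_init__(self) -> None:
        if self.bootstrap_sd is not None and np.any(self.bootstrap_sd < 0):
            raise ValueError("bootstrap SD must be >= 0")


@dataclass
class WellDepth:
    """Depth of the binding well under the large-distance zero convention."""

    bound: bool
    depth_kj_per_mol: float
    depth_kbt: float
    depth_kbt_rounded: int
    location: float | None


def _window_histograms(
    windows: list[UmbrellaWindow], bins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # bins span the restrained range only: tail bins beyond the terminal
    # window centres are sampled by a handful of tail configurations and
    # carry large, systematically biased errors
    lo = min(w.center for w in windows)
    hi = max(w.center for w in windows)
    edges = np.linspace(lo, hi, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([np.histogram(w.series, bins=edges)[0] for w in windows],
                      dtype=float)
    return centers, edges, counts


def _check_overlap(windows: list[UmbrellaWindow], counts: np.ndarray) -> None:
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order, order[1:]):
        shared = np.minimum(counts[a] > 0, counts[b] > 0)
        n_shared = int(np.minimum(counts[a], counts[b])[shared].sum())
        if not shared.any():
            raise WindowOverlapError(
                f"no histogram overlap between windows at "
                f"{windows[a].center:.3f} and {windows[b].center:.3f}"
            )
        if n_shared < 10:
            warnings.warn(
                f"windows at {windows[a].center:.3f} and {windows[b].center:.3f} "
                f"share only {n_shared} samples",
                stacklevel=3,
            )


def wham(
    windows: list[UmbrellaWindow],
    bins: int = 50,
    tol: float = WHAM_TOL,
    max_iter: int = WHAM_MAX_ITER,
    temperature: float | None = None,
    window_weights: np.ndarray | None = None,
    n_bootstrap: int = 0,
    bootstrap_seed: int | None = None,
) -> PMFProfile:
    """Self-consistent WHAM over umbrella windows.

    ``window_weights`` (unit-mean) rescale whole windows, the hook used by
    the Bayesian bootstrap.  With ``n_bootstrap`` >= 2 the bootstrap SD per
    bin is estimated; the reported profile is always from the full data.
    """
    if len(windows) < 2:
        raise ValueError("WHAM needs >= 2 windows (single window is underdetermined)")
    if temperature is None:
        temperature = windows[0].temperature
    beta = 1.0 / (KB * temperature)

    centers, _, counts = _window_histograms(windows, bins)
    _check_overlap(windows, counts)

    if window_weights is not None:
        counts = counts * np.asarray(window_weights, dtype=float)[:, None]

    w_centers = np.array([w.center for w in windows])
    kappas = np.array([w.force_constant for w in windows])
    # restraint energy of every window at every bin centre
    w_ib = 0.5 * kappas[:, None] * (centers[None, :] - w_centers[:, None]) ** 2
    boltz = np.exp(-beta * w_ib)

    n_i = counts.sum(axis=1)
    numer = counts.sum(axis=0)
    f = np.zeros(len(windows))
    for _ in range(max_iter):
        denom = (n_i * np.exp(beta * f)) @ boltz
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, numer / denom, 0.0)
        z = boltz @ p
        f_new = -np.log(np.where(z > 0, z, 1.0)) / beta
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    else:
        warnings.warn("WHAM did not converge within max_iter", stacklevel=2)

    denom = (n_i * np.exp(beta * f)) @ boltz
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where((denom > 0) & (numer > 0), numer / denom, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        free = -np.log(p) / beta
    free = _shift_large_distance_zero(free)

    sd = None
    if n_bootstrap:
        sd = bayesian_bootstrap(windows, n_boot=n_bootstrap,
                                seed=bootstrap_seed or 0, bins=bins, tol=tol,
                                max_iter=max_iter, temperature=temperature)
    return PMFProfile(centers, free, sd, n_bootstrap, temperature)


def _shift_large_distance_zero(free: np.ndarray) -> np.ndarray:
    """Shift so the mean of the two outermost sampled bins is zero."""
    finite = np.nonzero(np.isfinite(free))[0]
    outer = free[finite[-2:]] if len(finite) >= 2 else free[finite]
    return free - outer.mean()


def bayesian_bootstrap(
    windows: list[UmbrellaWindow],
    n_boot: int = 100,
    seed: int = 0,
    bins: int = 50,
    tol: float = WHAM_TOL,
    max_iter: int = WHAM_MAX_ITER,
    temperature: float | None = None,
) -> np.ndarray:
    """Per-bin SD over WHAM re-runs with Dirichlet window weights.

    Each replicate draws unit-mean weights over complete windows (the
    trajectory is the resampling unit) and re-solves WHAM; the SD is taken
    over replicates per bin.
    """
    if n_boot < 2:
        raise ValueError("need n_boot >= 2 for a defined SD")
    rng = np.random.default_rng(seed)
    n_w = len(windows)
    profiles = []
    for _ in range(n_boot):
        weights = rng.dirichlet(np.ones(n_w)) * n_w
        prof = wham(windows, bins=bins, tol=tol, max_iter=max_iter,
                    temperature=temperature, window_weights=weights)
        profiles.append(prof.free_energy)
    stack = np.array(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(stack, axis=0)


def well_depth(profile: PMFProfile, temperature: float | None = None) -> WellDepth:
    """Binding-well depth in kJ/mol and units of k_B T.

    Depth is 0 - min(F) under the large-distance zero convention.  A profile
    whose minimum sits on the boundary (monotonic profile) has no bound
    state.
    """
    if temperature is None:
        temperature = profile.temperature
    free = profile.free_energy
    finite = np.nonzero(np.isfinite(free))[0]
    i_min = finite[np.argmin(free[finite])]
    interior = finite[0] < i_min < finite[-1]
    depth = float(0.0 - free[i_min])
    if not interior or depth <= 0:
        return WellDepth(False, 0.0, 0.0, 0, None)
    kbt = depth / (KB * temperature)
    return WellDepth(True, depth, kbt, int(round(kbt)),
                     float(profile.bin_centers[i_min]))


def depth_in_kbt(depth_kj_per_mol: float, temperature: float = 300.0) -> float:
    """Convert a stabilization free energy to units of k_B T."""
    return depth_kj_per_mol / (KB * temperature)
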