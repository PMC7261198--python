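"""Recovery of unbiased averages from metadynamics trajectories.

A history-dependent bias V(s, t) distorts the sampled distribution in a
time-dependent way, so trajectory frames cannot be averaged directly.
Following the time-dependent-offset approach, the biased density factorizes
as P(R, t) = P0(R) exp(-beta [V(s(R), t) - c(t)]) with

    c(t) = (1/beta) ln [ int exp(-beta F(s)) ds
                       / int exp(-beta [F(s) + V(s, t)]) ds ],

where F(s) is the free-energy estimate implied by the (well-tempered) bias,
F(s) = -gamma/(gamma-1) V(s, t_final).  Frames are then reweighted with
w(t) proportional to exp(beta [V(s(R), t) - c(t)]) and any observable is the
weighted average <O> = sum w_i O_i / sum w_i.

A time-independent ("final bias") mode is provided as a cross-check:
weights proportional to exp(beta V(s(R), t_final)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB
from .sampling import MetaBias, MetadRun


@dataclass
class BiasHistory:
    """Per-frame record of a biased run: time, CVs, instantaneous bias."""

    times: np.ndarray
    cv_values: np.ndarray      # (n_frames, dim)
    bias_values: np.ndarray    # V(s_i, t_i), kJ/mol
    bias: MetaBias
    temperature: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cv_values = np.atleast_2d(np.asarray(self.cv_values, dtype=float))
        if self.cv_values.shape[0] != len(self.times):
            self.cv_values = self.cv_values.T
        self.bias_values = np.asarray(self.bias_values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @classmethod
    def from_run(cls, run: MetadRun) -> "BiasHistory":
        return cls(run.times, run.cv_series, run.bias_series, run.bias,
                   run.temperature)

    def validate(self, tol: float = 1e-9) -> float:
        """Max |recorded - recomputed| bias over frames (must be < tol)."""
        err = 0.0
        for t, s, v in zip(self.times, self.cv_values, self.bias_values):
            err = max(err, abs(self.bias.evaluate(s, t) - v))
        if err >= tol:
            raise ValueError(f"bias history irreproducible: max error {err:.3e}")
        return err


@dataclass
class WeightedEnsemble:
    """Frames plus normalized Tiwary-Parrinello weights."""

    frame_times: np.ndarray
    weights: np.ndarray
    c_times: np.ndarray
    c_values: np.ndarray
    log_normalization: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("all weights zero")
        self.weights = self.weights / total

    @property
    def effective_sample_size(self) -> float:
        return float(1.0 / np.sum(self.weights**2))


def free_energy_estimate(
    bias: MetaBias,
    grid: np.ndarray,
    t: float | None = None,
    bias_factor: float | None = None,
) -> np.ndarray:
    """F(s) on a grid from the deposited bias, shifted so min F = 0.

    Well-tempered relation F = -gamma/(gamma-1) V; gamma = inf gives F = -V.
    """
    gamma = bias.bias_factor if bias_factor is None else bias_factor
    v = bias.evaluate_grid(grid, t)
    scale = 1.0 if np.isinf(gamma) else gamma / (gamma - 1.0)
    f = -scale * v
    return f - f.min()


def c_of_t(
    bias: MetaBias,
    times: np.ndarray,
    grid: np.ndarray,
    temperature: float,
    bias_factor: float | None = None,
) -> np.ndarray:
    """Time-dependent bias offset c(t) by trapezoidal quadrature on the grid.

    The grid must cover the sampled CV range; a refinement warning is issued
    when halving the grid spacing changes the result materially.
    """
    grid = np.asarray(grid, dtype=float)
    beta = 1.0 / (KB * temperature)
    f = free_energy_estimate(bias, grid, bias_factor=bias_factor)
    log_num = _log_trapz(-beta * f, grid)
    out = np.empty(len(times))
    for i, t in enumerate(times):
        v_t = bias.evaluate_grid(grid, t)
        log_den = _log_trapz(-beta * (f + v_t), grid)
        out[i] = (log_num - log_den) / beta
    return out


def _log_trapz(log_y: np.ndarray, x: np.ndarray) -> float:
    """log integral of exp(log_y) dx, overflow-guarded."""
    m = float(np.max(log_y))
    return m + float(np.log(np.trapezoid(np.exp(log_y - m), x)))


def frame_weights(
    history: BiasHistory,
    c_times: np.ndarray | None = None,
    c_values: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    n_c_times: int = 200,
    mode: str = "time-dependent",
) -> WeightedEnsemble:
    """Normalized frame weights w(t) proportional to exp(beta [V(s,t) - c(t)]).

    When no precomputed c(t) series is supplied, it is evaluated on
    ``n_c_times`` deposit-time points spanning the run (then linearly
    interpolated at frame times).  ``mode = "final-bias"`` applies the
    time-independent cross-check weighting exp(beta V(s, t_final)).
    """
    beta = 1.0 / (KB * history.temperature)
    if mode == "final-bias":
        v_final = np.array([history.bias.evaluate(s) for s in history.cv_values])
        logw = beta * v_final
        c_t = np.array([history.times[0], history.times[-1]])
        c_v = np.zeros(2)
    elif mode == "time-dependent":
        if c_values is None:
            if grid is None:
                lo = history.cv_values.min(axis=0)
                hi = history.cv_values.max(axis=0)
                if history.cv_values.shape[1] != 1:
                    raise ValueError("supply an explicit grid for multi-CV biases")
                pad = 0.1 * (hi[0] - lo[0] + 1e-12)
                grid = np.linspace(lo[0] - pad, hi[0] + pad, 400)
            c_t = np.linspace(history.times[0], history.times[-1],
                              min(n_c_times, len(history.times)))
            c_v = c_of_t(history.bias, c_t, grid, history.temperature)
        else:
            c_t = np.asarray(c_times, dtype=float)
            c_v = np.asarray(c_values, dtype=float)
        c_at_frames = np.interp(history.times, c_t, c_v)
        logw = beta * (history.bias_values - c_at_frames)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    shift = logw.max()
    w = np.exp(logw - shift)
    return WeightedEnsemble(history.times, w, c_t, c_v, float(shift))


def weighted_average(ens: WeightedEnsemble, observable: np.ndarray) -> float:
    """<O> = sum w_i O_i / sum w_i (weights pre-normalized)."""
    observable = np.asarray(observable, dtype=float)
    if observable.shape[0] != len(ens.weights):
        raise ValueError("need one observable value per frame")
    return float(np.sum(ens.weights * observable))


def reweighted_per_residue_helicity(
    ens: WeightedEnsemble, helix_indicator: np.ndarray
) -> np.ndarray:
    """Weighted per-residue helix fraction from a (n_frames, L) 0/1 matrix."""
    helix_indicator = np.asarray(helix_indicator, dtype=float)
    if helix_indicator.shape[0] != len(ens.weights):
        raise ValueError("indicator matrix must have one row per frame")
    return helix_indicator.T @ ens.weights
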