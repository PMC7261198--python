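"""Bias engines and replica orchestration.

Implements the enhanced-sampling toolbox on top of any Metropolis system
(`MCSystem`): history-dependent Gaussian bias deposition (metadynamics),
its well-tempered variant, the well-tempered-ensemble (WTE) stage that
biases the potential energy itself to broaden energy fluctuations,
temperature replica exchange (T-REMD), the combined PTMetaD-WTE two-stage
protocol, and harmonic umbrella sampling.

The bias accumulated at time t is

    V(S, t) = sum_{t' <= t} W_{t'} exp(-(S - S_{t'})^2 / (2 sigma^2))

with fixed heights W in plain metadynamics and heights decaying as
``W exp(-V(S,t)/(k_B dT))``, dT = (gamma - 1) T, in the well-tempered
variant (gamma = inf reproduces fixed-height deposition).  Replica swaps
use the bias-aware Metropolis rule

    P = min{1, exp[(b_i - b_j)(U_i - U_j) + b_i (V_i(S_i) - V_i(S_j))
                                          + b_j (V_j(S_j) - V_j(S_i))]}.

Time is measured in Monte-Carlo steps; the configured
``STEPS_PER_PS`` constant maps schedule conventions quoted in
picoseconds onto step counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from .constants import KB

#: Declared conversion between "ps" schedule language and MC steps.
STEPS_PER_PS = 10


class MCSystem(Protocol):
    """Anything a sampler can propagate: energy, symmetric proposals, CVs."""

    cv_names: tuple[str, ...]

    def initial_state(self, rng: np.random.Generator): ...

    def propose(self, state, rng: np.random.Generator): ...

    def energy(self, state) -> float: ...

    def cvs(self, state) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# metadynamics bias

@dataclass(frozen=True)
class GaussianKernel:
    """One deposited Gaussian: centre, per-CV width, height, deposit time."""

    center: tuple[float, ...]
    sigma: tuple[float, ...]
    height: float
    time: int

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma must be > 0")
        if self.height <= 0:
            raise ValueError("height must be > 0")


class MetaBias:
    """Accumulated metadynamics bias: ordered kernels plus bookkeeping.

    ``bias_factor`` gamma may be ``math.inf`` (plain, non-well-tempered
    deposition).  Evaluation at time ``t`` sums only kernels deposited at
    ``t' <= t``; multi-dimensional kernels are products of per-CV Gaussians.
    """

    def __init__(
        self,
        cv_names: Sequence[str],
        bias_factor: float = math.inf,
        stride: int = 500,
    ) -> None:
        if bias_factor <= 1:
            raise ValueError("bias_factor must be > 1 (inf for non-well-tempered)")
        self.cv_names = tuple(cv_names)
        self.bias_factor = float(bias_factor)
        self.stride = int(stride)
        self._centers: list[tuple[float, ...]] = []
        self._sigmas: list[tuple[float, ...]] = []
        self._heights: list[float] = []
        self._times: list[int] = []
        self._cache: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None

    # -- container views ----------------------------------------------------
    @property
    def n_kernels(self) -> int:
        return len(self._heights)

    @property
    def kernels(self) -> list[GaussianKernel]:
        return [
            GaussianKernel(c, s, h, t)
            for c, s, h, t in zip(self._centers, self._sigmas, self._heights, self._times)
        ]

    @property
    def dim(self) -> int:
        return len(self.cv_names)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        if self._cache is None:
            d = self.dim
            self._cache = (
                np.asarray(self._centers, dtype=float).reshape(-1, d),
                np.asarray(self._sigmas, dtype=float).reshape(-1, d),
                np.asarray(self._heights, dtype=float),
                np.asarray(self._times, dtype=float),
            )
        return self._cache

    # -- deposition / evaluation --------------------------------------------
    def evaluate(self, s, t: float | None = None) -> float:
        """Exact kernel-sum bias V(S, t) in kJ/mol."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if len(s) != self.dim:
            raise ValueError(
                f"CV dimension mismatch: got {len(s)}, bias has {self.cv_names}"
            )
        if self.n_kernels == 0:
            return 0.0
        centers, sigmas, heights, times = self.arrays()
        if t is not None:
            mask = times <= t
            centers, sigmas, heights = centers[mask], sigmas[mask], heights[mask]
        if len(heights) == 0:
            return 0.0
        z = (s[None, :] - centers) / sigmas
        return float(np.sum(heights * np.exp(-0.5 * (z * z).sum(axis=1))))

    def evaluate_grid(self, grid: np.ndarray, t: float | None = None) -> np.ndarray:
        """Bias on a grid of CV points, shape (n_points, dim) or (n_points,)."""
        grid = np.asarray(grid, dtype=float)
        if grid.ndim == 1:
            grid = grid[:, None]
        centers, sigmas, heights, times = self.arrays()
        if t is not None:
            mask = times <= t
            centers, sigmas, heights = centers[mask], sigmas[mask], heights[mask]
        if len(heights) == 0:
            return np.zeros(len(grid))
        out = np.zeros(len(grid))
        chunk = max(1, int(2e6 // max(len(grid), 1)))
        for lo in range(0, len(heights), chunk):
            hi = lo + chunk
            z = (grid[:, None, :] - centers[None, lo:hi, :]) / sigmas[None, lo:hi, :]
            out += (heights[lo:hi] * np.exp(-0.5 * (z * z).sum(axis=2))).sum(axis=1)
        return out

    def deposit(
        self,
        s_now,
        base_height: float,
        temperature: float,
        time: int,
        sigma: Sequence[float],
    ) -> GaussianKernel:
        """Add a kernel at ``s_now`` with well-tempered height decay.

        Height = W exp(-V(s_now, t) / (k_B dT)) with dT = (gamma - 1) T;
        gamma = inf keeps the full base height (plain deposition).
        """
        s_now = tuple(np.atleast_1d(np.asarray(s_now, dtype=float)))
        if len(s_now) != self.dim:
            raise ValueError("CV dimension mismatch in deposit")
        if math.isinf(self.bias_factor):
            height = base_height
        else:
            delta_t = (self.bias_factor - 1.0) * temperature
            height = base_height * math.exp(-self.evaluate(s_now) / (KB * delta_t))
        kernel = GaussianKernel(s_now, tuple(float(x) for x in sigma), height, time)
        self._centers.append(kernel.center)
        self._sigmas.append(kernel.sigma)
        self._heights.append(kernel.height)
        self._times.append(time)
        self._cache = None
        return kernel

    @classmethod
    def from_kernels(
        cls,
        kernels: Sequence[GaussianKernel],
        cv_names: Sequence[str],
        bias_factor: float = math.inf,
        stride: int = 500,
    ) -> "MetaBias":
        times = [k.time for k in kernels]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("kernels must be time-ordered")
        bias = cls(cv_names, bias_factor, stride)
        for k in kernels:
            bias._centers.append(tuple(k.center))
            bias._sigmas.append(tuple(k.sigma))
            bias._heights.append(k.height)
            bias._times.append(k.time)
        bias._cache = None
        return bias


def deposit(
    bias: MetaBias,
    s_now,
    base_height: float,
    temperature: float,
    time: int,
    sigma: Sequence[float],
) -> MetaBias:
    """Functional wrapper around :meth:`MetaBias.deposit` (returns the bias)."""
    bias.deposit(s_now, base_height, temperature, time, sigma)
    return bias


def evaluate_bias(bias: MetaBias, s, t: float | None = None) -> float:
    return bias.evaluate(s, t)


# ---------------------------------------------------------------------------
# metadynamics driver

@dataclass(frozen=True)
class MetadParams:
    """Deposition schedule for one metadynamics stage."""

    height: float = 1.0
    sigma: tuple[float, ...] = (0.1,)
    stride: int = 500
    bias_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("height must be >= 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class BiasHistoryRecord:
    time: int
    cvs: np.ndarray
    bias: float
    energy: float


@dataclass
class MetadRun:
    """Output of a metadynamics run: the bias, per-frame history, statistics."""

    bias: MetaBias
    records: list[BiasHistoryRecord]
    temperature: float
    acceptance_rate: float
    final_state: object

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records], dtype=float)

    @property
    def cv_series(self) -> np.ndarray:
        return np.array([r.cvs for r in self.records])

    @property
    def bias_series(self) -> np.ndarray:
        return np.array([r.bias for r in self.records])

    @property
    def energy_series(self) -> np.ndarray:
        return np.array([r.energy for r in self.records])


def run_metad(
    system: MCSystem,
    params: MetadParams,
    n_steps: int,
    seed: int | np.random.Generator,
    temperature: float = 300.0,
    record_stride: int = 10,
    cv_indices: Sequence[int] | None = None,
    extra_bias: Callable[[np.ndarray, float], float] | None = None,
    initial_state=None,
) -> MetadRun:
    """Well-tempered metadynamics over the selected CVs of ``system``.

    ``extra_bias(cvs, energy)`` is an optional frozen additive bias (used to
    carry a fixed WTE bias into a production stage).  Deposition is skipped
    entirely when ``params.height == 0``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = 1.0 / (KB * temperature)
    idx = list(cv_indices) if cv_indices is not None else list(range(len(params.sigma)))
    names = tuple(system.cv_names[i] for i in idx)
    bias = MetaBias(names, params.bias_factor, params.stride)

    state = system.initial_state(rng) if initial_state is None else initial_state
    e = system.energy(state)
    s = np.asarray(system.cvs(state), dtype=float)[idx]

    def total_bias(s_, e_) -> float:
        v = bias.evaluate(s_)
        if extra_bias is not None:
            v += extra_bias(s_, e_)
        return v

    v = total_bias(s, e)
    records: list[BiasHistoryRecord] = []
    n_acc = 0
    for step in range(1, n_steps + 1):
        cand = system.propose(state, rng)
        e_cand = system.energy(cand)
        s_cand = np.asarray(system.cvs(cand), dtype=float)[idx]
        v_cand = total_bias(s_cand, e_cand)
        d = (e_cand + v_cand) - (e + v)
        if d <= 0 or rng.random() < math.exp(-beta * d):
            state, e, s, v = cand, e_cand, s_cand, v_cand
            n_acc += 1
        if params.height > 0 and step % params.stride == 0:
            bias.deposit(s, params.height, temperature, step, params.sigma)
            v = total_bias(s, e)
        if step % record_stride == 0:
            records.append(BiasHistoryRecord(step, s.copy(), bias.evaluate(s), e))
    return MetadRun(bias, records, temperature, n_acc / max(n_steps, 1), state)


# ---------------------------------------------------------------------------
# replica ladders and exchange

@dataclass(frozen=True)
class ReplicaLadder:
    """Geometric temperature ladder T_i = T_min (T_max/T_min)^((i-1)/(N-1))."""

    t_min: float
    t_max: float
    n_replicas: int
    temperatures: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_replicas < 2:
            raise ValueError("need at least 2 replicas")
        if not (0 < self.t_min < self.t_max):
            raise ValueError("require 0 < T_min < T_max")
        if not self.temperatures:
            temps = tuple(
                self.t_min * (self.t_max / self.t_min) ** (i / (self.n_replicas - 1))
                for i in range(self.n_replicas)
            )
            object.__setattr__(self, "temperatures", temps)

    def __len__(self) -> int:
        return self.n_replicas

    def __getitem__(self, i: int) -> float:
        return self.temperatures[i]


def temperature_ladder(t_min: float, t_max: float, n: int) -> ReplicaLadder:
    return ReplicaLadder(t_min, t_max, n)


@dataclass
class ReplicaState:
    """One replica: its temperature, configuration, energy and own bias."""

    replica_id: int
    temperature: float
    state: object
    potential_energy: float
    bias: MetaBias | None = None
    cv_values: np.ndarray | None = None

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)


def exchange_probability(
    a: ReplicaState,
    b: ReplicaState,
    v_a_of=None,
    v_b_of=None,
) -> float:
    """Bias-aware swap probability between two replicas.

    ``v_a_of(replica)`` returns replica ``a``'s bias evaluated at the given
    replica's configuration (likewise ``v_b_of``); omitted terms are zero,
    recovering the plain T-REMD Metropolis factor
    ``min{1, exp[(b_a - b_b)(U_a - U_b)]}``.
    """
    va_sa = v_a_of(a) if v_a_of is not None else 0.0
    va_sb = v_a_of(b) if v_a_of is not None else 0.0
    vb_sb = v_b_of(b) if v_b_of is not None else 0.0
    vb_sa = v_b_of(a) if v_b_of is not None else 0.0
    arg = (
        (a.beta - b.beta) * (a.potential_energy - b.potential_energy)
        + a.beta * (va_sa - va_sb)
        + b.beta * (vb_sb - vb_sa)
    )
    return min(1.0, math.exp(min(arg, 0.0)) if arg < 0 else 1.0)


@dataclass
class ExchangeStats:
    attempts: np.ndarray  # per adjacent pair
    accepts: np.ndarray
    log: list[tuple[int, int, bool]] = field(default_factory=list)  # (cycle, pair, accepted)

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.attempts > 0, self.accepts / self.attempts, np.nan)

    @property
    def mean_rate(self) -> float:
        return float(np.nansum(self.accepts) / max(np.nansum(self.attempts), 1))


def _propagate(system, replica: ReplicaState, n_steps: int, rng,
               effective_bias=None) -> float:
    """Metropolis-propagate one replica; returns acceptance fraction."""
    beta = replica.beta
    state, e = replica.state, replica.potential_energy
    v = effective_bias(replica) if effective_bias is not None else 0.0
    n_acc = 0
    for _ in range(n_steps):
        cand = system.propose(state, rng)
        e_cand = system.energy(cand)
        if effective_bias is not None:
            probe = ReplicaState(replica.replica_id, replica.temperature, cand,
                                 e_cand, replica.bias,
                                 np.asarray(system.cvs(cand), dtype=float))
            v_cand = effective_bias(probe)
        else:
            v_cand = 0.0
        d = (e_cand + v_cand) - (e + v)
        if d <= 0 or rng.random() < math.exp(-beta * d):
            state, e, v = cand, e_cand, v_cand
            n_acc += 1
    replica.state = state
    replica.potential_energy = e
    replica.cv_values = np.asarray(system.cvs(state), dtype=float)
    return n_acc / max(n_steps, 1)


@dataclass
class TremdResult:
    replicas: list[ReplicaState]
    exchange: ExchangeStats
    records: list[list[tuple[int, float, np.ndarray]]]  # per replica (cycle, U, cvs)

    def energies(self, replica: int) -> np.ndarray:
        return np.array([u for _, u, _ in self.records[replica]])


def run_tremd(
    system: MCSystem,
    ladder: ReplicaLadder | Sequence[float],
    n_cycles: int,
    steps_per_cycle: int,
    seed: int,
    effective_bias=None,
    replicas: list[ReplicaState] | None = None,
) -> TremdResult:
    """Temperature replica exchange: propagate / swap adjacent pairs.

    Swap attempts alternate even and odd adjacent pairs each cycle.  Swaps
    exchange configurations (states, energies, CVs) between temperature
    slots, so the pooled set of configurations is conserved; each replica's
    bias stays attached to its temperature slot.
    """
    temps = list(ladder.temperatures if isinstance(ladder, ReplicaLadder) else ladder)
    n_rep = len(temps)
    ss = np.random.SeedSequence(seed)
    rep_rngs = [np.random.default_rng(s) for s in ss.spawn(n_rep)]
    ex_rng = np.random.default_rng(ss.spawn(1)[0])

    if replicas is None:
        replicas = []
        for i, t in enumerate(temps):
            st = system.initial_state(rep_rngs[i])
            replicas.append(ReplicaState(i, t, st, system.energy(st), None,
                                         np.asarray(system.cvs(st), dtype=float)))
    stats = ExchangeStats(np.zeros(n_rep - 1), np.zeros(n_rep - 1))
    records: list[list[tuple[int, float, np.ndarray]]] = [[] for _ in range(n_rep)]

    for cycle in range(n_cycles):
        for i, rep in enumerate(replicas):
            _propagate(system, rep, steps_per_cycle, rep_rngs[i], effective_bias)
            records[i].append((cycle, rep.potential_energy, rep.cv_values.copy()))
        parity = cycle % 2
        for pair in range(parity, n_rep - 1, 2):
            a, b = replicas[pair], replicas[pair + 1]
            v_a = (lambda r, bias=a: effective_bias(
                ReplicaState(bias.replica_id, bias.temperature, r.state,
                             r.potential_energy, bias.bias, r.cv_values)))\
                if effective_bias is not None else None
            v_b = (lambda r, bias=b: effective_bias(
                ReplicaState(bias.replica_id, bias.temperature, r.state,
                             r.potential_energy, bias.bias, r.cv_values)))\
                if effective_bias is not None else None
            p = exchange_probability(a, b, v_a, v_b)
            stats.attempts[pair] += 1
            accepted = ex_rng.random() < p
            if accepted:
                stats.accepts[pair] += 1
                a.state, b.state = b.state, a.state
                a.potential_energy, b.potential_energy = (
                    b.potential_energy, a.potential_energy)
                a.cv_values, b.cv_values = b.cv_values, a.cv_values
            stats.log.append((cycle, pair, bool(accepted)))
    return TremdResult(replicas, stats, records)


# ---------------------------------------------------------------------------
# PTMetaD-WTE

@dataclass(frozen=True)
class WTEParams:
    """Preliminary well-tempered-ensemble stage: bias on the potential energy."""

    height: float = 2.5
    sigma: float = 10.0
    stride: int = 250
    bias_factor: float = 50.0


@dataclass
class PtmetadWteResult:
    wte_biases: list[MetaBias]
    production: TremdResult | None
    production_biases: list[MetaBias] | None
    wte_energy_series: list[np.ndarray]


def run_wte_stage(
    system: MCSystem,
    ladder: ReplicaLadder,
    wte: WTEParams,
    n_steps: int,
    seed: int,
) -> tuple[list[MetaBias], list[np.ndarray], list[object]]:
    """Per-replica metadynamics on the potential energy U (the WTE stage)."""
    ss = np.random.SeedSequence(seed)
    biases, series, states = [], [], []
    for i, (t, child) in enumerate(zip(ladder.temperatures, ss.spawn(len(ladder)))):
        rng = np.random.default_rng(child)

        class _EnergyCV:
            cv_names = ("energy",)

            def __init__(self, base):
                self._base = base

            def initial_state(self, r):
                return self._base.initial_state(r)

            def propose(self, st, r):
                return self._base.propose(st, r)

            def energy(self, st):
                return self._base.energy(st)

            def cvs(self, st):
                return np.array([self._base.energy(st)])

        run = run_metad(
            _EnergyCV(system),
            MetadParams(wte.height, (wte.sigma,), wte.stride, wte.bias_factor),
            n_steps,
            rng,
            temperature=t,
            record_stride=max(1, n_steps // 500),
        )
        biases.append(run.bias)
        series.append(run.energy_series)
        states.append(run.final_state)
    return biases, series, states


def run_ptmetad_wte(
    system: MCSystem,
    ladder: ReplicaLadder,
    wte: WTEParams,
    production: MetadParams,
    production_cv_indices: Sequence[int],
    n_wte_steps: int,
    n_production_cycles: int,
    steps_per_cycle: int,
    seed: int,
) -> PtmetadWteResult:
    """Two-stage protocol: WTE pre-run, then production metadynamics.

    Stage 1 deposits a well-tempered bias on U for every replica; stage 2
    freezes those biases and runs independent well-tempered metadynamics on
    the production CVs per replica, with bias-aware exchanges that include
    both the frozen WTE term and the growing CV bias.
    """
    wte_biases, wte_series, states = run_wte_stage(system, ladder, wte, n_wte_steps, seed)

    prod_biases = [
        MetaBias(tuple(system.cv_names[i] for i in production_cv_indices),
                 production.bias_factor, production.stride)
        for _ in range(len(ladder))
    ]
    idx = list(production_cv_indices)

    step_counter = {"n": 0}

    def effective_bias(rep: ReplicaState) -> float:
        v = wte_biases[rep.replica_id].evaluate([rep.potential_energy])
        if rep.cv_values is not None:
            v += prod_biases[rep.replica_id].evaluate(rep.cv_values[idx])
        return v

    # production: alternate short propagation bursts with deposits + swaps
    ss = np.random.SeedSequence(seed + 1)
    rep_rngs = [np.random.default_rng(s) for s in ss.spawn(len(ladder))]
    ex_rng = np.random.default_rng(ss.spawn(1)[0])
    replicas = []
    for i, t in enumerate(ladder.temperatures):
        st = states[i]
        replicas.append(ReplicaState(i, t, st, system.energy(st), prod_biases[i],
                                     np.asarray(system.cvs(st), dtype=float)))
    n_rep = len(replicas)
    stats = ExchangeStats(np.zeros(n_rep - 1), np.zeros(n_rep - 1))
    records: list[list[tuple[int, float, np.ndarray]]] = [[] for _ in range(n_rep)]

    for cycle in range(n_production_cycles):
        for i, rep in enumerate(replicas):
            _propagate(system, rep, steps_per_cycle, rep_rngs[i], effective_bias)
            records[i].append((cycle, rep.potential_energy, rep.cv_values.copy()))
        step_counter["n"] += steps_per_cycle
        if production.height > 0 and step_counter["n"] >= step_counter.get("next", production.stride):
            step_counter["next"] = step_counter["n"] + production.stride
            for i, rep in enumerate(replicas):
                prod_biases[i].deposit(rep.cv_values[idx], production.height,
                                       rep.temperature, step_counter["n"],
                                       production.sigma)
        parity = cycle % 2
        for pair in range(parity, n_rep - 1, 2):
            a, b = replicas[pair], replicas[pair + 1]

            def v_of(owner):
                def _v(r: ReplicaState) -> float:
                    probe = ReplicaState(owner.replica_id, owner.temperature,
                                         r.state, r.potential_energy,
                                         owner.bias, r.cv_values)
                    return effective_bias(probe)
                return _v

            p = exchange_probability(a, b, v_of(a), v_of(b))
            stats.attempts[pair] += 1
            if ex_rng.random() < p:
                stats.accepts[pair] += 1
                a.state, b.state = b.state, a.state
                a.potential_energy, b.potential_energy = (
                    b.potential_energy, a.potential_energy)
                a.cv_values, b.cv_values = b.cv_values, a.cv_values
            stats.log.append((cycle, pair, None))
    production_result = TremdResult(replicas, stats, records)
    return PtmetadWteResult(wte_biases, production_result, prod_biases, wte_series)


# ---------------------------------------------------------------------------
# umbrella sampling

@dataclass
class UmbrellaWindow:
    """One harmonic-restraint window along a reaction coordinate."""

    center: float
    force_constant: float
    series: np.ndarray          # retained CV samples (after discard)
    n_discarded: int
    temperature: float

    def __post_init__(self) -> None:
        if self.force_constant <= 0:
            raise ValueError("force constant must be > 0")
        if len(self.series) == 0:
            raise ValueError("window series empty after discard")


def run_umbrella(
    system: MCSystem,
    centers: Sequence[float],
    force_constant: float,
    n_steps: int,
    seed: int,
    cv_index: int = 0,
    discard_fraction: float = 0.25,
    temperature: float = 300.0,
    record_stride: int = 5,
) -> list[UmbrellaWindow]:
    """Harmonic umbrella sampling: 0.5 k (s - s0)^2 added to the energy.

    Windows are run independently (seeded per window); the configured
    initial fraction of each series is discarded as equilibration.
    """
    centers = list(centers)
    if sorted(centers) != centers:
        raise ValueError("centers must be sorted")
    if force_constant <= 0:
        raise ValueError("force constant must be > 0")
    beta = 1.0 / (KB * temperature)
    ss = np.random.SeedSequence(seed)
    windows = []
    for center, child in zip(centers, ss.spawn(len(centers))):
        rng = np.random.default_rng(child)
        state = system.initial_state(rng)
        e = system.energy(state)
        s = float(np.asarray(system.cvs(state), dtype=float)[cv_index])
        samples = []
        for step in range(1, n_steps + 1):
            cand = system.propose(state, rng)
            e_cand = system.energy(cand)
            s_cand = float(np.asarray(system.cvs(cand), dtype=float)[cv_index])
            d = (e_cand + 0.5 * force_constant * (s_cand - center) ** 2) - (
                e + 0.5 * force_constant * (s - center) ** 2)
            if d <= 0 or rng.random() < math.exp(-beta * d):
                state, e, s = cand, e_cand, s_cand
            if step % record_stride == 0:
                samples.append(s)
        n_disc = int(len(samples) * discard_fraction)
        retained = np.array(samples[n_disc:])
        if len(retained) < 100:
            import warnings

            warnings.warn(
                f"window at {center}: only {len(retained)} retained samples",
                stacklevel=2,
            )
        windows.append(UmbrellaWindow(center, force_constant, retained, n_disc,
                                      temperature))
    return windows
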