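"""Exact stochastic simulation (Gillespie/SSA) of the antenna model.

The state of one cable is its integer length plus the formin's chemical
state.  Four reactions connect states: POLYMERIZE (rate ``r``, ON only),
DEPOLYMERIZE (rate ``d`` whenever the length is positive), BIND (rate
``w*l``, ON only) and UNBIND (rate ``k_off``, OFF only).  Waiting times are
exponential in the total propensity and events are chosen proportionally to
their rates, so trajectories are statistically exact realizations of the
underlying master equation.

Steady-state sampling takes one length per independent trajectory at the
final time by default, which avoids within-trajectory autocorrelation;
thinned within-trajectory samples are opt-in.  Standard errors are
bootstrapped over trajectories.  Reproducibility: each trajectory gets its
own substream seeded from a ``numpy.random.SeedSequence`` spawn of the
top-level seed, so results do not depend on scheduling or call order.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .distributions import LengthDistribution
from .params import AntennaParameters, CableState, ForminState

logger = logging.getLogger(__name__)

_DEFAULT_BOOTSTRAP = 400


class Event(enum.Enum):
    POLYMERIZE = "polymerize"
    DEPOLYMERIZE = "depolymerize"
    BIND = "bind"
    UNBIND = "unbind"


def transition_rates(l: int, formin_on: bool, params: AntennaParameters) -> dict:
    """Reaction rates out of state (l, formin).  Single source of truth for
    the simulator and the master-equation generator, including the
    reflecting boundary at l = 0 (no depolymerization below zero length)."""
    if l < 0:
        raise ValueError("cable length must be non-negative")
    rates: dict[Event, float] = {}
    if formin_on:
        if params.r > 0:
            rates[Event.POLYMERIZE] = params.r
        if params.w * l > 0:
            rates[Event.BIND] = params.w * l
    else:
        if params.r_off > 0:
            rates[Event.POLYMERIZE] = params.r_off
        if params.k_off > 0:
            rates[Event.UNBIND] = params.k_off
    if l > 0 and params.d > 0:
        rates[Event.DEPOLYMERIZE] = params.d
    return rates


def propensities(state: CableState, params: AntennaParameters) -> dict:
    """Propensity of every possible event from ``state`` (all entries > 0)."""
    return transition_rates(state.l, state.formin is ForminState.ON, params)


@dataclass(frozen=True)
class Trajectory:
    """Event record of one stochastic realization.

    ``times[i]``, ``lengths[i]``, ``formin_on[i]`` give the state after the
    i-th event (record 0 is the initial condition).  ``absorbed`` flags a
    realization that reached a state with zero total propensity before
    ``t_end`` (possible only when r and d vanish at the boundary).
    """

    times: np.ndarray
    lengths: np.ndarray
    formin_on: np.ndarray
    params: AntennaParameters
    seed: int
    t_end: float
    absorbed: bool = False

    def __len__(self) -> int:
        return self.times.size

    def final_state(self) -> CableState:
        return CableState(
            int(self.lengths[-1]),
            ForminState.ON if self.formin_on[-1] else ForminState.OFF,
            float(self.times[-1]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "length_subunits": self.lengths,
                "state": np.where(self.formin_on, "on", "off"),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Independent 31-bit kernel seeds derived from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    raw = ss.generate_state(4 * n, dtype=np.uint32) & 0x7FFFFFFF
    seeds = pd.unique(raw)[:n]
    if seeds.size < n:  # astronomically unlikely; top up deterministically
        extra = ss.spawn(1)[0].generate_state(8 * n, dtype=np.uint32) & 0x7FFFFFFF
        seeds = pd.unique(np.concatenate([seeds, extra]))[:n]
    return seeds.astype(np.int64)


def _initial(initial: Optional[CableState]) -> tuple[int, bool]:
    if initial is None:
        return 0, True
    return initial.l, initial.formin is ForminState.ON


def simulate(
    params: AntennaParameters,
    t_end: float,
    seed: int,
    initial: Optional[CableState] = None,
    max_events: Optional[int] = None,
) -> Trajectory:
    """One exact realization from ``initial`` (default: empty cable, formin
    free) up to time ``t_end``, with the full event record."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    l0, on0 = _initial(initial)
    rate_scale = params.r + params.d + params.k_off + params.r_off + 1.0
    cap = int(min(max_events or (2.0 * rate_scale * t_end + 10_000), 2e8))
    kernel_seed = int(_spawn_seeds(seed, 1)[0])
    while True:
        ts, ls, ons, n, absorbed, overflow = _kernels.direct_trajectory(
            params.r, params.d, params.w, params.k_off, params.r_off,
            float(t_end), kernel_seed, l0, on0, cap,
        )
        if not overflow:
            break
        if max_events is not None or cap >= 2e8:
            raise RuntimeError(
                f"trajectory exceeded {cap} events before t_end={t_end}"
            )
        cap *= 2  # same kernel seed reproduces the identical prefix
    if absorbed:
        logger.warning("all propensities vanished at t=%g; trajectory ended early",
                       ts[n - 1])
    return Trajectory(
        ts[:n].copy(), ls[:n].copy(), ons[:n].astype(bool).copy(),
        params, seed, t_end, absorbed,
    )


def lengths_at_times(
    params: AntennaParameters,
    times: Sequence[float],
    n_traj: int,
    seed: int,
    initial: Optional[CableState] = None,
    method: str = "direct",
) -> np.ndarray:
    """Length of ``n_traj`` independent cables at each requested time.

    Returns an ``(n_traj, len(times))`` integer array.  ``method`` selects
    the event-by-event sampler (``"direct"``) or the exact
    switching-aggregated sampler (``"aggregated"``), which is orders of
    magnitude faster when inhibitor binding/unbinding dominates the event
    count.  Both produce the same law; see :mod:`antenna._kernels`.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(np.diff(times) < 0) or np.any(times < 0):
        raise ValueError("times must be non-negative and sorted ascending")
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if method not in ("direct", "aggregated"):
        raise ValueError(f"unknown method {method!r}")
    if method == "aggregated" and params.r_off != 0:
        raise ValueError("aggregated sampler requires r_off = 0")
    l0, on0 = _initial(initial)
    seeds = _spawn_seeds(seed, n_traj)
    out = np.empty((n_traj, times.size), dtype=np.int64)
    for i in range(n_traj):
        if method == "direct":
            out[i] = _kernels.direct_lengths_at_times(
                params.r, params.d, params.w, params.k_off, params.r_off,
                times, int(seeds[i]), l0, on0,
            )
        else:
            out[i] = _kernels.aggregated_lengths_at_times(
                params.r, params.d, params.w, params.k_off,
                times, int(seeds[i]), l0, on0,
            )
    return out


@dataclass(frozen=True)
class EnsembleSummary:
    """Steady-state sample over independent trajectories with bootstrap SEs."""

    params: AntennaParameters
    n_traj: int
    burn_in: float
    t_end: float
    seed: int
    method: str
    lengths: np.ndarray = field(repr=False)  # (n_traj, n_samples_per_traj)
    distribution: LengthDistribution = field(repr=False)
    mean: float
    mean_se: float
    variance: float
    variance_se: float
    cv2: float
    cv2_se: float

    def to_dict(self) -> dict:
        return {
            "params": {
                "r": self.params.r, "d": self.params.d, "w": self.params.w,
                "k_off": self.params.k_off, "r_off": self.params.r_off,
            },
            "n_traj": self.n_traj,
            "burn_in": self.burn_in,
            "t_end": self.t_end,
            "seed": self.seed,
            "method": self.method,
            "mean": self.mean, "mean_se": self.mean_se,
            "variance": self.variance, "variance_se": self.variance_se,
            "cv2": self.cv2, "cv2_se": self.cv2_se,
        }


def _bootstrap_ses(lengths: np.ndarray, seed: int, n_boot: int) -> tuple:
    """Bootstrap SEs of mean/variance/cv2, resampling whole trajectories so
    that within-trajectory autocorrelation never tightens the errors."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = lengths.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    flat = lengths[idx].reshape(n_boot, -1).astype(float)
    means = flat.mean(axis=1)
    variances = flat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2s = variances / means**2
    return (
        float(means.std(ddof=1)),
        float(variances.std(ddof=1)),
        float(np.nanstd(cv2s, ddof=1)),
    )


def sample_steady_state(
    params: AntennaParameters,
    n_traj: int,
    burn_in: float,
    t_end: float,
    seed: int,
    initial: Optional[CableState] = None,
    method: str = "direct",
    thin_spacing: Optional[float] = None,
    n_boot: int = _DEFAULT_BOOTSTRAP,
) -> EnsembleSummary:
    """Steady-state length statistics from independent trajectories.

    By default one sample is taken per trajectory at ``t_end`` (``burn_in``
    documents the time after which the process is treated as stationary and
    must precede ``t_end``).  With ``thin_spacing`` set, additional samples
    are taken every ``thin_spacing`` seconds from ``burn_in`` onward; these
    are autocorrelated, so all standard errors are still bootstrapped across
    whole trajectories.
    """
    if n_traj < 2:
        raise ValueError("n_traj must be >= 2")
    if burn_in >= t_end:
        raise ValueError("burn_in must be smaller than t_end")
    if thin_spacing is None:
        times = np.array([t_end])
    else:
        if thin_spacing <= 0:
            raise ValueError("thin_spacing must be positive")
        times = np.arange(burn_in + thin_spacing, t_end + 1e-9, thin_spacing)
        if times.size == 0:
            raise ValueError("no sample times between burn_in and t_end")
    lengths = lengths_at_times(params, times, n_traj, seed, initial, method)
    dist = LengthDistribution.from_samples(lengths.ravel())
    flat = lengths.ravel().astype(float)
    mean = float(flat.mean())
    variance = float(flat.var(ddof=1))
    cv2 = variance / mean**2 if mean > 0 else float("nan")
    mean_se, var_se, cv2_se = _bootstrap_ses(lengths, seed, n_boot)
    return EnsembleSummary(
        params=params, n_traj=n_traj, burn_in=burn_in, t_end=t_end, seed=seed,
        method=method, lengths=lengths, distribution=dist,
        mean=mean, mean_se=mean_se, variance=variance, variance_se=var_se,
        cv2=cv2, cv2_se=cv2_se,
    )


def time_resolved_distributions(
    params: AntennaParameters,
    times: Sequence[float],
    n_traj: int,
    seed: int,
    initial: Optional[CableState] = None,
    method: str = "direct",
) -> list[LengthDistribution]:
    """Empirical length distribution at each requested time, from ``n_traj``
    independent trajectories started from ``initial`` (default length 0)."""
    times = np.asarray(times, dtype=float)
    samples = lengths_at_times(params, times, n_traj, seed, initial, method)
    return [LengthDistribution.from_samples(samples[:, j]) for j in range(times.size)]
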