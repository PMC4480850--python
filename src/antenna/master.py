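"""Truncated master-equation solver: the numerical ground truth.

The chemical master equation for the antenna model couples, for each length
``l``, the probabilities of the formin-free (ON) and inhibited (OFF) states:

    dP_on(l)/dt  = r P_on(l-1) - r P_on(l) + d P_on(l+1) - d P_on(l)
                   + k_off P_off(l) - w l P_on(l)
    dP_off(l)/dt = d P_off(l+1) - d P_off(l) - k_off P_off(l) + w l P_on(l)

(for l > 0; at l = 0 depolymerization is disabled — the same reflecting
boundary used by the stochastic simulator).  Truncating the state space at
``l_max`` (upward transitions out of ``l_max`` removed) turns this into a
finite sparse linear system whose null vector is the stationary law and
whose exponential action gives transients.  This solver is exact up to
truncation, which is auto-grown until the stationary boundary mass is
negligible, and serves as the independent check on both the analytic
recursion and the stochastic simulation.

Convention: the generator ``Q`` has ``Q[i, j]`` equal to the rate from state
``j`` to state ``i``; columns sum to zero and ``dP/dt = Q @ P``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .analytic import mean_length_balance
from .distributions import LengthDistribution, Provenance
from .gillespie import Event, transition_rates
from .params import AntennaParameters

#: Stationary mass allowed within _BOUNDARY_WINDOW states of the truncation
#: before the state space is considered too small.
_BOUNDARY_MASS_TOL = 1e-10
_BOUNDARY_WINDOW = 50
_MAX_STATES = 4_000_000


def _state_index(l: int, on: bool) -> int:
    return 2 * l + (0 if on else 1)


@dataclass(frozen=True)
class TruncatedCME:
    """Sparse generator of the master equation truncated at ``l_max``.

    States are indexed ``2*l`` (formin ON) and ``2*l + 1`` (formin OFF) for
    ``l`` in ``0..l_max``.
    """

    params: AntennaParameters
    l_max: int
    generator: sp.csc_matrix

    @property
    def n_states(self) -> int:
        return 2 * (self.l_max + 1)

    def marginal_lengths(self, vec: np.ndarray) -> np.ndarray:
        """Collapse a state vector onto lengths: P(l) = P_on(l) + P_off(l)."""
        return vec.reshape(self.l_max + 1, 2).sum(axis=1)

    def split(self, vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        resh = vec.reshape(self.l_max + 1, 2)
        return resh[:, 0].copy(), resh[:, 1].copy()


def build_generator(params: AntennaParameters, l_max: int) -> TruncatedCME:
    """Assemble the truncated generator from the simulator's reaction rules.

    Every transition is taken from :func:`antenna.gillespie.transition_rates`
    so the oracle and the stochastic simulation share one source of truth for
    the reaction network and the l = 0 boundary convention.
    """
    if l_max < 10:
        raise ValueError("l_max must be at least 10")
    rows, cols, vals = [], [], []

    def add(src: int, dst: int, rate: float) -> None:
        rows.append(dst)
        cols.append(src)
        vals.append(rate)
        rows.append(src)
        cols.append(src)
        vals.append(-rate)

    for l in range(l_max + 1):
        for on in (True, False):
            src = _state_index(l, on)
            for event, rate in transition_rates(l, on, params).items():
                if event is Event.POLYMERIZE:
                    if l == l_max:
                        continue  # truncation: no upward flux out of l_max
                    dst = _state_index(l + 1, on)
                elif event is Event.DEPOLYMERIZE:
                    dst = _state_index(l - 1, on)
                elif event is Event.BIND:
                    dst = _state_index(l, False)
                else:  # UNBIND
                    dst = _state_index(l, True)
                add(src, dst, rate)

    n = 2 * (l_max + 1)
    generator = sp.csc_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
    return TruncatedCME(params=params, l_max=l_max, generator=generator)


def boundary_mass(cme: TruncatedCME, length_dist: np.ndarray) -> float:
    """Stationary mass within `_BOUNDARY_WINDOW` lengths of the truncation."""
    lo = max(cme.l_max - _BOUNDARY_WINDOW, 0)
    return float(np.asarray(length_dist)[lo:].sum())


def stationary_distribution(cme: TruncatedCME) -> LengthDistribution:
    """Stationary length distribution of a truncated generator.

    Solves ``Q p = 0`` by pinning the probability of a reference state near
    the bulk of the distribution to 1 (replacing that state's redundant
    balance equation with ``p[ref] = 1``) and normalizing afterwards.  The
    sparse replacement keeps the generator banded, so the LU factorization
    stays cheap; pinning near the mode keeps all other entries <= O(1), so
    far tails underflow harmlessly instead of overflowing.  Raises if the
    truncation holds non-negligible stationary mass near ``l_max``; use
    :func:`solve_stationary` for automatic growth of the state space.
    """
    n = cme.n_states
    try:
        mean_est = mean_length_balance(cme.params)
    except ValueError:
        mean_est = 0.0
    ref = _state_index(min(max(int(mean_est), 0), cme.l_max), True)
    A = sp.lil_matrix(cme.generator)
    A.rows[ref] = [ref]
    A.data[ref] = [1.0]
    b = np.zeros(n)
    b[ref] = 1.0
    vec = spla.spsolve(sp.csc_matrix(A), b)
    if not np.all(np.isfinite(vec)):
        raise RuntimeError(f"stationary solve failed for {cme.params}")
    vec = np.clip(vec, 0.0, None)
    vec /= vec.sum()
    lengths = cme.marginal_lengths(vec)
    if boundary_mass(cme, lengths) > _BOUNDARY_MASS_TOL:
        raise RuntimeError(
            f"truncation at l_max={cme.l_max} holds "
            f"{boundary_mass(cme, lengths):.2e} stationary mass; increase l_max"
        )
    p_on, p_off = cme.split(vec)
    return LengthDistribution(lengths, Provenance.ORACLE, p_on=p_on, p_off=p_off)


def _initial_l_max(params: AntennaParameters) -> int:
    try:
        mean = mean_length_balance(params)
    except ValueError:
        mean = 0.0
    if mean == 0.0 and params.d > 0 and 0 < params.r < params.d:
        mean = (params.r / params.d) / (1.0 - params.r / params.d)
    return int(2 * mean) + 200


def solve_stationary(
    params: AntennaParameters,
    l_max: int | None = None,
) -> tuple[LengthDistribution, TruncatedCME]:
    """Stationary distribution with the truncation grown until the boundary
    mass is below tolerance."""
    l_max = max(l_max or _initial_l_max(params), 10)
    while True:
        cme = build_generator(params, l_max)
        try:
            return stationary_distribution(cme), cme
        except RuntimeError:
            if 2 * (l_max + 1) > _MAX_STATES:
                raise
            l_max = int(1.5 * l_max) + 100


def transient_solution(
    cme: TruncatedCME,
    times: Sequence[float],
    initial: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> list[LengthDistribution]:
    """Integrate ``dP/dt = Q P`` and return the length distribution at each
    requested time.

    The default initial condition is a point mass on (length 0, formin ON),
    matching the simulation protocol.  The system is stiff (rates spanning
    orders of magnitude), so a BDF integrator with the exact sparse Jacobian
    is used.  Probability conservation is enforced to 1e-8 and each output
    is renormalized before return.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be non-negative and sorted ascending")
    if initial is None:
        p0 = np.zeros(cme.n_states)
        p0[_state_index(0, True)] = 1.0
    else:
        p0 = np.asarray(initial, dtype=float)
        if p0.size != cme.n_states or abs(p0.sum() - 1.0) > 1e-9:
            raise ValueError("initial must be a normalized state vector")

    Q = sp.csr_matrix(cme.generator)
    out: list[LengthDistribution] = []
    eval_times = times.copy()
    prepend_zero = eval_times[0] == 0.0
    if prepend_zero:
        out.append(
            LengthDistribution(cme.marginal_lengths(p0), Provenance.ORACLE,
                               *cme.split(p0))
        )
        eval_times = eval_times[1:]
    if eval_times.size:
        sol = solve_ivp(
            lambda t, y: Q @ y,
            (0.0, float(eval_times[-1])),
            p0,
            method="BDF",
            t_eval=eval_times,
            jac=cme.generator,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"transient integration failed: {sol.message}")
        for j in range(eval_times.size):
            vec = sol.y[:, j]
            mass_defect = abs(vec.sum() - 1.0)
            if mass_defect > 1e-8:
                raise RuntimeError(
                    f"probability mass defect {mass_defect:.2e} at "
                    f"t={eval_times[j]}; tighten tolerances"
                )
            vec = np.clip(vec, 0.0, None)
            vec /= vec.sum()
            out.append(
                LengthDistribution(cme.marginal_lengths(vec), Provenance.ORACLE,
                                   *cme.split(vec))
            )
    return out
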