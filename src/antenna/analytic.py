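"""Closed-form and recursive analytic results for the antenna model.

The central quantity is the length-averaged polymerization rate

    rbar(l) = r * k_off / (k_off + w*l),

the rate r weighted by the fraction of time the formin spends uninhibited at
cable length ``l``.  Balancing ``rbar`` against the constant disassembly rate
``d`` gives the steady-state mean length

    <l> = (k_off / w) * (r/d - 1),

and, in the fast-switching regime (inhibitor binding/unbinding much faster
than assembly/disassembly), detailed balance

    P(l) * rbar(l) = P(l+1) * d

determines the full stationary length distribution.  The detailed-balance
recursion is the normative analytic distribution here; the equivalent
Gamma-function form is provided as a cross-check.  Outside fast switching the
recursion keeps the correct mean but underestimates the variance — the
master-equation oracle (:mod:`antenna.master`) and the stochastic simulation
(:mod:`antenna.gillespie`) are exact in all regimes.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.special import gammaln, logsumexp

from .distributions import LengthDistribution, Provenance
from .params import AntennaParameters

logger = logging.getLogger(__name__)

#: Hard cap on the recursion support; parameters needing more states than
#: this to capture the stationary tail are rejected with an error.
_L_MAX_HARD = 5_000_000

#: Stop extending the support once the largest probability over the last
#: this-many states falls below _TAIL_DROP times the running maximum.
_TAIL_WINDOW = 50
_TAIL_DROP = 1e-14


def binding_rate(l: float, params: AntennaParameters) -> float:
    """Length-dependent inhibitor-binding rate ``k_on(l) = w*l`` (1/s)."""
    return params.binding_rate(l)


def average_polymerization_rate(l: float, params: AntennaParameters) -> float:
    """Time-averaged assembly rate at length ``l`` (subunits/s).

    The formin spends a fraction ``k_off/(k_off + w*l)`` of its time
    uninhibited, so the average rate is ``r`` scaled by that fraction (plus
    the residual ``r_off`` weighted by the inhibited fraction, zero by
    default).  Strictly decreasing in ``l`` when ``w > 0``.
    """
    if l < 0:
        raise ValueError("cable length must be non-negative")
    k_on = params.w * l
    denom = params.k_off + k_on
    if denom == 0:  # no switching at all: formin stays in its current state
        return params.r
    if params.k_off == 0 and k_on > 0:
        # permanently inhibited once any inhibitor arrives
        logger.warning("k_off = 0 with w*l > 0: formin permanently inhibited")
        return params.r_off
    return (params.r * params.k_off + params.r_off * k_on) / denom


def mean_length_balance(params: AntennaParameters) -> float:
    """Steady-state mean length (subunits) from rate balance rbar(<l>) = d.

    Returns ``(k_off/w) * (r/d - 1)``.  For ``r <= d`` there is no positive
    balance point (growth never outpaces disassembly) and 0 is returned with
    a warning; the stationary law in that regime is the geometric law of the
    plain birth-death process.
    """
    if params.d <= 0 or params.w <= 0 or params.k_off <= 0:
        raise ValueError("mean_length_balance requires d, w, k_off > 0")
    if params.r < params.d:
        logger.warning(
            "r < d: no net growth; the mean-length balance has no positive root"
        )
        return 0.0
    return (params.k_off / params.w) * (params.r / params.d - 1.0)


def solve_for_d(r: float, k_off: float, w: float, target_mean: float) -> float:
    """Depolymerization rate (subunits/s) producing a given mean length.

    Inverts the mean-length balance: ``d = r / (1 + w*target_mean/k_off)``.
    """
    if min(r, k_off, w) <= 0 or target_mean <= 0:
        raise ValueError("solve_for_d requires r, k_off, w, target_mean > 0")
    return r / (1.0 + w * target_mean / k_off)


def solve_for_w(r: float, d: float, k_off: float, target_mean: float) -> float:
    """Delivery rate constant (1/(subunit*s)) producing a given mean length.

    Inverts the mean-length balance: ``w = (k_off/target_mean) * (r/d - 1)``.
    Used to hold the mean fixed while the switching speed (k_off) varies.
    """
    if d <= 0 or k_off <= 0 or target_mean <= 0:
        raise ValueError("solve_for_w requires d, k_off, target_mean > 0")
    if r <= d:
        raise ValueError("solve_for_w requires r > d (no positive w otherwise)")
    return (k_off / target_mean) * (r / d - 1.0)


def _log_growth_ratio(l: np.ndarray, params: AntennaParameters) -> np.ndarray:
    """log of the detailed-balance ratio P(l+1)/P(l) = rbar(l)/d."""
    k_on = params.w * l
    num = params.r * params.k_off + params.r_off * k_on
    denom = params.d * (params.k_off + k_on)
    if params.k_off == 0:
        # no switching at l = 0: the formin stays ON and grows at rate r
        num = np.where(l == 0, params.r, num)
        denom = np.where(l == 0, params.d, denom)
    with np.errstate(divide="ignore"):
        return np.log(num) - np.log(denom)


def stationary_distribution_recursive(
    params: AntennaParameters,
    l_max: int | None = None,
    tail_tol: float = 1e-10,
) -> LengthDistribution:
    """Detailed-balance stationary length distribution (fast-switching limit).

    Accumulates ``log P(l+1) = log P(l) + log rbar(l) - log d`` in log space
    and normalizes once, avoiding under/overflow at means of thousands of
    subunits.  The support is extended automatically until the probability
    over the last `_TAIL_WINDOW` states drops `_TAIL_DROP`-fold below the
    mode (and the geometric tail bound is below ``tail_tol``), unless a fixed
    ``l_max`` is requested.
    """
    if params.d <= 0:
        raise ValueError("stationary distribution requires d > 0")
    if params.w == 0 and params.r >= params.d:
        raise ValueError(
            "no stationary distribution: w = 0 with r >= d grows without bound"
        )
    if params.k_off == 0 and params.w > 0 and params.r_off >= params.d:
        raise ValueError("k_off = 0 with r_off >= d has no stationary distribution")

    if l_max is not None:
        l = np.arange(l_max)
        logp = np.concatenate(([0.0], np.cumsum(_log_growth_ratio(l, params))))
    else:
        chunk = 8192
        blocks = [np.array([0.0])]
        last = 0.0
        running_max = 0.0
        start = 0
        while True:
            l = np.arange(start, start + chunk)
            block = last + np.cumsum(_log_growth_ratio(l, params))
            blocks.append(block)
            last = block[-1]
            running_max = max(running_max, float(block.max()))
            tail_ok = block[-_TAIL_WINDOW:].max() < running_max + math.log(_TAIL_DROP)
            ratio = math.exp(_log_growth_ratio(np.array([start + chunk - 1]), params)[0])
            geo_ok = ratio < 1 and (
                math.exp(block[-1] - running_max) * ratio / (1 - ratio) < tail_tol
            )
            if tail_ok and geo_ok:
                break
            start += chunk
            if start > _L_MAX_HARD:
                raise RuntimeError(
                    f"stationary support exceeds {_L_MAX_HARD} subunits for "
                    f"parameters {params}; tail criterion unreachable"
                )
        logp = np.concatenate(blocks)

    logz = logsumexp(logp)
    return LengthDistribution(np.exp(logp - logz), Provenance.ANALYTIC_RECURSION)


def stationary_distribution_closed_form(
    params: AntennaParameters,
    l_max: int | None = None,
) -> LengthDistribution:
    """Gamma-function form of the detailed-balance distribution.

    Iterating the detailed-balance condition from length 0 gives

        P(l) ∝ (r/d)^l (k_off/w)^l Γ(k_off/w) / Γ(k_off/w + l),

    evaluated here through log-Gamma and normalized numerically over the
    support.  Provided as a cross-check of the recursion (the two agree to
    floating-point rounding by construction); the recursion is normative.
    Requires full inhibition (``r_off = 0``), where the product form above
    telescopes.
    """
    if params.r_off != 0:
        raise ValueError("closed form requires r_off = 0")
    if params.w <= 0 or params.k_off <= 0 or params.d <= 0 or params.r <= 0:
        raise ValueError("closed form requires r, d, w, k_off > 0")
    if l_max is None:
        l_max = stationary_distribution_recursive(params).l_max
    a = params.k_off / params.w
    l = np.arange(l_max + 1)
    logp = (
        l * (math.log(params.r) - math.log(params.d))
        + l * math.log(a)
        + gammaln(a)
        - gammaln(a + l)
    )
    return LengthDistribution(
        np.exp(logp - logsumexp(logp)), Provenance.CLOSED_FORM
    )


def geometric_characteristic_length(params: AntennaParameters) -> float:
    """Characteristic length ``1/log(d/r)`` of the w = 0, r < d geometric law."""
    if not (0 < params.r < params.d):
        raise ValueError("geometric regime requires 0 < r < d")
    return 1.0 / math.log(params.d / params.r)
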