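"""Back-of-envelope in-vivo calculations behind the model's parameter values.

Two groups of deterministic estimates live here:

* The motor-counting argument that fixes the delivery rate constant ``w``
  from the observed number of myosin+Smy1 complexes on a cable, plus the
  mean-length inversion that fixes the depolymerization rate ``d`` — the
  chain that produces the yeast parameter presets.
* Order-of-magnitude estimates for two *alternative* length-control
  mechanisms (a finite actin monomer pool and cofilin-mediated severing),
  both of which predict steady-state cables several-fold longer than
  observed, which is the quantitative argument that neither suffices on its
  own.

All functions are pure: the same inputs always give the same outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .analytic import solve_for_d
from .params import (
    SUBUNIT_LENGTH_UM,
    SUBUNITS_PER_MICRON,
    microns_to_subunits,
    subunits_to_microns,
)

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23
_LITRES_PER_CUBIC_MICRON = 1e-15


@dataclass(frozen=True)
class MotorTransportObservables:
    """Observables of Smy1 delivery used to estimate ``w``.

    ``n_tot``: myosin+Smy1 complexes per cable (count); ``cable_length_um``:
    cable length L (um); ``myosin_speed_um_s``: motor speed V (um/s);
    ``subunit_um``: subunit size L0 (um).  The per-subunit stepping rate is
    ``v = V / L0``.
    """

    n_tot: float
    cable_length_um: float
    myosin_speed_um_s: float
    subunit_um: float = SUBUNIT_LENGTH_UM

    def __post_init__(self) -> None:
        if min(self.n_tot, self.cable_length_um, self.myosin_speed_um_s,
               self.subunit_um) < 0:
            raise ValueError("observables must be non-negative")
        if self.myosin_speed_um_s < 1.0:
            # delivery must outpace cable elongation for the antenna feedback
            # to reach the formin at all
            logger.warning(
                "myosin speed %.2f um/s < 1 um/s: Smy1 delivery would not "
                "outrun cable elongation", self.myosin_speed_um_s,
            )

    @property
    def stepping_rate(self) -> float:
        """Per-subunit stepping rate v = V/L0 (1/s)."""
        return self.myosin_speed_um_s / self.subunit_um


@dataclass(frozen=True)
class FinitePoolParameters:
    """Inputs to the finite-monomer-pool estimate.

    ``n_actin``: total actin molecules in the mother cell; ``n_cables``:
    number of cables; ``filaments_per_cable``: filaments bundled per cable;
    ``r_prime``: per-free-monomer assembly rate (1/s), equal to ``r/N`` when
    all actin is monomeric; ``d``: depolymerization rate (subunits/s).
    """

    n_actin: float
    n_cables: float
    filaments_per_cable: float
    r_prime: float
    d: float

    def __post_init__(self) -> None:
        if min(self.n_actin, self.n_cables, self.filaments_per_cable,
               self.r_prime, self.d) <= 0:
            raise ValueError("finite-pool parameters must be positive")


@dataclass(frozen=True)
class SeveringParameters:
    """Polymerization rate (um/s) and severing rate per micron (1/(um*s))."""

    r_um_s: float
    s_per_um_s: float

    def __post_init__(self) -> None:
        if self.r_um_s <= 0 or self.s_per_um_s <= 0:
            raise ValueError("severing parameters must be positive")


# --- motor transport / w estimate -------------------------------------------

def motor_density_profile(x: float, kon0: float, v: float) -> float:
    """Expected motors at subunit ``x`` of the cable: ``x * kon0 / v``.

    Motors land uniformly (rate ``kon0`` per subunit, proportional to Smy1
    concentration) and step toward the formin at rate ``v`` without
    detaching, so the flux through subunit ``x`` balances the landings on
    the ``x`` subunits behind it: a linear density ramp.
    """
    if x < 0:
        raise ValueError("subunit index must be non-negative")
    if kon0 <= 0 or v <= 0:
        raise ValueError("kon0 and v must be positive")
    return x * kon0 / v


def total_motors(l: int, kon0: float, v: float) -> float:
    """Expected motors on a cable of ``l`` subunits: ``(kon0/v) l(l+1)/2``
    (the linear density profile summed over all subunits)."""
    if l < 0:
        raise ValueError("cable length must be non-negative")
    return kon0 / v * l * (l + 1) / 2.0


def estimate_w(obs: MotorTransportObservables) -> float:
    """Delivery rate constant ``w`` (1/(subunit*s)) from motor counting.

    In micron units the total-motor relation reads
    ``N_tot = w L (L + L0) / (2 L0 V)``; solving for ``w`` gives
    ``w = 2 L0 V N_tot / (L (L + L0))``.  With the observed N_tot = 5
    complexes on an L = 5 um cable and V = 3.5 um/s this yields 0.0038,
    i.e. 0.004 to one significant figure.
    """
    L = obs.cable_length_um
    if L <= 0:
        raise ValueError("cable length must be positive")
    return 2.0 * obs.subunit_um * obs.myosin_speed_um_s * obs.n_tot / (
        L * (L + obs.subunit_um)
    )


# --- alternative mechanisms --------------------------------------------------

def finite_pool_mean(p: FinitePoolParameters) -> float:
    """Mean cable length (subunits) when growth is limited only by monomer
    depletion: ``<n> = (N - d/r') / (N_c * D)``.

    Returns 0 with a warning when the pool cannot sustain any cable
    (``N <= d/r'``).
    """
    if p.n_actin <= p.d / p.r_prime:
        logger.warning("monomer pool too small to sustain cables; mean is 0")
        return 0.0
    return (p.n_actin - p.d / p.r_prime) / (p.n_cables * p.filaments_per_cable)


def actin_count_from_concentration(conc_molar: float, radius_um: float) -> float:
    """Total actin molecules in a sphere of ``radius_um`` at ``conc_molar``.

    With the nominal 10 uM concentration and 2.5 um mother-cell radius this
    evaluates to ~3.9e5 molecules; agreement with the conventionally quoted
    3e5 is order-of-magnitude only, and both numbers should be reported
    rather than silently reconciled.
    """
    if conc_molar < 0 or radius_um < 0:
        raise ValueError("concentration and radius must be non-negative")
    volume_litres = 4.0 / 3.0 * math.pi * radius_um**3 * _LITRES_PER_CUBIC_MICRON
    return conc_molar * AVOGADRO * volume_litres


def severing_depolymerization_rate(l_um: float, s_per_um_s: float) -> float:
    """Effective subunit-loss rate (um/s) from length-dependent severing.

    Severing anywhere along a cable of length ``l`` occurs at rate ``s*l``
    and removes on average half the cable, so the loss rate is ``s*l^2/2``.
    """
    if l_um < 0:
        raise ValueError("length must be non-negative")
    return s_per_um_s * l_um**2 / 2.0


def severing_steady_length(p: SeveringParameters) -> float:
    """Steady-state length (um) balancing growth against severing loss:
    ``l = sqrt(2 r / s)``."""
    return math.sqrt(2.0 * p.r_um_s / p.s_per_um_s)


# --- unit conversions and reporting ------------------------------------------

def micron_subunit_conversions(value: float, direction: str) -> float:
    """Convert between microns and subunits at the fixed 370 subunits/um.

    ``direction`` is ``"um_to_subunits"`` or ``"subunits_to_um"``.
    """
    if direction == "um_to_subunits":
        return microns_to_subunits(value)
    if direction == "subunits_to_um":
        return subunits_to_microns(value)
    raise ValueError(f"unknown direction {direction!r}")


def round_to_sig_figs(value: float, n: int) -> float:
    """Round ``value`` to ``n`` significant figures."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, -exponent + n - 1)


#: Nominal in-vivo observables behind the yeast presets and the alternative
#: mechanism estimates.
NOMINAL_OBSERVABLES = {
    "max_growth_rate_um_s": 1.0,   # fastest observed cable elongation
    "smy1_pause_s": 1.0,           # Smy1 dwell at the bud neck -> k_off
    "n_tot_complexes": 5.0,        # myosin+Smy1 complexes per cable
    "cable_length_um": 5.0,        # typical cable length
    "myosin_speed_um_s": 3.5,      # anterograde motor speed
    "actin_conc_molar": 10e-6,     # cytoplasmic actin concentration
    "mother_radius_um": 2.5,
    "n_actin_nominal": 3e5,        # conventionally quoted pool size
    "n_cables": 10.0,
    "filaments_per_cable": 4.0,
    "r_prime_per_s": 1.2e-3,       # per-monomer assembly rate
    "severing_rate_per_um_s": 1e-3,
}


def parameter_provenance(observables: dict | None = None) -> list[dict]:
    """Full derivation chain from observables to the four model rates and
    the alternative-mechanism estimates, one row per quantity.

    Each row records the formula, the full-precision value, and the value
    rounded the way each quantity is conventionally reported (w to one
    significant figure, d in um/s to two decimals, lengths to the nearest
    micron).
    """
    obs = dict(NOMINAL_OBSERVABLES)
    if observables:
        obs.update(observables)

    r_sub = microns_to_subunits(obs["max_growth_rate_um_s"])
    k_off = 1.0 / obs["smy1_pause_s"]
    motor_obs = MotorTransportObservables(
        n_tot=obs["n_tot_complexes"],
        cable_length_um=obs["cable_length_um"],
        myosin_speed_um_s=obs["myosin_speed_um_s"],
    )
    w = estimate_w(motor_obs)
    w_rounded = round_to_sig_figs(w, 1)
    target_mean = microns_to_subunits(obs["cable_length_um"])
    d_sub = solve_for_d(r_sub, k_off, w_rounded, target_mean)
    d_um = subunits_to_microns(d_sub)

    n_from_conc = actin_count_from_concentration(
        obs["actin_conc_molar"], obs["mother_radius_um"]
    )
    pool = FinitePoolParameters(
        n_actin=obs["n_actin_nominal"],
        n_cables=obs["n_cables"],
        filaments_per_cable=obs["filaments_per_cable"],
        r_prime=obs["r_prime_per_s"],
        d=round(d_sub),
    )
    pool_mean_sub = finite_pool_mean(pool)
    pool_mean_um = subunits_to_microns(pool_mean_sub)
    sever = SeveringParameters(
        r_um_s=obs["max_growth_rate_um_s"],
        s_per_um_s=obs["severing_rate_per_um_s"],
    )
    sever_um = severing_steady_length(sever)

    return [
        {"quantity": "r", "units": "subunits/s",
         "formula": "max growth rate x 370 subunits/um",
         "value": r_sub, "rounded": r_sub},
        {"quantity": "k_off", "units": "1/s",
         "formula": "1 / (Smy1 pause time)",
         "value": k_off, "rounded": k_off},
        {"quantity": "w", "units": "1/(subunit s)",
         "formula": "2 L0 V N_tot / (L (L + L0))",
         "value": w, "rounded": w_rounded},
        {"quantity": "d", "units": "subunits/s",
         "formula": "r / (1 + w <l> / k_off)",
         "value": d_sub, "rounded": round(d_sub)},
        {"quantity": "d", "units": "um/s",
         "formula": "d / 370",
         "value": d_um, "rounded": round(d_um, 2)},
        {"quantity": "actin pool N", "units": "molecules",
         "formula": "conc x N_A x (4/3) pi R^3",
         "value": n_from_conc, "rounded": round_to_sig_figs(n_from_conc, 1)},
        {"quantity": "finite-pool mean length", "units": "um",
         "formula": "(N - d/r') / (N_c D) / 370",
         "value": pool_mean_um, "rounded": round(pool_mean_um)},
        {"quantity": "severing steady length", "units": "um",
         "formula": "sqrt(2 r / s)",
         "value": sever_um, "rounded": round(sever_um)},
    ]
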