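"""Kinetic parameters, unit conventions, and state types for the antenna model.

The antenna model describes a single effective polymer (an actin cable in
budding yeast) assembled by a formin that is anchored at the bud neck.  The
formin switches between an uninhibited *ON* state, in which it adds subunits
at rate ``r``, and an inhibited *OFF* state in which it adds none.  Inhibitor
(Smy1) is delivered by myosin motors walking along the cable, so the
inhibition rate grows linearly with cable length, ``k_on(l) = w*l``; the
inhibitor unbinds at rate ``k_off``.  Subunits are removed from the far end at
a constant rate ``d`` regardless of the formin state.

All rates are expressed per second, with length counted in actin subunits.
Micron values always use the fixed conversion of 370 subunits per micron.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

#: Fixed conversion used throughout: one micron of cable is 370 actin subunits.
#: This integer convention is used verbatim (not 1/0.0027, which is 370.37).
SUBUNITS_PER_MICRON = 370

#: Size of one actin subunit along the cable axis, in microns (2.7 nm).
SUBUNIT_LENGTH_UM = 0.0027


def microns_to_subunits(value_um: float) -> float:
    """Convert a length (or speed per second) from microns to subunits."""
    if value_um < 0:
        raise ValueError("length must be non-negative")
    return value_um * SUBUNITS_PER_MICRON


def subunits_to_microns(value_subunits: float) -> float:
    """Convert a length (or speed per second) from subunits to microns."""
    if value_subunits < 0:
        raise ValueError("length must be non-negative")
    return value_subunits / SUBUNITS_PER_MICRON


class ForminState(enum.Enum):
    """Chemical state of the formin at the growing cable end."""

    ON = "on"    # inhibitor-free; polymerization proceeds at rate r
    OFF = "off"  # inhibitor bound; polymerization paused

    def __bool__(self) -> bool:  # truthy == growing-capable
        return self is ForminState.ON


@dataclass(frozen=True)
class AntennaParameters:
    """The four kinetic rates of the antenna model.

    Parameters
    ----------
    r
        Polymerization rate when the formin is free (subunits/s).
    d
        Depolymerization rate at the far end (subunits/s); active in both
        formin states.
    w
        Per-subunit inhibitor-delivery rate constant (1/(subunit*s)), so the
        length-dependent inhibition rate is ``k_on(l) = w*l``.  Proportional
        to the cytoplasmic Smy1 concentration.
    k_off
        Inhibitor unbinding rate from the formin (1/s).  Proportional to the
        Smy1-formin dissociation constant.
    r_off
        Residual polymerization rate while inhibited (subunits/s).  The model
        assumes full inhibition (0); exposed because the conclusions only
        require ``r_off < r``.
    """

    r: float
    d: float
    w: float
    k_off: float
    r_off: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r", "d", "w", "k_off", "r_off"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {value!r}")

    def binding_rate(self, l: float) -> float:
        """Length-dependent inhibitor-binding rate ``k_on(l) = w*l`` (1/s)."""
        if l < 0:
            raise ValueError("cable length must be non-negative")
        return self.w * l

    def with_(self, **changes: float) -> "AntennaParameters":
        """Return a copy with the given rates replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class CableState:
    """Instantaneous state of one cable: length, formin state, elapsed time."""

    l: int
    formin: ForminState = ForminState.ON
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError("cable length must be non-negative")
        if self.t < 0:
            raise ValueError("time must be non-negative")


# --- Named parameter presets -------------------------------------------------
#
# The in-vivo yeast set comes from the parameter estimation chain implemented
# in :mod:`antenna.estimates`: r = 1 um/s = 370 subunits/s (maximum observed
# cable growth rate), k_off = 1/s (observed ~1 s pause of Smy1 at the bud
# neck), w = 0.004 1/(subunit*s) (motor counting), and d fixed by requiring a
# 5 um mean length.  The inversion gives d = 44.05 subunits/s (0.12 um/s at
# two decimals); simulations conventionally use the rounded d = 45.

#: Yeast parameters with the conventional rounded depolymerization rate.
YEAST = AntennaParameters(r=370.0, d=45.0, w=0.004, k_off=1.0)

#: Yeast parameters with d kept at full precision from the mean-length inversion.
YEAST_EXACT_D = AntennaParameters(r=370.0, d=370.0 / 8.4, w=0.004, k_off=1.0)

#: Fast-switching regime: inhibitor binding/unbinding far faster than
#: assembly/disassembly, where the detailed-balance distribution is exact.
FAST_SWITCHING = AntennaParameters(r=0.2, d=0.001, w=10.0, k_off=40.0)

#: Slow-switching regime: switching comparable to assembly/disassembly, where
#: the detailed-balance distribution underestimates the variance.
SLOW_SWITCHING = AntennaParameters(r=200.0, d=100.0, w=0.005, k_off=4.0)
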