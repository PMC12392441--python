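"""Closed-form pseudo-first-order kinetics of chain scission.

Hydroxyl radical attack on a dissolved polymer backbone is modeled as a
pseudo-first-order process in the monomeric units: with a second-order rate
constant ``kM`` and a steady-state radical concentration ``[OH]_ss``, the
per-unit rate is ``k1 = kM * [OH]_ss``.  Assuming every monomeric unit of a
chain reacts with equal probability, the average number of scissions per
initial chain after time ``t`` is

    SiC(t) = (1 - exp(-k1 * t)) * Mn(t0) / MW_monomer

i.e. the fraction of reacted units times the initial average degree of
polymerization.  Because every scission turns one chain into two, the
number-average molecular weight follows

    Mn(t) = Mn(t0) / (SiC(t) + 1).

All times are SI seconds internally; the CLI accepts hour/day suffixes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import DomainError, UnreachableExtentError, ValidationError

#: Experimental second-order rate constant for hydroxyl radical attack on a
#: monomeric unit of dissolved PEG (M^-1 s^-1).
DEFAULT_KM = 2.1e9

#: Molecular weight of the unlabeled ethylene-oxide repeat unit (Da).  Chain
#: MW is n * MW_monomer throughout (no end-group mass).
DEFAULT_MW_MONOMER = 44.0

# exp(-x) underflows long before x = 700; treat the conversion as complete.
_SATURATION_EXPONENT = 700.0


@dataclass(frozen=True)
class KineticsParams:
    """Parameters of the pseudo-first-order scission model.

    Parameters
    ----------
    oh_ss : float
        Steady-state hydroxyl-radical concentration (M).  Sunlit surface
        waters span roughly 1e-17 to 1e-15 M.
    mn0 : float
        Initial number-average molecular weight (Da).
    km : float
        Second-order rate constant for radical attack on one monomeric
        unit (M^-1 s^-1).
    mw_monomer : float
        Monomer molecular weight (Da).
    """

    oh_ss: float
    mn0: float
    km: float = DEFAULT_KM
    mw_monomer: float = DEFAULT_MW_MONOMER

    def __post_init__(self) -> None:
        for name in ("oh_ss", "mn0", "km", "mw_monomer"):
            value = getattr(self, name)
            if not value > 0:
                raise DomainError(f"{name} must be strictly positive, got {value!r}")
        if self.mn0 < self.mw_monomer:
            raise DomainError(
                f"mn0 ({self.mn0}) must be at least one monomer ({self.mw_monomer} Da)"
            )

    @property
    def k1(self) -> float:
        """Pseudo-first-order rate constant (s^-1)."""
        return pseudo_first_order_rate(self.km, self.oh_ss)

    @property
    def dp0(self) -> float:
        """Initial average degree of polymerization, Mn(t0)/MW_monomer."""
        return self.mn0 / self.mw_monomer


@dataclass(frozen=True)
class KineticsResult:
    """Model state at one reaction time."""

    t: float  # s
    k1: float  # s^-1
    sic: float  # scissions per initial chain
    mn_t: float  # Da


def pseudo_first_order_rate(km: float, oh_ss: float) -> float:
    """Return ``k1 = kM * [OH]_ss`` in s^-1."""
    if not km > 0:
        raise DomainError(f"km must be strictly positive, got {km!r}")
    if not oh_ss > 0:
        raise DomainError(f"oh_ss must be strictly positive, got {oh_ss!r}")
    return km * oh_ss


def scissions_per_chain(params: KineticsParams, t: float) -> float:
    """Average number of scissions per initial chain after time ``t`` (s).

    Monotone nondecreasing in ``t``; saturates at the initial degree of
    polymerization (every unit reacted).
    """
    if t < 0:
        raise DomainError(f"reaction time must be nonnegative, got {t!r}")
    x = params.k1 * t
    fraction_reacted = 1.0 if x > _SATURATION_EXPONENT else -math.expm1(-x)
    return fraction_reacted * params.dp0


def mn_from_scissions(mn0: float, sic: float) -> float:
    """Number-average MW after ``sic`` scissions per initial chain."""
    if not mn0 > 0:
        raise DomainError(f"mn0 must be strictly positive, got {mn0!r}")
    if sic < 0:
        raise DomainError(f"sic must be nonnegative, got {sic!r}")
    return mn0 / (sic + 1.0)


def time_for_scissions(params: KineticsParams, sic_target: float) -> float:
    """Invert ``scissions_per_chain``: the time (s) at which the average
    number of scissions per initial chain reaches ``sic_target``.
    """
    if sic_target < 0:
        raise DomainError(f"sic_target must be nonnegative, got {sic_target!r}")
    fraction = sic_target / params.dp0
    if fraction >= 1.0:
        raise UnreachableExtentError(
            f"sic_target={sic_target} requires a reacted-unit fraction of "
            f"{fraction:.4g} >= 1; at most {params.dp0:.6g} scissions per chain "
            "are reachable"
        )
    return -math.log1p(-fraction) / params.k1


def evaluate(params: KineticsParams, t: float) -> KineticsResult:
    """Full model state (k1, SiC, Mn) at time ``t``."""
    sic = scissions_per_chain(params, t)
    return KineticsResult(t=t, k1=params.k1, sic=sic, mn_t=mn_from_scissions(params.mn0, sic))


def kinetics_profile(params: KineticsParams, t_grid: Sequence[float]) -> pd.DataFrame:
    """Tabulate the model on a time grid.

    Returns a DataFrame with columns ``t_s, k1_per_s, sic, mn_da``; the
    ``sic`` column is nondecreasing and ``mn_da`` nonincreasing.
    """
    grid = list(t_grid)
    if not grid:
        raise ValidationError("t_grid must be nonempty")
    if any(t < 0 for t in grid):
        raise ValidationError("t_grid values must be nonnegative")
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValidationError("t_grid must be nondecreasing")
    rows = [evaluate(params, t) for t in grid]
    return pd.DataFrame(
        {
            "t_s": [r.t for r in rows],
            "k1_per_s": [r.k1 for r in rows],
            "sic": [r.sic for r in rows],
            "mn_da": [r.mn_t for r in rows],
        }
    )
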