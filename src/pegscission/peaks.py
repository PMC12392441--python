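"""Oligomer peak-table ingestion and reduction to cumulative curves.

Liquid chromatography with charged-aerosol detection resolves individual
oligomers over a window (here ~2000-6400 Da for a 6.4-kDa polymer); CAD
response is proportional to analyte mass and independent of MW, so peak
integrals are mass-proportional and normalize directly to wt%.  Oligomers
outside the resolved window appear only as bulk "lump" integrals below and
above the censoring boundaries.  Parallel high-resolution MS assigns each
resolved peak a repeat-unit count n from its m/z and charge:

    n = round((z * mz - end_group_mass - z * adduct_mass) / repeat_mass)

The defaults describe a 13C2-labeled ethylene-oxide repeat (46.05 Da),
water end groups (18.01 Da) and protonation (1.007 Da per charge); the
adduct convention is exposed rather than guessed, and the assignment
reports its mass residual so an inconsistent convention is visible
immediately on known oligomer series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import CumulativeMWCurve
from .errors import DomainError, ValidationError

logger = logging.getLogger(__name__)

#: MW of the 13C2-labeled ethylene-oxide repeat unit (Da).
REPEAT_MASS_13C2 = 46.05
#: MW of the unlabeled repeat unit as measured by MS (Da).
REPEAT_MASS_UNLABELED = 44.03
#: Water end groups of HO-(C2H4O)n-H (Da).
DEFAULT_END_GROUP_MASS = 18.01
#: Proton adduct mass per charge (Da).
DEFAULT_ADDUCT_MASS = 1.007

KIND_RESOLVED = "resolved"
KIND_LUMP_LOW = "lump_low"
KIND_LUMP_HIGH = "lump_high"

#: Default censoring boundaries of the resolved chromatographic window (Da).
DEFAULT_CENSOR_BOUNDS = (2000.0, 6400.0)


@dataclass(frozen=True)
class PeakAssignment:
    """Repeat-unit assignment of one ion."""

    n: int
    mw: float  # n * repeat_mass + end_group_mass
    residual_da: float  # observed neutral mass minus assigned mass
    flagged: bool  # residual exceeds half a repeat unit


def assign_repeat_units(
    mz: float,
    z: int,
    repeat_mass: float = REPEAT_MASS_13C2,
    end_group_mass: float = DEFAULT_END_GROUP_MASS,
    adduct_mass_per_charge: float = DEFAULT_ADDUCT_MASS,
) -> PeakAssignment:
    """Assign a repeat-unit count to an (m/z, charge) observation.

    Consistent across charge states: all charge states of one oligomer map
    to the same n.  The residual between observed and reconstructed neutral
    mass is reported and flagged when above half a repeat unit.
    """
    if z < 1 or int(z) != z:
        raise DomainError(f"charge must be a positive integer, got {z!r}")
    if not mz > 0:
        raise DomainError(f"mz must be positive, got {mz!r}")
    neutral = z * mz - end_group_mass - z * adduct_mass_per_charge
    n = int(round(neutral / repeat_mass))
    if n < 1:
        raise DomainError(
            f"(mz={mz}, z={z}) implies a nonpositive repeat count ({n})"
        )
    mw = n * repeat_mass + end_group_mass
    residual = neutral - n * repeat_mass
    return PeakAssignment(
        n=n, mw=mw, residual_da=residual, flagged=abs(residual) > 0.5 * repeat_mass
    )


@dataclass
class PeakTable:
    """Chromatographic peak integrals with optional censored end lumps.

    ``rows`` is a DataFrame with columns ``kind`` (resolved / lump_low /
    lump_high), ``mw_da`` (NaN for lumps), ``integral`` (mass-proportional
    detector units) and optional passthrough ``rt_min``.
    """

    rows: pd.DataFrame
    repeat_mass: float = REPEAT_MASS_13C2
    end_group_mass: float = DEFAULT_END_GROUP_MASS
    adduct_mass_per_charge: float = DEFAULT_ADDUCT_MASS

    def __post_init__(self) -> None:
        df = self.rows.reset_index(drop=True)
        for col in ("kind", "integral"):
            if col not in df.columns:
                raise ValidationError(f"peak table is missing column {col!r}")
        bad_kind = ~df["kind"].isin([KIND_RESOLVED, KIND_LUMP_LOW, KIND_LUMP_HIGH])
        if bad_kind.any():
            raise ValidationError(
                f"row {bad_kind.idxmax()}: unknown kind {df.loc[bad_kind.idxmax(), 'kind']!r}"
            )
        neg = df["integral"] < 0
        if neg.any():
            raise ValidationError(f"row {neg.idxmax()}: negative integral")
        for kind in (KIND_LUMP_LOW, KIND_LUMP_HIGH):
            if (df["kind"] == kind).sum() > 1:
                raise ValidationError(f"duplicate {kind} row")
        resolved = df[df["kind"] == KIND_RESOLVED]
        if "mw_da" not in df.columns or resolved["mw_da"].isna().any():
            raise ValidationError("every resolved row needs an mw_da")
        mw = resolved["mw_da"].to_numpy(dtype=float)
        if len(mw) > 1 and np.any(np.diff(np.sort(mw)) <= 0):
            raise ValidationError("resolved rows must have distinct MWs")
        self.rows = df

    @property
    def resolved(self) -> pd.DataFrame:
        res = self.rows[self.rows["kind"] == KIND_RESOLVED]
        return res.sort_values("mw_da").reset_index(drop=True)

    def lump_integral(self, kind: str) -> float:
        sel = self.rows[self.rows["kind"] == kind]
        return float(sel["integral"].iloc[0]) if len(sel) else 0.0

    @property
    def total_integral(self) -> float:
        return float(self.rows["integral"].sum())


@dataclass
class FitInput:
    """Normalized experimental cumulative curve ready for fitting."""

    curve: CumulativeMWCurve
    censor_bounds: tuple[float, float]
    source: str = ""
    normalization_total: float = 0.0


def read_peak_table(
    path: str | Path,
    repeat_mass: float = REPEAT_MASS_13C2,
    end_group_mass: float = DEFAULT_END_GROUP_MASS,
    adduct_mass_per_charge: float = DEFAULT_ADDUCT_MASS,
) -> PeakTable:
    """Read a peak CSV with columns kind, mw_da, mz, z, integral[, rt_min].

    Either ``mw_da`` or the pair ``(mz, z)`` identifies a resolved row; if
    both are present ``mw_da`` takes precedence (logged).  Unknown columns
    are ignored with a warning.
    """
    df = pd.read_csv(path, comment="#")
    known = {"kind", "mw_da", "mz", "z", "integral", "rt_min"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("ignoring unknown peak-table columns %s in %s", extra, path)
        df = df.drop(columns=extra)
    if "integral" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'integral'")
    if "kind" not in df.columns:
        df["kind"] = KIND_RESOLVED
    df["kind"] = df["kind"].fillna(KIND_RESOLVED)
    if "mw_da" not in df.columns:
        df["mw_da"] = np.nan

    has_mz = "mz" in df.columns and "z" in df.columns
    for i in df.index[df["kind"] == KIND_RESOLVED]:
        if not np.isnan(df.at[i, "mw_da"]):
            if has_mz and not np.isnan(df.at[i, "mz"]):
                logger.info("row %d of %s: both mw_da and mz given; mw_da wins", i, path)
            continue
        if not has_mz or np.isnan(df.at[i, "mz"]):
            raise ValidationError(f"row {i} of {path}: resolved row needs mw_da or (mz, z)")
        assignment = assign_repeat_units(
            float(df.at[i, "mz"]),
            int(df.at[i, "z"]),
            repeat_mass,
            end_group_mass,
            adduct_mass_per_charge,
        )
        if assignment.flagged:
            logger.warning(
                "row %d of %s: m/z assignment residual %.3f Da exceeds half a repeat",
                i,
                path,
                assignment.residual_da,
            )
        df.at[i, "mw_da"] = assignment.mw
    keep = ["kind", "mw_da", "integral"] + (["rt_min"] if "rt_min" in df.columns else [])
    return PeakTable(
        df[keep],
        repeat_mass=repeat_mass,
        end_group_mass=end_group_mass,
        adduct_mass_per_charge=adduct_mass_per_charge,
    )


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    """Write a peak table CSV that round-trips through read_peak_table."""
    table.rows.to_csv(path, index=False)


def to_fit_input(
    table: PeakTable,
    censor_bounds: tuple[float, float] = DEFAULT_CENSOR_BOUNDS,
    source: str = "",
) -> FitInput:
    """Normalize integrals to wt% and build the cumulative curve.

    CAD response is mass-proportional, so wt% per row is its integral over
    the total.  The low lump becomes the curve's value at the low censoring
    boundary; the high lump is the residual above the upper boundary.
    """
    low, high = censor_bounds
    if not low < high:
        raise ValidationError(f"censor bounds must be increasing, got {censor_bounds!r}")
    total = table.total_integral
    if not total > 0:
        raise DomainError("total peak integral must be positive")
    lump_low = table.lump_integral(KIND_LUMP_LOW) / total * 100.0
    lump_high = table.lump_integral(KIND_LUMP_HIGH) / total * 100.0
    resolved = table.resolved
    mw = resolved["mw_da"].to_numpy(dtype=float)
    wt = resolved["integral"].to_numpy(dtype=float) / total * 100.0

    points = [low]
    cum_vals = [lump_low]
    running = lump_low
    for m_val, w in zip(mw, wt):
        running += w
        if m_val <= low:
            cum_vals[0] = running  # sub-boundary resolved mass folds into the intercept
            continue
        points.append(m_val)
        cum_vals.append(running)
    cum = np.asarray(cum_vals)
    if abs((cum[-1] + lump_high) - 100.0) > 1e-6:
        cum = cum * (100.0 - lump_high) / cum[-1] if cum[-1] else cum
    curve = CumulativeMWCurve(
        np.asarray(points), cum, lump_low=lump_low, lump_high=lump_high
    )
    return FitInput(
        curve=curve,
        censor_bounds=(low, high),
        source=source,
        normalization_total=total,
    )
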