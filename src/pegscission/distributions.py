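"""Molecular-weight distribution summaries of chain ensembles.

Two abundance scales are used throughout: nr% (number percent — each chain
counts once) and wt% (weight percent — each chain counts with its mass,
i.e. its length).  Cumulative curves are right-continuous step functions:
a chain of MW x contributes to the curve at every point >= x.  Curves may
carry censored end lumps, mirroring chromatograms in which oligomers below
and above the resolved window are integrated only in bulk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ensemble import ChainEnsemble
from .errors import DomainError, ValidationError


@dataclass
class MWDistribution:
    """Binned nr% / wt% histogram over MW.

    ``bins`` are the N+1 edges of N half-open bins ``(lo, hi]``; a chain of
    MW exactly on an edge falls in the lower bin, so with a bin width of one
    repeat unit each occupied bin's upper edge is an exact chain MW.
    """

    bins: np.ndarray  # Da, strictly increasing edges
    nr_pct: np.ndarray
    wt_pct: np.ndarray

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        self.nr_pct = np.asarray(self.nr_pct, dtype=float)
        self.wt_pct = np.asarray(self.wt_pct, dtype=float)
        if not np.all(np.diff(self.bins) > 0):
            raise ValidationError("bin edges must be strictly increasing")
        if len(self.bins) != len(self.nr_pct) + 1 or len(self.nr_pct) != len(self.wt_pct):
            raise ValidationError("bin edge/count shape mismatch")
        for name, arr in (("nr_pct", self.nr_pct), ("wt_pct", self.wt_pct)):
            if abs(arr.sum() - 100.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 100, got {arr.sum()!r}")

    @property
    def bin_upper(self) -> np.ndarray:
        return self.bins[1:]

    @property
    def bin_lower(self) -> np.ndarray:
        return self.bins[:-1]


@dataclass
class CumulativeMWCurve:
    """Cumulative wt% versus MW with optional censored end lumps.

    ``cum_wt_pct[i]`` is the wt% of mass at MW <= ``mw_points[i]``
    (including ``lump_low``); ``lump_high`` is the wt% above the last
    resolved point, so ``cum_wt_pct[-1] + lump_high = 100``.
    """

    mw_points: np.ndarray
    cum_wt_pct: np.ndarray
    lump_low: float = 0.0
    lump_high: float = 0.0

    def __post_init__(self) -> None:
        self.mw_points = np.asarray(self.mw_points, dtype=float)
        self.cum_wt_pct = np.asarray(self.cum_wt_pct, dtype=float)
        if self.mw_points.ndim != 1 or len(self.mw_points) != len(self.cum_wt_pct):
            raise ValidationError("mw_points/cum_wt_pct shape mismatch")
        if len(self.mw_points) == 0:
            raise ValidationError("curve must have at least one point")
        if not np.all(np.diff(self.mw_points) > 0):
            raise ValidationError("mw_points must be strictly increasing")
        if np.any(np.diff(self.cum_wt_pct) < -1e-9):
            raise ValidationError("cum_wt_pct must be nondecreasing")
        if abs(self.cum_wt_pct[-1] + self.lump_high - 100.0) > 1e-6:
            raise ValidationError(
                "cum_wt_pct[-1] + lump_high must equal 100, got "
                f"{self.cum_wt_pct[-1] + self.lump_high!r}"
            )
        if self.cum_wt_pct[0] < self.lump_low - 1e-9:
            raise ValidationError("first curve value cannot be below lump_low")

    def value_at(self, mw: float | np.ndarray) -> np.ndarray | float:
        """Step-interpolated cumulative wt% at arbitrary MW.

        Value at the greatest tabulated point <= the query; below the first
        point the curve equals ``lump_low`` (all censored low-MW mass sits
        at or below the first point by convention).
        """
        idx = np.searchsorted(self.mw_points, np.asarray(mw, dtype=float), side="right")
        padded = np.concatenate(([self.lump_low], self.cum_wt_pct))
        out = padded[idx]
        return float(out) if np.isscalar(mw) else out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# lump_low\t{float(self.lump_low)!r}\n")
            fh.write(f"# lump_high\t{float(self.lump_high)!r}\n")
            fh.write("mw_da\tcum_wt_pct\n")
            for mw, c in zip(self.mw_points, self.cum_wt_pct):
                fh.write(f"{float(mw)!r}\t{float(c)!r}\n")


def histogram(ensemble: ChainEnsemble, bin_width: float | None = None) -> MWDistribution:
    """nr% / wt% histogram of an ensemble's chain MWs.

    ``bin_width`` defaults to one repeat unit so each bin holds exactly one
    chain length; edges start at 0 and bins are ``(lo, hi]``.
    """
    if bin_width is None:
        bin_width = ensemble.mw_monomer
    if not bin_width > 0:
        raise DomainError(f"bin_width must be positive, got {bin_width!r}")
    lengths, counts = ensemble.lengths_and_counts()
    mw = lengths * ensemble.mw_monomer
    n_bins = int(math.ceil(mw.max() / bin_width - 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    # (lo, hi] binning: exact multiples of the bin width land on upper edges
    idx = np.ceil(mw / bin_width - 1e-9).astype(int) - 1
    nr = np.zeros(n_bins)
    wt = np.zeros(n_bins)
    np.add.at(nr, idx, counts)
    np.add.at(wt, idx, counts * lengths)
    return MWDistribution(edges, nr / nr.sum() * 100.0, wt / wt.sum() * 100.0)


def cumulative_curve(distribution: MWDistribution) -> CumulativeMWCurve:
    """Running cumulative wt% over bins in increasing MW.

    Points are placed at the upper bin edges: mass in ``(lo, hi]`` is
    counted at every MW >= hi, the right-continuous step convention.
    """
    occupied = distribution.wt_pct > 0
    points = distribution.bin_upper[occupied]
    cum = np.cumsum(distribution.wt_pct[occupied])
    cum[-1] = 100.0  # absorb float rounding
    return CumulativeMWCurve(points, cum)


def fraction_below(source: ChainEnsemble | CumulativeMWCurve, threshold: float) -> float:
    """wt% of mass in chains with MW strictly below ``threshold``.

    For an ensemble this is an exact chain-by-chain mass sum; for a curve
    it is the step value just below the threshold.
    """
    if not threshold > 0:
        raise DomainError(f"threshold must be positive, got {threshold!r}")
    if isinstance(source, ChainEnsemble):
        lengths, counts = source.lengths_and_counts()
        mass = lengths * counts
        below = lengths * source.mw_monomer < threshold
        return float(mass[below].sum() / mass.sum() * 100.0)
    # strict inequality: evaluate the step just left of the threshold
    return float(source.value_at(np.nextafter(threshold, -np.inf)))
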