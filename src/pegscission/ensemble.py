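"""Chain ensembles and the chain-length-dependent rate law.

The simulator's state is a multiset of integer chain lengths (monomer
units).  Initial ensembles are drawn from a normal chain-length
distribution evaluated at integer lengths, truncated at n >= 1 and
renormalized.  The probability that a given chain is selected for scission
is proportional to its length-specific rate constant

    k(n) = 0.8 * kM * n                     for n <= 30
    k(n) = 0.8 * kM * 30 * (n / 30)^0.57    for n >  30

which is linear in length for short chains (every unit equally exposed)
and sublinear for long chains, and continuous at the breakpoint.

Chain MW is ``n * mw_monomer`` exactly — no end-group mass — matching the
convention of the closed-form kinetics.  Length-1 chains (ethylene glycol,
the terminal product) are retained in the ensemble but are never eligible
for further scission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import DomainError, ExhaustedEnsembleError, ValidationError
from .kinetics import DEFAULT_KM, DEFAULT_MW_MONOMER

#: Minimum chain length eligible for scission: monomers are terminal.
ELIGIBLE_MIN_LENGTH = 2

RoundingPolicy = Literal["deterministic-largest-remainder", "multinomial"]


def da_to_length(mw_da: float, mw_monomer: float = DEFAULT_MW_MONOMER) -> float:
    """Convert a molecular weight in Da to a chain length in monomer units.

    A Da-scale specification such as "6380 ± 400 Da" maps to lambda = 145,
    sigma ~ 9.09 monomer units for a 44-Da repeat.
    """
    if not mw_monomer > 0:
        raise DomainError(f"mw_monomer must be positive, got {mw_monomer!r}")
    return mw_da / mw_monomer


@dataclass(frozen=True)
class EnsembleSpec:
    """Specification of an initial normal chain-length ensemble.

    Parameters
    ----------
    m : int
        Total number of initial chains.
    lambda_len : float
        Mean chain length (monomer units; may be fractional).
    sigma_len : float
        Standard deviation of chain length (monomer units).
    mw_monomer : float
        Monomer MW in Da.
    rounding_policy : str
        ``"deterministic-largest-remainder"`` (default, bit-reproducible)
        apportions expected counts p(n)*m by largest remainder;
        ``"multinomial"`` draws counts from the multinomial distribution.
    """

    m: int
    lambda_len: float
    sigma_len: float
    mw_monomer: float = DEFAULT_MW_MONOMER
    rounding_policy: RoundingPolicy = "deterministic-largest-remainder"

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValidationError(f"m must be an integer >= 1, got {self.m!r}")
        if not self.lambda_len >= 1:
            raise ValidationError(f"lambda_len must be >= 1, got {self.lambda_len!r}")
        if not self.sigma_len >= 0:
            raise ValidationError(f"sigma_len must be >= 0, got {self.sigma_len!r}")
        if not self.mw_monomer > 0:
            raise ValidationError(f"mw_monomer must be > 0, got {self.mw_monomer!r}")
        if self.rounding_policy not in (
            "deterministic-largest-remainder",
            "multinomial",
        ):
            raise ValidationError(f"unknown rounding policy {self.rounding_policy!r}")

    @classmethod
    def from_mw(
        cls,
        m: int,
        mn0_da: float,
        sigma_da: float,
        mw_monomer: float = DEFAULT_MW_MONOMER,
        rounding_policy: RoundingPolicy = "deterministic-largest-remainder",
    ) -> "EnsembleSpec":
        """Build a spec from a Da-scale mean and standard deviation."""
        return cls(
            m=m,
            lambda_len=da_to_length(mn0_da, mw_monomer),
            sigma_len=da_to_length(sigma_da, mw_monomer),
            mw_monomer=mw_monomer,
            rounding_policy=rounding_policy,
        )


@dataclass
class ChainEnsemble:
    """Multiset of chain lengths, stored as a length -> count mapping."""

    counts: dict[int, int]
    mw_monomer: float = DEFAULT_MW_MONOMER

    def __post_init__(self) -> None:
        clean: dict[int, int] = {}
        for n, c in self.counts.items():
            n = int(n)
            c = int(c)
            if n < 1:
                raise DomainError(f"chain length must be >= 1, got {n}")
            if c < 0:
                raise DomainError(f"count for length {n} must be >= 0, got {c}")
            if c:
                clean[n] = c
        if not clean:
            raise DomainError("ensemble must contain at least one chain")
        self.counts = dict(sorted(clean.items()))

    @property
    def total_chains(self) -> int:
        return sum(self.counts.values())

    @property
    def total_monomers(self) -> int:
        return sum(n * c for n, c in self.counts.items())

    @property
    def max_length(self) -> int:
        return max(self.counts)

    def lengths_and_counts(self) -> tuple[np.ndarray, np.ndarray]:
        lengths = np.fromiter(self.counts.keys(), dtype=np.int64)
        counts = np.fromiter(self.counts.values(), dtype=np.int64)
        return lengths, counts

    def copy(self) -> "ChainEnsemble":
        return ChainEnsemble(dict(self.counts), self.mw_monomer)

    def to_csv(self, path: str | Path) -> None:
        """Write a two-column ``length_n,count`` CSV (exact round trip)."""
        with open(path, "w") as fh:
            fh.write("length_n,count\n")
            for n, c in self.counts.items():
                fh.write(f"{n},{c}\n")

    @classmethod
    def from_csv(cls, path: str | Path, mw_monomer: float = DEFAULT_MW_MONOMER) -> "ChainEnsemble":
        counts: dict[int, int] = {}
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            if header[:2] != ["length_n", "count"]:
                raise ValidationError(f"unexpected ensemble CSV header {header!r}")
            for line in fh:
                if not line.strip():
                    continue
                n_str, c_str = line.strip().split(",")[:2]
                counts[int(n_str)] = counts.get(int(n_str), 0) + int(c_str)
        return cls(counts, mw_monomer)


@dataclass(frozen=True)
class RateModel:
    """Piecewise chain-length-dependent rate constant k(n)."""

    km: float = DEFAULT_KM
    prefactor: float = 0.8
    breakpoint: int = 30
    exponent: float = 0.57

    def __post_init__(self) -> None:
        for name in ("km", "prefactor", "breakpoint", "exponent"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")

    def k_of_n(self, n: np.ndarray | int) -> np.ndarray | float:
        """Vectorized k(n); continuous at the breakpoint by construction."""
        arr = np.asarray(n, dtype=float)
        base = self.prefactor * self.km
        short = base * arr
        long = base * self.breakpoint * (arr / self.breakpoint) ** self.exponent
        out = np.where(arr <= self.breakpoint, short, long)
        return float(out) if np.isscalar(n) or arr.ndim == 0 else out


def chain_rate_constant(n: int, model: RateModel | None = None) -> float:
    """Rate constant k(n) (M^-1 s^-1) for a chain of ``n`` monomer units."""
    if model is None:
        model = RateModel()
    if n < 1 or int(n) != n:
        raise DomainError(f"chain length must be an integer >= 1, got {n!r}")
    return float(model.k_of_n(int(n)))


def _normal_pmf_on_lengths(lambda_len: float, sigma_len: float) -> tuple[np.ndarray, np.ndarray]:
    """Normal density evaluated at integer lengths n >= 1, renormalized.

    Returns (lengths, probabilities).  With sigma = 0 all mass sits at
    round(lambda), clipped to >= 1.
    """
    if sigma_len == 0:
        n0 = max(1, int(round(lambda_len)))
        return np.array([n0]), np.array([1.0])
    lo = max(1, int(math.floor(lambda_len - 10 * sigma_len)))
    hi = int(math.ceil(lambda_len + 10 * sigma_len))
    lengths = np.arange(lo, hi + 1)
    z = (lengths - lambda_len) / sigma_len
    density = np.exp(-0.5 * z * z)
    total = density.sum()
    if total <= 0:
        raise DomainError("degenerate normal discretization")
    return lengths, density / total


def build_initial_ensemble(spec: EnsembleSpec, seed: int | None = None) -> ChainEnsemble:
    """Apportion ``m`` chains over integer lengths from the truncated normal.

    Deterministic largest-remainder apportionment (default) assigns
    ``floor(p(n) * m)`` per length and distributes the remaining chains by
    descending fractional remainder (ties to the smaller length); it is
    reproducible with no RNG.  The multinomial policy draws counts with
    ``numpy.random.default_rng(seed)``.
    """
    lengths, probs = _normal_pmf_on_lengths(spec.lambda_len, spec.sigma_len)
    if spec.rounding_policy == "multinomial":
        if seed is None:
            raise ValidationError("multinomial rounding requires a seed")
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(spec.m, probs)
    else:
        expected = probs * spec.m
        counts = np.floor(expected).astype(np.int64)
        remainder = spec.m - int(counts.sum())
        if remainder:
            frac = expected - counts
            # descending remainder, ties to the smaller length
            order = np.lexsort((lengths, -frac))
            counts[order[:remainder]] += 1
    mapping = {int(n): int(c) for n, c in zip(lengths, counts) if c > 0}
    return ChainEnsemble(mapping, spec.mw_monomer)


def selection_weights(
    ensemble: ChainEnsemble,
    model: RateModel | None = None,
    eligible_min_length: int = ELIGIBLE_MIN_LENGTH,
) -> dict[int, float]:
    """Per-length-class selection probabilities.

    The weight of length class ``n`` is ``m(n) * k(n)`` over eligible
    classes (``n >= eligible_min_length``), normalized to sum to 1 —
    identical to summing the per-chain selection probabilities
    ``k(n_i) / sum_j k(n_j)`` over the chains of each class.
    """
    if model is None:
        model = RateModel()
    lengths, counts = ensemble.lengths_and_counts()
    eligible = lengths >= eligible_min_length
    if not eligible.any():
        raise ExhaustedEnsembleError("no chain of eligible length remains")
    weights = np.where(eligible, counts * model.k_of_n(lengths), 0.0)
    weights = weights / weights.sum()
    return {int(n): float(w) for n, w in zip(lengths, weights)}


def number_average_mw(ensemble: ChainEnsemble) -> float:
    """Mn = mw_monomer * (total monomers) / (total chains)."""
    return ensemble.mw_monomer * ensemble.total_monomers / ensemble.total_chains


def weight_average_mw(ensemble: ChainEnsemble) -> float:
    """Mw = mw_monomer * sum(n^2 m(n)) / sum(n m(n))."""
    lengths, counts = ensemble.lengths_and_counts()
    return ensemble.mw_monomer * float((lengths**2 * counts).sum() / (lengths * counts).sum())


def dispersity(ensemble: ChainEnsemble) -> float:
    """Dispersity D = Mw / Mn >= 1."""
    return weight_average_mw(ensemble) / number_average_mw(ensemble)
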