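"""Information-theoretic complexity indices for serially homologous counts.

The vertebral column is treated as a collection of ``N`` elements
(vertebrae) distributed over ``k`` regions (cervical, thoracic, lumbar).
Two summary statistics quantify how the elements are spread across
regions:

* the Brillouin index ``H_R = (1/N) * ln(N! / prod(n_i!))``, an
  information measure appropriate for fully enumerated collections
  (as opposed to random samples), and
* the evenness index ``H'_R``, which rescales ``H_R`` by its maximum
  over the most even partition of ``N`` elements into ``k`` regions,
  so that ``H'_R = 1`` exactly when the counts are maximally even.

Both indices use the natural logarithm and are computed through
log-gamma, never raw factorials, so they remain exact in double
precision for totals far beyond anything anatomically plausible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import DomainError

__all__ = [
    "RegionPartition",
    "ComplexityProfile",
    "SpeciesProfile",
    "brillouin",
    "evenness",
    "tl_ratio",
    "logit_tl",
    "compute_profile",
    "truncate",
]


def _log_factorial(n: int) -> float:
    # lgamma(n + 1) == ln(n!), with the 0! = 1 convention built in
    return math.lgamma(n + 1)


def truncate(x: float, decimals: int = 4) -> float:
    """Truncate ``x`` toward zero at ``decimals`` decimal places.

    Printed reference values for the indices are floored, not rounded,
    at the fourth decimal (0.21799... is reported as 0.2179); this
    helper reproduces that display convention for comparisons.  All
    internal computation keeps full double precision.
    """
    factor = 10.0**decimals
    return math.trunc(x * factor) / factor


def _coerce_counts(partition: "RegionPartition | Sequence[int]") -> tuple[int, ...]:
    if isinstance(partition, RegionPartition):
        return partition.counts
    counts = tuple(int(c) for c in partition)
    if any(c != float(raw) for c, raw in zip(counts, partition)):
        raise DomainError("region counts must be integers")
    return counts


@dataclass(frozen=True)
class RegionPartition:
    """An ordered vector of per-region element counts ``n_1 .. n_k``.

    The order of regions never affects either index (permutation
    invariance); it is retained only for provenance.
    """

    counts: tuple[int, ...]

    def __init__(self, counts: Iterable[int]) -> None:
        counts = tuple(int(c) for c in counts)
        if len(counts) == 0:
            raise DomainError("a region partition needs at least one region")
        if any(c < 0 for c in counts):
            raise DomainError(f"negative region count in {counts}")
        if sum(counts) < 1:
            raise DomainError("total element count must be at least 1")
        object.__setattr__(self, "counts", counts)

    @property
    def k(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts)


def brillouin(partition: RegionPartition | Sequence[int]) -> float:
    """Brillouin index ``H_R`` of a region partition (natural log).

    Returns ``(1/N) * ln(N! / prod(n_i!))``; exactly 0.0 for a single
    region.  Zero counts contribute nothing (0! = 1).
    """
    counts = _coerce_counts(partition)
    if len(counts) == 0:
        raise DomainError("empty counts vector")
    n_total = sum(counts)
    if n_total < 1:
        raise DomainError("total count must be >= 1")
    log_multinomial = _log_factorial(n_total) - sum(_log_factorial(c) for c in counts)
    value = log_multinomial / n_total
    # guard against -0.0 from rounding on one-region input
    return 0.0 if value == 0 else value


def evenness(partition: RegionPartition | Sequence[int]) -> float:
    """Evenness index ``H'_R``: Brillouin value relative to its maximum.

    The maximum of ``H_R`` over partitions of ``N`` into ``k`` parts is
    attained by the most even split, where every part equals
    ``c = N // k`` or ``c + 1`` with exactly ``d = N % k`` parts at
    ``c + 1``.  The index therefore equals exactly 1 on such splits.
    Undefined for a single region (the normalizer vanishes).
    """
    counts = _coerce_counts(partition)
    k = len(counts)
    if k < 2:
        raise DomainError("evenness requires at least two regions (k >= 2)")
    n_total = sum(counts)
    if n_total < 1:
        raise DomainError("total count must be >= 1")
    c, d = divmod(n_total, k)
    # a maximally even split (every count in {c, c+1}, d of them at c+1)
    # attains the normalizer exactly: return 1 without dividing, so the
    # bound holds to the last bit regardless of summation order
    if sorted(counts) == [c] * (k - d) + [c + 1] * d:
        return 1.0
    denominator = (
        _log_factorial(n_total)
        - (k - d) * _log_factorial(c)
        - d * _log_factorial(c + 1)
    )
    numerator = _log_factorial(n_total) - sum(_log_factorial(x) for x in counts)
    return numerator / denominator


def tl_ratio(thoracic: int, lumbar: int) -> float:
    """Thoracic-to-lumbar count ratio T:L."""
    if lumbar < 1:
        raise DomainError("T:L ratio undefined for lumbar count 0")
    return thoracic / lumbar


def logit_tl(thoracic: int, lumbar: int) -> float:
    """Logit of the thoracic proportion, ``ln(T/L)``.

    Equivalent to ``logit(T / (T + L))`` and antisymmetric under
    swapping the two counts; zero when T == L.
    """
    if thoracic < 1 or lumbar < 1:
        raise DomainError("logit T:L requires both counts >= 1")
    return math.log(thoracic / lumbar)


@dataclass(frozen=True)
class ComplexityProfile:
    """Brillouin and evenness values for one scope (presacral or TL)."""

    brillouin: float
    evenness: float
    scope: str  # "presacral" (k = 3) or "thoracolumbar" (k = 2)


@dataclass
class SpeciesProfile:
    """Full per-species index record: counts, both index scopes, ratios."""

    species_id: str
    group_label: str
    cervical_count: int
    thoracic_count: int
    lumbar_count: int
    ctl_count: int = field(init=False)
    tl_count: int = field(init=False)
    brillouin_ctl: float = field(init=False)
    evenness_ctl: float = field(init=False)
    brillouin_tl: float = field(init=False)
    evenness_tl: float = field(init=False)
    tl_ratio: float = field(init=False)
    logit_tl: float = field(init=False)

    def __post_init__(self) -> None:
        c, t, l = self.cervical_count, self.thoracic_count, self.lumbar_count
        self.ctl_count = c + t + l
        self.tl_count = t + l
        presacral = (c, t, l)
        thoracolumbar = (t, l)
        self.brillouin_ctl = brillouin(presacral)
        self.evenness_ctl = evenness(presacral)
        self.brillouin_tl = brillouin(thoracolumbar)
        self.evenness_tl = evenness(thoracolumbar)
        self.tl_ratio = tl_ratio(t, l)
        self.logit_tl = logit_tl(t, l)

    INDEX_NAMES = (
        "brillouin_ctl",
        "evenness_ctl",
        "brillouin_tl",
        "evenness_tl",
        "tl_ratio",
        "logit_tl",
    )


def compute_profile(formula) -> SpeciesProfile:
    """Compute the full index record for one species' vertebral formula.

    ``formula`` is any object with ``species_id``, ``group_label`` and
    the three region counts (see :class:`axialtrends.formulae.VertebralFormula`).
    """
    return SpeciesProfile(
        species_id=formula.species_id,
        group_label=formula.group_label,
        cervical_count=formula.cervical_count,
        thoracic_count=formula.thoracic_count,
        lumbar_count=formula.lumbar_count,
    )
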