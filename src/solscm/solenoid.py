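"""Solenoidal projection and the spectrum scoring function.

A set of integer site positions on a linear support of length ``L`` (the
1's of a sparse boolean sequence, e.g. transcription starts along a
genome) is wrapped around a candidate period ``P`` by the congruence
``x -> (x mod P) / P``.  Sites that repeat with period ``P`` coincide on
this circle; the scoring function rewards the resulting clustering (and
the complementary depleted arcs) by summing the information content of
nearest-neighbor distances under the uniform null:

    S(P) = -1/(2 J N) * sum_{i=0}^{N-1} sum_{j=1}^{J} log p_j^N(x_{i,j})

where ``x_{i,j}`` is the normalized circular distance between the j-th
neighbors on each side of site ``i`` and ``p_j^N`` the two-tailed
spacing p-value of :func:`solscm.neighbor_stats.pair_pvalue`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betainc

from .neighbor_stats import PVALUE_FLOOR

logger = logging.getLogger(__name__)

__all__ = [
    "SiteSequence",
    "ProjectedSites",
    "project_modulo",
    "neighbor_distance",
    "default_J",
    "scs_score",
    "score_projected",
]


@dataclass(frozen=True)
class SiteSequence:
    """Sorted distinct integer site positions on a support of length ``L``.

    ``positions`` is canonicalized on construction: sorted ascending,
    duplicates dropped with a logged warning.  Positions are 0-based and
    must lie in ``[0, L)``.
    """

    length: int
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"support length must be positive, got {self.length}")
        pos = np.asarray(self.positions, dtype=np.int64)
        uniq = np.unique(pos)
        if uniq.size < pos.size:
            logger.warning(
                "dropped %d duplicate site position(s)", pos.size - uniq.size
            )
        if uniq.size and (uniq[0] < 0 or uniq[-1] >= self.length):
            raise ValueError(
                f"positions must lie in [0, {self.length}), "
                f"got range [{uniq[0]}, {uniq[-1]}]"
            )
        object.__setattr__(self, "positions", uniq)

    @property
    def n(self) -> int:
        return int(self.positions.size)

    def reflect(self) -> "SiteSequence":
        """Mirror the support: position -> L - 1 - position."""
        return SiteSequence(self.length, self.length - 1 - self.positions)


@dataclass(frozen=True)
class ProjectedSites:
    """Normalized angles of sites on the face view of a P-periodic solenoid."""

    period: float
    theta: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.size and (th.min() < 0 or th.max() >= 1):
            raise ValueError("theta must lie in [0, 1)")
        if np.any(np.diff(th) < 0):
            raise ValueError("theta must be sorted ascending")
        object.__setattr__(self, "theta", th)

    @property
    def n(self) -> int:
        return int(self.theta.size)


def project_modulo(sites: SiteSequence, period: float) -> ProjectedSites:
    """Wrap site positions around a period: theta = (pos mod P) / P, sorted."""
    if not 1 < period <= sites.length:
        raise ValueError(
            f"period must satisfy 1 < P <= L = {sites.length}, got {period}"
        )
    theta = np.sort((sites.positions % period) / period)
    return ProjectedSites(period, theta)


def neighbor_distance(proj: ProjectedSites, i: int, j: int) -> float:
    """Circular arc between the j-th neighbors on each side of site ``i``.

    The two endpoints (indices ``i-j`` and ``i+j`` modulo N in the sorted
    clockwise order) enclose ``2j - 1`` sites, ``i`` among them.
    """
    n = proj.n
    if not 0 <= i < n:
        raise ValueError(f"site index {i} out of range [0, {n})")
    if j < 1 or 2 * j - 1 > n - 2:
        raise ValueError(f"neighbor order j={j} invalid for N={n} (need 2j-1 <= N-2)")
    lo = proj.theta[(i - j) % n]
    hi = proj.theta[(i + j) % n]
    return float((hi - lo) % 1.0)


def default_J(n_sites: int) -> int:
    """Default neighbor depth: max(floor(N/16), 1), capped so 2J-1 <= N-2.

    The depth grows with N so that dense regions keep being probed, while
    keeping the cost of a spectrum O(J N) per period.
    """
    if n_sites < 2:
        raise ValueError(f"need at least 2 sites, got {n_sites}")
    j = max(n_sites // 16, 1)
    return min(j, max((n_sites - 1) // 2, 1))


def _neighbor_gaps(theta: np.ndarray, j: int) -> np.ndarray:
    # theta sorted along the last axis; arc from index i-j to i+j, wrapping.
    hi = np.roll(theta, -j, axis=-1)
    lo = np.roll(theta, j, axis=-1)
    return (hi - lo) % 1.0


def score_projected(theta: np.ndarray, J: int, eps: float = PVALUE_FLOOR) -> np.ndarray:
    """Scoring function from sorted angles, vectorized over leading axes.

    ``theta`` has shape ``(..., N)`` with each row sorted ascending; the
    return value has shape ``(...)``.
    """
    theta = np.asarray(theta, dtype=float)
    n = theta.shape[-1]
    if n < 3:
        raise ValueError(f"need at least 3 sites to score, got {n}")
    if J < 1 or 2 * J - 1 > n - 2:
        raise ValueError(f"neighbor depth J={J} invalid for N={n} (need 2J-1 <= N-2)")
    total = np.zeros(theta.shape[:-1])
    for j in range(1, J + 1):
        x = _neighbor_gaps(theta, j)
        f = betainc(2 * j, n - 2 * j, x)
        p = np.clip(np.minimum(f, 1.0 - f), eps, 0.5)
        total += np.sum(np.log(p), axis=-1)
    return -total / (2.0 * J * n)


def alignment_multiplicity(sites: SiteSequence, period: float, J: int | None = None) -> int:
    """Number of score terms with exactly coincident projected neighbors.

    A pattern that is exactly periodic at P keeps the same coincidence
    count at every integer divisor of P (the clusters merely change their
    angular positions), while harmonics kP and near-rational aliases
    split the clusters and lose coincidences.  This makes the count the
    discriminant for picking the fundamental among exactly-tied alias
    peaks.
    """
    if J is None:
        J = default_J(sites.n)
    theta = np.sort((sites.positions % period) / period)
    return int(sum(np.sum(_neighbor_gaps(theta, j) == 0.0) for j in range(1, J + 1)))


def scs_score(
    sites: SiteSequence, period: float, J: int | None = None, eps: float = PVALUE_FLOOR
) -> float:
    """Solenoidal clustering score of a site set at one candidate period."""
    if sites.n < 3:
        raise ValueError(f"need at least 3 sites to score, got N={sites.n}")
    proj = project_modulo(sites, period)
    if J is None:
        J = default_J(sites.n)
    if np.all(proj.theta == proj.theta[0]):
        warnings.warn(
            "all sites coincide modulo the period; score saturates at the "
            "p-value floor",
            stacklevel=2,
        )
    return float(score_projected(proj.theta, J, eps=eps))
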