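"""Exact circular-spacing statistics for uniform sites on a circle.

For ``N`` sites drawn independently and uniformly on a circle of unit
perimeter, the arc length between two sites that enclose exactly ``i``
other sites is a classical order statistic: it follows a
``Beta(i + 1, N - 1 - i)`` law.  Equivalently, the density is

    rho_i^N(x) = (N - 1) * C(N - 2, i) * x**i * (1 - x)**(N - 2 - i)

These laws are the null model behind every score in this package: the
spectrum scoring function compares observed neighbor distances (after
projection modulo a candidate period) against them, and converts each
distance into a two-tailed p-value whose negative logarithm is the
information content of the observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, comb

__all__ = ["SpacingLaw", "spacing_pdf", "spacing_cdf", "pair_pvalue", "PVALUE_FLOOR"]

#: Default floor applied to p-values so that log(p) stays finite even for
#: coincident sites (distance exactly zero after projection).
PVALUE_FLOOR = 1e-300


@dataclass(frozen=True)
class SpacingLaw:
    """Distribution of the circular arc enclosing ``n_between`` sites.

    Parameters
    ----------
    n_sites:
        Total number of sites ``N`` on the circle, at least 2.
    n_between:
        Number of sites strictly between the two endpoints of the arc,
        ``0 <= n_between <= N - 2``.
    """

    n_sites: int
    n_between: int

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError(f"n_sites must be >= 2, got {self.n_sites}")
        if not 0 <= self.n_between <= self.n_sites - 2:
            raise ValueError(
                f"n_between must satisfy 0 <= i <= N-2 = {self.n_sites - 2}, "
                f"got {self.n_between}"
            )

    @property
    def beta_a(self) -> int:
        return self.n_between + 1

    @property
    def beta_b(self) -> int:
        return self.n_sites - 1 - self.n_between

    def pdf(self, x):
        return spacing_pdf(self, x)

    def cdf(self, x):
        return spacing_cdf(self, x)


def _check_x(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("normalized distances must lie in [0, 1]")
    return x


def spacing_pdf(law: SpacingLaw, x):
    """Density of the arc spanning ``law.n_between`` intermediate sites.

    Evaluates ``(N-1) * C(N-2, i) * x**i * (1-x)**(N-2-i)``, the
    ``Beta(i+1, N-1-i)`` density, at normalized distance ``x``.
    """
    x = _check_x(x)
    n, i = law.n_sites, law.n_between
    coeff = (n - 1) * comb(n - 2, i, exact=True)
    with np.errstate(invalid="ignore"):
        out = coeff * x**i * (1.0 - x) ** (n - 2 - i)
    return out if out.ndim else float(out)


def spacing_cdf(law: SpacingLaw, x):
    """Repartition function of the spacing law (regularized incomplete Beta)."""
    x = _check_x(x)
    out = betainc(law.beta_a, law.beta_b, x)
    return out if np.ndim(out) else float(out)


def pair_pvalue(j: int, n_sites: int, x, eps: float = PVALUE_FLOOR):
    """Two-tailed p-value for the distance between j-th neighbors.

    The j-th nearest neighbors on each side of a site are separated by
    ``2j - 1`` sites, so the relevant null law is ``SpacingLaw(N, 2j-1)``.
    The p-value is approximated by ``min(F, 1 - F)`` with ``F`` the
    repartition function: small for tight clusters (small arcs) and for
    depleted regions (large arcs) alike, both of which signal periodic
    structure.  The result is floored at ``eps`` so its logarithm is
    finite.
    """
    if j < 1:
        raise ValueError(f"neighbor order j must be >= 1, got {j}")
    if 2 * j - 1 > n_sites - 2:
        raise ValueError(
            f"too few sites for neighbor order j={j}: need 2j-1 <= N-2, "
            f"got N={n_sites}"
        )
    f = spacing_cdf(SpacingLaw(n_sites, 2 * j - 1), x)
    p = np.minimum(f, 1.0 - f)
    p = np.clip(p, eps, 0.5)
    return p if np.ndim(p) else float(p)
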