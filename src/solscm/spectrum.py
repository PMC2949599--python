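"""Solenoidal spectra: period sweep, Monte-Carlo calibration, peak reading.

The spectrum (SoS) is the clustering score evaluated over a grid of
candidate periods.  Its p-valued counterpart (pSoS) calibrates every
score against an ensemble of uniform-random site sets with the same N
and neighbor depth J: the p-value of a period is the probability that
pure noise scores at least as high.  Because uniform angles modulo any
period are uniform on the circle, a single null ensemble serves the
whole grid.

Peak post-processing has to contend with sub-harmonic aliasing: a
pattern of true period P aligns *perfectly* at every divisor P/m as
well (all its sites still coincide after projection), and partially at
rational multiples (m/q)P.  Peaks are therefore grouped into harmonic
families (connected components under integer period ratios), weak
rational aliases are pruned by a dominance filter on raw scores, and
each family's fundamental is the largest member of maximal
exact-alignment multiplicity (falling back to the top raw-score
plateau when nothing aligns exactly) — the largest period among the
exactly-tied divisor aliases is the true one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .neighbor_stats import PVALUE_FLOOR
from .solenoid import SiteSequence, alignment_multiplicity, default_J, score_projected

__all__ = [
    "SolenoidalSpectrum",
    "Peak",
    "PeakSet",
    "compute_sos",
    "null_ensemble",
    "compute_psos",
    "family_correction",
    "find_peaks",
    "solenoidal_spectrum",
    "default_period_grid",
    "main_period",
]


@dataclass(frozen=True)
class SolenoidalSpectrum:
    """Per-period scores with optional Monte-Carlo calibration.

    ``pvalues`` and ``neglog10p`` are ``None`` until the spectrum is
    calibrated against a null ensemble; ``null_meta`` records how the
    ensemble was generated (replicates, seed, N, J).
    """

    periods: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)
    n_sites: int
    J: int
    pvalues: np.ndarray | None = field(default=None, repr=False)
    neglog10p: np.ndarray | None = field(default=None, repr=False)
    null_meta: dict | None = None

    def __post_init__(self) -> None:
        periods = np.asarray(self.periods, dtype=float)
        scores = np.asarray(self.scores, dtype=float)
        if periods.size == 0:
            raise ValueError("period grid must not be empty")
        if periods.shape != scores.shape:
            raise ValueError("periods and scores must have the same length")
        if np.any(np.diff(periods) <= 0):
            raise ValueError("periods must be strictly ascending")
        object.__setattr__(self, "periods", periods)
        object.__setattr__(self, "scores", scores)
        for name in ("pvalues", "neglog10p"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != periods.shape:
                    raise ValueError(f"{name} must match the period grid length")
                object.__setattr__(self, name, arr)

    @property
    def calibrated(self) -> bool:
        return self.pvalues is not None


@dataclass(frozen=True)
class Peak:
    period: float
    score: float
    neglog10p: float
    group_id: int
    fundamental: bool


@dataclass(frozen=True)
class PeakSet:
    """Significant spectrum peaks, sorted by descending significance."""

    peaks: tuple[Peak, ...]

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def fundamentals(self) -> list[float]:
        """Fundamental period of each harmonic family, most significant first."""
        seen: list[float] = []
        for pk in self.peaks:  # peaks are sorted by family significance
            if pk.fundamental:
                seen.append(pk.period)
        return seen


def default_period_grid(length: int, p_min: int = 10, p_max: int | None = None):
    """Integer candidate periods from ``p_min`` to ``min(L/2, 40000)``."""
    if p_max is None:
        p_max = min(length // 2, 40000)
    p_max = min(p_max, length)
    if p_max <= p_min:
        raise ValueError(f"empty period grid: p_min={p_min}, p_max={p_max}")
    step = max(1, (p_max - p_min) // 4000)
    return np.arange(p_min, p_max + 1, step, dtype=float)


def compute_sos(
    sites: SiteSequence,
    periods,
    J: int | None = None,
    eps: float = PVALUE_FLOOR,
) -> np.ndarray:
    """Score a site set over a grid of candidate periods (the raw SoS)."""
    periods = np.atleast_1d(np.asarray(periods, dtype=float))
    if periods.size == 0:
        raise ValueError("period grid must not be empty")
    if np.any((periods <= 1) | (periods > sites.length)):
        raise ValueError("every period must satisfy 1 < P <= L")
    if sites.n < 3:
        raise ValueError(f"need at least 3 sites, got N={sites.n}")
    if J is None:
        J = default_J(sites.n)
    theta = np.sort(sites.positions[None, :] % periods[:, None] / periods[:, None], axis=1)
    return score_projected(theta, J, eps=eps)


def null_ensemble(
    n_sites: int,
    J: int,
    R: int = 1000,
    seed=None,
    eps: float = PVALUE_FLOOR,
) -> np.ndarray:
    """Scores of ``R`` uniform-random site sets on the continuous circle.

    The null is drawn directly as sorted uniform angles: the projection of
    uniform positions modulo any period is uniform on the circle, so one
    ensemble per (N, J) calibrates every period of the grid.
    """
    if R < 100:
        warnings.warn(
            f"R={R} null replicates give coarse p-value resolution (floor "
            f"1/{R + 1})",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    theta = np.sort(rng.random((R, n_sites)), axis=1)
    return score_projected(theta, J, eps=eps)


def null_ensemble_discrete(
    n_sites: int,
    J: int,
    period: int,
    length: int,
    R: int = 1000,
    seed=None,
    eps: float = PVALUE_FLOOR,
) -> np.ndarray:
    """Exact-null variant: uniform integer positions reduced modulo a period.

    Differs from :func:`null_ensemble` only by O(P/L) discretization
    effects; provided for exactness studies.
    """
    rng = np.random.default_rng(seed)
    pos = rng.integers(0, length, size=(R, n_sites))
    theta = np.sort((pos % period) / period, axis=1)
    return score_projected(theta, J, eps=eps)


def compute_psos(scores, null_scores, n_sites=None, J=None, null_meta=None):
    """Exceedance p-values of observed scores within a null ensemble.

    Uses the add-one estimator ``p = (1 + #{null >= s}) / (R + 1)`` so a
    p-value is never zero; the resolution floor is ``1/(R+1)``.
    """
    scores = np.atleast_1d(np.asarray(scores, dtype=float))
    null_scores = np.asarray(null_scores, dtype=float)
    if null_meta is not None:
        if n_sites is not None and null_meta.get("n_sites") != n_sites:
            raise ValueError("null ensemble was generated for a different N")
        if J is not None and null_meta.get("J") != J:
            raise ValueError("null ensemble was generated for a different J")
    r = null_scores.size
    srt = np.sort(null_scores)
    n_below = np.searchsorted(srt, scores, side="left")
    pvals = (1.0 + r - n_below) / (r + 1.0)
    return pvals


def family_correction(p_star: float, n_peaks: int) -> float:
    """Probability that at least one of ``n_peaks`` independent peaks
    reaches p-value ``p_star``: ``1 - (1 - p_star)**n_peaks``."""
    if not 0 <= p_star <= 1:
        raise ValueError(f"p_star must lie in [0, 1], got {p_star}")
    if n_peaks < 1:
        raise ValueError(f"n_peaks must be >= 1, got {n_peaks}")
    return float(1.0 - (1.0 - p_star) ** n_peaks)


def solenoidal_spectrum(
    sites: SiteSequence,
    periods=None,
    J: int | None = None,
    R: int = 1000,
    seed=None,
    eps: float = PVALUE_FLOOR,
) -> SolenoidalSpectrum:
    """Compute the calibrated pSoS of a site set in one call."""
    if periods is None:
        periods = default_period_grid(sites.length)
    if J is None:
        J = default_J(sites.n)
    periods = np.atleast_1d(np.asarray(periods, dtype=float))
    scores = compute_sos(sites, periods, J=J, eps=eps)
    nulls = null_ensemble(sites.n, J, R=R, seed=seed, eps=eps)
    pvals = compute_psos(scores, nulls)
    return SolenoidalSpectrum(
        periods=periods,
        scores=scores,
        n_sites=sites.n,
        J=J,
        pvalues=pvals,
        neglog10p=-np.log10(pvals),
        null_meta={"R": R, "seed": seed, "n_sites": sites.n, "J": J},
    )


# ---------------------------------------------------------------------------
# Peak reading


def _plateau_local_maxima(sig: np.ndarray, scores: np.ndarray) -> list[int]:
    """Indices of local maxima of ``sig``, one representative per plateau.

    Runs of equal significance (common when Monte-Carlo p-values saturate
    at the resolution floor) count as a single peak; the representative
    index is the one with the highest raw score inside the run.
    """
    n = sig.size
    maxima: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sig[j + 1] == sig[i]:
            j += 1
        left_ok = i == 0 or sig[i - 1] < sig[i]
        right_ok = j == n - 1 or sig[j + 1] < sig[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            maxima.append(i + int(np.argmax(scores[i : j + 1])))
        i = j + 1
    return maxima


def _integer_ratio(a: float, b: float, tol: float) -> bool:
    """True if a ~= k*b for some integer k >= 1 (a >= b assumed)."""
    k = round(a / b)
    return k >= 1 and abs(a / (k * b) - 1.0) <= tol


def find_peaks(
    spectrum: SolenoidalSpectrum,
    min_neglog10p: float = 2.0,
    harmonic_tol: float = 0.02,
    dominance: float = 0.25,
    plateau_tol: float = 0.05,
    sites: SiteSequence | None = None,
) -> PeakSet:
    """Read significant peaks and group them into harmonic families.

    Parameters
    ----------
    min_neglog10p:
        Significance threshold on ``-log10 p`` (raw score for an
        uncalibrated spectrum, where the threshold is ignored).
    harmonic_tol:
        Relative tolerance for the integer period-ratio test that links
        two peaks of the same family.
    dominance:
        Peaks whose raw score is below ``dominance`` times the strongest
        peak's are discarded: partial rational aliases of a true period
        saturate Monte-Carlo p-values just like the fundamental but
        cluster far more weakly, and the raw score separates them.
    plateau_tol:
        Relative raw-score band defining a family's top plateau; the
        fundamental is the largest period inside it (divisor aliases of a
        true period tie with it up to inter-cluster fluctuations, while
        genuine harmonics kP score distinctly lower).
    sites:
        When given, exactly periodic patterns are disambiguated by their
        exact-alignment multiplicity: every integer divisor of the true
        period keeps the full coincidence count, so the fundamental is
        the largest family member of maximal multiplicity.  Without
        sites, the raw-score plateau alone decides, which can prefer a
        divisor alias whose accidental cluster geometry scores slightly
        higher.
    """
    if spectrum.calibrated:
        sig = spectrum.neglog10p
    else:
        sig = spectrum.scores
        min_neglog10p = -np.inf
    scores = spectrum.scores
    idx = [
        i
        for i in _plateau_local_maxima(sig, scores)
        if sig[i] >= min_neglog10p
    ]
    if not idx:
        return PeakSet(peaks=())
    top = max(scores[i] for i in idx)
    idx = [i for i in idx if scores[i] >= dominance * top]
    periods = [float(spectrum.periods[i]) for i in idx]

    # harmonic families = connected components under integer period ratios
    parent = list(range(len(idx)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(len(idx)):
        for b in range(a):
            hi, lo = max(periods[a], periods[b]), min(periods[a], periods[b])
            if _integer_ratio(hi, lo, harmonic_tol):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb

    groups: dict[int, list[int]] = {}
    for a in range(len(idx)):
        groups.setdefault(find(a), []).append(a)

    def family_sig(members: list[int]) -> tuple[float, float]:
        return (
            max(float(sig[idx[m]]) for m in members),
            max(float(scores[idx[m]]) for m in members),
        )

    multiplicity = None
    if sites is not None:
        multiplicity = {
            m: alignment_multiplicity(sites, periods[m], J=spectrum.J or None)
            for m in range(len(idx))
        }

    peaks: list[Peak] = []
    ordered = sorted(groups.values(), key=family_sig, reverse=True)
    for gid, members in enumerate(ordered):
        if multiplicity is not None and max(multiplicity[m] for m in members) > 0:
            m_top = max(multiplicity[m] for m in members)
            plateau = [m for m in members if multiplicity[m] == m_top]
        else:
            fam_top = max(scores[idx[m]] for m in members)
            plateau = [
                m for m in members if scores[idx[m]] >= (1 - plateau_tol) * fam_top
            ]
        fundamental = max(periods[m] for m in plateau)
        for m in sorted(members, key=lambda m: -sig[idx[m]]):
            neglog = float(sig[idx[m]]) if spectrum.calibrated else float("nan")
            peaks.append(
                Peak(
                    period=periods[m],
                    score=float(scores[idx[m]]),
                    neglog10p=neglog,
                    group_id=gid,
                    fundamental=periods[m] == fundamental,
                )
            )
    return PeakSet(peaks=tuple(peaks))


def modal_period(values, tol: float = 0.02) -> float:
    """Most frequent period among noisy estimates, binned within ``tol``.

    Sorted values fall into relative bins anchored at each bin's first
    member (a value opens a new bin once it exceeds the anchor by more
    than ``tol``); anchoring prevents scattered outliers from daisy-
    chaining into one wide cluster.  The representative of the most
    populated bin is its median member; ties between equally populated
    bins go to the larger period.
    """
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("no period estimates given")
    clusters: list[list[float]] = [[values[0]]]
    for v in values[1:]:
        if v <= clusters[-1][0] * (1 + tol):
            clusters[-1].append(v)
        else:
            clusters.append([v])
    best = max(clusters, key=lambda c: (len(c), c[-1]))
    return float(best[len(best) // 2])


def main_period(
    spectrum: SolenoidalSpectrum,
    harmonic_tol: float = 0.02,
    plateau_tol: float = 0.05,
    sites: SiteSequence | None = None,
) -> float:
    """Fundamental period of the most significant harmonic family.

    Works on calibrated and raw spectra alike (the raw route is fully
    deterministic).  Raises if no peak clears the significance threshold.
    """
    peaks = find_peaks(
        spectrum, harmonic_tol=harmonic_tol, plateau_tol=plateau_tol, sites=sites
    )
    fundamentals = peaks.fundamentals
    if not fundamentals:
        raise ValueError("no significant peak in the spectrum")
    return fundamentals[0]
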