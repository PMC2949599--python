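"""Synthetic site generators: combs, motif trains, jitter, contamination.

These generators produce every benchmark condition used to validate the
detector: an ideal Dirac comb, an aperiodic multi-site motif repeated
with a fixed period, uniform positional jitter around each site, site
deletion (false negatives) with replacement by uniform impostors (false
positives), and superpositions of two trains with different periods.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .solenoid import SiteSequence

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "dirac_comb",
    "motif_train",
    "random_motif_offsets",
    "add_jitter",
    "contaminate",
    "mixture",
    "LabeledSites",
    "benchmark_comb",
    "benchmark_motif_train",
    "benchmark_two_train_mixture",
    "benchmark_grid",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Record of how a synthetic site set was built (written as a JSON sidecar)."""

    kind: str
    periods: tuple[float, ...]
    offsets: tuple[tuple[int, ...], ...] = ()
    repeats: tuple[int, ...] = ()
    length: int = 0
    jitter_amplitude: float = 0.0
    jitter_mode: str = "full"
    n_delete: int = 0
    n_add: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.periods):
            raise ValueError("periods must be positive")
        if self.jitter_amplitude < 0:
            raise ValueError("jitter amplitude must be nonnegative")
        if self.periods and self.jitter_amplitude >= min(self.periods):
            raise ValueError("jitter amplitude must be smaller than the period")
        if self.n_delete < 0 or self.n_add < 0:
            raise ValueError("contamination counts must be nonnegative")
        for per, offs in zip(self.periods, self.offsets):
            if any(not 0 <= o < per for o in offs):
                raise ValueError("motif offsets must lie in [0, period)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class LabeledSites:
    """Union of two trains with the provenance of every surviving site."""

    sites: SiteSequence
    labels: np.ndarray = field(repr=False)  # 0 = first train, 1 = second


def dirac_comb(period: int, length: int) -> SiteSequence:
    """Sites at 0, P, 2P, ... below the support length."""
    if not 0 < period <= length:
        raise ValueError(f"need 0 < period <= length, got P={period}, L={length}")
    return SiteSequence(length, np.arange(0, length, period, dtype=np.int64))


def motif_train(
    offsets, period: int, repeats: int, length: int | None = None
) -> SiteSequence:
    """Repeat a within-period motif: union of {offset + k*P, k < repeats}."""
    offsets = np.asarray(offsets, dtype=np.int64)
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    if np.any((offsets < 0) | (offsets >= period)):
        raise ValueError("offsets must lie in [0, period)")
    if length is None:
        length = repeats * period
    pos = (offsets[None, :] + period * np.arange(repeats)[:, None]).ravel()
    pos = pos[pos < length]
    if np.unique(pos).size < pos.size:
        logger.warning("motif train produced duplicate positions; deduplicated")
    return SiteSequence(length, pos)


def random_motif_offsets(
    n_offsets: int, period: int, rng: np.random.Generator, min_sep: int | None = None
) -> np.ndarray:
    """Draw distinct aperiodic motif offsets within one period.

    Redraws until all pairwise spacings (including the wrap-around ones)
    are distinct, so the motif shares no internal spacing that could
    masquerade as a shorter period.
    """
    if min_sep is None:
        min_sep = max(period // (20 * n_offsets), 1)
    for _ in range(1000):
        offs = np.sort(rng.integers(0, period, size=n_offsets))
        gaps_all = np.abs(offs[:, None] - offs[None, :])
        diffs = gaps_all[np.triu_indices(n_offsets, k=1)]
        circ = np.concatenate([diffs, period - diffs])
        if np.min(np.diff(offs), initial=period) < min_sep:
            continue
        if np.unique(circ).size == circ.size:
            return offs
    raise RuntimeError("could not draw an aperiodic motif")  # pragma: no cover


def add_jitter(
    sites: SiteSequence,
    amplitude: float,
    rng: np.random.Generator,
    mode: str = "full",
) -> SiteSequence:
    """Displace every site by an independent uniform draw.

    ``mode='full'`` reads ``amplitude`` as the full width of the uniform
    law (draws in [-A/2, +A/2]); ``mode='half'`` as the half width
    (draws in [-A, +A]).  Displaced positions are rounded, clipped to the
    support and re-sorted.
    """
    if amplitude < 0:
        raise ValueError("jitter amplitude must be nonnegative")
    if mode not in ("full", "half"):
        raise ValueError(f"jitter mode must be 'full' or 'half', got {mode!r}")
    half = amplitude / 2.0 if mode == "full" else float(amplitude)
    disp = rng.uniform(-half, half, size=sites.n)
    pos = np.clip(np.rint(sites.positions + disp), 0, sites.length - 1)
    return SiteSequence(sites.length, pos.astype(np.int64))


def contaminate(
    sites: SiteSequence,
    n_delete: int,
    n_add: int,
    rng: np.random.Generator,
) -> SiteSequence:
    """Delete sites at random (false negatives) and add uniform impostors.

    Added positions are resampled on collision with surviving sites so
    the output size is exactly ``N - n_delete + n_add``.
    """
    if n_delete > sites.n:
        raise ValueError(f"cannot delete {n_delete} of {sites.n} sites")
    keep = np.sort(rng.choice(sites.n, size=sites.n - n_delete, replace=False))
    pos = set(sites.positions[keep].tolist())
    while len(pos) < sites.n - n_delete + n_add:
        pos.add(int(rng.integers(0, sites.length)))
    return SiteSequence(sites.length, np.fromiter(pos, dtype=np.int64))


def mixture(train1: SiteSequence, train2: SiteSequence) -> LabeledSites:
    """Sorted union of two trains, keeping per-site provenance labels.

    A position present in both trains is kept once and labeled with the
    first train.
    """
    if train1.length != train2.length:
        raise ValueError("trains must share the same support length")
    pos = np.concatenate([train1.positions, train2.positions])
    lab = np.concatenate(
        [np.zeros(train1.n, dtype=np.int64), np.ones(train2.n, dtype=np.int64)]
    )
    order = np.argsort(pos, kind="stable")
    pos, lab = pos[order], lab[order]
    uniq, first = np.unique(pos, return_index=True)
    if uniq.size < pos.size:
        logger.warning("mixture trains overlap at %d position(s)", pos.size - uniq.size)
    return LabeledSites(
        sites=SiteSequence(train1.length, uniq), labels=lab[np.sort(first)]
    )


# ---------------------------------------------------------------------------
# Canonical benchmark scenarios
#
# These builders pin down the validation conditions used throughout the
# test suite: a 20-tooth comb of spacing 10000 on a 200 kb support, an
# aperiodic 5-site motif repeated 8 times at period 10000 (40 sites), and
# a superposition of two 3-site motif trains with repeat distances 7270
# and 10000 laid down up to position 80000 (~57 sites).  Candidate
# periods are swept over 2000..40000 in steps of 10.

def benchmark_grid() -> np.ndarray:
    """Default candidate-period grid for the benchmark scenarios."""
    return np.arange(2000, 40001, 10, dtype=float)


def benchmark_comb(period: int = 10000, length: int = 200000) -> SiteSequence:
    """Ideal Dirac comb: spacing 10000 on a 200 kb support (20 sites)."""
    return dirac_comb(period, length)


def benchmark_motif_train(
    seed, n_offsets: int = 5, period: int = 10000, repeats: int = 8
) -> tuple[SiteSequence, ScenarioSpec]:
    """Aperiodic multi-site motif repeated with a fixed period (40 sites)."""
    rng = np.random.default_rng(seed)
    offsets = random_motif_offsets(n_offsets, period, rng)
    sites = motif_train(offsets, period, repeats)
    spec = ScenarioSpec(
        kind="motif_train",
        periods=(float(period),),
        offsets=(tuple(int(o) for o in offsets),),
        repeats=(repeats,),
        length=sites.length,
        seed=None if seed is None else int(seed),
    )
    return sites, spec


def benchmark_two_train_mixture(
    seed,
    periods: tuple[int, int] = (7270, 10000),
    n_offsets: int = 3,
    length: int = 80000,
) -> tuple[LabeledSites, ScenarioSpec]:
    """Superposition of two motif trains with different repeat distances."""
    rng = np.random.default_rng(seed)
    p1, p2 = periods
    off1 = random_motif_offsets(n_offsets, p1, rng)
    off2 = random_motif_offsets(n_offsets, p2, rng)
    t1 = motif_train(off1, p1, -(-length // p1), length=length)
    t2 = motif_train(off2, p2, -(-length // p2), length=length)
    mix = mixture(t1, t2)
    spec = ScenarioSpec(
        kind="mixture",
        periods=(float(p1), float(p2)),
        offsets=(tuple(int(o) for o in off1), tuple(int(o) for o in off2)),
        repeats=(-(-length // p1), -(-length // p2)),
        length=length,
        seed=None if seed is None else int(seed),
    )
    return mix, spec


def add_jitter_labeled(
    labeled: LabeledSites,
    amplitude: float,
    rng: np.random.Generator,
    mode: str = "full",
) -> LabeledSites:
    """Jitter a labeled mixture, keeping labels attached through re-sorting.

    Replicates where the jitter makes two sites collide are rare; the
    colliding sites are deduplicated and the first label kept.
    """
    if mode not in ("full", "half"):
        raise ValueError(f"jitter mode must be 'full' or 'half', got {mode!r}")
    half = amplitude / 2.0 if mode == "full" else float(amplitude)
    sites = labeled.sites
    disp = rng.uniform(-half, half, size=sites.n)
    pos = np.clip(np.rint(sites.positions + disp), 0, sites.length - 1).astype(np.int64)
    order = np.argsort(pos, kind="stable")
    pos, lab = pos[order], labeled.labels[order]
    uniq, first = np.unique(pos, return_index=True)
    return LabeledSites(sites=SiteSequence(sites.length, uniq), labels=lab[first])
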