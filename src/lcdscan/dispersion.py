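"""Linear dispersion of residues within a sequence window.

The linear dispersion statistic quantifies how uniformly a set of residues
of interest (set A) is spread across a window, relative to all other
residues (set B) and the sequence termini.  For each set, the 1-based
positions are augmented with virtual termini at 0 and L+1 and consecutive
differences are taken; the two gap arrays are combined and their population
standard deviation ``s`` is computed.  ``s`` is then normalized against the
minimum and maximum standard deviations attainable by any arrangement of
the same number of target residues in a window of the same length:

    s_norm = 1 - (s - s_min) / (s_max - s_min)

so that ``s_norm`` ranges from 0 (target residues fully clustered at one
end) to 1 (target residues spread as uniformly as possible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

__all__ = [
    "SpacingProfile",
    "DispersionBounds",
    "spacing_values",
    "dispersion_bounds",
    "normalized_dispersion",
]


@dataclass(frozen=True)
class SpacingProfile:
    """Combined residue-spacing array of a window.

    Attributes
    ----------
    gaps : tuple of int
        Consecutive position differences ``d_i`` for the target set
        followed by those for the complement set.  Every gap is >= 1 and
        the gaps sum to ``2 * (L + 1)`` for a window of length ``L``.
    mean_gap : float
        Mean of the combined gap array.
    count : int
        Number of gaps ``N``; always ``L + 2``.
    raw_sd : float
        Population standard deviation ``s`` of the gaps (divide by N).
    """

    gaps: tuple[int, ...]
    mean_gap: float
    count: int
    raw_sd: float


@dataclass(frozen=True)
class DispersionBounds:
    """Extremal spacing standard deviations for (L, k).

    ``min_arrangement`` / ``max_arrangement`` are binary occupancy strings
    of length L ('1' = target residue) realizing ``s_min`` and ``s_max``.
    """

    s_min: float
    s_max: float
    min_arrangement: str
    max_arrangement: str


def _consecutive_gaps(positions: Sequence[int], length: int) -> list[int]:
    """Successive differences over sorted 1-based positions augmented with
    virtual termini 0 and length+1.  An empty set yields the single gap
    ``length + 1``."""
    gaps = []
    prev = 0
    for p in positions:
        gaps.append(p - prev)
        prev = p
    gaps.append(length + 1 - prev)
    return gaps


def _population_sd(values: Sequence[int]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, math.sqrt(var)


def spacing_values(window: str, target_set: Iterable[str]) -> SpacingProfile:
    """Compute the combined spacing array of ``window`` for ``target_set``.

    Positions of target residues and of all remaining residues are each
    augmented with the window termini; the two consecutive-gap arrays are
    concatenated and summarized.

    Raises
    ------
    ValueError
        If the window is empty or the target set is empty.
    """
    if not window:
        raise ValueError("window must be non-empty")
    targets = frozenset(target_set)
    if not targets:
        raise ValueError("target set must be non-empty")
    length = len(window)
    target_pos = [i + 1 for i, aa in enumerate(window) if aa in targets]
    other_pos = [i + 1 for i, aa in enumerate(window) if aa not in targets]
    gaps = _consecutive_gaps(target_pos, length) + _consecutive_gaps(other_pos, length)
    mean, sd = _population_sd(gaps)
    return SpacingProfile(gaps=tuple(gaps), mean_gap=mean, count=len(gaps), raw_sd=sd)


def _arrangement_sd(occupancy: str) -> float:
    return spacing_values(occupancy, {"1"}).raw_sd


@lru_cache(maxsize=4096)
def dispersion_bounds(length: int, k: int) -> DispersionBounds:
    """Constructive extremal arrangements of ``k`` target residues in a
    window of ``length``.

    The minimum-SD arrangement spreads residues as uniformly as possible so
    that every combined gap differs from the mean gap by less than one:
    the smaller of the two sets is placed at near-equal intervals (m+1 gaps
    of size floor/ceil of ``(length + 1) / (m + 1)``, larger gaps
    N-terminal), which interleaves both sets.  The maximum-SD arrangement
    clusters all k target residues at the N-terminus.
    """
    if length < 1:
        raise ValueError("window length must be >= 1")
    if k < 0 or k > length:
        raise ValueError(f"target count k={k} must satisfy 0 <= k <= L={length}")

    # place the minority set uniformly; the complement fills the gaps
    minority = min(k, length - k)
    q, r = divmod(length + 1, minority + 1)
    gap_sizes = [q + 1] * r + [q] * (minority + 1 - r)
    occupied = [False] * length
    pos = 0
    for g in gap_sizes[:-1]:
        pos += g
        occupied[pos - 1] = True
    if k > length - k:
        occupied = [not o for o in occupied]
    min_arr = "".join("1" if o else "0" for o in occupied)

    max_arr = "1" * k + "0" * (length - k)

    s_min = _arrangement_sd(min_arr)
    s_max = _arrangement_sd(max_arr)
    return DispersionBounds(
        s_min=s_min, s_max=s_max, min_arrangement=min_arr, max_arrangement=max_arr
    )


def normalized_dispersion(window: str, target_set: Iterable[str]) -> float:
    """Normalized linear dispersion ``s_norm`` of ``window`` in [0, 1].

    Degenerate windows where the bounds coincide (k = 0, k = L, or very
    short windows) return 1.0 by convention: a homopolymeric window is
    treated as maximally dispersed.
    """
    profile = spacing_values(window, target_set)
    targets = frozenset(target_set)
    k = sum(1 for aa in window if aa in targets)
    bounds = dispersion_bounds(len(window), k)
    span = bounds.s_max - bounds.s_min
    if span <= 1e-12:
        return 1.0
    s_norm = 1.0 - (profile.raw_sd - bounds.s_min) / span
    return min(1.0, max(0.0, s_norm))
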