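"""Deterministic benchmark sequences and synthetic proteomes.

Two kinds of generators: exhaustive two-letter benchmark sequences for
validating the dispersion statistic against brute force, and synthetic
proteomes with planted low-complexity segments of known class and position
embedded in compositionally diverse background, for end-to-end recovery
tests of the scanner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .scanner import CANONICAL_AA, SearchCriteria, scan_protein

__all__ = ["PlantedProteome", "binary_benchmark", "planted_proteome"]

_MAX_BENCHMARK_LENGTH = 14


@dataclass(frozen=True)
class PlantedProteome:
    """A synthetic proteome with ground-truth planted LCD annotations.

    ``truth`` rows are (protein_id, class_label, start, end), 1-based
    inclusive, matching the planted segments exactly.
    """

    proteins: tuple[tuple[str, str], ...]
    truth: tuple[tuple[str, str, int, int], ...]
    seed: int

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for pid, seq in self.proteins:
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tclass\tstart\tend\n")
            for pid, cls, start, end in self.truth:
                fh.write(f"{pid}\t{cls}\t{start}\t{end}\n")


def binary_benchmark(
    length: int, alphabet: Sequence[str] = ("Q", "A"), k: int | None = None
) -> Iterator[str]:
    """Yield every two-letter sequence of ``length`` (optionally at fixed
    count ``k`` of the first letter).

    Exhaustive and duplicate-free: 2**length sequences, or C(length, k)
    when ``k`` is given.  ``length`` is capped at 14 as a combinatorial
    guard.
    """
    if length > _MAX_BENCHMARK_LENGTH:
        raise ValueError(
            f"benchmark length {length} exceeds guard {_MAX_BENCHMARK_LENGTH}"
        )
    if length < 1:
        raise ValueError("length must be >= 1")
    a, b = alphabet
    if k is None:
        for combo in itertools.product((a, b), repeat=length):
            yield "".join(combo)
    else:
        if not 0 <= k <= length:
            raise ValueError(f"k={k} outside 0..{length}")
        for pos in itertools.combinations(range(length), k):
            yield "".join(a if i in pos else b for i in range(length))


def _sample_background(
    rng: np.random.Generator, length: int, profile: dict[str, float]
) -> str:
    letters = sorted(profile)
    probs = np.array([profile[aa] for aa in letters], dtype=float)
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def _has_passing_window(seq: str, criteria: SearchCriteria) -> bool:
    if len(seq) < criteria.window_size:
        return False
    return any(ev.passes for ev in scan_protein(seq, criteria))


def planted_proteome(
    n_background: int,
    background_composition: dict[str, float] | None,
    plants: Sequence[tuple[str, int, int]],
    seed: int,
    length_range: tuple[int, int] = (150, 350),
    reject_criteria: SearchCriteria | None = None,
    max_attempts: int = 200,
) -> PlantedProteome:
    """Generate a reproducible proteome with planted LCD segments.

    Parameters
    ----------
    n_background : int
        Number of pure-background proteins.
    background_composition : dict residue -> weight, or None
        Background residue profile (None = uniform over the 20 canonical
        residues).  For plant-bearing proteins the plant-class residues are
        removed from the profile so that planted boundaries are exact: the
        flanks can never extend a recovered domain.
    plants : sequence of (class_string, length, copies)
        Each copy becomes one extra protein carrying one planted segment of
        ``length`` residues drawn uniformly from ``class_string``.
    seed : int
        Single seed governing all randomness; identical seeds give
        byte-identical proteomes.
    reject_criteria : SearchCriteria, optional
        Background sequences containing a window passing these criteria
        are resampled (rejection sampling), guaranteeing a clean null.

    Raises
    ------
    RuntimeError
        If rejection sampling cannot produce a clean background within
        ``max_attempts`` tries (infeasible composition constraints).
    """
    rng = np.random.default_rng(seed)
    if background_composition is None:
        background_composition = {aa: 1.0 for aa in CANONICAL_AA}
    lo, hi = length_range

    def clean_background(length: int, profile: dict[str, float]) -> str:
        for _ in range(max_attempts):
            seq = _sample_background(rng, length, profile)
            if reject_criteria is None or not _has_passing_window(seq, reject_criteria):
                return seq
        raise RuntimeError(
            "could not sample a background sequence free of passing windows; "
            "composition constraints are infeasible"
        )

    proteins: list[tuple[str, str]] = []
    truth: list[tuple[str, str, int, int]] = []

    for i in range(n_background):
        length = int(rng.integers(lo, hi + 1))
        proteins.append((f"bg{i + 1:04d}", clean_background(length, background_composition)))

    plant_idx = 0
    for cls, seg_len, copies in plants:
        cls_set = set(cls)
        flank_profile = {
            aa: wt for aa, wt in background_composition.items() if aa not in cls_set
        }
        if not flank_profile:
            raise RuntimeError(
                f"background profile has no residues outside plant class {cls!r}"
            )
        for _ in range(copies):
            plant_idx += 1
            length = int(rng.integers(lo, hi + 1))
            host = clean_background(length, flank_profile)
            segment = "".join(rng.choice(sorted(cls_set), size=seg_len))
            insert_at = int(rng.integers(0, length + 1))  # 0-based insertion point
            seq = host[:insert_at] + segment + host[insert_at:]
            pid = f"plant{plant_idx:03d}_{cls}"
            proteins.append((pid, seq))
            truth.append((pid, cls, insert_at + 1, insert_at + seg_len))

    return PlantedProteome(proteins=tuple(proteins), truth=tuple(truth), seed=seed)
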