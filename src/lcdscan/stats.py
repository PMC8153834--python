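"""Composition-centric statistics on LCD result tables.

Downstream of the scanner: partition each primary LCD class into
subclasses by the unambiguous second-most-abundant residue, compare
observed subclass frequencies against whole-proteome window frequencies by
log odds ratio and Fisher's exact test, enumerate the full
primary/secondary subclass search grid, count co-occurring (non-
overlapping, distinct-class) LCDs per protein, and summarize proteome LCD
content percentages.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .scanner import CANONICAL_AA, SearchCriteria, scan_proteome

__all__ = [
    "EnrichmentResult",
    "ProteomeSummary",
    "WholeProteomeFrequencies",
    "assign_secondary",
    "whole_proteome_window_frequencies",
    "subclass_enrichment",
    "secondary_enrichment_analysis",
    "subclass_search_grid",
    "cooccurrence_matrix",
    "proteome_lcd_content",
]

CONTENT_BINS: tuple[tuple[float, float, str], ...] = (
    (0.0, 0.1, "extremely low (0-0.1%)"),
    (0.1, 0.5, "very low (0.1-0.5%)"),
    (0.5, 2.0, "low (0.5-2%)"),
    (2.0, 5.0, "medium (2-5%)"),
    (5.0, 10.0, "high (5-10%)"),
    (10.0, 15.0, "very high (10-15%)"),
    (15.0, math.inf, "extremely high (>15%)"),
)


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one (primary, secondary) LCD subclass.

    ``log_odds`` is E_s = ln(OR_s) with OR_s the odds ratio of the observed
    subclass fraction against the whole-proteome window fraction.  Status
    is ``excluded_low_frequency`` when the scaled whole-proteome frequency
    (f_wp x total observed LCDs) is below 1, ``imputed`` when no LCD was
    observed but the scaled frequency is >= 1 (observed count set to 1 as a
    conservatively biased estimate), and ``included`` otherwise.
    """

    primary_aa: str
    secondary_aa: str
    observed_count: int
    f_obs: float
    f_wp: float
    scaled_wp_frequency: float
    odds_ratio: float
    log_odds: float
    p_value: float
    p_bonferroni: float
    status: str


@dataclass(frozen=True)
class WholeProteomeFrequencies:
    """Secondary-assignment tallies from an exhaustive proteome window scan."""

    primary_aa: str
    counts: dict[str, int]
    total_windows: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.total_windows == 0:
            return {aa: 0.0 for aa in self.counts}
        return {aa: c / self.total_windows for aa, c in self.counts.items()}


@dataclass(frozen=True)
class ProteomeSummary:
    """Per-class LCD content of a proteome.

    Residues inside overlapping LCDs of different classes count once per
    class, so ``total_percent`` (the sum over classes) may slightly exceed
    the percentage of residues in the union of all LCDs.
    """

    per_class_lcd_residues: dict[str, int]
    total_residues: int
    per_class_percent: dict[str, float]
    per_class_bin: dict[str, str]
    total_percent: float


def assign_secondary(sequence: str, primary_aa: str) -> str | None:
    """Unambiguous secondary residue of a window or LCD sequence.

    Excluding the primary residue, the secondary residue is the unique most
    abundant canonical residue — i.e. it is either unambiguously the most
    abundant overall, or second-most abundant behind only the primary.
    Returns None when tied (ambiguous) or when no other residue occurs.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    counts = Counter(aa for aa in sequence if aa in CANONICAL_AA and aa != primary_aa)
    if not counts:
        return None
    best = max(counts.values())
    leaders = [aa for aa, c in counts.items() if c == best]
    if len(leaders) != 1:
        return None
    return leaders[0]


def whole_proteome_window_frequencies(
    proteome, primary_aa: str, window_size: int = 20
) -> WholeProteomeFrequencies:
    """Tally secondary assignments over every window of a proteome.

    Every window of every protein of length >= ``window_size`` is assigned
    a secondary residue (or none, when ambiguous); fractions are normalized
    by the total number of windows encountered, so they sum to <= 1.
    """
    if isinstance(proteome, (str, bytes)) or hasattr(proteome, "__fspath__"):
        from .io import read_fasta

        proteins = read_fasta(proteome)
    else:
        proteins = list(proteome)

    counts: Counter[str] = Counter()
    total = 0
    for _, seq in proteins:
        if len(seq) < window_size:
            continue
        # sliding tally: update residue counts at the window edges only
        window_counts = Counter(seq[:window_size])
        total += 1
        sec = _secondary_from_counts(window_counts, primary_aa)
        if sec is not None:
            counts[sec] += 1
        for i in range(1, len(seq) - window_size + 1):
            window_counts[seq[i - 1]] -= 1
            window_counts[seq[i + window_size - 1]] += 1
            total += 1
            sec = _secondary_from_counts(window_counts, primary_aa)
            if sec is not None:
                counts[sec] += 1
    all_secondary = {aa: counts.get(aa, 0) for aa in CANONICAL_AA if aa != primary_aa}
    return WholeProteomeFrequencies(
        primary_aa=primary_aa, counts=all_secondary, total_windows=total
    )


def _secondary_from_counts(window_counts: Mapping[str, int], primary_aa: str) -> str | None:
    best = 0
    leader = None
    tied = False
    for aa, c in window_counts.items():
        if aa == primary_aa or aa not in CANONICAL_AA or c <= 0:
            continue
        if c > best:
            best, leader, tied = c, aa, False
        elif c == best and c > 0:
            tied = True
    return None if tied or leader is None else leader


def subclass_enrichment(
    observed: Mapping[str, int],
    wp_freqs: Mapping[str, float],
    total_observed: int,
    primary_aa: str = "?",
    wp_counts: Mapping[str, int] | None = None,
    wp_total: int | None = None,
) -> list[EnrichmentResult]:
    """Enrichment/depletion of each LCD subclass versus proteome windows.

    For each secondary residue: subclasses whose scaled whole-proteome
    frequency (f_wp x total_observed) is < 1 are excluded; subclasses with
    no observed LCDs but scaled frequency >= 1 get an imputed observed
    count of 1.  E_s = ln[(f_obs/(1-f_obs)) / (f_wp/(1-f_wp))].  The
    two-sided Fisher exact p-value uses the integer 2x2 table
    [obs_s, obs_total - obs_s; wp_s, wp_total - wp_s] and requires
    ``wp_counts``/``wp_total`` (NaN otherwise); Bonferroni correction is
    applied over the non-excluded tests.

    Degenerate fractions (f_obs or f_wp equal to 0 or 1 after imputation)
    yield NaN odds ratios rather than infinities.
    """
    if total_observed < 1:
        raise ValueError("total_observed must be >= 1")
    results: list[EnrichmentResult] = []
    for aa in sorted(wp_freqs):
        f_wp = float(wp_freqs[aa])
        scaled = f_wp * total_observed
        obs = int(observed.get(aa, 0))
        if scaled < 1.0:
            results.append(
                EnrichmentResult(
                    primary_aa=primary_aa,
                    secondary_aa=aa,
                    observed_count=obs,
                    f_obs=obs / total_observed,
                    f_wp=f_wp,
                    scaled_wp_frequency=scaled,
                    odds_ratio=float("nan"),
                    log_odds=float("nan"),
                    p_value=float("nan"),
                    p_bonferroni=float("nan"),
                    status="excluded_low_frequency",
                )
            )
            continue
        status = "included"
        if obs == 0:
            obs = 1
            status = "imputed"
        f_obs = obs / total_observed
        if 0.0 < f_obs < 1.0 and 0.0 < f_wp < 1.0:
            odds_ratio = (f_obs / (1 - f_obs)) / (f_wp / (1 - f_wp))
            log_odds = math.log(odds_ratio)
        else:
            odds_ratio = float("nan")
            log_odds = float("nan")
        if wp_counts is not None and wp_total is not None:
            table = [
                [obs, total_observed - obs],
                [wp_counts.get(aa, 0), wp_total - wp_counts.get(aa, 0)],
            ]
            p_value = float(fisher_exact(table, alternative="two-sided")[1])
        else:
            p_value = float("nan")
        results.append(
            EnrichmentResult(
                primary_aa=primary_aa,
                secondary_aa=aa,
                observed_count=obs,
                f_obs=f_obs,
                f_wp=f_wp,
                scaled_wp_frequency=scaled,
                odds_ratio=odds_ratio,
                log_odds=log_odds,
                p_value=p_value,
                p_bonferroni=float("nan"),
                status=status,
            )
        )
    n_tests = sum(1 for r in results if r.status != "excluded_low_frequency")
    corrected = []
    for r in results:
        if r.status == "excluded_low_frequency" or math.isnan(r.p_value):
            corrected.append(r)
        else:
            corrected.append(replace(r, p_bonferroni=min(1.0, r.p_value * n_tests)))
    return corrected


def secondary_enrichment_analysis(
    proteome,
    primary_aa: str,
    composition_threshold: float = 40.0,
    window_size: int = 20,
    dispersion_threshold: float = 0.5,
) -> pd.DataFrame:
    """End-to-end subclass enrichment for one primary LCD class.

    Scans the proteome for LCDs of the primary class, assigns each LCD its
    secondary residue, tallies whole-proteome window frequencies, and runs
    :func:`subclass_enrichment`.  Returns a tidy DataFrame (one row per
    secondary residue).
    """
    criteria = SearchCriteria(
        groups=[{primary_aa}],
        thresholds=[composition_threshold],
        window_size=window_size,
        dispersion_threshold=dispersion_threshold,
    )
    table = scan_proteome(proteome, criteria)
    observed: Counter[str] = Counter()
    for seq in table["domain_sequence"]:
        sec = assign_secondary(seq, primary_aa)
        if sec is not None:
            observed[sec] += 1
    total_observed = int(sum(observed.values()))
    wp = whole_proteome_window_frequencies(proteome, primary_aa, window_size)
    if total_observed == 0:
        return pd.DataFrame(
            columns=[
                "primary_aa", "secondary_aa", "observed_count", "f_obs", "f_wp",
                "scaled_wp_frequency", "odds_ratio", "log_odds", "p_value",
                "p_bonferroni", "status",
            ]
        )
    results = subclass_enrichment(
        observed,
        wp.fractions,
        total_observed,
        primary_aa=primary_aa,
        wp_counts=wp.counts,
        wp_total=wp.total_windows,
    )
    return pd.DataFrame([r.__dict__ for r in results])


def subclass_search_grid(
    proteome,
    primary_threshold: float = 40.0,
    secondary_threshold: float = 20.0,
    window_size: int = 20,
    dispersion_threshold: float = 0.5,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Scan once per ordered (primary, secondary) residue pair.

    Each of the 20 x 19 = 380 combinations runs the scanner with two
    single-residue groups at (primary_threshold, secondary_threshold).
    """
    if isinstance(proteome, (str, bytes)) or hasattr(proteome, "__fspath__"):
        from .io import read_fasta

        proteome = read_fasta(proteome)
    grid: dict[tuple[str, str], pd.DataFrame] = {}
    for primary in CANONICAL_AA:
        for secondary in CANONICAL_AA:
            if secondary == primary:
                continue
            criteria = SearchCriteria(
                groups=[{primary}, {secondary}],
                thresholds=[primary_threshold, secondary_threshold],
                window_size=window_size,
                dispersion_threshold=dispersion_threshold,
            )
            grid[(primary, secondary)] = scan_proteome(proteome, criteria)
    return grid


def cooccurrence_matrix(lcd_table: pd.DataFrame) -> pd.DataFrame:
    """Protein counts of co-occurring LCDs for each pair of classes.

    Entry (i, j), i != j, counts the proteins containing at least one
    class-i LCD and at least one class-j LCD that do not overlap in
    coordinates.  Symmetric with zero diagonal, indexed by the 20 canonical
    single-residue classes.
    """
    classes = list(CANONICAL_AA)
    matrix = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    if lcd_table.empty:
        return matrix
    for _, protein_rows in lcd_table.groupby("protein_id"):
        by_class: dict[str, list[tuple[int, int]]] = {}
        for _, row in protein_rows.iterrows():
            cls = str(row["class_label"])
            if cls in CANONICAL_AA:  # single-residue classes only
                by_class.setdefault(cls, []).append((int(row["start"]), int(row["end"])))
        labels = sorted(by_class)
        for i, ci in enumerate(labels):
            for cj in labels[i + 1 :]:
                if any(
                    e1 < s2 or e2 < s1
                    for (s1, e1) in by_class[ci]
                    for (s2, e2) in by_class[cj]
                ):
                    matrix.loc[ci, cj] += 1
                    matrix.loc[cj, ci] += 1
    return matrix


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def proteome_lcd_content(lcd_table: pd.DataFrame, proteome) -> ProteomeSummary:
    """Percentage of proteome residues lying within LCDs, per class.

    Overlapping same-class LCDs are merged before counting so each residue
    counts once per class; the total percent is the sum over classes and
    may double-count residues shared between classes.  Bins are half-open
    (lo, hi], with "none (0%)" reserved for exactly zero.
    """
    if isinstance(proteome, (str, bytes)) or hasattr(proteome, "__fspath__"):
        from .io import read_fasta

        proteome = read_fasta(proteome)
    total_residues = sum(len(seq) for _, seq in proteome)
    if total_residues == 0:
        raise ValueError("proteome contains no residues")

    per_class_residues: dict[str, int] = {}
    if not lcd_table.empty:
        for (cls,), class_rows in lcd_table.groupby(["class_label"]):
            n = 0
            for _, protein_rows in class_rows.groupby("protein_id"):
                intervals = [
                    (int(r["start"]), int(r["end"])) for _, r in protein_rows.iterrows()
                ]
                n += sum(e - s + 1 for s, e in _merge_intervals(intervals))
            per_class_residues[str(cls)] = n

    per_class_percent = {
        cls: 100.0 * n / total_residues for cls, n in per_class_residues.items()
    }
    per_class_bin = {cls: content_bin(p) for cls, p in per_class_percent.items()}
    return ProteomeSummary(
        per_class_lcd_residues=per_class_residues,
        total_residues=total_residues,
        per_class_percent=per_class_percent,
        per_class_bin=per_class_bin,
        total_percent=float(sum(per_class_percent.values())),
    )


def content_bin(percent: float) -> str:
    """Categorical LCD-content bin for a percentage; half-open (lo, hi]."""
    if percent < 0 or percent > 100:
        raise ValueError("percent outside [0, 100]")
    if percent == 0:
        return "none (0%)"
    for lo, hi, label in CONTENT_BINS:
        if lo < percent <= hi:
            return label
    raise AssertionError("unreachable")
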