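"""Sliding-window identification and demarcation of low-complexity domains.

Each protein is scanned with a fixed-size window (step 1).  A window passes
when every user-defined residue group meets its minimum composition
threshold and the normalized linear dispersion of the combined group
residues meets the dispersion threshold (with two escape hatches: windows
whose combined composition exceeds the midpoint between the threshold and
100% skip the dispersion check, and 100%-composition windows always pass).
Overlapping passing windows are merged and the merged span is trimmed from
both ends until its terminal residues belong to the residue set of
interest; final compositions and dispersion are recomputed on the trimmed
domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dispersion import normalized_dispersion

logger = logging.getLogger(__name__)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "CANONICAL_AA",
    "SearchCriteria",
    "WindowEvaluation",
    "LCDRecord",
    "window_composition",
    "evaluate_window",
    "scan_protein",
    "merge_and_trim",
    "scan_proteome",
]

_EPS = 1e-9


@dataclass(frozen=True)
class SearchCriteria:
    """User-defined LCD search criteria.

    Parameters
    ----------
    groups : sequence of frozenset of str
        Ordered, pairwise-disjoint groups of canonical 1-letter residue
        codes; the union of the groups is the set of residues of interest.
    thresholds : sequence of float
        Minimum composition (percent, 0-100) per group, positionally
        aligned with ``groups``.
    window_size : int
        Scanning window length (default 20).
    dispersion_threshold : float
        Minimum normalized linear dispersion in [0, 1] (default 0.5).
    ignore_cutoff : float or None
        Combined-composition percent above which the dispersion check is
        skipped.  ``None`` (default) uses the midpoint rule: the midpoint
        between the summed group thresholds (capped at 100) and 100%.
    """

    groups: tuple[frozenset[str], ...]
    thresholds: tuple[float, ...]
    window_size: int = 20
    dispersion_threshold: float = 0.5
    ignore_cutoff: float | None = None

    def __init__(
        self,
        groups: Sequence[Iterable[str]],
        thresholds: Sequence[float],
        window_size: int = 20,
        dispersion_threshold: float = 0.5,
        ignore_cutoff: float | None = None,
    ):
        groups = tuple(frozenset(g) for g in groups)
        thresholds = tuple(float(t) for t in thresholds)
        if not groups:
            raise ValueError("at least one residue group is required")
        if len(groups) != len(thresholds):
            raise ValueError(
                f"{len(groups)} group(s) but {len(thresholds)} threshold(s)"
            )
        seen: set[str] = set()
        for g in groups:
            if not g:
                raise ValueError("residue groups must be non-empty")
            bad = g - set(CANONICAL_AA)
            if bad:
                raise ValueError(f"non-canonical residue code(s): {sorted(bad)}")
            if g & seen:
                raise ValueError("residue groups must be pairwise disjoint")
            seen |= g
        for t in thresholds:
            if not 0.0 <= t <= 100.0:
                raise ValueError(f"threshold {t} outside [0, 100]")
        if window_size < 3:
            raise ValueError("window size must be >= 3")
        if not 0.0 <= dispersion_threshold <= 1.0:
            raise ValueError("dispersion threshold must be in [0, 1]")
        if ignore_cutoff is not None and not 0.0 <= ignore_cutoff <= 100.0:
            raise ValueError("ignore cutoff must be in [0, 100]")
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "thresholds", thresholds)
        object.__setattr__(self, "window_size", int(window_size))
        object.__setattr__(self, "dispersion_threshold", float(dispersion_threshold))
        object.__setattr__(self, "ignore_cutoff", ignore_cutoff)

    @property
    def union(self) -> frozenset[str]:
        """Set A: union of all residue groups."""
        return frozenset().union(*self.groups)

    @property
    def effective_ignore_cutoff(self) -> float:
        """Combined-composition percent above which dispersion is ignored."""
        if self.ignore_cutoff is not None:
            return float(self.ignore_cutoff)
        total = min(100.0, sum(self.thresholds))
        return (total + 100.0) / 2.0

    @property
    def class_label(self) -> str:
        return "_".join(
            "".join(sorted(g, key=CANONICAL_AA.index)) for g in self.groups
        )


@dataclass(frozen=True)
class WindowEvaluation:
    """Scores for one window position (1-based ``start``)."""

    start: int
    group_compositions: tuple[float, ...]
    combined_composition: float
    s_norm: float  # NaN when not computed (composition already failed)
    dispersion_ignored: bool
    passes: bool


@dataclass(frozen=True)
class LCDRecord:
    """A final merged and trimmed low-complexity domain (1-based inclusive)."""

    protein_id: str
    start: int
    end: int
    sequence: str
    final_group_compositions: tuple[float, ...]
    final_s_norm: float
    class_label: str


def window_composition(window: str, group: Iterable[str]) -> float:
    """Percent composition of ``group`` residues in ``window``.

    Non-canonical letters (X, B, Z, U, O, J) count toward the window length
    but never toward a group.
    """
    if not window:
        raise ValueError("window must be non-empty")
    g = frozenset(group)
    return 100.0 * sum(1 for aa in window if aa in g) / len(window)


def _dispersion_verdict(
    combined: float, criteria: SearchCriteria
) -> tuple[bool, bool]:
    """(dispersion_ignored, auto_pass_full_composition)."""
    full = combined >= 100.0 - _EPS
    ignored = combined > criteria.effective_ignore_cutoff + _EPS
    return ignored, full


def evaluate_window(window: str, criteria: SearchCriteria) -> WindowEvaluation:
    """Score a single window against the criteria (start position 1)."""
    if len(window) != criteria.window_size:
        raise ValueError(
            f"window length {len(window)} != criteria window size "
            f"{criteria.window_size}"
        )
    comps = tuple(window_composition(window, g) for g in criteria.groups)
    combined = sum(comps)
    comp_ok = all(c >= t - _EPS for c, t in zip(comps, criteria.thresholds))
    ignored, full = _dispersion_verdict(combined, criteria)
    if comp_ok and not (ignored or full):
        s_norm = normalized_dispersion(window, criteria.union)
        passes = s_norm >= criteria.dispersion_threshold - _EPS
    else:
        s_norm = (
            normalized_dispersion(window, criteria.union)
            if comp_ok
            else float("nan")
        )
        passes = comp_ok
    return WindowEvaluation(
        start=1,
        group_compositions=comps,
        combined_composition=combined,
        s_norm=s_norm,
        dispersion_ignored=bool(ignored),
        passes=bool(passes),
    )


def _group_window_counts(
    sequence: str, groups: Sequence[frozenset[str]], w: int
) -> np.ndarray:
    """Per-group residue counts for every window, shape (G, n_windows)."""
    n = len(sequence)
    counts = np.empty((len(groups), n - w + 1), dtype=np.int64)
    for gi, g in enumerate(groups):
        mask = np.fromiter((aa in g for aa in sequence), dtype=np.int64, count=n)
        cs = np.concatenate(([0], np.cumsum(mask)))
        counts[gi] = cs[w:] - cs[:-w]
    return counts


def scan_protein(
    sequence: str,
    criteria: SearchCriteria,
    compute_all_dispersion: bool = False,
) -> list[WindowEvaluation]:
    """Evaluate every window of a protein (step size 1).

    Returns ``len(sequence) - window_size + 1`` evaluations in order of
    start position.  By default the dispersion statistic is only computed
    for windows whose composition already passes (it cannot change the
    verdict otherwise); ``compute_all_dispersion=True`` scores every window
    for verbose output.
    """
    w = criteria.window_size
    if len(sequence) < w:
        raise ValueError(
            f"protein length {len(sequence)} shorter than window size {w}"
        )
    counts = _group_window_counts(sequence, criteria.groups, w)
    comps = counts * 100.0 / w
    combined = comps.sum(axis=0)
    thr = np.asarray(criteria.thresholds)[:, None]
    comp_ok = np.all(comps >= thr - _EPS, axis=0)
    cutoff = criteria.effective_ignore_cutoff
    ignored = combined > cutoff + _EPS
    full = combined >= 100.0 - _EPS
    union = criteria.union

    evaluations: list[WindowEvaluation] = []
    for i in range(comps.shape[1]):
        need_disp = compute_all_dispersion or (
            comp_ok[i] and not (ignored[i] or full[i])
        )
        if need_disp:
            s_norm = normalized_dispersion(sequence[i : i + w], union)
        else:
            s_norm = float("nan")
        passes = bool(comp_ok[i]) and (
            bool(full[i])
            or bool(ignored[i])
            or s_norm >= criteria.dispersion_threshold - _EPS
        )
        evaluations.append(
            WindowEvaluation(
                start=i + 1,
                group_compositions=tuple(comps[:, i]),
                combined_composition=float(combined[i]),
                s_norm=s_norm,
                dispersion_ignored=bool(ignored[i]),
                passes=passes,
            )
        )
    return evaluations


def merge_and_trim(
    evaluations: Sequence[WindowEvaluation],
    sequence: str,
    criteria: SearchCriteria,
    protein_id: str = "",
) -> list[LCDRecord]:
    """Merge overlapping passing windows and trim to the residue set.

    Passing window spans are unioned into maximal overlapping runs (spans
    that merely abut are kept separate); each merged span is trimmed from
    both termini until the terminal residue is in the union of groups, and
    final compositions and dispersion are recomputed on the trimmed
    sequence.
    """
    w = criteria.window_size
    union = criteria.union
    spans: list[list[int]] = []  # 0-based [start, end] inclusive
    for ev in evaluations:
        if not ev.passes:
            continue
        s0 = ev.start - 1
        e0 = s0 + w - 1
        if spans and s0 <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], e0)
        else:
            spans.append([s0, e0])

    records: list[LCDRecord] = []
    for s0, e0 in spans:
        while s0 <= e0 and sequence[s0] not in union:
            s0 += 1
        while e0 >= s0 and sequence[e0] not in union:
            e0 -= 1
        if s0 > e0:
            logger.warning(
                "merged span in %s trimmed to nothing; dropped", protein_id or "?"
            )
            continue
        domain = sequence[s0 : e0 + 1]
        comps = tuple(window_composition(domain, g) for g in criteria.groups)
        records.append(
            LCDRecord(
                protein_id=protein_id,
                start=s0 + 1,
                end=e0 + 1,
                sequence=domain,
                final_group_compositions=comps,
                final_s_norm=normalized_dispersion(domain, union),
                class_label=criteria.class_label,
            )
        )
    return records


def _records_to_frame(
    records: Sequence[LCDRecord], criteria: SearchCriteria
) -> pd.DataFrame:
    comp_cols = [
        f"{''.join(sorted(g, key=CANONICAL_AA.index))}_composition"
        for g in criteria.groups
    ]
    rows = []
    for r in records:
        row = {
            "protein_id": r.protein_id,
            "domain_sequence": r.sequence,
            "start": r.start,
            "end": r.end,
        }
        row.update(dict(zip(comp_cols, r.final_group_compositions)))
        row["final_s_norm"] = r.final_s_norm
        row["class_label"] = r.class_label
        rows.append(row)
    columns = ["protein_id", "domain_sequence", "start", "end"] + comp_cols + [
        "final_s_norm",
        "class_label",
    ]
    return pd.DataFrame(rows, columns=columns)


def scan_proteome(
    proteome,
    criteria: SearchCriteria,
    verbose: bool = False,
):
    """Scan a whole proteome for LCDs matching the criteria.

    Parameters
    ----------
    proteome : str, path, or sequence of (id, sequence) pairs
        FASTA path or pre-parsed records.
    criteria : SearchCriteria
    verbose : bool
        When True, additionally return a per-window table scoring every
        window of every protein regardless of pass/fail.

    Returns
    -------
    pandas.DataFrame, or (DataFrame, DataFrame) when ``verbose``
        One row per identified domain; columns: protein_id,
        domain_sequence, start, end, one composition column per group,
        final_s_norm, class_label.
    """
    if isinstance(proteome, (str, bytes)) or hasattr(proteome, "__fspath__"):
        from .io import read_fasta

        proteins = read_fasta(proteome)
    else:
        proteins = list(proteome)

    all_records: list[LCDRecord] = []
    verbose_rows: list[dict] = []
    n_skipped = 0
    for pid, seq in proteins:
        if len(seq) < criteria.window_size:
            n_skipped += 1
            continue
        evaluations = scan_protein(seq, criteria, compute_all_dispersion=verbose)
        all_records.extend(merge_and_trim(evaluations, seq, criteria, pid))
        if verbose:
            for ev in evaluations:
                row = {"protein_id": pid, "window_start": ev.start}
                for g, c in zip(criteria.groups, ev.group_compositions):
                    key = "".join(sorted(g, key=CANONICAL_AA.index))
                    row[f"{key}_composition"] = c
                row["s_norm"] = ev.s_norm
                row["passes"] = ev.passes
                verbose_rows.append(row)
    if n_skipped:
        logger.info(
            "skipped %d protein(s) shorter than the %daa window",
            n_skipped,
            criteria.window_size,
        )

    table = _records_to_frame(all_records, criteria)
    if verbose:
        return table, pd.DataFrame(verbose_rows)
    return table
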