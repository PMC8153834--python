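"""FASTA input, criteria parsing, and TSV serialization."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .scanner import SearchCriteria

logger = logging.getLogger(__name__)

__all__ = ["CriteriaError", "parse_criteria", "read_fasta", "write_results", "write_verbose"]

FLOAT_FORMAT = "%.4f"


class CriteriaError(ValueError):
    """Invalid search-criteria specification (a usage error)."""


def parse_criteria(
    a_string: str,
    c_string: str,
    window_size: int = 20,
    dispersion_threshold: float = 0.5,
    ignore_cutoff: float | None = None,
) -> SearchCriteria:
    """Build :class:`SearchCriteria` from command-line style strings.

    ``a_string`` is an underscore-separated list of residue groups (e.g.
    ``"QN_Y"``) and ``c_string`` the matching thresholds (e.g. ``"40_10"``).
    """
    groups = [g.upper() for g in a_string.split("_") if g != ""]
    thresh_tokens = [t for t in c_string.split("_") if t != ""]
    if len(groups) != len(thresh_tokens):
        raise CriteriaError(
            f"{len(groups)} residue group(s) in {a_string!r} but "
            f"{len(thresh_tokens)} threshold(s) in {c_string!r}"
        )
    try:
        thresholds = [float(t) for t in thresh_tokens]
    except ValueError as exc:
        raise CriteriaError(f"non-numeric threshold in {c_string!r}") from exc
    try:
        return SearchCriteria(
            groups=groups,
            thresholds=thresholds,
            window_size=window_size,
            dispersion_threshold=dispersion_threshold,
            ignore_cutoff=ignore_cutoff,
        )
    except ValueError as exc:
        raise CriteriaError(str(exc)) from exc


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a protein FASTA file into an ordered list of (id, sequence).

    The identifier is the first whitespace-delimited token of the header;
    sequences are uppercased and '*' stop characters stripped.  Duplicate
    identifiers are suffixed ``.2``, ``.3``, ... with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        seq = str(rec.seq).upper().replace("*", "")
        if pid in seen:
            seen[pid] += 1
            new_id = f"{pid}.{seen[pid]}"
            logger.warning("duplicate identifier %r renamed to %r", pid, new_id)
            pid = new_id
        else:
            seen[pid] = 1
        records.append((pid, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_results(table: pd.DataFrame, path) -> None:
    """Write an LCD result table as TSV (floats fixed at 4 decimals)."""
    _write_tsv(table, path)


def write_verbose(table: pd.DataFrame, path) -> None:
    """Write a per-window verbose score table as TSV."""
    _write_tsv(table, path)


def read_results(path) -> pd.DataFrame:
    """Read back a TSV table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
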