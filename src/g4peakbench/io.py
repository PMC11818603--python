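"""Readers and writers for BED, ENCODE narrowPeak, and chromosome-size tables.

narrowPeak significance columns hold -log10-transformed values; they are
converted to plain p-values on read and back on write. A p-value of exactly 0
(reported by some callers) is written as the configured -log10 cap.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Optional

from .intervals import GenomicInterval, PeakSet, ValidationError

__all__ = ["read_peaks", "write_peaks", "read_chrom_sizes", "PeakFileError"]

NEG_LOG10_CAP = 500.0


class PeakFileError(ValueError):
    """Malformed peak file content, with the offending line number."""


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column (name, length) chromosome-size table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise PeakFileError(f"{path}:{lineno}: expected 'name length'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise PeakFileError(f"{path}:{lineno}: non-integer length") from exc
    return sizes


def _parse_row(parts: list[str], fmt: str, significance_column: Optional[int],
               neg_log10: bool, lineno: int, path) -> GenomicInterval:
    try:
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
    except (IndexError, ValueError) as exc:
        raise PeakFileError(f"{path}:{lineno}: bad chrom/start/end fields") from exc
    if start >= end:
        raise PeakFileError(f"{path}:{lineno}: start >= end ({start} >= {end})")
    name = parts[3] if len(parts) > 3 and parts[3] != "." else None
    score = None
    if len(parts) > 4 and parts[4] not in (".", ""):
        try:
            score = float(parts[4])
        except ValueError as exc:
            raise PeakFileError(f"{path}:{lineno}: non-numeric score") from exc
    strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
    pvalue = None
    if significance_column is not None:
        try:
            raw = float(parts[significance_column])
        except (IndexError, ValueError) as exc:
            raise PeakFileError(
                f"{path}:{lineno}: significance column {significance_column} unreadable"
            ) from exc
        if neg_log10:
            pvalue = min(1.0, 10.0 ** (-raw))
        else:
            pvalue = raw
        if not (0.0 <= pvalue <= 1.0):
            raise PeakFileError(f"{path}:{lineno}: p-value {pvalue} outside [0,1]")
    try:
        return GenomicInterval(chrom, start, end, name=name, score=score,
                               pvalue=pvalue, strand=strand)
    except ValidationError as exc:
        raise PeakFileError(f"{path}:{lineno}: {exc}") from exc


def read_peaks(
    path,
    format: str = "bed",
    significance_column: Optional[int] = None,
    neg_log10: Optional[bool] = None,
    label: Optional[str] = None,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> PeakSet:
    """Read a BED or narrowPeak file into a normalized (coordinate-sorted) PeakSet.

    Parameters
    ----------
    significance_column:
        0-based column index holding the significance value. Defaults to
        column 7 (-log10 p) for narrowPeak, none for BED.
    neg_log10:
        Whether the significance column is -log10 transformed. Defaults to
        True for narrowPeak, False for BED.
    chrom_sizes:
        Optional name->length table; rows on unknown chromosomes are dropped
        with a single warning reporting the count.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValidationError(f"unknown peak format {format!r}")
    if format == "narrowPeak":
        if significance_column is None:
            significance_column = 7
        if neg_log10 is None:
            neg_log10 = True
    else:
        if neg_log10 is None:
            neg_log10 = False
    intervals = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            iv = _parse_row(parts, format, significance_column, neg_log10, lineno, path)
            if chrom_sizes is not None and iv.chrom not in chrom_sizes:
                n_rejected += 1
                continue
            intervals.append(iv)
    if n_rejected:
        warnings.warn(
            f"{path}: dropped {n_rejected} row(s) on chromosomes absent from the sizes table"
        )
    return PeakSet(intervals, label=label if label is not None else Path(str(path)).stem)


def _neg_log10(p: Optional[float]) -> float:
    if p is None:
        return -1.0
    if p <= 0.0:
        return NEG_LOG10_CAP
    return min(NEG_LOG10_CAP, -math.log10(p))


def write_peaks(peaks: PeakSet, path, format: str = "bed") -> None:
    """Write a PeakSet as BED6 (BED3 when no annotation present) or narrowPeak.

    Round-trip stable: reading the written file reproduces coordinates and,
    for narrowPeak, significance to printed precision.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValidationError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks):
            name = iv.name if iv.name is not None else f"{peaks.label or 'peak'}_{i + 1}"
            if format == "bed":
                if iv.name is None and iv.score is None and iv.strand == ".":
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
                else:
                    score = 0.0 if iv.score is None else iv.score
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
                    )
            else:
                score = 0 if iv.score is None else iv.score
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}"
                    f"\t0\t{_neg_log10(iv.pvalue):.10g}\t-1\t-1\n"
                )
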