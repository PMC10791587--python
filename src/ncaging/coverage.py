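"""Covered-sequence statistics from read-alignment intervals.

For each reference ncRNA the union of its aligned read intervals gives the
covered length; the longest merged contiguous stretch is the *maximal
assembly*.  Fragment-based sequencing recovers long references only
partially, so the assembly fraction is expected to fall with reference
length — quantified here by a Spearman correlation across features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._stats import spearman


@dataclass(frozen=True)
class CoverageRecord:
    feature_id: str
    reference_length: int
    covered_length: int        # size of the union of intervals
    covered_pct: float         # 100 * covered_length / reference_length
    maximal_assembly: int      # longest merged contiguous interval
    longest_read: int          # longest raw interval
    total_reads: int
    mean_read_len: float       # arithmetic mean of raw interval lengths


def merge_intervals(intervals: Sequence[tuple[int, int]]
                    ) -> list[tuple[int, int]]:
    """Sort-merge half-open intervals; touching intervals merge."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def coverage_record(feature_id: str, reference_length: int,
                    intervals: Sequence[tuple[int, int]]) -> CoverageRecord:
    """Coverage statistics for one feature from 0-based half-open intervals.

    An empty interval list yields an all-zero record; an interval outside
    [0, reference_length) is an error.
    """
    if reference_length < 1:
        raise ValueError("reference_length must be >= 1")
    for start, end in intervals:
        if start < 0 or end > reference_length:
            raise ValueError(
                f"{feature_id}: interval [{start}, {end}) outside reference "
                f"of length {reference_length}")
        if end <= start:
            raise ValueError(f"{feature_id}: empty interval [{start}, {end})")
    if not intervals:
        return CoverageRecord(feature_id, reference_length, 0, 0.0, 0, 0, 0,
                              0.0)
    merged = merge_intervals(intervals)
    covered = sum(e - s for s, e in merged)
    lengths = [e - s for s, e in intervals]
    return CoverageRecord(
        feature_id=feature_id,
        reference_length=reference_length,
        covered_length=covered,
        covered_pct=100.0 * covered / reference_length,
        maximal_assembly=max(e - s for s, e in merged),
        longest_read=max(lengths),
        total_reads=len(intervals),
        mean_read_len=float(np.mean(lengths)))


def assembly_length_correlation(records: Sequence[CoverageRecord]
                                ) -> tuple[float, float]:
    """Spearman correlation of assembly fraction vs. reference length.

    The assembly fraction is maximal_assembly / reference_length.  Returns
    (rho, p); constant input yields (nan, nan) with a warning.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 coverage records")
    frac = np.array([r.maximal_assembly / r.reference_length
                     for r in records], dtype=float)
    length = np.array([r.reference_length for r in records], dtype=float)
    if np.ptp(frac) == 0 or np.ptp(length) == 0:
        warnings.warn("constant input: correlation undefined")
        return float("nan"), float("nan")
    return spearman(frac, length)
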