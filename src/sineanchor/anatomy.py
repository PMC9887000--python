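"""Element position and orientation relative to peak summits.

Elements inside a summit window are classified into four groups by genomic
strand and by which side of the summit their midpoint falls on:

    1: plus strand, upstream of the summit
    2: minus strand, upstream
    3: plus strand, downstream
    4: minus strand, downstream

Because a SINE's head (5' end) sits at the low-coordinate end on the plus
strand and at the high-coordinate end on the minus strand, groups 2 and 3
are the "head-inward" configurations — the element's head faces the summit.
A two-sided exact binomial test against 0.5 asks whether head-inward
placement is more common than chance.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .core import PeakRegion, RepeatInstance
from .profiles import PositionalProfile, profile_from_offsets

AT_SUMMIT = "at_summit"


@dataclasses.dataclass
class QuadrantCounts:
    n1: int = 0  # + strand, upstream (tail-inward)
    n2: int = 0  # - strand, upstream (head-inward)
    n3: int = 0  # + strand, downstream (head-inward)
    n4: int = 0  # - strand, downstream (tail-inward)
    n_at_summit: int = 0  # midpoint exactly at summit; excluded from the test

    @property
    def head_inward(self) -> int:
        return self.n2 + self.n3

    @property
    def tail_inward(self) -> int:
        return self.n1 + self.n4

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4


@dataclasses.dataclass
class OrientationSummary:
    counts: QuadrantCounts
    head_inward_fraction: float
    p: float


def classify_quadrant(peak: PeakRegion, element: RepeatInstance) -> int | str:
    """Quadrant 1-4 of an element relative to a summit, or ``at_summit``."""
    strand = element.interval.strand
    if strand not in ("+", "-"):
        raise ValueError("orientation analysis requires a stranded element")
    mid = element.midpoint
    if mid == peak.summit:
        return AT_SUMMIT
    upstream = mid < peak.summit
    if strand == "+":
        return 1 if upstream else 3
    return 2 if upstream else 4


def _element_arrays(elements: Sequence[RepeatInstance]):
    """Per-chromosome numpy views of element coordinates for window queries."""
    by_chrom: dict[str, dict[str, np.ndarray]] = {}
    grouped: dict[str, list[RepeatInstance]] = {}
    for e in elements:
        grouped.setdefault(e.interval.chrom, []).append(e)
    for chrom, sub in grouped.items():
        by_chrom[chrom] = {
            "start": np.array([e.interval.start for e in sub], dtype=np.int64),
            "end": np.array([e.interval.end for e in sub], dtype=np.int64),
            "mid": np.array([e.midpoint for e in sub], dtype=np.int64),
            "head": np.array([e.head_pos for e in sub], dtype=np.int64),
            "tail": np.array([e.tail_pos for e in sub], dtype=np.int64),
            "plus": np.array(
                [e.interval.strand == "+" for e in sub], dtype=bool
            ),
        }
    return by_chrom


def count_quadrants(
    peaks: Sequence[PeakRegion],
    elements: Sequence[RepeatInstance],
    w: int = 500,
) -> QuadrantCounts:
    """Tally quadrants over all (peak, element-in-window) pairs.

    An element lying inside two peaks' windows contributes once per pair,
    the same semantics as the per-peak window counts.
    """
    if w <= 0:
        raise ValueError("window half-width must be positive")
    for e in elements:
        if e.interval.strand not in ("+", "-"):
            raise ValueError("orientation analysis requires stranded elements")
    counts = QuadrantCounts()
    arrays = _element_arrays(elements)
    for peak in peaks:
        arr = arrays.get(peak.chrom)
        if arr is None:
            continue
        lo, hi = peak.summit - w, peak.summit + w + 1
        inside = (arr["start"] < hi) & (arr["end"] > lo)
        mid = arr["mid"][inside]
        plus = arr["plus"][inside]
        upstream = mid < peak.summit
        downstream = mid > peak.summit
        counts.n1 += int(np.count_nonzero(upstream & plus))
        counts.n2 += int(np.count_nonzero(upstream & ~plus))
        counts.n3 += int(np.count_nonzero(downstream & plus))
        counts.n4 += int(np.count_nonzero(downstream & ~plus))
        counts.n_at_summit += int(np.count_nonzero(mid == peak.summit))
    return counts


def orientation_bias_test(counts: QuadrantCounts) -> OrientationSummary:
    """Two-sided exact binomial test of head-inward placement against 0.5.

    The p-value doubles the smaller exact tail and caps at 1.
    """
    total = counts.total
    if total < 1:
        raise ValueError("no strand-resolved elements off the summit to test")
    k = counts.head_inward
    lower = float(stats.binom.cdf(k, total, 0.5))
    upper = float(stats.binom.sf(k - 1, total, 0.5))
    p = min(1.0, 2.0 * min(lower, upper))
    return OrientationSummary(counts, k / total, p)


def element_position_profile(
    peaks: Sequence[PeakRegion],
    elements: Sequence[RepeatInstance],
    w: int = 500,
    feature: str = "midpoint",
    smoothing_bp: int = 11,
) -> PositionalProfile:
    """Density of element feature positions as offsets from peak summits.

    ``feature`` picks the recorded position: the element ``midpoint``,
    ``head``, ``tail``, or ``body-coverage`` (every covered base, yielding an
    occupancy profile rather than a point profile).
    """
    if not peaks:
        raise ValueError("no peaks supplied")
    if feature not in ("midpoint", "head", "tail", "body-coverage"):
        raise ValueError(f"unknown feature {feature!r}")
    arrays = _element_arrays(elements)
    offsets: list[int] = []
    key = {"midpoint": "mid", "head": "head", "tail": "tail"}.get(feature)
    for peak in peaks:
        arr = arrays.get(peak.chrom)
        if arr is None:
            continue
        lo, hi = peak.summit - w, peak.summit + w + 1
        inside = (arr["start"] < hi) & (arr["end"] > lo)
        if key is not None:
            offsets.extend((arr[key][inside] - peak.summit).tolist())
        else:  # body-coverage: every covered base inside the window
            for s, e in zip(arr["start"][inside], arr["end"][inside]):
                offsets.extend(
                    range(max(int(s), lo) - peak.summit, min(int(e), hi) - peak.summit)
                )
    return profile_from_offsets(offsets, w, len(peaks), smoothing_bp)
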