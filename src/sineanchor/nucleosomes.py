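"""Nucleosome dyad positioning around repeat-element midpoints.

MNase-protected fragments are reduced to single-bp dyads (fragment
midpoints). A dyad frequency profile around element midpoints shows whether
nucleosomes are translationally positioned on the element — for ~140 bp
B1-like elements wrapped by ~147 bp of nucleosomal DNA, a dyad peak at the
element midpoint puts the element head and tail at the DNA entry/exit sites.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .core import GenomicInterval
from .motifs import Anchor
from .profiles import PositionalProfile, profile_from_offsets


@dataclasses.dataclass
class DyadSet:
    """Single-bp dyad positions grouped by chromosome."""

    dyads: list[tuple[str, int]]

    def by_chrom(self) -> dict[str, np.ndarray]:
        grouped: dict[str, list[int]] = {}
        for chrom, pos in self.dyads:
            grouped.setdefault(chrom, []).append(pos)
        return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in grouped.items()}

    def __len__(self) -> int:
        return len(self.dyads)


@dataclasses.dataclass
class DyadProfile:
    profile: PositionalProfile
    norm: str  # per_region | raw


def fragments_to_dyads(
    fragments: Sequence[GenomicInterval],
    length_filter: tuple[int, int] | None = None,
) -> DyadSet:
    """One dyad per fragment at its midpoint (floor).

    ``length_filter=(lo, hi)`` keeps only fragments whose length lies in the
    closed range — e.g. (120, 180) to retain mononucleosome-sized fragments.
    Zero-length fragments are rejected at interval construction, so every
    input has a well-defined midpoint.
    """
    dyads = []
    for frag in fragments:
        if length_filter is not None:
            lo, hi = length_filter
            if not lo <= frag.length <= hi:
                continue
        dyads.append((frag.chrom, frag.midpoint))
    return DyadSet(dyads)


def positions_to_dyads(points: Sequence[GenomicInterval]) -> DyadSet:
    """Treat BED records as pre-called dyad positions (record start)."""
    return DyadSet([(p.chrom, p.start) for p in points])


def dyad_frequency_profile(
    anchors: Sequence[Anchor],
    dyads: DyadSet,
    w: int = 500,
    flip_minus: bool = True,
    smoothing_bp: int = 21,
    norm: str = "per_region",
) -> DyadProfile:
    """Offset histogram of dyads within +/- ``w`` of each anchor.

    ``flip_minus`` negates offsets at minus-strand anchors so profiles are in
    element-oriented coordinates. ``norm`` chooses events-per-region
    (comparable across anchor sets of different size) or raw counts.
    """
    if w <= 0:
        raise ValueError("window half-width must be positive")
    if not anchors:
        raise ValueError("no anchors supplied")
    if norm not in ("per_region", "raw"):
        raise ValueError(f"unknown norm {norm!r}")
    grouped = dyads.by_chrom()
    offsets: list[int] = []
    for anchor in anchors:
        positions = grouped.get(anchor.chrom)
        if positions is None:
            continue
        lo = np.searchsorted(positions, anchor.pos - w, side="left")
        hi = np.searchsorted(positions, anchor.pos + w, side="right")
        sign = -1 if (flip_minus and anchor.strand == "-") else 1
        offsets.extend(sign * (int(p) - anchor.pos) for p in positions[lo:hi])
    n_regions = len(anchors) if norm == "per_region" else 1
    profile = profile_from_offsets(offsets, w, n_regions, smoothing_bp)
    return DyadProfile(profile, norm)
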