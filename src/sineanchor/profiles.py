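"""Offset-indexed positional profiles shared by the summit, motif and
nucleosome analyses."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np


@dataclasses.dataclass
class PositionalProfile:
    """Event density on the offset grid [-w, +w] around an anchor.

    ``values[i]`` is the event frequency (events per contributing region per
    bp) at offset ``offsets[i]``. ``raw_counts`` keeps the unsmoothed,
    unnormalized per-offset event counts so total mass can be audited.
    """

    offsets: np.ndarray
    values: np.ndarray
    n_regions: int
    smoothing_bp: int
    raw_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.offsets.shape != self.values.shape:
            raise ValueError("offsets and values must have equal length")
        if np.any(self.values < -1e-12):
            raise ValueError("profile values must be non-negative")

    @property
    def window(self) -> int:
        return int(self.offsets[-1])

    def mode_offset(self, side: str = "both") -> int:
        """Offset of the maximum value, optionally restricted to one side.

        Uniform smoothing turns an isolated event into a flat plateau of
        tied maxima; ties resolve to the central offset of the plateau.
        """
        mask = np.ones_like(self.offsets, dtype=bool)
        if side == "left":
            mask = self.offsets < 0
        elif side == "right":
            mask = self.offsets > 0
        vals = self.values[mask]
        offs = self.offsets[mask]
        tied = np.flatnonzero(vals >= vals.max() - 1e-12)
        return int(offs[tied[len(tied) // 2]])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_regions={self.n_regions}\tsmoothing_bp={self.smoothing_bp}\n")
            fh.write("offset\tvalue\n")
            for o, v in zip(self.offsets, self.values):
                fh.write(f"{o}\t{v:.8g}\n")


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered uniform moving average; conserves mass except at boundaries."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd so the kernel is centered")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(np.asarray(values, dtype=float), kernel, mode="same")


def profile_from_offsets(
    offsets: Iterable[int],
    w: int,
    n_regions: int,
    smoothing_bp: int = 11,
) -> PositionalProfile:
    """Histogram integer offsets on [-w, +w], normalize per region, smooth.

    Offsets outside the window are dropped (they belong to events beyond the
    anchor window and carry no positional information at this scale).
    """
    if w <= 0:
        raise ValueError("window half-width must be positive")
    if n_regions <= 0:
        raise ValueError("need at least one contributing region")
    arr = np.fromiter((int(o) for o in offsets), dtype=np.int64)
    arr = arr[(arr >= -w) & (arr <= w)]
    counts = np.bincount(arr + w, minlength=2 * w + 1).astype(float)
    values = moving_average(counts / n_regions, smoothing_bp)
    return PositionalProfile(
        offsets=np.arange(-w, w + 1),
        values=values,
        n_regions=n_regions,
        smoothing_bp=smoothing_bp,
        raw_counts=counts,
    )
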