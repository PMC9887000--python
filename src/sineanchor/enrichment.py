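"""TE-family enrichment in a peak set.

The hypergeometric model needs a finite universe of exchangeable draws, which
raw genomic intervals do not provide. The genome is therefore tiled into
fixed-length bins (default 500 bp, matching the summit-window scale of the
positional analyses): the universe is all N bins, the "sample" is the n bins
touched by at least one peak, the "successes" are the K bins touched by at
least one element of the family, and k counts bins touched by both. The
one-tailed p-value is P(X >= k) for X ~ Hypergeom(N, K, n) and the fold
ratio is (k/n)/(K/N). A shuffle-based empirical mode is provided as an
independent cross-check of the analytic p-values.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .core import (
    GenomeIndex,
    PeakRegion,
    RepeatInstance,
    bh_adjust,
    overlaps,
    shuffle_intervals,
)


@dataclasses.dataclass
class BinUniverse:
    """Deterministic fixed-length tiling of the genome.

    Bins never span chromosomes; the last bin of each chromosome may be
    shorter than ``bin_length``.
    """

    bin_length: int
    chrom_offsets: dict[str, tuple[int, int]]  # chrom -> (first bin idx, n bins)
    N: int

    def bin_range(self, chrom: str, start: int, end: int) -> range:
        """Global bin indices overlapped by [start, end) on chrom."""
        if chrom not in self.chrom_offsets:
            return range(0)
        first, nbins = self.chrom_offsets[chrom]
        lo = max(0, start // self.bin_length)
        hi = min(nbins - 1, (end - 1) // self.bin_length)
        if hi < lo:
            return range(0)
        return range(first + lo, first + hi + 1)


def build_bin_universe(genome: GenomeIndex, bin_length: int = 500) -> BinUniverse:
    if bin_length <= 0:
        raise ValueError("bin_length must be positive")
    if not genome.chrom_sizes:
        raise ValueError("empty genome")
    offsets: dict[str, tuple[int, int]] = {}
    total = 0
    for chrom, size in genome.chrom_sizes.items():
        nbins = math.ceil(size / bin_length)
        offsets[chrom] = (total, nbins)
        total += nbins
    return BinUniverse(bin_length, offsets, total)


@dataclasses.dataclass
class TEEnrichmentResult:
    family: str
    k: int
    n: int
    K: int
    N: int
    fold: float  # NaN when K == 0 (fold undefined, not depletion)
    p: float
    q: float = float("nan")


def _mask_for_intervals(universe: BinUniverse, items) -> np.ndarray:
    mask = np.zeros(universe.N, dtype=bool)
    for chrom, start, end in items:
        rng = universe.bin_range(chrom, start, end)
        if len(rng):
            mask[rng.start : rng.stop] = True
    return mask


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if k <= max(0, n + K - N):
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def te_family_enrichment(
    peaks: Sequence[PeakRegion],
    repeats: Sequence[RepeatInstance],
    universe: BinUniverse,
    level: str = "subfamily",
) -> list[TEEnrichmentResult]:
    """One enrichment result per repeat family present in ``repeats``.

    ``level`` selects subfamily resolution (B1, B2, ...) or the family rollup
    (SINE, LINE, LTR). BH correction runs across all families tested in the
    call. Families absent from the binned genome (K = 0) are reported with
    fold NaN and p = 1.
    """
    if not peaks:
        raise ValueError("need at least one peak")
    if not repeats:
        raise ValueError("need at least one repeat instance")
    if level not in ("subfamily", "family"):
        raise ValueError(f"unknown level {level!r}")

    peak_mask = _mask_for_intervals(
        universe, ((p.chrom, p.interval.start, p.interval.end) for p in peaks)
    )
    n = int(peak_mask.sum())
    if n == 0:
        raise ValueError("no peak overlaps any bin of the universe")

    label = (lambda r: r.subfamily) if level == "subfamily" else (lambda r: r.family)
    groups: dict[str, list[RepeatInstance]] = {}
    for r in repeats:
        groups.setdefault(label(r), []).append(r)

    results: list[TEEnrichmentResult] = []
    for fam in sorted(groups):
        fam_mask = _mask_for_intervals(
            universe,
            ((r.interval.chrom, r.interval.start, r.interval.end) for r in groups[fam]),
        )
        K = int(fam_mask.sum())
        k = int((fam_mask & peak_mask).sum())
        if K == 0:
            fold, p = float("nan"), 1.0
        else:
            fold = (k / n) / (K / universe.N)
            p = hypergeom_upper_tail(k, universe.N, K, n)
        results.append(TEEnrichmentResult(fam, k, n, K, universe.N, fold, p))

    qvals = bh_adjust([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = float(q)
    return results


def count_peaks_with_family(
    peaks: Sequence[PeakRegion],
    repeats: Sequence[RepeatInstance],
    family: str | None = None,
) -> tuple[int, int, float]:
    """(peaks with >=1 overlapping element, peaks without, integer percent).

    A peak counts once however many instances it overlaps. ``family`` matches
    either the family or subfamily label; None counts overlap with any
    element.
    """
    if not peaks:
        raise ValueError("empty peak set")
    selected = [
        r
        for r in repeats
        if family is None or family in (r.family, r.subfamily)
    ]
    by_chrom: dict[str, list[RepeatInstance]] = {}
    for r in selected:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    with_count = 0
    for p in peaks:
        hits = by_chrom.get(p.chrom, ())
        if any(overlaps(p.interval, r.interval) for r in hits):
            with_count += 1
    without = len(peaks) - with_count
    return with_count, without, percent(with_count, len(peaks))


def percent(
    numerator: int | float,
    denominator: int | float,
    ndigits: int = 0,
    mode: str = "nearest",
) -> float:
    """Ratio as a percentage with an explicit rounding convention.

    ``mode`` is one of ``nearest`` (round-half-away-from-zero at ``ndigits``
    decimals, the convention behind printed summaries like "92% (441/479)"),
    ``floor``, ``ceil`` or ``raw``.
    """
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    value = 100.0 * numerator / denominator
    scale = 10.0 ** ndigits
    if mode == "nearest":
        return math.floor(value * scale + 0.5) / scale
    if mode == "floor":
        return math.floor(value * scale) / scale
    if mode == "ceil":
        return math.ceil(value * scale) / scale
    if mode == "raw":
        return value
    raise ValueError(f"unknown rounding mode {mode!r}")


def empirical_family_enrichment(
    peaks: Sequence[PeakRegion],
    repeats: Sequence[RepeatInstance],
    genome: GenomeIndex,
    family: str,
    n_shuffles: int = 200,
    seed: int = 0,
) -> float:
    """Shuffle-based empirical p for peaks-with-family overlap counts.

    Re-places the peak intervals uniformly ``n_shuffles`` times and returns
    the add-one empirical probability that a shuffle reaches the observed
    number of family-overlapping peaks.
    """
    observed, _, _ = count_peaks_with_family(peaks, repeats, family)
    at_least = 0
    for i in range(n_shuffles):
        shuffled = shuffle_intervals(
            [p.interval for p in peaks], genome, seed=seed + i
        )
        fake_peaks = [PeakRegion(iv, iv.midpoint) for iv in shuffled]
        cnt, _, _ = count_peaks_with_family(fake_peaks, repeats, family)
        if cnt >= observed:
            at_least += 1
    return (at_least + 1) / (n_shuffles + 1)


def write_enrichment_tsv(results: Sequence[TEEnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tk\tn\tK\tN\tfold\tp\tq\n")
        for r in results:
            fold = "NA" if math.isnan(r.fold) else f"{r.fold:.6g}"
            fh.write(
                f"{r.family}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t{fold}\t"
                f"{r.p:.6g}\t{r.q:.6g}\n"
            )
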