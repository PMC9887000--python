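"""Coordinate conventions, interval arithmetic, and readers/writers.

All internal coordinates are 0-based half-open (BED-native). Conversions to
and from 1-based inclusive systems (RepeatMasker ``.out``) happen only at the
format boundary, so no off-by-one arithmetic leaks into the analyses.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A stranded 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end (zero-length intervals rejected)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclasses.dataclass(frozen=True)
class PeakRegion:
    """A peak with the absolute genomic position of its signal summit."""

    interval: GenomicInterval
    summit: int

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclasses.dataclass(frozen=True)
class RepeatInstance:
    """A repeat-element copy with family labels and an oriented head.

    The head is the element's 5' end in its own transcriptional orientation:
    ``interval.start`` on the plus strand, ``interval.end - 1`` on the minus
    strand.
    """

    interval: GenomicInterval
    family: str
    subfamily: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("repeat instances require an explicit +/- strand")

    @property
    def head_pos(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def tail_pos(self) -> int:
        if self.interval.strand == "+":
            return self.interval.end - 1
        return self.interval.start

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclasses.dataclass(frozen=True)
class GenomeIndex:
    """Chromosome name -> length map used for bounds checks and shuffling."""

    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"non-positive length for chromosome {chrom}")

    def check(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self.chrom_sizes:
            raise ValueError(f"chromosome {interval.chrom} not in genome index")
        if interval.end > self.chrom_sizes[interval.chrom]:
            raise ValueError(
                f"interval end {interval.end} beyond {interval.chrom} length "
                f"{self.chrom_sizes[interval.chrom]}"
            )


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base.

    Half-open semantics: abutting intervals ([0,100) vs [100,200)) do not
    overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def window_count(
    peaks: Sequence[PeakRegion],
    elements: Sequence[RepeatInstance],
    w: int = 500,
) -> np.ndarray:
    """Per-peak count of elements overlapping the +/- ``w`` summit window.

    The window around a summit ``s`` is ``[s - w, s + w + 1)``: ``w`` bases on
    either side plus the summit base itself.
    """
    if w <= 0:
        raise ValueError("window half-width w must be positive")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {e.interval.chrom for e in elements}:
        sub = [e for e in elements if e.interval.chrom == chrom]
        by_chrom[chrom] = (
            np.array([e.interval.start for e in sub], dtype=np.int64),
            np.array([e.interval.end for e in sub], dtype=np.int64),
        )
    counts = np.zeros(len(peaks), dtype=np.int64)
    for i, peak in enumerate(peaks):
        if peak.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[peak.chrom]
        lo, hi = peak.summit - w, peak.summit + w + 1
        counts[i] = int(np.count_nonzero((starts < hi) & (ends > lo)))
    return counts


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    genome: GenomeIndex,
    seed: int,
) -> list[GenomicInterval]:
    """Uniform random re-placement of each interval within its chromosome.

    Lengths, chromosomes, strands and names are preserved; only starts move.
    """
    rng = np.random.default_rng(seed)
    out = []
    for iv in intervals:
        if iv.chrom not in genome.chrom_sizes:
            raise ValueError(f"chromosome {iv.chrom} not in genome index")
        chrom_len = genome.chrom_sizes[iv.chrom]
        if iv.length > chrom_len:
            raise ValueError(
                f"interval of length {iv.length} longer than {iv.chrom} "
                f"({chrom_len} bp)"
            )
        start = int(rng.integers(0, chrom_len - iv.length + 1))
        out.append(
            dataclasses.replace(iv, start=start, end=start + iv.length)
        )
    return out


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeIndex:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        sizes[fields[0]] = int(fields[1])
    if not sizes:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return GenomeIndex(sizes)


def _parse_bed_fields(fields: list[str], lineno: int, path) -> GenomicInterval:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score = None
    if len(fields) > 4 and fields[4] != ".":
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad score field") from exc
    strand = fields[5] if len(fields) > 5 else "."
    try:
        return GenomicInterval(chrom, start, end, strand, name, score)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc


def read_regions(path: str | Path, format: str = "bed") -> list[PeakRegion]:
    """Read peaks from BED (>=3 columns) or ENCODE narrowPeak (10 columns).

    narrowPeak summits are ``start + column-10 offset``; an offset of ``-1``
    (summit not called) and plain BED fall back to the interval midpoint.
    File order is preserved.
    """
    if format not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown region format {format!r}")
    peaks: list[PeakRegion] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        interval = _parse_bed_fields(fields, lineno, path)
        if format == "narrowpeak":
            if len(fields) != 10:
                raise ValueError(
                    f"{path}:{lineno}: narrowPeak requires 10 columns, "
                    f"got {len(fields)}"
                )
            offset = int(fields[9])
            if offset == -1:
                summit = interval.midpoint
            elif 0 <= offset < interval.length:
                summit = interval.start + offset
            else:
                raise ValueError(
                    f"{path}:{lineno}: summit offset {offset} outside peak "
                    f"of length {interval.length}"
                )
        else:
            summit = interval.midpoint
        peaks.append(PeakRegion(interval, summit))
    return peaks


def write_narrowpeak(peaks: Sequence[PeakRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{iv.name or f'peak{i}'}\t{int(iv.score or 0)}\t{iv.strand}\t"
                f"0\t-1\t-1\t{p.summit - iv.start}\n"
            )


def read_repeats(path: str | Path, format: str = "bed6_family") -> list[RepeatInstance]:
    """Read repeat annotations.

    ``bed6_family``: BED6 with the name column holding ``family/subfamily``
    (e.g. ``SINE/B1``); a bare name without ``/`` is kept with family
    ``unknown``. ``repeatmasker_out``: the RepeatMasker ``.out`` table, with
    1-based inclusive coordinates and strand ``C`` meaning minus; coordinates
    are normalized to 0-based half-open on read.
    """
    if format == "bed6_family":
        return _read_repeats_bed6(path)
    if format == "repeatmasker_out":
        return _read_repeats_rmsk(path)
    raise ValueError(f"unknown repeat format {format!r}")


def _split_family(label: str) -> tuple[str, str]:
    if "/" in label:
        family, subfamily = label.split("/", 1)
        return family, subfamily
    return "unknown", label


def _read_repeats_bed6(path) -> list[RepeatInstance]:
    out: list[RepeatInstance] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: bed6_family requires 6 columns")
        interval = _parse_bed_fields(fields, lineno, path)
        family, subfamily = _split_family(fields[3] or "")
        out.append(RepeatInstance(interval, family, subfamily))
    return out


def _read_repeats_rmsk(path) -> list[RepeatInstance]:
    out: list[RepeatInstance] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        fields = line.split()
        if not fields or not fields[0].lstrip("-").isdigit():
            continue  # header / blank lines
        if len(fields) < 11:
            raise ValueError(f"{path}:{lineno}: truncated RepeatMasker row")
        chrom = fields[4]
        start = int(fields[5]) - 1  # 1-based inclusive -> 0-based half-open
        end = int(fields[6])
        raw_strand = fields[8]
        if raw_strand == "+":
            strand = "+"
        elif raw_strand in ("C", "-"):
            strand = "-"
        else:
            raise ValueError(
                f"{path}:{lineno}: unknown strand symbol {raw_strand!r}"
            )
        repeat_name = fields[9]
        class_family = fields[10]
        family, _ = _split_family(class_family)
        if family == "unknown" and "/" not in class_family:
            family = class_family
        subfamily = class_family.split("/", 1)[1] if "/" in class_family else repeat_name
        interval = GenomicInterval(chrom, start, end, strand, repeat_name)
        out.append(RepeatInstance(interval, family, subfamily))
    return out


def write_repeats_bed6(repeats: Sequence[RepeatInstance], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{r.family}/{r.subfamily}\t0\t{iv.strand}\n"
            )


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{iv.score if iv.score is not None else 0}\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        out.append(_parse_bed_fields(line.rstrip("\n").split("\t"), lineno, path))
    return out
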