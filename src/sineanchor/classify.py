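"""Signal matrices from coverage tracks and two-class region partitioning.

Accessibility regions that open in a knockout fall into two behaviors: a
minority that are already open in fibroblasts and resist closing during
reprogramming, and a majority that are closed in fibroblasts and open up
once the reprogramming factors act. Summit-centered binned coverage across
the sample panel, log1p-transformed, feeds a seeded K-means with k = 2; the
cluster with the higher mean fibroblast (MEF) signal is the "open-in-MEF"
class.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .core import PeakRegion

logger = logging.getLogger(__name__)

CLUSTER1_LABEL = "cluster1_open_in_MEF"
CLUSTER2_LABEL = "cluster2_closed_in_MEF_opening"


class CoverageTrack:
    """Step-function coverage from a bedGraph file.

    Intervals are sorted per chromosome; uncovered positions count as zero.
    """

    def __init__(self, by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._by_chrom = by_chrom

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "CoverageTrack":
        raw: dict[str, list[tuple[int, int, float]]] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph requires 4 columns")
            raw.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), float(fields[3]))
            )
        by_chrom = {}
        for chrom, rows in raw.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            by_chrom[chrom] = (starts, ends, values)
        return cls(by_chrom)

    @property
    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean coverage over [start, end); uncovered bases contribute 0."""
        if end <= start:
            raise ValueError("empty query interval")
        if chrom not in self._by_chrom:
            return 0.0
        starts, ends, values = self._by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        s, e, v = starts[lo:hi], ends[lo:hi], values[lo:hi]
        spans = np.minimum(e, end) - np.maximum(s, start)
        return float((np.clip(spans, 0, None) * v).sum() / (end - start))


@dataclasses.dataclass
class SignalMatrix:
    regions: list[PeakRegion]
    samples: list[str]
    bins_per_region: int
    values: np.ndarray  # regions x (samples * bins), non-negative
    transform: str  # raw | log1p

    def sample_columns(self, sample: str) -> slice:
        i = self.samples.index(sample)
        return slice(i * self.bins_per_region, (i + 1) * self.bins_per_region)

    def write_tsv(self, path: str | Path) -> None:
        header = ["region"] + [
            f"{s}_bin{b}" for s in self.samples for b in range(self.bins_per_region)
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for region, row in zip(self.regions, self.values):
                name = region.interval.name or (
                    f"{region.chrom}:{region.interval.start}-{region.interval.end}"
                )
                fh.write(name + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


def build_signal_matrix(
    regions: Sequence[PeakRegion],
    tracks: dict[str, CoverageTrack],
    window_bp: int = 2000,
    bins_per_region: int = 50,
    transform: str = "log1p",
) -> SignalMatrix:
    """Summit-centered mean coverage per bin per sample.

    Each region contributes a ``window_bp`` window centered on its summit,
    split into ``bins_per_region`` equal bins per sample; sample blocks are
    concatenated in the order of ``tracks``. A track missing a chromosome
    yields zeros with a logged warning.
    """
    if window_bp % bins_per_region != 0:
        raise ValueError("window_bp must be divisible by bins_per_region")
    if transform not in ("raw", "log1p"):
        raise ValueError(f"unknown transform {transform!r}")
    bin_bp = window_bp // bins_per_region
    half = window_bp // 2
    samples = list(tracks)
    values = np.zeros((len(regions), len(samples) * bins_per_region))
    warned: set[tuple[str, str]] = set()
    for ri, region in enumerate(regions):
        left = region.summit - half
        for si, sample in enumerate(samples):
            track = tracks[sample]
            if region.chrom not in track.chroms:
                if (sample, region.chrom) not in warned:
                    logger.warning(
                        "track %s has no coverage on %s; filling zeros",
                        sample,
                        region.chrom,
                    )
                    warned.add((sample, region.chrom))
                continue
            base = si * bins_per_region
            for b in range(bins_per_region):
                a = left + b * bin_bp
                values[ri, base + b] = track.mean(region.chrom, a, a + bin_bp)
    if transform == "log1p":
        values = np.log1p(values)
    return SignalMatrix(list(regions), samples, bins_per_region, values, transform)


@dataclasses.dataclass
class KMeansResult:
    k: int
    assignment: np.ndarray  # region index -> cluster id
    centroids: np.ndarray
    inertia: float
    seed: int


def kmeans_partition(
    matrix: SignalMatrix,
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> KMeansResult:
    """Seeded k-means++ / Lloyd partition, best of ``n_init`` restarts."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(matrix.regions) < k:
        raise ValueError("fewer regions than clusters")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        random_state=seed,
        algorithm="lloyd",
    ).fit(matrix.values)
    return KMeansResult(
        k=k,
        assignment=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
    )


def label_mor_classes(
    result: KMeansResult,
    matrix: SignalMatrix,
    mef_samples: Sequence[str] | None = None,
) -> dict[int, str]:
    """Name the two clusters by fibroblast signal content.

    The cluster with the higher mean signal across MEF sample columns is
    labeled open-in-MEF (cluster 1); the other, closed-in-MEF-opening
    (cluster 2). MEF samples are found by label substring "MEF"
    (case-insensitive) unless given explicitly.
    """
    if result.k != 2:
        raise ValueError("class labeling is defined for k = 2")
    if mef_samples is None:
        mef_samples = [s for s in matrix.samples if "mef" in s.lower()]
    if not mef_samples:
        raise ValueError("no MEF samples identified in sample labels")
    cols = np.concatenate(
        [np.arange(matrix.values.shape[1])[matrix.sample_columns(s)] for s in mef_samples]
    )
    means = [
        float(matrix.values[result.assignment == c][:, cols].mean())
        if np.any(result.assignment == c)
        else float("-inf")
        for c in range(2)
    ]
    if means[0] == means[1]:
        raise ValueError(
            "clusters tie on mean MEF signal; label manually"
        )
    open_cluster = int(np.argmax(means))
    return {
        open_cluster: CLUSTER1_LABEL,
        1 - open_cluster: CLUSTER2_LABEL,
    }


def write_assignment_bed(
    matrix: SignalMatrix,
    result: KMeansResult,
    labels: dict[int, str],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for region, cluster in zip(matrix.regions, result.assignment):
            iv = region.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{labels[int(cluster)]}\t0\t.\n"
            )
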