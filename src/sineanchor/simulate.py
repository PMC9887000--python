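"""Self-consistent synthetic datasets for every pipeline stage.

The generator emits a toy genome with planted ~140 bp B1-like elements,
accessibility peaks whose summits sit ~70 bp from element midpoints with a
head-inward orientation bias, KLF-like/SOX-like motifs at element heads and
tails, MNase fragments whose dyads center on element midpoints, and
four-sample coverage tracks realizing the two behavioral region classes.
Every planted value is recorded in a truth file, so recovery of the planted
statistics by the analysis modules is a closed loop.

Also houses the screen-design arithmetic: the Poisson zero-class model for
lentiviral infection efficiency at a given multiplicity of infection.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    GenomeIndex,
    GenomicInterval,
    PeakRegion,
    RepeatInstance,
    write_narrowpeak,
    write_repeats_bed6,
)
from .motifs import Anchor

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {65: 84, 67: 71, 71: 67, 84: 65}

# Synthetic stand-in for a B1-like consensus: G/C-rich head and tail with an
# A-rich tail interior. It is a constructed sequence with the right base
# composition anatomy, not the genuine B1 repeat consensus. It deliberately
# contains no near-match (within one mismatch) to either packaged motif, so
# motif signal in simulations comes only from explicit planting.
B1_LIKE_CONSENSUS = (
    "GGCAGGCACGCGGCAGCTCACGCCGGTAAG"
    "CCGGCACTCGAGAGGCAGAGGCAGACGGAT"
    "TTCTGAGTTCGAGGCCAGCCTGGTCTACAG"
    "AGTGAGTTCCAGGACAGCCAAAAAAAAAAA"
    "AAGAGGCAGGAGGCAGGAAG"
)

KLF_LIKE_MOTIF = "GGGGTGGGG"
SOX_LIKE_MOTIF = "AACAATG"

SAMPLE_LABELS = ("WT-MEF", "KO-MEF", "WT-72h", "KO-72h")


@dataclasses.dataclass
class SyntheticConfig:
    """All planted parameters of a synthetic dataset.

    Defaults encode the study conditions the analyses are meant to recover:
    140 bp elements, 92% of 479 peaks carrying one, summit-to-element-midpoint
    distances ~ Normal(70, 15), a 0.75 head-inward orientation probability,
    and nucleosome dyads ~ Normal(element midpoint, 20).
    """

    seed: int = 0
    genome: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"chr1": 1_200_000, "chr2": 800_000}
    )
    n_elements: int = 700
    element_length: int = 140
    consensus: str = B1_LIKE_CONSENSUS
    mutation_rate: float = 0.05
    head_motif: str = KLF_LIKE_MOTIF
    tail_motif: str = SOX_LIKE_MOTIF
    plant_prob: float = 0.9
    n_peaks: int = 479
    frac_peaks_with_element: float = 0.92
    offset_mean: float = 70.0
    offset_sd: float = 15.0
    head_inward_prob: float = 0.75
    dyad_sd: float = 20.0
    dyads_per_element: int = 20
    mor_effect: float = 6.0
    background_coverage: float = 5.0
    cluster1_frac: float = 121 / 1522
    n_decoy_elements: int = 150
    peak_halfwidth: int = 250
    min_site_separation: int = 1300

    def validate(self) -> None:
        for name in (
            "mutation_rate",
            "plant_prob",
            "frac_peaks_with_element",
            "head_inward_prob",
            "cluster1_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.element_length < max(len(self.head_motif), len(self.tail_motif)):
            raise ValueError("element shorter than a planted motif")
        if len(self.consensus) != self.element_length:
            raise ValueError("consensus length must equal element_length")
        if self.offset_mean <= 0 or self.offset_sd <= 0 or self.dyad_sd <= 0:
            raise ValueError("offset and dyad scales must be positive")
        if self.n_peaks < 1:
            raise ValueError("need at least one peak")


@dataclasses.dataclass
class SyntheticDataset:
    genome_fasta: Path
    chrom_sizes: Path
    elements_bed: Path
    peaks_narrowpeak: Path
    mnase_bed: Path
    coverage_tracks: dict[str, Path]
    truth_json: Path
    truth: dict


def poisson_infection_efficiency(moi: float) -> float:
    """Fraction of cells with >= 1 viral integration under a Poisson model.

    At multiplicity of infection ``moi`` the integration count per cell is
    Poisson(moi); the infected fraction is 1 - P(0) = 1 - exp(-moi).
    """
    if moi < 0:
        raise ValueError("multiplicity of infection cannot be negative")
    return 1.0 - math.exp(-moi)


# ---------------------------------------------------------------------------
# Site placement and geometry
# ---------------------------------------------------------------------------

def _place_sites(
    rng: np.random.Generator,
    genome: dict[str, int],
    n_sites: int,
    min_sep: int,
    margin: int,
) -> list[tuple[str, int]]:
    """Rejection-sample site centers with a minimum same-chromosome spacing."""
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    usable = lengths - 2 * margin
    if np.any(usable <= 0):
        raise ValueError("chromosome too short for the placement margin")
    weights = usable / usable.sum()
    accepted: dict[str, list[int]] = {c: [] for c in chroms}
    placed: list[tuple[str, int]] = []
    max_attempts = 400 * n_sites
    attempts = 0
    while len(placed) < n_sites:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "genome too small to place the requested non-overlapping "
                "sites; enlarge the genome or reduce counts"
            )
        ci = int(rng.choice(len(chroms), p=weights))
        chrom = chroms[ci]
        center = int(rng.integers(margin, genome[chrom] - margin))
        if all(abs(center - other) >= min_sep for other in accepted[chrom]):
            accepted[chrom].append(center)
            placed.append((chrom, center))
    return placed


def _plant_peak_geometry(
    rng: np.random.Generator,
    chrom: str,
    center: int,
    cfg_offset_mean: float,
    cfg_offset_sd: float,
    head_inward_prob: float,
    element_length: int,
    peak_halfwidth: int,
    name: str,
    subfamily: str = "B1",
) -> tuple[PeakRegion, RepeatInstance, dict]:
    """One peak with its planted element; the element midpoint is ``center``.

    The summit is displaced from the element midpoint by |Normal(mean, sd)|,
    on the side that makes the element head face the summit with probability
    ``head_inward_prob``. On the plus strand the head is the low-coordinate
    end, so head-inward means the summit lies below the midpoint; on the
    minus strand the relation flips.
    """
    strand = "+" if rng.random() < 0.5 else "-"
    offset = int(round(abs(rng.normal(cfg_offset_mean, cfg_offset_sd))))
    offset = min(max(offset, 1), peak_halfwidth - 50)
    head_inward = bool(rng.random() < head_inward_prob)
    if strand == "+":
        summit = center - offset if head_inward else center + offset
    else:
        summit = center + offset if head_inward else center - offset
    start = element_length // 2
    element = RepeatInstance(
        GenomicInterval(chrom, center - start, center - start + element_length, strand),
        family="SINE",
        subfamily=subfamily,
    )
    peak = PeakRegion(
        GenomicInterval(chrom, summit - peak_halfwidth, summit + peak_halfwidth, ".", name),
        summit,
    )
    truth = {
        "name": name,
        "chrom": chrom,
        "summit": summit,
        "element_midpoint": center,
        "strand": strand,
        "offset": offset,
        "head_inward": head_inward,
    }
    return peak, element, truth


def simulate_orientation_geometry(
    n_elements: int,
    head_inward_prob: float = 0.75,
    offset_mean: float = 70.0,
    offset_sd: float = 15.0,
    seed: int = 0,
    element_length: int = 140,
) -> tuple[list[PeakRegion], list[RepeatInstance]]:
    """Coordinate-only peaks/elements with planted orientation structure.

    Fast path for statistical calibration: identical geometry rules to the
    full generator, on a virtual chromosome, with no sequence or file output.
    """
    rng = np.random.default_rng(seed)
    peaks, elements = [], []
    spacing = 2000
    for i in range(n_elements):
        center = 1000 + i * spacing
        peak, element, _ = _plant_peak_geometry(
            rng, "chrS", center, offset_mean, offset_sd, head_inward_prob,
            element_length, 250, f"peak{i}",
        )
        peaks.append(peak)
        elements.append(element)
    return peaks, elements


def simulate_dyad_geometry(
    n_anchors: int,
    dyads_per_anchor: int,
    dyad_sd: float = 20.0,
    seed: int = 0,
    spacing: int = 2000,
):
    """Anchors on a virtual chromosome plus dyads ~ Normal(anchor, sd)."""
    from .nucleosomes import DyadSet

    rng = np.random.default_rng(seed)
    anchors = []
    dyads = []
    for i in range(n_anchors):
        pos = 1000 + i * spacing
        anchors.append(Anchor("chrS", pos, strand="+"))
        draws = np.rint(rng.normal(pos, dyad_sd, size=dyads_per_anchor)).astype(int)
        dyads.extend(("chrS", int(d)) for d in draws)
    return anchors, DyadSet(dyads)


# ---------------------------------------------------------------------------
# Full dataset generation
# ---------------------------------------------------------------------------

def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return seq
    hit = rng.random(seq.size) < rate
    if not hit.any():
        return seq
    seq = seq.copy()
    # substitute with one of the three other bases
    shifts = rng.integers(1, 4, size=int(hit.sum()))
    base_idx = np.searchsorted(_BASES, seq[hit])
    seq[hit] = _BASES[(base_idx + shifts) % 4]
    return seq


def _revcomp(seq: np.ndarray) -> np.ndarray:
    out = np.empty_like(seq)
    for src, dst in _COMPLEMENT.items():
        out[seq == src] = dst
    return out[::-1]


def _element_sequence(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    seq = np.frombuffer(cfg.consensus.encode(), dtype=np.uint8).copy()
    if rng.random() < cfg.plant_prob:
        head = np.frombuffer(cfg.head_motif.encode(), dtype=np.uint8)
        seq[: head.size] = head
    if rng.random() < cfg.plant_prob:
        tail = np.frombuffer(cfg.tail_motif.encode(), dtype=np.uint8)
        seq[seq.size - tail.size :] = tail
    return _mutate(rng, seq, cfg.mutation_rate)


def _write_fasta(path: Path, sequences: dict[str, np.ndarray], width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, arr in sequences.items():
            fh.write(f">{chrom}\n")
            text = arr.tobytes().decode("ascii")
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> SyntheticDataset:
    """Generate the full dataset; fully reproducible from ``config.seed``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # which peaks carry an element
    has_element = rng.random(config.n_peaks) < config.frac_peaks_with_element
    n_with = int(has_element.sum())
    n_background = config.n_elements - n_with
    if n_background < 0:
        raise ValueError(
            "n_elements smaller than the number of element-bearing peaks"
        )

    n_sites = config.n_peaks + n_background + config.n_decoy_elements
    margin = config.peak_halfwidth + 1100
    sites = _place_sites(
        rng, config.genome, n_sites, config.min_site_separation, margin
    )

    peaks: list[PeakRegion] = []
    elements: list[RepeatInstance] = []
    peak_truth: list[dict] = []
    site_iter = iter(sites)
    for i in range(config.n_peaks):
        chrom, center = next(site_iter)
        if has_element[i]:
            peak, element, truth = _plant_peak_geometry(
                rng, chrom, center,
                config.offset_mean, config.offset_sd, config.head_inward_prob,
                config.element_length, config.peak_halfwidth, f"peak{i}",
            )
            peaks.append(peak)
            truth["element_index"] = len(elements)
            elements.append(element)
        else:
            peak = PeakRegion(
                GenomicInterval(
                    chrom,
                    center - config.peak_halfwidth,
                    center + config.peak_halfwidth,
                    ".",
                    f"peak{i}",
                ),
                center,
            )
            peaks.append(peak)
            truth = {
                "name": f"peak{i}",
                "chrom": chrom,
                "summit": center,
                "element_midpoint": None,
                "strand": None,
                "offset": None,
                "head_inward": None,
                "element_index": None,
            }
        truth["has_element"] = bool(has_element[i])
        peak_truth.append(truth)

    half = config.element_length // 2
    for _ in range(n_background):
        chrom, center = next(site_iter)
        strand = "+" if rng.random() < 0.5 else "-"
        elements.append(
            RepeatInstance(
                GenomicInterval(
                    chrom, center - half, center - half + config.element_length, strand
                ),
                family="SINE",
                subfamily="B1",
            )
        )
    decoys: list[RepeatInstance] = []
    for _ in range(config.n_decoy_elements):
        chrom, center = next(site_iter)
        strand = "+" if rng.random() < 0.5 else "-"
        decoys.append(
            RepeatInstance(
                GenomicInterval(
                    chrom, center - half, center - half + config.element_length, strand
                ),
                family="SINE",
                subfamily="B2",
            )
        )

    # genome sequence with elements written in
    sequences = {
        chrom: _BASES[rng.integers(0, 4, size=size)]
        for chrom, size in config.genome.items()
    }
    for element in elements:
        seq = _element_sequence(rng, config)
        if element.interval.strand == "-":
            seq = _revcomp(seq)
        sequences[element.interval.chrom][
            element.interval.start : element.interval.end
        ] = seq
    for decoy in decoys:
        seq = _BASES[rng.integers(0, 4, size=config.element_length)]
        sequences[decoy.interval.chrom][
            decoy.interval.start : decoy.interval.end
        ] = seq

    # MNase fragments: 147 bp windows whose midpoints are Normal(element mid, sd)
    frag_half = 73
    mnase: list[GenomicInterval] = []
    for element in elements:
        draws = np.rint(
            rng.normal(element.midpoint, config.dyad_sd, size=config.dyads_per_element)
        ).astype(int)
        for d in draws:
            mnase.append(
                GenomicInterval(element.interval.chrom, int(d) - frag_half, int(d) + frag_half + 1)
            )

    # coverage: two behavioral classes over the peak set
    cluster1 = rng.random(config.n_peaks) < config.cluster1_frac
    level_multipliers = {
        # (cluster1, cluster2) multipliers of background at the peak core
        "WT-MEF": (config.mor_effect, 1.0),
        "KO-MEF": (config.mor_effect, 1.0),
        "WT-72h": (1.0, 0.45 * config.mor_effect),
        "KO-72h": (0.6 * config.mor_effect, config.mor_effect),
    }
    step = 10
    cov_half = 1200
    core_half = 300
    track_paths: dict[str, Path] = {}
    for sample in SAMPLE_LABELS:
        path = out / f"coverage_{sample}.bedGraph"
        with open(path, "w") as fh:
            order = sorted(
                range(config.n_peaks),
                key=lambda i: (peaks[i].chrom, peaks[i].summit),
            )
            for i in order:
                peak = peaks[i]
                mult = level_multipliers[sample][0 if cluster1[i] else 1]
                for a in range(peak.summit - cov_half, peak.summit + cov_half, step):
                    level = (
                        config.background_coverage * mult
                        if abs(a + step // 2 - peak.summit) <= core_half
                        else config.background_coverage
                    )
                    v = int(rng.poisson(level))
                    fh.write(f"{peak.chrom}\t{a}\t{a + step}\t{v}\n")
        track_paths[sample] = path

    genome_fasta = out / "genome.fa"
    _write_fasta(genome_fasta, sequences)
    chrom_sizes = out / "genome.chrom.sizes"
    chrom_sizes.write_text(
        "".join(f"{c}\t{n}\n" for c, n in config.genome.items())
    )
    elements_bed = out / "elements.bed"
    write_repeats_bed6(elements + decoys, elements_bed)
    peaks_np = out / "peaks.narrowPeak"
    write_narrowpeak(peaks, peaks_np)
    mnase_bed = out / "mnase_fragments.bed"
    with open(mnase_bed, "w") as fh:
        for frag in mnase:
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\n")

    truth = {
        "config": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_peaks_with_element": n_with,
        "n_head_inward": sum(
            1 for t in peak_truth if t["head_inward"] is True
        ),
        "n_cluster1": int(cluster1.sum()),
        "cluster_assignment": {
            peak_truth[i]["name"]: (1 if cluster1[i] else 2)
            for i in range(config.n_peaks)
        },
        "peaks": peak_truth,
    }
    truth_json = out / "truth.json"
    truth_json.write_text(json.dumps(truth, indent=1, sort_keys=True))

    return SyntheticDataset(
        genome_fasta=genome_fasta,
        chrom_sizes=chrom_sizes,
        elements_bed=elements_bed,
        peaks_narrowpeak=peaks_np,
        mnase_bed=mnase_bed,
        coverage_tracks=track_paths,
        truth_json=truth_json,
        truth=truth,
    )


def element_anchors(
    peaks: Sequence[PeakRegion],
    elements: Sequence[RepeatInstance],
    w: int = 500,
) -> list[Anchor]:
    """Midpoint anchors (with quadrant groups) for elements in summit windows."""
    from .anatomy import classify_quadrant

    by_chrom: dict[str, list[RepeatInstance]] = {}
    for e in elements:
        by_chrom.setdefault(e.interval.chrom, []).append(e)
    anchors = []
    for peak in peaks:
        lo, hi = peak.summit - w, peak.summit + w + 1
        for e in by_chrom.get(peak.chrom, ()):
            if e.interval.start < hi and e.interval.end > lo:
                group = classify_quadrant(peak, e)
                anchors.append(
                    Anchor(e.interval.chrom, e.midpoint, str(group), e.interval.strand)
                )
    return anchors
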