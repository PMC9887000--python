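"""PWM log-odds scanning and anchor-centered positional motif profiles.

Scanning is anchored either at peak summits (which motifs crowd the point of
maximal accessibility?) or at repeat-element midpoints split by strand/side
group (where do KLF-like and SOX-like motifs sit along the element body?).
Hit positions are recorded at the motif center so offsets mean the same
thing for motifs of different lengths.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .profiles import PositionalProfile, profile_from_offsets

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclasses.dataclass
class PWM:
    """Position probability matrix with a background model.

    ``probs`` is L x 4 over A,C,G,T; rows sum to 1. ``pseudocount`` records
    the per-cell count added before normalization when the matrix was built
    from counts.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or len(self.probs) < 2:
            raise ValueError("PWM requires an L x 4 matrix with L >= 2")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM row must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: np.ndarray | None = None,
    ) -> "PWM":
        """Normalize an L x 4 count matrix with a per-cell pseudocount."""
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else background
        return cls(name, probs, bg, pseudocount)

    def __len__(self) -> int:
        return len(self.probs)

    @property
    def log_odds(self) -> np.ndarray:
        # tiny floor guards PWMs built directly from probabilities with zeros
        return np.log2(np.maximum(self.probs, 1e-9) / self.background)

    @property
    def score_range(self) -> tuple[float, float]:
        lom = self.log_odds
        return float(lom.min(axis=1).sum()), float(lom.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))


@dataclasses.dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based start of the match on the scanned sequence
    strand: str
    score: float  # log-odds, bits
    rel_score: float  # (score - min) / (max - min), in [0, 1]


@dataclasses.dataclass
class MotifPositionalEnrichment:
    motif: str
    group: str
    profile: PositionalProfile


def read_jaspar(path: str | Path) -> list[PWM]:
    """Read JASPAR four-row count matrices; empty file yields an empty list.

    Counts are converted to probabilities with a 0.01 per-cell pseudocount.
    """
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
            parsed = list(parsed)
        except Exception as exc:
            raise ValueError(f"{path}: malformed JASPAR file: {exc}") from exc
    out = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in _BASES] for i in range(m.length)])
        name = m.name or m.matrix_id or "motif"
        out.append(PWM.from_counts(str(name), counts))
    return out


def write_jaspar(pwms: Sequence[PWM], path: str | Path, scale: float = 1e8) -> None:
    """Write PWMs as JASPAR count matrices (probabilities x ``scale``).

    The large default scale keeps the read-time pseudocount negligible, so a
    write/read round trip preserves probabilities to better than 1e-9.
    """
    with open(path, "w") as fh:
        for i, pwm in enumerate(pwms, 1):
            fh.write(f">SYN{i:04d}.1 {pwm.name}\n")
            counts = pwm.probs * scale
            for b in _BASES:
                row = " ".join(f"{c:.4f}" for c in counts[:, _BASE_INDEX[b]])
                fh.write(f"{b} [ {row} ]\n")


def load_packaged_motifs() -> list[PWM]:
    """KLF-like and SOX-like PWMs shipped with the package.

    These are synthetic stand-in matrices built around the G-rich KLF and
    A/T-rich SOX family consensus cores, not matrices taken from a motif
    database.
    """
    ref = resources.files("sineanchor.data") / "synthetic_klf_sox_motifs.jaspar"
    with resources.as_file(ref) as path:
        return read_jaspar(path)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        idx[arr == ord(b)] = i
    return idx


def scan_sequence(seq: str, pwm: PWM, min_rel_score: float = 0.8) -> list[MotifHit]:
    """Scan both strands of ``seq``; windows containing N are skipped.

    A minus-strand hit at position i means the reverse complement of
    ``seq[i:i+L]`` matches the motif. Hits are sorted by position.
    """
    if not 0.0 <= min_rel_score <= 1.0:
        raise ValueError("min_rel_score must lie in [0, 1]")
    L = len(pwm)
    S = len(seq)
    if S < L:
        return []
    idx = _encode(seq)
    n_win = S - L + 1
    lom = pwm.log_odds
    lom_rc = lom[::-1, ::-1]  # reverse-complement scoring on the forward text
    fwd = np.zeros(n_win)
    rev = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for j in range(L):
        col = idx[j : j + n_win]
        ok = col >= 0
        valid &= ok
        safe = np.where(ok, col, 0)
        fwd += np.where(ok, lom[j, safe], 0.0)
        rev += np.where(ok, lom_rc[j, safe], 0.0)
    lo, hi = pwm.score_range
    span = hi - lo if hi > lo else 1.0
    hits: list[MotifHit] = []
    for pos in np.flatnonzero(valid):
        for strand, score in (("+", fwd[pos]), ("-", rev[pos])):
            rel = (score - lo) / span
            if rel >= min_rel_score:
                hits.append(MotifHit(int(pos), strand, float(score), float(rel)))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


@dataclasses.dataclass(frozen=True)
class Anchor:
    """A single-bp anchor (element midpoint or peak summit) with a group
    label used to split profiles (quadrants 1-4, or "all")."""

    chrom: str
    pos: int
    group: str = "all"
    strand: str = "."


def anchored_motif_profile(
    anchors: Sequence[Anchor],
    genome_fasta: str | Path,
    pwm: PWM,
    w: int = 500,
    min_rel_score: float = 0.8,
    smoothing_bp: int = 11,
    flip_minus: bool = False,
) -> dict[str, MotifPositionalEnrichment]:
    """Per-group profiles of motif-hit centers as offsets from anchors.

    ``flip_minus`` negates offsets at minus-strand anchors, merging the two
    strands into element-oriented coordinates; the default keeps genomic
    coordinates so per-quadrant panels stay separate.
    """
    import pyfaidx

    fasta = pyfaidx.Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    L = len(pwm)
    offsets_by_group: dict[str, list[int]] = {}
    n_by_group: dict[str, int] = {}
    for anchor in anchors:
        if anchor.chrom not in fasta:
            raise ValueError(f"chromosome {anchor.chrom} missing from FASTA")
        chrom_len = len(fasta[anchor.chrom])
        seg_start = max(0, anchor.pos - w - L + 1)
        seg_end = min(chrom_len, anchor.pos + w + L)
        seq = str(fasta[anchor.chrom][seg_start:seg_end])
        n_by_group[anchor.group] = n_by_group.get(anchor.group, 0) + 1
        bucket = offsets_by_group.setdefault(anchor.group, [])
        for hit in scan_sequence(seq, pwm, min_rel_score):
            center = seg_start + hit.position + L // 2
            offset = center - anchor.pos
            if flip_minus and anchor.strand == "-":
                offset = -offset
            if -w <= offset <= w:
                bucket.append(offset)
    return {
        group: MotifPositionalEnrichment(
            pwm.name,
            group,
            profile_from_offsets(
                offsets_by_group[group], w, n_by_group[group], smoothing_bp
            ),
        )
        for group in offsets_by_group
    }
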