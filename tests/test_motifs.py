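"""PWM parsing, log-odds scanning, and anchored positional profiles."""

import itertools
import math

import numpy as np
import pytest

from sineanchor.motifs import (
    PWM,
    Anchor,
    anchored_motif_profile,
    load_packaged_motifs,
    read_jaspar,
    scan_sequence,
    write_jaspar,
)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(COMPLEMENT)[::-1]


def brute_force_hits(seq, pwm, min_rel_score):
    """Oracle: score every window of every strand from the probability matrix."""
    L = len(pwm)
    lom = np.log2(np.maximum(pwm.probs, 1e-9) / pwm.background)
    lo = lom.min(axis=1).sum()
    hi = lom.max(axis=1).sum()
    hits = []
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for pos in range(len(seq) - L + 1):
        window = seq[pos : pos + L].upper()
        if any(b not in index for b in window):
            continue
        for strand, text in (("+", window), ("-", revcomp(window))):
            score = sum(lom[j, index[b]] for j, b in enumerate(text))
            rel = (score - lo) / (hi - lo)
            if rel >= min_rel_score:
                hits.append((pos, strand))
    return sorted(hits)


class TestJasparIO:
    def test_counts_normalized_with_pseudocount(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(
            ">M1 toy\n"
            "A [ 10 10 10 10 ]\n"
            "C [ 0 0 0 0 ]\n"
            "G [ 0 0 0 0 ]\n"
            "T [ 0 0 0 0 ]\n"
        )
        (pwm,) = read_jaspar(p)
        np.testing.assert_allclose(pwm.probs[:, 0], 10.01 / 10.04)
        np.testing.assert_allclose(pwm.probs[:, 1:], 0.01 / 10.04)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.jaspar"
        p.write_text("")
        assert read_jaspar(p) == []

    def test_round_trip_preserves_probabilities(self, tmp_path):
        pwms = load_packaged_motifs()
        path = tmp_path / "rt.jaspar"
        write_jaspar(pwms, path)
        back = read_jaspar(path)
        for a, b in zip(pwms, back):
            np.testing.assert_allclose(a.probs, b.probs, atol=1e-9)

    def test_unequal_rows_rejected(self, tmp_path):
        p = tmp_path / "bad.jaspar"
        p.write_text(
            ">M1 bad\nA [ 10 10 ]\nC [ 0 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        )
        with pytest.raises(ValueError):
            read_jaspar(p)


class TestPWMType:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PWM("bad", np.array([[0.5, 0.5, 0.5, 0.5], [0.25] * 4]))

    def test_minimum_length_two(self):
        with pytest.raises(ValueError):
            PWM("short", np.array([[0.25] * 4]))


class TestScanSequence:
    def test_consensus_hit_at_planted_offset(self):
        pwm = load_packaged_motifs()[0]
        seq = "ACGTACGTAC" + pwm.consensus + "TTACGTTACG"
        hits = scan_sequence(seq, pwm, min_rel_score=1.0)
        assert [(h.position, h.strand) for h in hits] == [(10, "+")]
        assert hits[0].rel_score == pytest.approx(1.0)

    def test_reverse_complement_hit_on_minus_strand(self):
        pwm = load_packaged_motifs()[1]
        seq = "ACGTACGTAC" + revcomp(pwm.consensus) + "TTACGTTACG"
        hits = scan_sequence(seq, pwm, min_rel_score=1.0)
        assert [(h.position, h.strand) for h in hits] == [(10, "-")]

    def test_sequence_shorter_than_motif(self):
        pwm = load_packaged_motifs()[0]
        assert scan_sequence("ACG", pwm) == []

    def test_windows_with_n_skipped(self):
        pwm = load_packaged_motifs()[0]
        seq = pwm.consensus[:4] + "N" + pwm.consensus[5:]
        assert scan_sequence(seq, pwm, min_rel_score=0.0) == []

    def test_dinucleotide_pwm_matches_exhaustive_oracle(self):
        counts = np.array([[8, 1, 1, 0], [0, 1, 2, 7]])
        pwm = PWM.from_counts("dinuc", counts)
        for a, b in itertools.product("ACGT", repeat=2):
            seq = a + b
            for threshold in (0.0, 0.5, 0.8, 1.0):
                got = [(h.position, h.strand) for h in scan_sequence(seq, pwm, threshold)]
                assert got == brute_force_hits(seq, pwm, threshold), (seq, threshold)

    def test_random_sequences_match_oracle_for_short_motifs(self):
        rng = np.random.default_rng(12)
        for L in (2, 3, 4):
            counts = rng.integers(0, 20, size=(L, 4))
            pwm = PWM.from_counts(f"m{L}", counts)
            seq = "".join(rng.choice(list("ACGTN"), size=200, p=[0.24] * 4 + [0.04]))
            got = [(h.position, h.strand) for h in scan_sequence(seq, pwm, 0.8)]
            assert got == brute_force_hits(seq, pwm, 0.8)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


class TestAnchoredProfile:
    def test_single_hit_at_anchor_lands_at_offset_zero(self, tmp_path):
        pwm = load_packaged_motifs()[0]
        L = len(pwm)
        flank = "TATATATATATATATATATATATATATATA"  # motif-free
        # place the motif so its center sits exactly on the anchor
        anchor_pos = len(flank) + L // 2
        seq = flank + pwm.consensus + flank
        fasta = tmp_path / "g.fa"
        write_fasta(fasta, {"chr1": seq})
        profiles = anchored_motif_profile(
            [Anchor("chr1", anchor_pos)], fasta, pwm, w=20, smoothing_bp=1
        )
        raw = profiles["all"].profile.raw_counts
        assert raw[20] == 1  # offset 0
        assert raw.sum() == 1

    def test_missing_chromosome_named_in_error(self, tmp_path):
        fasta = tmp_path / "g.fa"
        write_fasta(fasta, {"chr1": "ACGT" * 50})
        pwm = load_packaged_motifs()[0]
        with pytest.raises(ValueError, match="chrX"):
            anchored_motif_profile([Anchor("chrX", 50)], fasta, pwm, w=10)

    def test_profiles_translation_equivariant(self, tmp_path):
        rng = np.random.default_rng(4)
        pwm = load_packaged_motifs()[1]
        core = "".join(rng.choice(list("ACGT"), size=300))
        shift = 17
        f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(f1, {"chr1": core})
        write_fasta(f2, {"chr1": "N" * shift + core})  # N prefix adds no hits
        p1 = anchored_motif_profile([Anchor("chr1", 150)], f1, pwm, w=60, min_rel_score=0.7)
        p2 = anchored_motif_profile(
            [Anchor("chr1", 150 + shift)], f2, pwm, w=60, min_rel_score=0.7
        )
        np.testing.assert_allclose(
            p1["all"].profile.values, p2["all"].profile.values
        )

    def test_planted_head_and_tail_motifs_localize(self, clean_motif_dataset):
        """KLF-like hits cluster at the element head (-70 for a 140 bp
        element) and SOX-like at the tail (+70) in element-oriented
        coordinates."""
        from sineanchor.core import read_regions, read_repeats
        from sineanchor.simulate import element_anchors

        ds = clean_motif_dataset
        peaks = read_regions(ds.peaks_narrowpeak, "narrowpeak")
        b1 = [r for r in read_repeats(ds.elements_bed) if r.subfamily == "B1"]
        anchors = [
            Anchor(a.chrom, a.pos, "all", a.strand)
            for a in element_anchors(peaks, b1)
        ]
        klf, sox = load_packaged_motifs()
        klf_prof = anchored_motif_profile(
            anchors, ds.genome_fasta, klf, w=200, flip_minus=True
        )["all"].profile
        sox_prof = anchored_motif_profile(
            anchors, ds.genome_fasta, sox, w=200, flip_minus=True
        )["all"].profile
        assert abs(klf_prof.mode_offset() - (-70)) <= 10
        assert abs(sox_prof.mode_offset() - 70) <= 10
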