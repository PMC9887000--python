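# sineanchor

Toolkit for asking how transposable elements — rodent B1-like SINEs in
particular — organize chromatin accessibility regions. It grew out of the
observation that when a SINE-binding KRAB zinc-finger repressor is removed,
the regions that gain accessibility ("more open regions", MORs) are not
random: almost all of them contain a SINE, the element sits ~70 bp to the
side of the peak summit rather than on it, its 5' head preferentially faces
the summit, KLF-family and SOX-family motifs sit at the element's head and
tail, and a nucleosome is positioned with its dyad on the element midpoint.
`sineanchor` turns each of those observations into a reusable, tested
computation, and ships a synthetic-data generator that plants all of that
structure in a toy genome so the whole pipeline can be exercised and
calibrated without any sequencing data.

## What it computes

- **TE-family enrichment** (`sineanchor.enrichment`). The genome is tiled
  into fixed bins (default 500 bp). With `N` total bins, `n` peak bins, `K`
  family bins and `k` bins carrying both, the one-tailed p-value is the
  upper hypergeometric tail `P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`, and fold
  enrichment is `(k/n)/(K/N)`; Benjamini–Hochberg correction runs across
  families. Peak-level tallies (`count_peaks_with_family`) give the
  "x% of peaks contain ≥1 element" summaries.
- **Summit anatomy** (`sineanchor.anatomy`). Elements within ±500 bp of a
  summit are split into four groups by strand × side; head-inward
  configurations (minus/upstream, plus/downstream) are tested against 0.5 by
  a two-sided exact binomial test (doubled smaller tail). Positional
  profiles record element midpoints/heads/tails as offsets from the summit.
- **Motif profiles** (`sineanchor.motifs`). JASPAR PWMs, log₂-odds scanning
  of both strands with a relative-score threshold, and positional profiles
  of motif-hit centers around arbitrary anchors (summits, or element
  midpoints split by quadrant).
- **Nucleosome dyads** (`sineanchor.nucleosomes`). MNase fragments →
  midpoint dyads → dyad frequency profiles around element midpoints.
- **Region classes** (`sineanchor.classify`). Summit-centered binned
  coverage across a sample panel, log1p-transformed, partitioned by seeded
  K-means (k = 2); the cluster with higher fibroblast signal is labeled
  "open-in-MEF", the other "closed-in-MEF, opening".
- **Synthetic data** (`sineanchor.simulate`). Plants all of the above with
  configurable truth (element fraction 0.92 of 479 peaks, offsets
  Normal(70, 15), head-inward probability 0.75, dyad spread 20 bp, two
  coverage classes at 121:1401-like proportions) and writes
  FASTA/BED/narrowPeak/bedGraph plus a truth JSON. Also includes the screen
  design arithmetic: infection efficiency `1 − e^(−MOI)`.

## Worked example

Run the whole pipeline on a small synthetic dataset:

```
cat > pipeline.yaml <<'YAML'
seed: 7
simulate:
  genome: {chr1: 300000, chr2: 200000}
  n_peaks: 60
  n_elements: 90
  n_decoy_elements: 20
YAML
sineanchor run --config pipeline.yaml --out run/
```

Selected stage output (the command prints the full JSON report):

```
"enrich":  {"top_family": "B1", "top_fold": 5.33, "top_p": 4.0e-47,
            "peaks_with_B1": 57, "percent_with_B1": 95.0}
"anatomy": {"head_inward_fraction": 0.789, "orientation_p": 1.3e-05,
            "profile_mode_left": -75, "profile_mode_right": 66}
"dyads":   {"dyad_mode_offset": 4, "n_dyads": 1800}
"classify":{"cluster_sizes": {"cluster1_open_in_MEF": 3,
                              "cluster2_closed_in_MEF_opening": 57}}
```

Reading: the planted B1-like family is the top-enriched family (fold 5.3
over the binned-genome background, hypergeometric p ≈ 4e-47); 57/60 peaks
carry an element; element heads face the summit in 79% of cases (exact
binomial p ≈ 1e-5); the element-position profile is bimodal around ±70 bp;
nucleosome dyads center on element midpoints; and K-means recovers the two
planted coverage classes. Per-stage TSV/JSON/BED outputs land under `run/`
together with `report.json` (parameters, statistics, file checksums).

Every stage is also available standalone (`sineanchor enrich|anatomy|
motifs|dyads|classify|simulate|convert`) on standard BED / narrowPeak /
RepeatMasker `.out` / JASPAR / bedGraph inputs.

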