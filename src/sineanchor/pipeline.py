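"""End-to-end orchestration: simulate -> enrich -> anatomy -> motifs ->
dyads -> classify, under one config and one seed, with a machine-readable
run report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import anatomy as anatomy_mod
from . import classify as classify_mod
from . import enrichment as enrichment_mod
from . import nucleosomes as nucleosomes_mod
from . import simulate as simulate_mod
from .core import read_bed, read_chrom_sizes, read_regions, read_repeats
from .motifs import anchored_motif_profile, load_packaged_motifs

logger = logging.getLogger(__name__)

_STAGE_DEFAULTS = {
    "simulate": {},
    "enrich": {"bin_length": 500},
    "anatomy": {"window": 500, "smoothing": 11, "subfamily": "B1"},
    "motifs": {"window": 500, "min_rel_score": 0.8, "smoothing": 11},
    "dyads": {"window": 500, "smoothing": 21},
    "classify": {"k": 2, "n_init": 10, "window_bp": 2000, "bins_per_region": 50},
}


def validate_config(config: dict) -> dict:
    """Check the schema before any stage runs; returns a filled-in copy."""
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    if "seed" not in config:
        raise ValueError("pipeline config requires an explicit seed")
    if not isinstance(config["seed"], int):
        raise ValueError("seed must be an integer")
    full = {"seed": config["seed"], "percent_rounding": config.get("percent_rounding", "nearest")}
    if full["percent_rounding"] not in ("nearest", "floor", "ceil", "raw"):
        raise ValueError(f"unknown percent rounding {full['percent_rounding']!r}")
    for stage, defaults in _STAGE_DEFAULTS.items():
        block = config.get(stage, {})
        if not isinstance(block, dict):
            raise ValueError(f"stage block {stage!r} must be a mapping")
        merged = dict(defaults)
        merged.update(block)
        full[stage] = merged
    return full


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute all stages in order and write ``report.json`` under out_dir.

    Any stage failure propagates after logging the stage name, so partial
    runs never produce a report.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg, "stages": {}, "files": {}}
    written: list[Path] = []

    def stage(name):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    def done(name, t0, **stats):
        report["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            **stats,
        }
        logger.info("stage %s done", name)

    try:
        # --- simulate ------------------------------------------------------
        t0 = stage("simulate")
        sim_cfg = simulate_mod.SyntheticConfig(
            seed=cfg["seed"], **cfg["simulate"]
        )
        dataset = simulate_mod.generate_dataset(sim_cfg, out / "data")
        done(
            "simulate",
            t0,
            n_peaks=sim_cfg.n_peaks,
            n_elements=sim_cfg.n_elements,
            n_peaks_with_element=dataset.truth["n_peaks_with_element"],
        )

        # re-read everything through the format readers
        peaks = read_regions(dataset.peaks_narrowpeak, "narrowpeak")
        repeats = read_repeats(dataset.elements_bed, "bed6_family")
        genome = read_chrom_sizes(dataset.chrom_sizes)

        # --- enrich --------------------------------------------------------
        t0 = stage("enrich")
        universe = enrichment_mod.build_bin_universe(
            genome, cfg["enrich"]["bin_length"]
        )
        results = enrichment_mod.te_family_enrichment(peaks, repeats, universe)
        enrich_tsv = out / "enrichment.tsv"
        enrichment_mod.write_enrichment_tsv(results, enrich_tsv)
        written.append(enrich_tsv)
        with_count, _, pct = enrichment_mod.count_peaks_with_family(
            peaks, repeats, "B1"
        )
        pct = enrichment_mod.percent(
            with_count, len(peaks), mode=cfg["percent_rounding"]
        )
        top = min(results, key=lambda r: r.p)
        done(
            "enrich",
            t0,
            top_family=top.family,
            top_p=top.p,
            top_fold=None if top.fold != top.fold else top.fold,
            peaks_with_B1=with_count,
            percent_with_B1=pct,
        )

        # --- anatomy -------------------------------------------------------
        t0 = stage("anatomy")
        sub = cfg["anatomy"]["subfamily"]
        b1 = [r for r in repeats if r.subfamily == sub]
        w = cfg["anatomy"]["window"]
        counts = anatomy_mod.count_quadrants(peaks, b1, w)
        summary = anatomy_mod.orientation_bias_test(counts)
        orientation_json = out / "orientation.json"
        orientation_json.write_text(
            json.dumps(
                {
                    "n1": counts.n1,
                    "n2": counts.n2,
                    "n3": counts.n3,
                    "n4": counts.n4,
                    "n_at_summit": counts.n_at_summit,
                    "head_inward_fraction": summary.head_inward_fraction,
                    "p": summary.p,
                },
                indent=1,
                sort_keys=True,
            )
        )
        written.append(orientation_json)
        profile = anatomy_mod.element_position_profile(
            peaks, b1, w, smoothing_bp=cfg["anatomy"]["smoothing"]
        )
        profile_tsv = out / "element_position_profile.tsv"
        profile.write_tsv(profile_tsv)
        written.append(profile_tsv)
        done(
            "anatomy",
            t0,
            head_inward_fraction=summary.head_inward_fraction,
            orientation_p=summary.p,
            profile_mode_left=profile.mode_offset("left"),
            profile_mode_right=profile.mode_offset("right"),
        )

        # --- motifs --------------------------------------------------------
        t0 = stage("motifs")
        anchors = simulate_mod.element_anchors(peaks, b1, w)
        motif_stats = {}
        for pwm in load_packaged_motifs():
            profiles = {}
            if anchors:
                profiles = anchored_motif_profile(
                    anchors,
                    dataset.genome_fasta,
                    pwm,
                    w=cfg["motifs"]["window"],
                    min_rel_score=cfg["motifs"]["min_rel_score"],
                    smoothing_bp=cfg["motifs"]["smoothing"],
                    flip_minus=True,
                )
            for enr in profiles.values():
                path = out / f"motif_{pwm.name}_group{enr.group}.tsv"
                enr.profile.write_tsv(path)
                written.append(path)
            motif_stats[pwm.name] = {"groups": sorted(profiles)}
        done("motifs", t0, **motif_stats)

        # --- dyads ---------------------------------------------------------
        t0 = stage("dyads")
        fragments = read_bed(dataset.mnase_bed)
        dyads = nucleosomes_mod.fragments_to_dyads(fragments)
        dyad_profile = nucleosomes_mod.dyad_frequency_profile(
            anchors,
            dyads,
            w=cfg["dyads"]["window"],
            smoothing_bp=cfg["dyads"]["smoothing"],
        )
        dyad_tsv = out / "dyad_profile.tsv"
        dyad_profile.profile.write_tsv(dyad_tsv)
        written.append(dyad_tsv)
        done(
            "dyads",
            t0,
            n_dyads=len(dyads),
            dyad_mode_offset=dyad_profile.profile.mode_offset(),
        )

        # --- classify ------------------------------------------------------
        t0 = stage("classify")
        tracks = {
            sample: classify_mod.CoverageTrack.from_bedgraph(path)
            for sample, path in dataset.coverage_tracks.items()
        }
        matrix = classify_mod.build_signal_matrix(
            peaks,
            tracks,
            window_bp=cfg["classify"]["window_bp"],
            bins_per_region=cfg["classify"]["bins_per_region"],
        )
        km = classify_mod.kmeans_partition(
            matrix,
            k=cfg["classify"]["k"],
            seed=cfg["seed"],
            n_init=cfg["classify"]["n_init"],
        )
        labels = classify_mod.label_mor_classes(km, matrix)
        assign_bed = out / "region_classes.bed"
        classify_mod.write_assignment_bed(matrix, km, labels, assign_bed)
        written.append(assign_bed)
        sizes = {
            labels[c]: int((km.assignment == c).sum()) for c in labels
        }
        done("classify", t0, cluster_sizes=sizes, inertia=km.inertia)
    except Exception:
        logger.exception("pipeline aborted")
        raise

    for path in written:
        report["files"][path.name] = _sha256(path)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
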