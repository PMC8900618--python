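"""End-to-end demo pipeline over simulated inputs.

Runs the full chain — simulate, scan coverage for large CNVs, segment
phased BAF, estimate relatedness, run the SNV cascade, validate calls
against simulated array intensities, and build the per-line report with
selection verdicts — writing every table plus a JSON run manifest to an
output directory. Everything is driven by one seed; the same seed
yields byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__, baf, doc_cnv, irs, report, sim, snv
from .kinship import ld_prune, maf_filter, pairwise_relatedness
from .sim import SimConfig, TruthEvent


def demo_config(seed: int = 0) -> SimConfig:
    """A small, quick cohort with a representative mix of implanted
    events: a fixed trisomy-arm-like gain, a mosaic gain, a mosaic loss
    and a telomere-extending mosaic CN-LOH."""
    events = [
        TruthEvent("S001", "chr1", 100, 160, 3, 1.0, "dup"),
        TruthEvent("S002", "chr1", 300, 350, 3, 0.5, "dup"),
        TruthEvent("S003", "chr1", 500, 560, 1, 0.6, "del"),
        TruthEvent("S004", "chr1", 900, 1000, 2, 0.5, "cnloh"),
    ]
    return SimConfig(
        seed=seed,
        n_samples=12,
        n_bins=1000,
        mean_depth=30,
        events=events,
        n_het_sites=4000,
        n_snps=4000,
        n_variants=1500,
        pedigree=[("S000", "F0", "F1"), ("S001", "F0", "F1")],
    )


def run_pipeline(cfg: SimConfig, out_dir) -> dict:
    """Run every stage on simulated inputs; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix, truth = sim.gen_coverage(cfg)
    matrix.to_tsv(out / "coverage.tsv")

    calls = doc_cnv.scan_large_cnvs(matrix)
    calls_df = pd.DataFrame([vars(c) for c in calls])
    calls_df.to_csv(out / "large_cnv_calls.tsv", sep="\t", index=False)

    counts = sim.gen_phased_counts(cfg)
    counts.to_csv(out / "phased_counts.tsv", sep="\t", index=False)
    chrom_lengths = {cfg.chrom: cfg.n_bins * cfg.bin_size}
    cnloh_accepted = []
    seg_rows = []
    for s in cfg.sample_ids():
        for seg in baf.segment_imbalance(counts, s):
            baf.classify_segment(seg, matrix)
            accepted = (
                baf.cnloh_accept(seg, chrom_lengths) if seg.klass == "cnloh" else False
            )
            if accepted:
                cnloh_accepted.append(seg)
            row = vars(seg).copy()
            row["accepted_cnloh"] = accepted
            seg_rows.append(row)
    pd.DataFrame(seg_rows).to_csv(out / "baf_segments.tsv", sep="\t", index=False)

    geno, rel_truth = sim.gen_pedigree_genotypes(cfg)
    kept = ld_prune(maf_filter(geno))
    rel = pairwise_relatedness(geno[kept])
    rel.to_csv(out / "relatedness.tsv", sep="\t", index=False)
    ids = set(cfg.sample_ids())
    rel_cohort = rel[rel["sample1"].isin(ids) & rel["sample2"].isin(ids)]

    variants = sim.gen_variant_table(cfg)
    cascade = snv.run_cascade(variants)
    cascade.to_csv(out / "snv_cascade.tsv", sep="\t", index=False)
    burden = snv.burden_summary(cascade)
    burden.to_csv(out / "snv_burden.tsv", sep="\t")

    depth_calls = [c for c in calls if c.n_bins < 200]
    intens, probes = sim.gen_array_intensities(depth_calls, [True] * len(depth_calls), cfg)
    irs_res = irs.irs_table(depth_calls, intens, probes)
    irs_res.to_csv(out / "irs.tsv", sep="\t", index=False)

    rep = report.build_report(
        cfg.sample_ids(),
        large_calls=calls,
        cnloh_segments=cnloh_accepted,
        snv_burden=burden,
        relatedness=rel_cohort,
    )
    rep.to_csv(out / "line_report.tsv", sep="\t")
    verdicts = report.select_lines(rep)
    pd.DataFrame(
        [
            {"line": v.line, "overall": v.overall, "reasons": "; ".join(v.reasons)}
            for v in verdicts
        ]
    ).to_csv(out / "selection.tsv", sep="\t", index=False)

    manifest = {
        "stemqc_version": __version__,
        "seed": cfg.seed,
        "n_samples": cfg.n_samples,
        "n_bins": cfg.n_bins,
        "n_truth_events": len(truth),
        "n_large_calls": len(calls),
        "n_accepted_cnloh": len(cnloh_accepted),
        "n_direct_pairs": int(
            rel["relationship"].isin(["full_sibling", "parent_child"]).sum()
        ),
        "thresholds": {
            "z_seed": doc_cnv.DEFAULT_Z_SEED,
            "z_report": doc_cnv.DEFAULT_Z_REPORT,
            "min_bins": doc_cnv.DEFAULT_MIN_BINS,
            "p_mosaic": doc_cnv.DEFAULT_P_MOSAIC,
            "lod": baf.DEFAULT_LOD,
        },
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
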