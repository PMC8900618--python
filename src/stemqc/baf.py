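"""Allelic-imbalance detection from phased heterozygous allele depths.

At a phased het site the B-allele frequency (BAF) is hap1 reads over
total reads; away from events its expectation is 0.5. A clonal or
mosaic event shifts it: with cell fraction f,

    CN-LOH:            BAF = (1 + f) / 2          (d = f / 2)
    single-copy dup:   BAF = (1 + f) / (2 + f)    (d = f / (2 (2 + f)))
    single-copy del:   BAF = 1 / (2 - f)          (d = f / (2 (2 - f)))

where d is the deviation |BAF - 0.5| on the over-represented haplotype.
Segmentation is a binomial likelihood-ratio scan: each site gets a
log10 likelihood-ratio score for a fixed alternative deviation, maximal
positive-scoring runs are extracted per orientation, and each run is
re-scored at its estimated deviation. Segments with LOD above 20 and
span above 1 Mbp are reported; coverage over the segment then separates
duplications and deletions from copy-neutral LOH, and CN-LOH events are
accepted only when mosaic and telomere-extending (the signature of a
single mitotic crossover arising in culture, as opposed to a fixed run
of homozygosity).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CoverageMatrix, ImbalanceSegment
from .doc_cnv import integer_divergence_test

__all__ = [
    "segment_imbalance",
    "classify_segment",
    "cnloh_accept",
    "lod_score",
]

DEFAULT_LOD = 20.0
DEFAULT_MIN_LENGTH = 1_000_000
SCAN_DELTA = 0.1  # fixed alternative deviation for the site scores
LOW_FRACTION = 0.1


def lod_score(hap1: np.ndarray, hap2: np.ndarray, d: float, orientation: int = 1) -> float:
    """Base-10 log likelihood ratio of binomial(p = 0.5 + orientation*d)
    vs. binomial(p = 0.5) for phased depths, summed over sites.

    Terms with zero count are dropped so a fully homozygous run (d=0.5)
    has a finite LOD.
    """
    hap1 = np.asarray(hap1, dtype=float)
    hap2 = np.asarray(hap2, dtype=float)
    p = 0.5 + orientation * d
    p = min(max(p, 0.0), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(hap1 > 0, hap1 * (np.log10(p) - np.log10(0.5)), 0.0)
        t2 = np.where(hap2 > 0, hap2 * (np.log10(1 - p) - np.log10(0.5)), 0.0)
    return float(np.sum(t1) + np.sum(t2))


def _max_scoring_segments(scores: np.ndarray, min_score: float) -> list[tuple]:
    """Disjoint maximal-sum runs with sum >= min_score, greedily by
    repeated maximum-subarray extraction."""
    s = scores.astype(float).copy()
    out = []
    while True:
        best_sum, best = -math.inf, None
        run_sum, run_start = 0.0, 0
        for i, v in enumerate(s):
            if run_sum <= 0:
                run_sum, run_start = v, i
            else:
                run_sum += v
            if run_sum > best_sum:
                best_sum, best = run_sum, (run_start, i + 1)
        if best is None or best_sum < min_score:
            break
        out.append(best)
        s[best[0] : best[1]] = -math.inf
    return out


def segment_imbalance(
    counts: pd.DataFrame,
    sample: str,
    lod_threshold: float = DEFAULT_LOD,
    min_length: int = DEFAULT_MIN_LENGTH,
    scan_delta: float = SCAN_DELTA,
) -> list[ImbalanceSegment]:
    """Detect allelic-imbalance segments for one sample.

    ``counts`` has columns chrom, pos, sample, hap1_depth, hap2_depth
    (phased het sites only). Returns segments with LOD > threshold and
    span > ``min_length`` bp.
    """
    sub = counts[counts["sample"] == sample]
    segments: list[ImbalanceSegment] = []
    for chrom, grp in sub.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        h1 = grp["hap1_depth"].to_numpy(dtype=float)
        h2 = grp["hap2_depth"].to_numpy(dtype=float)
        pos = grp["pos"].to_numpy()
        tot = h1 + h2
        keep = tot > 0
        h1, h2, pos, tot = h1[keep], h2[keep], pos[keep], tot[keep]
        if len(pos) == 0:
            continue
        for orient in (+1, -1):
            a, b = (h1, h2) if orient == 1 else (h2, h1)
            p_alt = 0.5 + scan_delta
            site_scores = a * math.log10(p_alt / 0.5) + b * math.log10((1 - p_alt) / 0.5)
            for start, end in _max_scoring_segments(site_scores, lod_threshold):
                baf = h1[start:end] / tot[start:end]
                d = abs(float(np.mean(baf)) - 0.5)
                # refine once at the estimated deviation: near-balanced
                # boundary sites score strongly negative under the real
                # alternative and fall out of the run
                p_hat = min(0.5 + d, 1 - 1e-9)
                s2 = a[start:end] * math.log10(p_hat / 0.5) + b[start:end] * math.log10(
                    (1 - p_hat) / 0.5
                )
                inner = _max_scoring_segments(s2, 0.0)
                if inner:
                    i0, i1 = max(inner, key=lambda iv: float(np.sum(s2[iv[0] : iv[1]])))
                    start, end = start + i0, start + i1
                    baf = h1[start:end] / tot[start:end]
                    d = abs(float(np.mean(baf)) - 0.5)
                lod = lod_score(a[start:end], b[start:end], d)
                span = int(pos[end - 1] - pos[start])
                if lod > lod_threshold and span > min_length:
                    segments.append(
                        ImbalanceSegment(
                            sample=sample,
                            chrom=chrom,
                            start=int(pos[start]),
                            end=int(pos[end - 1]),
                            n_sites=end - start,
                            deviation=d,
                            lod=lod,
                            orientation=orient,
                        )
                    )
    # the two orientations can both fire on the same strong segment with
    # opposite signs only if d=0; otherwise they are disjoint. Sort for
    # stable output.
    segments.sort(key=lambda s: (s.chrom, s.start, -s.lod))
    return segments


def classify_segment(
    seg: ImbalanceSegment,
    matrix: Optional[CoverageMatrix],
    alpha: float = 1e-3,
) -> ImbalanceSegment:
    """Classify an imbalance segment as dup / del / cnloh via coverage.

    Coverage over the segment significantly above 2 means a gain,
    significantly below 2 a loss, otherwise the event is copy-neutral.
    The mosaic cell fraction comes from inverting the BAF mixture
    identity of the assigned class; an inverted fraction outside (0,
    ~1] marks the segment ambiguous.
    """
    d = seg.deviation
    if matrix is None:
        mean_cn, p = 2.0, 1.0
    else:
        si = matrix.sample_index(seg.sample)
        b = matrix.bins
        mask = (
            (b["chrom"] == seg.chrom).to_numpy()
            & (b["end"].to_numpy() > seg.start)
            & (b["start"].to_numpy() < seg.end)
        )
        vals = matrix.cn[si, mask]
        if vals.size == 0:
            raise ValueError("coverage matrix does not cover segment")
        mean_cn = float(vals.mean())
        p = integer_divergence_test(vals, 2)

    if p < alpha and mean_cn > 2:
        klass, f = "dup", 4 * d / (1 - 2 * d) if d < 0.5 else float("inf")
    elif p < alpha and mean_cn < 2:
        klass, f = "del", 4 * d / (1 + 2 * d)
    else:
        klass, f = "cnloh", 2 * d

    if not 0 < f <= 1.0 + 1e-6:
        klass = "ambiguous"
        f = float("nan")
    else:
        f = min(f, 1.0)
    seg.klass = klass
    seg.mosaic_fraction = f
    seg.mean_cn = mean_cn
    seg.low_fraction = bool(f < LOW_FRACTION) if np.isfinite(f) else False
    return seg


def cnloh_accept(
    seg: ImbalanceSegment,
    chrom_lengths: dict,
    terminal_margin: int = 100_000,
) -> bool:
    """Acceptance rule for CN-LOH segments.

    Accepted iff the event is mosaic (cell fraction strictly below 1 —
    a full-fraction run of homozygosity is an inherited feature, not a
    culture-acquired event) and extends to a chromosome terminus
    (within ``terminal_margin`` of position 1 or the chromosome end),
    consistent with formation by a single mitotic crossover.
    """
    if seg.klass != "cnloh":
        raise ValueError("cnloh_accept applies only to cnloh segments")
    if chrom_lengths is None:
        raise ValueError("chromosome length table required")
    try:
        length = chrom_lengths[seg.chrom]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"no chromosome length for {seg.chrom!r}") from exc
    mosaic = seg.mosaic_fraction < 1.0
    telomeric = seg.start <= terminal_margin or seg.end >= length - terminal_margin
    seg.telomeric = bool(telomeric)
    return bool(mosaic and telomeric)
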