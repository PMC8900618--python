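"""Large-CNV detection from binned depth of coverage.

The scan compares each sample against the cohort: for a sample S and a
contiguous bin interval I the score is

    Z(S, I) = |coverage(S, I) - median(I)| / MAD(I)

where coverage(S, I) is S's mean normalized depth over I and median/MAD
are taken across samples (MAD raw, without the normal-consistency
factor). Candidate intervals are seeded at single bins with Z above a
seed threshold, grown greedily while Z does not decrease, locally
polished, and reported when they span at least ``min_bins`` bins, score
above the report threshold, and have sharp boundaries: the next bin
outside each end must sit more than halfway from the inside coverage
back toward that bin's cohort median.

Reported calls are tested for mosaicism by asking whether the mean CN's
divergence from the nearest non-diploid integer copy number could have
arisen by chance; calls with p below ``p_mosaic`` are mosaic and carry a
cellular-fraction estimate f = |mean CN - 2| under a single-copy-step
mixture (expected CN = 2 + f * (c - 2)).

Small-CNV post-processing (length thresholds, masking against large
events, recurrence screening, singleton counting) lives here as well.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .containers import CnvCall, CoverageMatrix, IntervalStats, SmallCnv

__all__ = [
    "interval_z",
    "boundary_is_sharp",
    "scan_large_cnvs",
    "integer_divergence_test",
    "classify_mosaicism",
    "filter_small_cnvs",
    "recurrent_cnv_screen",
    "singleton_burden",
    "reciprocal_overlap",
    "overlap_classes",
]

DEFAULT_Z_SEED = 3.0
DEFAULT_Z_REPORT = 5.0
DEFAULT_MIN_BINS = 10
DEFAULT_MIN_DEV = 0.1  # minimum |coverage - median| in CN units for a call
DEFAULT_P_MOSAIC = 1e-3
DEFAULT_MERGE_GAP = 1
DEL_MIN_LENGTH = 1117
DUP_MIN_LENGTH = 2750
LARGE_LENGTH = 1_000_000


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def interval_z(
    matrix: CoverageMatrix, sample: str, start_bin: int, end_bin: int
) -> IntervalStats:
    """Across-sample robust Z score for one sample over a bin interval.

    ``end_bin`` is exclusive. A zero across-sample MAD flags the
    interval degenerate; Z is then +inf (0 if the sample sits exactly on
    the median), never NaN.
    """
    if end_bin <= start_bin:
        raise ValueError("interval must be non-empty")
    if matrix.n_samples < 5:
        raise ValueError("need at least 5 samples")
    means = matrix.cn[:, start_bin:end_bin].mean(axis=1)
    si = matrix.sample_index(sample)
    return _stats_from_means(means, si, sample, start_bin, end_bin)


def _stats_from_means(means, si, sample, start_bin, end_bin) -> IntervalStats:
    med = float(np.median(means))
    mad = _mad(means)
    cov = float(means[si])
    num = abs(cov - med)
    if mad > 0:
        return IntervalStats(sample, start_bin, end_bin, cov, med, mad, num / mad)
    z = 0.0 if num == 0 else math.inf
    return IntervalStats(sample, start_bin, end_bin, cov, med, mad, z, degenerate=True)


def boundary_is_sharp(
    matrix: CoverageMatrix, sample: str, start_bin: int, end_bin: int
) -> tuple[bool, bool]:
    """Sharp-boundary test at both ends of a candidate interval.

    With c_in the sample's mean coverage inside the interval and b the
    next bin outside one end, that end is sharp iff the sample's
    coverage at b has moved more than halfway from c_in toward b's
    cohort median: |coverage(S, b) - c_in| > 0.5 * |median(b) - c_in|.
    Ends at a chromosome terminus auto-pass.
    """
    si = matrix.sample_index(sample)
    chrom_slc = _containing_chrom_slice(matrix, start_bin, end_bin)
    c_in = float(matrix.cn[si, start_bin:end_bin].mean())

    def test(adj_bin: int) -> bool:
        col = matrix.cn[:, adj_bin]
        med_b = float(np.median(col))
        return abs(float(col[si]) - c_in) > 0.5 * abs(med_b - c_in)

    left = True if start_bin == chrom_slc.start else test(start_bin - 1)
    right = True if end_bin == chrom_slc.stop else test(end_bin)
    return left, right


def _containing_chrom_slice(matrix: CoverageMatrix, start_bin: int, end_bin: int):
    for slc in matrix.chrom_slices().values():
        if slc.start <= start_bin and end_bin <= slc.stop:
            return slc
    raise ValueError("interval spans multiple chromosomes")


# ---------------------------------------------------------------------------
# mosaicism
# ---------------------------------------------------------------------------


def integer_divergence_test(values: np.ndarray, c_int: Optional[float] = None) -> float:
    """Two-sided p-value that the mean of per-bin CN values diverges from
    an integer copy number by chance (t test on the between-bin spread).

    ``c_int`` defaults to the nearest integer to the observed mean. With
    fewer than 2 bins or zero variance the test is degenerate and p=1.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        return 1.0
    mean = values.mean()
    if c_int is None:
        c_int = round(mean)
    sd = values.std(ddof=1)
    if sd == 0:
        return 1.0 if mean == c_int else 0.0
    t = (mean - c_int) / (sd / math.sqrt(n))
    return float(2.0 * stats.t.sf(abs(t), df=n - 1))


def classify_mosaicism(
    call: CnvCall, matrix: CoverageMatrix, p_threshold: float = DEFAULT_P_MOSAIC
) -> CnvCall:
    """Classify a reported large call as fixed or mosaic.

    Tests the call's mean CN against the nearest integer copy number not
    equal to 2 that is consistent with the call type; p below the
    threshold means the culture is a mixture (mosaic) and the cellular
    fraction is estimated as |mean CN - 2| / |c - 2| with c = 3 for
    gains and 1 for losses (single-copy step), clipped to (0, 1].
    """
    si = matrix.sample_index(call.sample)
    vals = matrix.cn[si, call.start_bin : call.end_bin]
    chat = float(vals.mean())
    if call.kind == "dup":
        c_int = max(3, int(round(chat)))
    else:
        c_int = min(1, max(0, int(round(chat))))
    p = integer_divergence_test(vals, c_int)
    if p < p_threshold:
        frac = min(1.0, abs(chat - 2.0))  # single-copy step: |c - 2| = 1
        frac = max(frac, 1e-9)
        return replace(call, status="mosaic", p_mosaic=p, cell_fraction=frac, mean_cn=chat)
    return replace(call, status="fixed", p_mosaic=p, cell_fraction=None, mean_cn=chat)


# ---------------------------------------------------------------------------
# large-CNV scan
# ---------------------------------------------------------------------------


def scan_large_cnvs(
    matrix: CoverageMatrix,
    z_seed: float = DEFAULT_Z_SEED,
    z_report: float = DEFAULT_Z_REPORT,
    min_bins: int = DEFAULT_MIN_BINS,
    min_dev: float = DEFAULT_MIN_DEV,
    p_mosaic: float = DEFAULT_P_MOSAIC,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[CnvCall]:
    """Scan every sample for large CNVs against the cohort.

    Per sample and chromosome: seed at single bins with Z > ``z_seed``
    and grow each seed by bin membership (a neighbor joins while it has
    not returned more than halfway toward its cohort median; terminal
    bins that have returned are trimmed). Candidates must span >=
    ``min_bins`` bins, have interval Z > ``z_report``, deviate from the
    cohort median by at least ``min_dev`` copy-number units (Z is
    self-normalized, so an absolute effect-size floor stands in for the
    manual review step and keeps event-free noise out), have sharp
    boundaries at both ends, and have inside-consistent terminal bins.
    Overlapping candidates are resolved in favor of the highest Z, and
    surviving calls separated by at most ``merge_gap`` bins are merged.
    Reported calls carry fixed/mosaic status.
    """
    calls: list[CnvCall] = []
    for chrom, slc in matrix.chrom_slices().items():
        sub = matrix.cn[:, slc]
        for si, sample in enumerate(matrix.samples):
            cands = _candidates_for_sample(sub, si, z_seed, min_bins, min_dev)
            kept = _select_calls(sub, si, cands, z_report, min_bins, min_dev)
            kept = _merge_calls(sub, si, kept, merge_gap)
            for start, end in kept:
                st = _stats_from_means(
                    sub[:, start:end].mean(axis=1), si, sample, start, end
                )
                kind = "dup" if st.coverage > st.median else "del"
                call = CnvCall(
                    sample=sample,
                    chrom=chrom,
                    start=int(matrix.bins["start"].iloc[slc.start + start]),
                    end=int(matrix.bins["end"].iloc[slc.start + end - 1]),
                    kind=kind,
                    z=st.z,
                    mean_cn=st.coverage,
                    n_bins=end - start,
                    start_bin=slc.start + start,
                    end_bin=slc.start + end,
                )
                calls.append(classify_mosaicism(call, matrix, p_mosaic))
    return calls


def _interval_means(cum: np.ndarray, start: int, end: int) -> np.ndarray:
    return (cum[:, end] - cum[:, start]) / (end - start)


def _z_of(cum: np.ndarray, si: int, start: int, end: int) -> float:
    means = _interval_means(cum, start, end)
    med = np.median(means)
    mad = _mad(means)
    num = abs(means[si] - med)
    if mad > 0:
        return float(num / mad)
    return 0.0 if num == 0 else math.inf


def _halfway_returned(sub: np.ndarray, si: int, bin_idx: int, c_in: float) -> bool:
    """The sample's coverage at ``bin_idx`` has moved more than halfway
    from the inside coverage ``c_in`` back toward that bin's cohort
    median — the bin behaves like an outside bin."""
    col = sub[:, bin_idx]
    return abs(float(col[si]) - c_in) > 0.5 * abs(float(np.median(col)) - c_in)


def _edges_consistent(sub: np.ndarray, si: int, start: int, end: int) -> bool:
    """Both terminal bins of the interval must themselves look inside:
    tested against the rest of the interval, neither may have returned
    more than halfway toward its cohort median. Intervals overshooting
    a true event by a bin fail this; undershooting ones fail the sharp
    test on the adjacent bin instead."""
    if end - start < 2:
        return True
    c_rest = float(sub[si, start + 1 : end].mean())
    if _halfway_returned(sub, si, start, c_rest):
        return False
    c_rest = float(sub[si, start : end - 1].mean())
    return not _halfway_returned(sub, si, end - 1, c_rest)


def _candidates_for_sample(
    sub: np.ndarray, si: int, z_seed: float, min_bins: int, min_dev: float
) -> set:
    """Grow candidate intervals from seed bins by bin-membership: a
    neighboring bin joins while it has not returned halfway to its
    cohort median, and terminal bins that have returned are trimmed."""
    n_bins = sub.shape[1]
    med = np.median(sub, axis=0)
    mad = np.median(np.abs(sub - med), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zb = np.abs(sub[si] - med) / mad
    zb = np.where(mad > 0, zb, np.where(sub[si] == med, 0.0, np.inf))
    seeds = np.nonzero(zb > z_seed)[0]

    cands: set = set()
    row = sub[si]
    cumrow = np.concatenate([[0.0], np.cumsum(row)])

    def mean_in(s, e):
        return (cumrow[e] - cumrow[s]) / (e - s)

    for seed in seeds:
        start, end = int(seed), int(seed) + 1
        for _ in range(4 * n_bins):
            changed = False
            if start > 0 and not _halfway_returned(sub, si, start - 1, mean_in(start, end)):
                start -= 1
                changed = True
            if end < n_bins and not _halfway_returned(sub, si, end, mean_in(start, end)):
                end += 1
                changed = True
            if end - start >= 2 and _halfway_returned(sub, si, start, mean_in(start + 1, end)):
                start += 1
                changed = True
            if end - start >= 2 and _halfway_returned(sub, si, end - 1, mean_in(start, end - 1)):
                end -= 1
                changed = True
            if not changed:
                break
        cands.add((start, end))
    return cands


def _select_calls(
    sub: np.ndarray,
    si: int,
    cands: Iterable[tuple],
    z_report: float,
    min_bins: int,
    min_dev: float = DEFAULT_MIN_DEV,
) -> list[tuple]:
    """Filter candidates (length, Z, effect size, sharp boundaries) then
    resolve overlaps in favor of the highest-Z (then longest, then
    leftmost)."""
    cum = np.concatenate([np.zeros((sub.shape[0], 1)), np.cumsum(sub, axis=1)], axis=1)
    scored = []
    for start, end in cands:
        if end - start < min_bins:
            continue
        means = _interval_means(cum, start, end)
        if abs(float(means[si]) - float(np.median(means))) < min_dev:
            continue
        z = _z_of(cum, si, start, end)
        if not z > z_report:
            continue
        if not all(_sharp_arr(sub, si, start, end)):
            continue
        if not _edges_consistent(sub, si, start, end):
            continue
        scored.append((z, end - start, -start, (start, end)))
    scored.sort(reverse=True)
    kept: list[tuple] = []
    for _, _, _, (start, end) in scored:
        if all(end <= ks or start >= ke for ks, ke in kept):
            kept.append((start, end))
    kept.sort()
    return kept


def _sharp_arr(sub: np.ndarray, si: int, start: int, end: int) -> tuple[bool, bool]:
    c_in = float(sub[si, start:end].mean())

    def test(adj: int) -> bool:
        col = sub[:, adj]
        return abs(float(col[si]) - c_in) > 0.5 * abs(float(np.median(col)) - c_in)

    left = True if start == 0 else test(start - 1)
    right = True if end == sub.shape[1] else test(end)
    return left, right


def _merge_calls(sub: np.ndarray, si: int, kept: list, merge_gap: int) -> list:
    if not kept:
        return kept
    med = np.median(sub, axis=0)
    merged = [kept[0]]
    for start, end in kept[1:]:
        ps, pe = merged[-1]
        same_dir = (sub[si, start:end].mean() > np.median(_col_means(sub, start, end))) == (
            sub[si, ps:pe].mean() > np.median(_col_means(sub, ps, pe))
        )
        if start - pe <= merge_gap and same_dir:
            merged[-1] = (ps, end)
        else:
            merged.append((start, end))
    return merged


def _col_means(sub: np.ndarray, start: int, end: int) -> np.ndarray:
    return sub[:, start:end].mean(axis=1)


# ---------------------------------------------------------------------------
# small-CNV post-processing
# ---------------------------------------------------------------------------


def _overlaps(a_chrom, a_start, a_end, b_chrom, b_start, b_end) -> bool:
    return a_chrom == b_chrom and a_start < b_end and b_start < a_end


def filter_small_cnvs(
    calls: Sequence[SmallCnv],
    large_calls: Sequence = (),
    masks: Sequence[tuple] = (),
    del_min: int = DEL_MIN_LENGTH,
    dup_min: int = DUP_MIN_LENGTH,
    max_length: int = LARGE_LENGTH,
) -> list[SmallCnv]:
    """Apply the small-CNV retention rules.

    Drops deletions shorter than ``del_min`` bp and duplications shorter
    than ``dup_min`` bp (length thresholds set so that array-validated
    FDR stays under target), anything longer than ``max_length`` (those
    are handled by the large-CNV scan), calls overlapping a large call
    in the same sample, and calls overlapping any mask region.
    """
    out = []
    for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sample)):
        if c.kind == "del" and c.length < del_min:
            continue
        if c.kind == "dup" and c.length < dup_min:
            continue
        if c.length > max_length:
            continue
        if any(
            lc.sample == c.sample and _overlaps(c.chrom, c.start, c.end, lc.chrom, lc.start, lc.end)
            for lc in large_calls
        ):
            continue
        if any(_overlaps(c.chrom, c.start, c.end, m[0], m[1], m[2]) for m in masks):
            continue
        out.append(c)
    return out


def reciprocal_overlap(a: SmallCnv, b: SmallCnv) -> float:
    """Fraction of the longer interval covered by the overlap (0 if on
    different chromosomes). Two calls are 'the same CNV' when this is
    >= 0.5 for both, i.e. overlap >= 0.5 * max(len_a, len_b)."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return ov / max(a.length, b.length)


def overlap_classes(calls: Sequence[SmallCnv], min_ro: float = 0.5) -> list[list[int]]:
    """Partition calls into equivalence classes by transitive closure of
    >= ``min_ro`` reciprocal overlap. Returns lists of indices."""
    n = len(calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: (calls[i].chrom, calls[i].start, calls[i].end))
    for ai in range(n):
        i = order[ai]
        for bi in range(ai + 1, n):
            j = order[bi]
            if calls[j].chrom != calls[i].chrom or calls[j].start >= calls[i].end:
                break
            if calls[i].kind == calls[j].kind and reciprocal_overlap(calls[i], calls[j]) >= min_ro:
                parent[find(i)] = find(j)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def recurrent_cnv_screen(
    hesc_calls: Sequence[SmallCnv],
    euro_control_calls: Sequence[SmallCnv],
    other_control_calls: Sequence[SmallCnv],
    n_other_samples: Optional[int] = None,
    min_hesc_lines: int = 5,
    max_other_fraction: float = 0.10,
    min_ro: float = 0.5,
) -> list[dict]:
    """Screen for CNVs recurrent in stem-cell lines but not in controls.

    A CNV equivalence class (>= 50% reciprocal overlap) is reported when
    it is present in at least ``min_hesc_lines`` stem-cell lines, absent
    from the European control cohort, and carried by fewer than
    ``max_other_fraction`` of the other control samples. Empty control
    cohorts satisfy their criterion vacuously; the output flags this.
    """
    all_calls = list(hesc_calls) + list(euro_control_calls) + list(other_control_calls)
    n_h = len(hesc_calls)
    n_e = len(euro_control_calls)
    if n_other_samples is None:
        n_other_samples = len({c.sample for c in other_control_calls})
    out = []
    for idxs in overlap_classes(all_calls, min_ro):
        h = {all_calls[i].sample for i in idxs if i < n_h}
        e = {all_calls[i].sample for i in idxs if n_h <= i < n_h + n_e}
        o = {all_calls[i].sample for i in idxs if i >= n_h + n_e}
        if len(h) < min_hesc_lines:
            continue
        if e:
            continue
        other_frac = len(o) / n_other_samples if n_other_samples else 0.0
        if n_other_samples and other_frac >= max_other_fraction:
            continue
        members = [all_calls[i] for i in idxs]
        out.append(
            {
                "chrom": members[0].chrom,
                "start": min(c.start for c in members),
                "end": max(c.end for c in members),
                "kind": members[0].kind,
                "hesc_lines": sorted(h),
                "other_fraction": other_frac,
                "vacuous_controls": not euro_control_calls or not other_control_calls,
            }
        )
    return out


def singleton_burden(
    all_calls: Sequence[SmallCnv],
    sibships: Sequence[Sequence[str]] = (),
    min_ro: float = 0.5,
) -> dict:
    """Per-sample count of singleton CNVs in the combined call set.

    A call is a singleton when its >= 50%-reciprocal-overlap equivalence
    class has exactly one member across everything supplied (other
    lines, human cohorts, reference sets). To avoid counting inherited
    variants shared between relatives, only the first member of each
    sibship (sorted) is retained before classing.
    """
    drop = set()
    for sib in sibships:
        keep = sorted(sib)[0]
        drop.update(s for s in sib if s != keep)
    calls = [c for c in all_calls if c.sample not in drop]
    counts: dict = {c.sample: 0 for c in calls}
    for idxs in overlap_classes(calls, min_ro):
        if len(idxs) == 1:
            counts[calls[idxs[0]].sample] += 1
    return counts
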