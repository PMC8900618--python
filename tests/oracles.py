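"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is written as plainly as possible (explicit loops over
every interval / base / record) and shares no code with the package
implementations it checks.
"""

import numpy as np


def exhaustive_large_cnv_scan(
    matrix,
    z_report: float = 5.0,
    min_bins: int = 10,
    min_dev: float = 0.1,
    merge_gap: int = 1,
):
    """Enumerate every contiguous bin interval for every sample and apply
    the large-call acceptance rules directly; resolve overlaps by
    highest Z (then longest, then leftmost) and merge near-adjacent
    survivors. Returns a set of (sample, chrom, start_bin, end_bin,
    kind) tuples in matrix-wide bin coordinates."""
    out = set()
    bins = matrix.bins
    chroms = bins["chrom"].to_numpy()
    boundaries = [0] + [
        i for i in range(1, len(chroms)) if chroms[i] != chroms[i - 1]
    ] + [len(chroms)]
    for ci in range(len(boundaries) - 1):
        lo, hi = boundaries[ci], boundaries[ci + 1]
        sub = matrix.cn[:, lo:hi]
        chrom = chroms[lo]
        n = sub.shape[1]
        for si, sample in enumerate(matrix.samples):
            qualifying = []
            for s in range(n):
                for e in range(s + min_bins, n + 1):
                    means = sub[:, s:e].mean(axis=1)
                    med = float(np.median(means))
                    mad = float(np.median(np.abs(means - med)))
                    dev = abs(float(means[si]) - med)
                    if dev < min_dev:
                        continue
                    if mad > 0:
                        z = dev / mad
                    else:
                        z = 0.0 if dev == 0 else float("inf")
                    if not z > z_report:
                        continue
                    c_in = float(sub[si, s:e].mean())
                    if s > 0:
                        col = sub[:, s - 1]
                        if not abs(float(col[si]) - c_in) > 0.5 * abs(float(np.median(col)) - c_in):
                            continue
                    if e < n:
                        col = sub[:, e]
                        if not abs(float(col[si]) - c_in) > 0.5 * abs(float(np.median(col)) - c_in):
                            continue
                    # terminal bins must not have returned halfway
                    c_rest = float(sub[si, s + 1 : e].mean())
                    col = sub[:, s]
                    if abs(float(col[si]) - c_rest) > 0.5 * abs(float(np.median(col)) - c_rest):
                        continue
                    c_rest = float(sub[si, s : e - 1].mean())
                    col = sub[:, e - 1]
                    if abs(float(col[si]) - c_rest) > 0.5 * abs(float(np.median(col)) - c_rest):
                        continue
                    qualifying.append((z, e - s, -s, (s, e)))
            qualifying.sort(reverse=True)
            kept = []
            for _, _, _, (s, e) in qualifying:
                if all(e <= ks or s >= ke for ks, ke in kept):
                    kept.append((s, e))
            kept.sort()
            merged = []
            for s, e in kept:
                direction = sub[si, s:e].mean() > np.median(sub[:, s:e].mean(axis=1))
                if merged and s - merged[-1][1] <= merge_gap and merged[-1][2] == direction:
                    merged[-1][1] = e
                else:
                    merged.append([s, e, direction])
            for s, e, direction in merged:
                out.add((sample, chrom, lo + s, lo + e, "dup" if direction else "del"))
    return out


def per_base_max_depth(intervals, lo: int, hi: int):
    """Maximum interval-overlap depth and the set of deepest bases over
    [lo, hi), counted one base at a time."""
    depth = np.zeros(hi - lo, dtype=int)
    for _, _, s, e in intervals:
        for b in range(max(s, lo), min(e, hi)):
            depth[b - lo] += 1
    best = int(depth.max())
    bases = {i + lo for i, d in enumerate(depth) if d == best}
    return best, bases


def brute_force_small_cnv_filter(calls, large_calls, del_min=1117, dup_min=2750, max_len=1_000_000):
    """Direct re-statement of the small-CNV retention rules."""
    kept = []
    for c in calls:
        length = c.end - c.start
        if c.kind == "del" and length < del_min:
            continue
        if c.kind == "dup" and length < dup_min:
            continue
        if length > max_len:
            continue
        hit = False
        for lc in large_calls:
            if (
                lc.sample == c.sample
                and lc.chrom == c.chrom
                and c.start < lc.end
                and lc.start < c.end
            ):
                hit = True
        if not hit:
            kept.append(c)
    return kept


def brute_force_gc(seq: str) -> float:
    seq = seq.upper()
    gc = 0
    acgt = 0
    for b in seq:
        if b in "ACGT":
            acgt += 1
            if b in "GC":
                gc += 1
    return gc / acgt
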