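"""Cross-line recurrence analyses.

* Minimal shared region: the maximum-overlap-depth interval of a set of
  duplication calls on one chromosome, found by a boundary sweep — the
  analog of mapping a minimally duplicated region shared by recurrent
  amplicons.
* Breakpoint motif scan: maximal tandem runs of a satellite repeat unit
  (default GGAAT, matching any cyclic rotation or reverse-complement
  rotation) in windows around CNV breakpoints.
* GC profile of intervals against a reference FASTA.
* Burden regression: ordinary least squares of per-line variant-burden
  counts on candidate covariates (passage number, ancestry fractions,
  provider, ...), with per-covariate two-sided p-values.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "minimal_region",
    "motif_variants",
    "motif_scan",
    "gc_profile",
    "burden_regression",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def minimal_region(intervals: Sequence[tuple]) -> dict:
    """Maximum-overlap-depth region of a set of intervals by boundary
    sweep.

    ``intervals`` is a sequence of (line_id, chrom, start, end) on one
    chromosome (0-based half-open). Returns the deepest interval(s) —
    the union of tied segments when several boundaries tie — with its
    depth and the contributing line ids. Disjoint inputs return the
    first deepest single interval with depth 1 and a flag.
    """
    if len(intervals) < 1:
        raise ValueError("need at least one interval")
    chroms = {iv[1] for iv in intervals}
    if len(chroms) > 1:
        raise ValueError("minimal-region query requires a single chromosome")
    chrom = chroms.pop()
    events = []
    for line, _, start, end in intervals:
        if end <= start:
            raise ValueError(f"invalid interval for {line}: [{start}, {end})")
        events.append((start, 1, line))
        events.append((end, -1, line))
    events.sort(key=lambda e: (e[0], -e[1]))

    depth = 0
    best_depth = 0
    segments: list[tuple] = []
    prev_pos = None
    for pos, delta, _ in events:
        if prev_pos is not None and depth > 0 and pos > prev_pos:
            if depth > best_depth:
                best_depth = depth
                segments = [(prev_pos, pos)]
            elif depth == best_depth:
                segments.append((prev_pos, pos))
        depth += delta
        prev_pos = pos

    merged = [list(segments[0])]
    for s, e in segments[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    start, end = merged[0]
    lines = sorted(
        {line for line, _, s, e in intervals if s < end and start < e}
    )
    return {
        "chrom": chrom,
        "start": int(start),
        "end": int(end),
        "depth": int(best_depth),
        "segments": [(int(s), int(e)) for s, e in merged],
        "lines": lines,
        "disjoint": best_depth == 1 and len(intervals) > 1,
    }


def motif_variants(unit: str = "GGAAT", include_revcomp: bool = True) -> list:
    """All cyclic rotations of the repeat unit (and of its reverse
    complement), deduplicated."""
    unit = unit.upper()
    rots = {unit[i:] + unit[:i] for i in range(len(unit))}
    if include_revcomp:
        rc = unit.translate(_COMPLEMENT)[::-1]
        rots |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return sorted(rots)


def motif_scan(
    sequence: str,
    unit: str = "GGAAT",
    min_units: int = 3,
    include_revcomp: bool = True,
) -> list[dict]:
    """Maximal tandem runs of the repeat unit in a sequence window.

    Any cyclic rotation of the unit (or its reverse complement) seeds a
    run; runs of at least ``min_units`` consecutive copies are reported
    with their 0-based start, length in units, and the phase (rotation)
    observed. Overlapping hits from different rotations of the same run
    are merged into the maximal one.
    """
    seq = sequence.upper()
    hits = []
    for var in motif_variants(unit, include_revcomp):
        for m in re.finditer(f"(?:{var}){{{min_units},}}", seq):
            hits.append(
                {
                    "start": m.start(),
                    "end": m.end(),
                    "n_units": (m.end() - m.start()) // len(unit),
                    "phase": var,
                }
            )
    hits.sort(key=lambda h: (h["start"], -h["end"]))
    merged: list[dict] = []
    for h in hits:
        if merged and h["start"] < merged[-1]["end"]:
            if h["end"] > merged[-1]["end"]:  # extend to the maximal run
                if h["n_units"] > merged[-1]["n_units"]:
                    merged[-1] = h
            continue
        merged.append(h)
    return merged


def breakpoint_windows(fasta, calls: Sequence, flank: int = 500) -> list[dict]:
    """Extract +/-``flank`` bp windows around each breakpoint of each
    call from an indexed FASTA (pyfaidx.Fasta or dict of str). Windows
    running off a contig are truncated and flagged."""
    out = []
    for call in calls:
        contig = fasta[call.chrom]
        clen = len(contig)
        for which, bp in (("start", call.start), ("end", call.end)):
            lo, hi = max(0, bp - flank), min(clen, bp + flank)
            seq = str(contig[lo:hi])
            out.append(
                {
                    "chrom": call.chrom,
                    "breakpoint": which,
                    "pos": bp,
                    "window_start": lo,
                    "window_end": hi,
                    "truncated": hi - lo < 2 * flank,
                    "sequence": seq,
                }
            )
    return out


def gc_profile(intervals: Sequence[tuple], fasta) -> pd.DataFrame:
    """GC fraction per interval (chrom, start, end), from an indexed
    FASTA. Intervals containing only N are excluded (NaN row dropped,
    counted in attrs)."""
    rows = []
    n_excluded = 0
    for iv in intervals:
        chrom, start, end = iv[-3], int(iv[-2]), int(iv[-1])
        seq = str(fasta[chrom][start:end]).upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            n_excluded += 1
            continue
        gc = (seq.count("G") + seq.count("C")) / acgt
        rows.append({"chrom": chrom, "start": start, "end": end, "gc": gc})
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"])
    out.attrs["n_excluded"] = n_excluded
    return out


def burden_regression(
    table: pd.DataFrame,
    burden_cols: Sequence[str],
    covariate_cols: Sequence[str],
) -> pd.DataFrame:
    """OLS of each burden class on the covariates.

    Categorical covariates are dummy-coded (first level dropped);
    collinear columns are dropped with a note in attrs. Returns a tidy
    table of coefficient, standard error and two-sided p per (burden
    class, covariate).
    """
    X = pd.get_dummies(
        table[list(covariate_cols)], drop_first=True, dtype=float
    )
    n = len(table)
    if n <= X.shape[1] + 2:
        raise ValueError("need more lines than covariates + 2")
    keep, dropped = [], []
    for col in X.columns:
        trial = keep + [col]
        if np.linalg.matrix_rank(X[trial].to_numpy()) == len(trial):
            keep.append(col)
        else:
            dropped.append(col)
    Xm = np.column_stack([np.ones(n), X[keep].to_numpy()])
    names = ["intercept"] + keep
    df_resid = n - Xm.shape[1]

    rows = []
    xtx_inv = np.linalg.pinv(Xm.T @ Xm)
    for burden in burden_cols:
        y = table[burden].to_numpy(dtype=float)
        beta = xtx_inv @ Xm.T @ y
        resid = y - Xm @ beta
        sigma2 = float(resid @ resid) / df_resid if df_resid > 0 else np.nan
        se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, 0.0)
        pvals = 2 * stats.t.sf(np.abs(tvals), df=df_resid)
        for name, b, s, t, p in zip(names, beta, se, tvals, pvals):
            rows.append(
                {
                    "burden": burden,
                    "covariate": name,
                    "coef": b,
                    "se": s,
                    "t": t,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["dropped_covariates"] = dropped
    return out
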