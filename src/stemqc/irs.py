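"""Intensity rank sum (IRS) validation of CNV calls.

For a CNV call with a known carrier set, array probe intensities inside
the call are ranked across all samples at each probe. A real deletion
pushes carrier intensities toward the bottom ranks (duplications toward
the top); under the null of no intensity shift the carrier ranks are
exchangeable draws without replacement from 1..N at each probe. The
one-sided p-value of the pooled carrier rank sum is computed exactly
(by convolution of the per-probe rank-sum distribution) when feasible,
else by normal approximation.

The cohort false discovery rate is estimated as

    FDR = 2 * fraction(p >= 0.5)

which exploits that false calls yield (approximately) uniform p and
true calls concentrate near 0, so the mass at p >= 0.5 counts half the
false calls. Length-threshold search finds the smallest call length at
which the retained-call FDR meets a target.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "irs_test",
    "assign_probes",
    "irs_table",
    "estimate_fdr",
    "threshold_search",
]

MAX_EXACT_STATES = 2_000_000  # DP table cap for the exact null


def _rank_sum_pmf_one_probe(n_samples: int, k: int) -> np.ndarray:
    """PMF of the sum of k ranks drawn without replacement from 1..N,
    index = sum value (0-based array; support [k(k+1)/2, ...])."""
    # DP over ranks: include rank r or not, track number chosen and sum
    max_sum = sum(range(n_samples - k + 1, n_samples + 1))
    table = np.zeros((k + 1, max_sum + 1))
    table[0, 0] = 1.0
    for r in range(1, n_samples + 1):
        for c in range(min(k, r), 0, -1):
            table[c, r:] += table[c - 1, : max_sum + 1 - r]
    total = math.comb(n_samples, k)
    return table[k] / total


def irs_test(
    intensities: np.ndarray,
    carrier_idx: Sequence[int],
    kind: str,
    exact: Optional[bool] = None,
) -> float:
    """One-sided pooled-rank-sum p for one CNV.

    ``intensities`` is probes x samples (the probes assigned to this
    call); ``carrier_idx`` are column indices of predicted carriers.
    Direction is the low tail for deletions, high tail for
    duplications. All-tied intensities give p = 0.5.
    """
    X = np.asarray(intensities, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    m, n = X.shape
    k = len(carrier_idx)
    if m < 1 or k < 1 or k >= n:
        raise ValueError("need >=1 probe, >=1 carrier and >=1 non-carrier")
    if np.all(X == X.flat[0]):
        return 0.5
    ranks = stats.rankdata(X, axis=1)  # midranks for ties
    obs = ranks[:, list(carrier_idx)].sum()
    if kind == "dup":  # high tail: reflect so the low tail is tested
        obs = m * k * (n + 1) - obs
    elif kind != "del":
        raise ValueError("kind must be 'del' or 'dup'")

    if exact is None:
        exact = (m * k * (k * n)) <= MAX_EXACT_STATES and float(obs).is_integer()
    if exact:
        pmf1 = _rank_sum_pmf_one_probe(n, k)
        pmf = pmf1.copy()
        for _ in range(m - 1):
            pmf = np.convolve(pmf, pmf1)
        return float(pmf[: int(obs) + 1].sum())
    mean = m * k * (n + 1) / 2.0
    var = m * k * (n - k) * (n + 1) / 12.0
    zval = (obs - mean) / math.sqrt(var)
    return float(stats.norm.cdf(zval))


def assign_probes(probes: pd.DataFrame, call) -> np.ndarray:
    """Indices of probes inside a call interval (0-based half-open)."""
    pos = probes["pos"].to_numpy()
    return np.nonzero(
        (probes["chrom"].to_numpy() == call.chrom) & (pos > call.start) & (pos <= call.end)
    )[0]


def irs_table(
    calls: Sequence,
    intensities: pd.DataFrame,
    probes: pd.DataFrame,
    min_probes: int = 2,
) -> pd.DataFrame:
    """Run the IRS test for every call with at least ``min_probes``
    assigned probes. Calls expose chrom/start/end/kind and sample (or
    samples) for the carrier set.

    Returns one row per tested call with p, probe count and length.
    """
    samples = list(intensities.columns)
    sidx = {s: i for i, s in enumerate(samples)}
    X = intensities.to_numpy(dtype=float)
    rows = []
    for i, call in enumerate(calls):
        pr = assign_probes(probes, call)
        if len(pr) < min_probes:
            continue
        carriers = getattr(call, "samples", None) or [call.sample]
        cidx = [sidx[c] for c in carriers]
        p = irs_test(X[pr], cidx, call.kind)
        rows.append(
            {
                "call_index": i,
                "chrom": call.chrom,
                "start": call.start,
                "end": call.end,
                "kind": call.kind,
                "length": call.end - call.start,
                "n_probes": len(pr),
                "n_carriers": len(cidx),
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def estimate_fdr(results: pd.DataFrame, min_calls: int = 20) -> float:
    """Cohort FDR = 2 x fraction of tested calls with p >= 0.5, clipped
    to [0, 1]. Requires at least ``min_calls`` tested calls."""
    if len(results) < min_calls:
        raise ValueError(f"need >= {min_calls} tested calls for a stable FDR estimate")
    frac = float((results["p"] >= 0.5).mean())
    return min(1.0, max(0.0, 2.0 * frac))


def threshold_search(
    results: pd.DataFrame,
    target_fdr: float = 0.03,
    by_type: bool = True,
    min_calls: int = 20,
) -> pd.DataFrame:
    """Smallest length cutoff per CNV type whose retained calls (length
    >= cutoff) achieve FDR <= target.

    Candidate cutoffs are the observed call lengths. When no cutoff
    attains the target the row carries the minimum attained FDR and an
    ``attained`` = False flag.
    """
    groups = results.groupby("kind") if by_type else [("all", results)]
    rows = []
    for kind, grp in groups:
        lengths = np.sort(grp["length"].unique())
        best = None
        min_fdr, min_fdr_len = math.inf, None
        for cut in lengths:
            sub = grp[grp["length"] >= cut]
            if len(sub) < min_calls:
                break
            fdr = min(1.0, 2.0 * float((sub["p"] >= 0.5).mean()))
            if fdr < min_fdr:
                min_fdr, min_fdr_len = fdr, int(cut)
            if fdr <= target_fdr:
                best = (int(cut), fdr)
                break
        if best is not None:
            rows.append(
                {"kind": kind, "length_threshold": best[0], "fdr": best[1], "attained": True}
            )
        else:
            rows.append(
                {
                    "kind": kind,
                    "length_threshold": min_fdr_len,
                    "fdr": None if min_fdr is math.inf else min_fdr,
                    "attained": False,
                }
            )
    return pd.DataFrame(rows)
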