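"""Relatedness and ancestry inference from biallelic genotypes.

Pipeline: sites with minor allele frequency below 1% are excluded, the
remainder are LD-pruned by variance-inflation factor (sliding windows
of 50 sites, step 5, VIF threshold 2), pairwise IBD0/1/2 fractions are
estimated by the method of moments from identity-by-state counts and
allele frequencies, and pairs with pi_hat (= IBD1/2 + IBD2) between
0.35 and 0.70 are classified as directly related (full sibling vs.
parent-child split on the IBD2 fraction). Kinship is reported as
pi_hat / 2. Ancestry fractions are predicted from the first three
principal components of the standardized genotype relationship matrix
via a linear model trained on labeled reference samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairRelatedness",
    "maf_filter",
    "ld_prune",
    "estimate_ibd",
    "classify_relationship",
    "pca_ancestry",
]

DIRECT_LOW = 0.35
DIRECT_HIGH = 0.70
SIB_IBD2_MIN = 0.10
MIN_SHARED_SITES = 1000


@dataclass
class PairRelatedness:
    sample1: str
    sample2: str
    ibd0: float
    ibd1: float
    ibd2: float
    pi_hat: float
    kinship: float
    ibs0: float
    n_sites: int
    relationship: str = ""
    low_confidence: bool = False


def maf_filter(geno: pd.DataFrame, min_maf: float = 0.01) -> pd.DataFrame:
    """Drop sites with minor allele frequency below ``min_maf``.
    ``geno`` is samples x sites with dosages 0/1/2 (NaN = missing)."""
    p = geno.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    return geno.loc[:, maf >= min_maf]


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def ld_prune(
    geno: pd.DataFrame, window: int = 50, step: int = 5, vif: float = 2.0
) -> list:
    """Variance-inflation-factor LD pruning over sliding site windows.

    Within each window of ``window`` consecutive sites (advancing by
    ``step``), the site with the largest VIF — 1/(1-R^2) from regressing
    its dosage on the other retained sites in the window, computed as
    the diagonal of the inverse correlation matrix — is removed
    repeatedly until all VIFs are at or below ``vif``. Constant sites
    have undefined VIF and are removed up front. Returns the retained
    site labels in original order.
    """
    X = geno.to_numpy(dtype=float)
    n_sites = X.shape[1]
    sd = X.std(axis=0)
    retained = sd > 0
    Xs = np.zeros_like(X)
    np.divide(X - X.mean(axis=0), sd, out=Xs, where=sd > 0)

    for w0 in range(0, max(1, n_sites - window + step), step):
        idx = np.nonzero(retained[w0 : w0 + window])[0] + w0
        while len(idx) > 1:
            C = np.corrcoef(Xs[:, idx], rowvar=False)
            # small ridge keeps perfectly correlated pairs invertible
            # (their VIF is then astronomically large and they get cut)
            Cinv = np.linalg.inv(C + 1e-10 * np.eye(len(idx)))
            vifs = np.diag(Cinv)
            worst = int(np.argmax(vifs))
            if vifs[worst] <= vif:
                break
            retained[idx[worst]] = False
            idx = np.delete(idx, worst)
    return [c for c, keep in zip(geno.columns, retained) if keep]


# ---------------------------------------------------------------------------
# IBD / kinship
# ---------------------------------------------------------------------------


def estimate_ibd(
    geno: pd.DataFrame,
    pair: tuple,
    freqs: Optional[np.ndarray] = None,
) -> PairRelatedness:
    """Method-of-moments IBD estimation for one sample pair.

    Uses shared non-missing sites. Expected identity-by-state
    proportions conditional on each IBD state follow from the allele
    frequencies (estimated across all samples in ``geno`` unless given);
    the IBD fractions solve the moment equations sequentially and are
    clipped onto the simplex. pi_hat = IBD1/2 + IBD2; kinship =
    pi_hat/2.
    """
    s1, s2 = pair
    g1 = geno.loc[s1].to_numpy(dtype=float)
    g2 = geno.loc[s2].to_numpy(dtype=float)
    if freqs is None:
        freqs = geno.mean(axis=0).to_numpy() / 2.0
    ok = ~np.isnan(g1) & ~np.isnan(g2) & (freqs > 0) & (freqs < 1)
    g1, g2, p = g1[ok], g2[ok], freqs[ok]
    q = 1 - p
    n = len(p)
    if n == 0:
        raise ValueError("no shared informative sites")

    diff = np.abs(g1 - g2)
    n_ibs0 = int(np.sum(diff == 2))
    n_ibs1 = int(np.sum(diff == 1))
    n_ibs2 = int(np.sum(diff == 0))

    e00 = float(np.sum(2 * p**2 * q**2))
    e10 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e20 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e11 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e21 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))

    ibd0 = n_ibs0 / e00 if e00 > 0 else 0.0
    ibd1 = (n_ibs1 - ibd0 * e10) / e11 if e11 > 0 else 0.0
    ibd2 = (n_ibs2 - ibd0 * e20 - ibd1 * e21) / n

    ibd = np.clip([ibd0, ibd1, ibd2], 0.0, 1.0)
    total = ibd.sum()
    if total > 0:
        ibd = ibd / total
    pi_hat = float(np.clip(ibd[1] / 2 + ibd[2], 0.0, 1.0))
    rel = PairRelatedness(
        sample1=s1,
        sample2=s2,
        ibd0=float(ibd[0]),
        ibd1=float(ibd[1]),
        ibd2=float(ibd[2]),
        pi_hat=pi_hat,
        kinship=pi_hat / 2.0,
        ibs0=n_ibs0 / n,
        n_sites=n,
        low_confidence=n < MIN_SHARED_SITES,
    )
    rel.relationship = classify_relationship(rel)
    return rel


def classify_relationship(rel: PairRelatedness) -> str:
    """Relationship call from pi_hat bands.

    Pairs with pi_hat in [0.35, 0.70] are directly related; IBD2 >= 0.10
    marks full siblings (expected IBD2 = 0.25) as opposed to
    parent-child (expected IBD2 = 0). pi_hat below 0.10 is unrelated;
    anything else (half siblings, duplicates, ...) is "other".
    """
    if DIRECT_LOW <= rel.pi_hat <= DIRECT_HIGH:
        return "full_sibling" if rel.ibd2 >= SIB_IBD2_MIN else "parent_child"
    if rel.pi_hat < 0.10:
        return "unrelated"
    return "other"


def pairwise_relatedness(
    geno: pd.DataFrame, freqs: Optional[np.ndarray] = None
) -> pd.DataFrame:
    """All-pairs IBD table (one row per unordered pair)."""
    rows = []
    samples = list(geno.index)
    if freqs is None:
        freqs = geno.mean(axis=0).to_numpy() / 2.0
    for i, s1 in enumerate(samples):
        for s2 in samples[i + 1 :]:
            r = estimate_ibd(geno, (s1, s2), freqs=freqs)
            rows.append(vars(r).copy())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ancestry
# ---------------------------------------------------------------------------


def genotype_pcs(geno: pd.DataFrame, n_pcs: int = 3) -> pd.DataFrame:
    """Principal components of the standardized-genotype relationship
    matrix (samples x samples); PCs are defined up to sign."""
    X = geno.to_numpy(dtype=float)
    p = np.nanmean(X, axis=0) / 2.0
    ok = (p > 0) & (p < 1)
    X = X[:, ok]
    p = p[ok]
    Xs = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    Xs = np.nan_to_num(Xs)
    grm = Xs @ Xs.T / Xs.shape[1]
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1][:n_pcs]
    pcs = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0))
    return pd.DataFrame(
        pcs, index=geno.index, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )


def pca_ancestry(
    geno: pd.DataFrame,
    reference_fractions: pd.DataFrame,
    n_pcs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ancestry fractions from a joint PCA and a reference-trained
    linear model.

    ``geno`` holds reference and query samples together (samples x
    sites); ``reference_fractions`` (reference samples x ancestry
    components, rows summing to 1) provides the training labels — pure
    labels for population panels, mixed labels allowed. A least-squares
    model maps PC1..PC{n_pcs} to each ancestry component; predictions
    are clipped to [0, 1] and renormalized to sum to 1.

    Returns (fractions for all samples, PCs for all samples).
    """
    if reference_fractions.shape[1] < 3:
        raise ValueError("need at least 3 ancestry components in the reference")
    missing = set(reference_fractions.index) - set(geno.index)
    if missing:
        raise ValueError(f"reference samples absent from genotypes: {sorted(missing)}")
    pcs = genotype_pcs(geno, n_pcs=n_pcs)
    ref_idx = reference_fractions.index
    X_ref = np.column_stack([np.ones(len(ref_idx)), pcs.loc[ref_idx].to_numpy()])
    beta, *_ = np.linalg.lstsq(
        X_ref, reference_fractions.to_numpy(dtype=float), rcond=None
    )
    X_all = np.column_stack([np.ones(len(geno)), pcs.to_numpy()])
    pred = np.clip(X_all @ beta, 0.0, 1.0)
    row_sums = pred.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    pred = pred / row_sums
    fractions = pd.DataFrame(
        pred, index=geno.index, columns=reference_fractions.columns
    )
    return fractions, pcs
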