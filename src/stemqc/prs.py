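"""Polygenic-score computation, PC adjustment, and control normalization.

A polygenic risk score (PRS) is the dosage-weighted sum of effect
alleles over markers whose source-study association p-value is below
0.5. Raw scores are residualized on the first 12 principal components
(ordinary least squares fit on a designated control cohort, to absorb
ancestry-correlated biases in the summary statistics), then z-scored
against the control residual distribution so controls have mean 0 and
SD 1 by construction. A line is an outlier for a trait when |z| >= 2;
lines are ranked as all-purpose controls by the sum of |z| across
traits, ascending.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "compute_raw_prs",
    "adjust_and_normalize",
    "rank_all_purpose",
]

DEFAULT_P_MAX = 0.5
DEFAULT_N_PCS = 12
DEFAULT_OUTLIER_SD = 2.0


def compute_raw_prs(
    dosages: pd.DataFrame, weights: pd.DataFrame, p_max: float = DEFAULT_P_MAX
) -> pd.Series:
    """Raw PRS per sample: sum of dosage x weight over retained markers.

    ``dosages`` is samples x markers (effect-allele dosage 0..2, NaN =
    missing, imputed by the cohort mean at that marker). ``weights``
    needs columns ``marker``, ``weight`` and ``p`` (source-study
    association p-value); only markers with p < ``p_max`` are scored.
    """
    w = weights[weights["p"] < p_max]
    common = [m for m in w["marker"] if m in dosages.columns]
    if not common:
        raise ValueError("no overlap between weight markers and genotyped markers")
    w = w.set_index("marker").loc[common, "weight"]
    X = dosages[common].to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    return pd.Series(X @ w.to_numpy(), index=dosages.index, name="raw_prs")


def adjust_and_normalize(
    raw: pd.Series,
    pcs: pd.DataFrame,
    control_ids: Sequence[str],
    n_pcs: int = DEFAULT_N_PCS,
    outlier_sd: float = DEFAULT_OUTLIER_SD,
) -> pd.DataFrame:
    """PC-residualize raw scores and z-score against the controls.

    OLS of raw score on PC1..PC{n_pcs} is fit on the control samples
    only; residuals for every sample are standardized by the control
    residual mean and SD (n-1 denominator), so control z-scores have
    mean 0 and SD 1 exactly. Collinear PCs are dropped with a warning
    flag in the output attrs.

    Returns a DataFrame indexed by sample with columns ``raw``,
    ``adjusted``, ``z``, ``outlier``.
    """
    controls = [c for c in control_ids if c in raw.index]
    n_use = min(n_pcs, pcs.shape[1])
    if len(controls) < n_use + 13:
        raise ValueError("need at least n_pcs + 13 control samples for a stable fit")
    cols = list(pcs.columns[:n_use])
    Xc = pcs.loc[controls, cols].to_numpy(dtype=float)
    # drop collinear PCs (rank-deficient design)
    keep, dropped = _independent_columns(Xc)
    Xc = Xc[:, keep]
    design_c = np.column_stack([np.ones(len(controls)), Xc])
    beta, *_ = np.linalg.lstsq(design_c, raw.loc[controls].to_numpy(), rcond=None)

    X_all = pcs.loc[raw.index, cols].to_numpy(dtype=float)[:, keep]
    design = np.column_stack([np.ones(len(raw)), X_all])
    resid = raw.to_numpy() - design @ beta

    resid_c = raw.loc[controls].to_numpy() - design_c @ beta
    mu, sd = resid_c.mean(), resid_c.std(ddof=1)
    z = (resid - mu) / sd
    out = pd.DataFrame(
        {
            "raw": raw.to_numpy(),
            "adjusted": resid,
            "z": z,
            "outlier": np.abs(z) >= outlier_sd,
        },
        index=raw.index,
    )
    out.attrs["dropped_pcs"] = [cols[i] for i in dropped]
    return out


def _independent_columns(X: np.ndarray) -> tuple[list, list]:
    keep: list = []
    dropped: list = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
        else:
            dropped.append(j)
    return keep, dropped


def rank_all_purpose(
    profiles: dict, expected_traits: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Rank lines by combined absolute PRS z across traits, ascending.

    ``profiles`` maps trait name -> DataFrame from
    :func:`adjust_and_normalize`. Lines missing any expected trait are
    excluded and flagged. Ties break by sample id. Rank 1 is the line
    closest to the population mean across all traits — the best
    all-purpose control.
    """
    traits = list(expected_traits) if expected_traits is not None else list(profiles)
    z = pd.DataFrame({t: profiles[t]["z"] for t in traits if t in profiles})
    complete = z.dropna()
    combined = complete.abs().sum(axis=1)
    n_outlier = (complete.abs() >= DEFAULT_OUTLIER_SD).sum(axis=1)
    out = pd.DataFrame({"combined_abs_z": combined, "n_outlier_traits": n_outlier})
    # sort by id first so the stable sort on the score breaks ties by id
    out = out.sort_index().sort_values("combined_abs_z", kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    excluded = sorted(set(z.index) - set(complete.index))
    out.attrs["excluded_lines"] = excluded
    return out
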