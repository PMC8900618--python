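"""Per-line aggregation and the rational line-selection scheme.

``build_report`` collapses the outputs of every upstream analysis into
one row per cell line: counts of large fixed and mosaic structural
variants, accepted CN-LOH events, SNV shortlist hits, outlier PRS
traits, ancestry fractions and sibling links. ``select_lines`` applies
a transparent tiered policy: findings map to pass / caution / avoid
per criterion and the overall recommendation is the worst tier, with a
reason attached to every non-pass. Mosaic structural variants rate
caution rather than avoid because such lines can often be rescued by
sub-cloning or by obtaining an earlier passage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["build_report", "select_lines", "DEFAULT_POLICY"]

_TIER_ORDER = {"pass": 0, "caution": 1, "avoid": 2}

#: criterion name -> (report column, predicate threshold, tier when hit)
DEFAULT_POLICY = {
    "aneuploidy": {"tier": "avoid"},
    "large_fixed_sv": {"tier": "avoid"},
    "large_mosaic_sv": {"tier": "caution"},
    "cnloh": {"tier": "caution"},
    "cancer_snv": {"tier": "avoid"},
    "disease_snv": {"tier": "avoid"},
    "fertility_snv": {"tier": "caution"},
    "prs_outliers": {"tier": "caution", "max_outlier_traits": 3},
}

_KNOWN_CRITERIA = set(DEFAULT_POLICY)


def build_report(
    line_ids: Sequence[str],
    large_calls: Optional[Sequence] = None,
    cnloh_segments: Optional[Sequence] = None,
    snv_burden: Optional[pd.DataFrame] = None,
    prs_ranking: Optional[pd.DataFrame] = None,
    ancestry: Optional[pd.DataFrame] = None,
    relatedness: Optional[pd.DataFrame] = None,
    aneuploid_threshold_bins: int = 200,
) -> pd.DataFrame:
    """Aggregate module outputs into one row per line.

    Any omitted module leaves its columns as NA (never silently zero).
    Inputs whose line ids are not in ``line_ids`` raise, listing the
    orphans. Large calls spanning at least ``aneuploid_threshold_bins``
    bins count as aneuploidy (whole-chromosome-scale events).
    """
    line_ids = list(line_ids)
    idx = pd.Index(line_ids, name="line")
    rep = pd.DataFrame(index=idx)

    def check_ids(ids, what):
        orphans = sorted(set(ids) - set(line_ids))
        if orphans:
            raise ValueError(f"{what} contains unknown line ids: {orphans}")

    for col in (
        "n_large_fixed_sv",
        "n_large_mosaic_sv",
        "n_aneuploid",
        "n_cnloh",
        "n_cancer_snv",
        "n_fertility_snv",
        "n_disease_snv",
        "n_outlier_prs_traits",
    ):
        rep[col] = pd.array([pd.NA] * len(idx), dtype="Int64")

    if large_calls is not None:
        check_ids([c.sample for c in large_calls], "large_calls")
        rep["n_large_fixed_sv"] = 0
        rep["n_large_mosaic_sv"] = 0
        rep["n_aneuploid"] = 0
        for c in large_calls:
            if c.n_bins >= aneuploid_threshold_bins:
                rep.loc[c.sample, "n_aneuploid"] += 1
            elif c.status == "mosaic":
                rep.loc[c.sample, "n_large_mosaic_sv"] += 1
            else:
                rep.loc[c.sample, "n_large_fixed_sv"] += 1

    if cnloh_segments is not None:
        check_ids([s.sample for s in cnloh_segments], "cnloh_segments")
        rep["n_cnloh"] = 0
        for s in cnloh_segments:
            rep.loc[s.sample, "n_cnloh"] += 1

    if snv_burden is not None:
        check_ids(snv_burden.index, "snv_burden")
        for src, dst in (
            ("cancer", "n_cancer_snv"),
            ("fertility", "n_fertility_snv"),
            ("disease", "n_disease_snv"),
        ):
            rep[dst] = snv_burden[src].reindex(idx).fillna(0).astype("Int64")

    if prs_ranking is not None:
        check_ids(prs_ranking.index, "prs_ranking")
        rep["n_outlier_prs_traits"] = (
            prs_ranking["n_outlier_traits"].reindex(idx).astype("Int64")
        )
        rep["prs_rank"] = prs_ranking["rank"].reindex(idx).astype("Int64")

    if ancestry is not None:
        present = [s for s in ancestry.index if s in line_ids]
        check_ids(present, "ancestry")
        for col in ancestry.columns:
            rep[f"ancestry_{col}"] = ancestry[col].reindex(idx)

    if relatedness is not None:
        sibs = {line: [] for line in line_ids}
        direct = relatedness[
            relatedness["relationship"].isin(["full_sibling", "parent_child"])
        ]
        check_ids(
            list(direct["sample1"]) + list(direct["sample2"]), "relatedness"
        )
        for _, row in direct.iterrows():
            sibs[row["sample1"]].append(row["sample2"])
            sibs[row["sample2"]].append(row["sample1"])
        rep["siblings"] = [",".join(sorted(sibs[line])) for line in line_ids]

    return rep


@dataclass
class SelectionVerdict:
    line: str
    tiers: dict
    overall: str
    reasons: list = field(default_factory=list)


def select_lines(report: pd.DataFrame, policy: Optional[dict] = None) -> list[SelectionVerdict]:
    """Apply the tiered selection policy to a line report.

    Per criterion a line is ``pass`` unless the corresponding finding is
    present (count > 0, or above the configured threshold for PRS
    outliers); findings set the criterion tier from the policy and the
    overall recommendation is the worst tier. Findings whose report
    column is NA (module not run) yield tier "unknown" and a reason but
    never improve the verdict. Unknown criterion names in the policy
    raise.
    """
    policy = dict(DEFAULT_POLICY if policy is None else policy)
    unknown = set(policy) - _KNOWN_CRITERIA
    if unknown:
        raise ValueError(f"unknown selection criteria: {sorted(unknown)}")

    col_for = {
        "aneuploidy": "n_aneuploid",
        "large_fixed_sv": "n_large_fixed_sv",
        "large_mosaic_sv": "n_large_mosaic_sv",
        "cnloh": "n_cnloh",
        "cancer_snv": "n_cancer_snv",
        "disease_snv": "n_disease_snv",
        "fertility_snv": "n_fertility_snv",
        "prs_outliers": "n_outlier_prs_traits",
    }
    verdicts = []
    for line, row in report.iterrows():
        tiers, reasons = {}, []
        for crit, cfg in policy.items():
            val = row.get(col_for[crit], pd.NA)
            if pd.isna(val):
                tiers[crit] = "unknown"
                reasons.append(f"{crit}: not assessed")
                continue
            threshold = cfg.get("max_outlier_traits", 0)
            if val > threshold:
                tiers[crit] = cfg["tier"]
                reasons.append(f"{crit}: {val} (tier {cfg['tier']})")
            else:
                tiers[crit] = "pass"
        known = [t for t in tiers.values() if t in _TIER_ORDER]
        overall = max(known, key=_TIER_ORDER.get) if known else "unknown"
        verdicts.append(SelectionVerdict(line=line, tiers=tiers, overall=overall, reasons=reasons))
    return verdicts
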