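"""Multi-stage SNV prioritization cascade.

Stages, applied in order to an annotated variant table (one row per
split biallelic record):

1. HC-HQ (high confidence, high quality): FILTER is PASS, at least one
   sample genotype has DP >= 10, GQ >= 20 and within-sample alternate
   allele fraction >= 0.2, the site is outside low-complexity regions
   and segmental duplications, and the population-database filter
   status is PASS or missing.
2. Consequence binning on the canonical transcript: LoF (frameshift,
   splice acceptor/donor, stop gained), missense (incl. in-frame
   indels, start/stop loss, protein-altering), synonymous, other.
3. Deleterious: LoF or missense, reference-population allele frequency
   < 0.1%, CADD phred > 20 and DANN > 0.99.
4. Cancer-associated: gene has documented COSMIC Tier 1 cancer
   relevance, the exact variant is in COSMIC at least twice, and
   FATHMM-cancer predicts it cancer-causing.
5. Fertility-associated: literature fertility gene, LOEUF <= 0.33, and
   autosomal-dominant inheritance in the Clinical Genomic Database.
6. Disease-associated (autosomes only): LOEUF < 0.33, CGD autosomal
   dominant, FATHMM-XF > 0.75, DANN > 0.999 and allele frequency
   < 1e-5.

Missing annotations fail their filter (conservative shortlists). Edge
semantics follow the thresholds as printed: note LOEUF is inclusive
(<= 0.33) for the fertility shortlist but strict (< 0.33) for the
disease shortlist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CascadeThresholds",
    "hc_hq_filter",
    "bin_consequence",
    "deleterious_filter",
    "cancer_filter",
    "fertility_filter",
    "disease_filter",
    "run_cascade",
    "burden_summary",
]

LOF_CONSEQUENCES = frozenset(
    ["frameshift_variant", "splice_acceptor_variant", "splice_donor_variant", "stop_gained"]
)
MISSENSE_CONSEQUENCES = frozenset(
    [
        "inframe_deletion",
        "inframe_insertion",
        "missense_variant",
        "start_lost",
        "stop_lost",
        "protein_altering_variant",
    ]
)
SYNONYMOUS_CONSEQUENCES = frozenset(
    ["synonymous_variant", "stop_retained_variant", "incomplete_terminal_codon_variant"]
)

SEX_CHROMS = frozenset(["chrX", "chrY", "X", "Y"])


@dataclass
class CascadeThresholds:
    """Tunable cutoffs for every cascade stage (defaults as printed in
    the filter definitions)."""

    min_dp: int = 10
    min_gq: int = 20
    min_allele_fraction: float = 0.2
    max_af_deleterious: float = 0.001
    min_cadd: float = 20.0
    min_dann: float = 0.99
    min_cosmic_count: int = 2
    max_loeuf_fertility: float = 0.33  # inclusive
    max_loeuf_disease: float = 0.33  # strict
    min_fathmm_xf: float = 0.75
    min_dann_disease: float = 0.999
    max_af_disease: float = 1e-5
    disease_autosomal_only: bool = True


def _num(df: pd.DataFrame, col: str) -> pd.Series:
    """Numeric column with missing values as NaN (which fail any
    threshold comparison)."""
    if col not in df:
        return pd.Series(np.nan, index=df.index)
    return pd.to_numeric(df[col], errors="coerce")


def _flag(df: pd.DataFrame, col: str) -> pd.Series:
    if col not in df:
        return pd.Series(False, index=df.index)
    return df[col].fillna(False).astype(bool)


def hc_hq_filter(records: pd.DataFrame, thr: Optional[CascadeThresholds] = None) -> pd.Series:
    """Boolean mask of records surviving the HC-HQ stage."""
    thr = thr or CascadeThresholds()
    ok = (
        (records["filter"] == "PASS")
        & (_num(records, "dp") >= thr.min_dp)
        & (_num(records, "gq") >= thr.min_gq)
        & (_num(records, "allele_fraction") >= thr.min_allele_fraction)
        & ~_flag(records, "low_complexity")
        & ~_flag(records, "segdup")
        & _flag(records, "gnomad_pass_or_missing")
    )
    return ok.fillna(False)


def bin_consequence(consequence) -> str:
    """Bin a canonical-transcript consequence string."""
    if consequence in LOF_CONSEQUENCES:
        return "lof"
    if consequence in MISSENSE_CONSEQUENCES:
        return "missense"
    if consequence in SYNONYMOUS_CONSEQUENCES:
        return "synonymous"
    return "other"


def deleterious_filter(records: pd.DataFrame, thr: Optional[CascadeThresholds] = None) -> pd.Series:
    thr = thr or CascadeThresholds()
    bins = records["consequence"].map(bin_consequence)
    return (
        bins.isin(["lof", "missense"])
        & (_num(records, "exac_af") < thr.max_af_deleterious)
        & (_num(records, "cadd_phred") > thr.min_cadd)
        & (_num(records, "dann") > thr.min_dann)
    ).fillna(False)


def cancer_filter(records: pd.DataFrame, thr: Optional[CascadeThresholds] = None) -> pd.Series:
    thr = thr or CascadeThresholds()
    return (
        _flag(records, "cosmic_tier1")
        & (_num(records, "cosmic_count") >= thr.min_cosmic_count)
        & _flag(records, "fathmm_cancer")
    ).fillna(False)


def fertility_filter(records: pd.DataFrame, thr: Optional[CascadeThresholds] = None) -> pd.Series:
    thr = thr or CascadeThresholds()
    return (
        _flag(records, "fertility_gene")
        & (_num(records, "loeuf") <= thr.max_loeuf_fertility)
        & (records.get("cgd_inheritance") == "AD")
    ).fillna(False)


def disease_filter(records: pd.DataFrame, thr: Optional[CascadeThresholds] = None) -> pd.Series:
    thr = thr or CascadeThresholds()
    mask = (
        (_num(records, "loeuf") < thr.max_loeuf_disease)
        & (records.get("cgd_inheritance") == "AD")
        & (_num(records, "fathmm_xf") > thr.min_fathmm_xf)
        & (_num(records, "dann") > thr.min_dann_disease)
        & (_num(records, "exac_af") < thr.max_af_disease)
    )
    if thr.disease_autosomal_only:
        mask &= ~records["chrom"].isin(SEX_CHROMS)
    return mask.fillna(False)


def run_cascade(
    records: pd.DataFrame, thr: Optional[CascadeThresholds] = None
) -> pd.DataFrame:
    """Run every stage; shortlist membership requires all upstream
    stages passed (monotone cascade).

    Returns the input with added columns ``pass_hc_hq``, ``bin``,
    ``pass_deleterious``, ``pass_cancer``, ``pass_fertility``,
    ``pass_disease`` and ``stage_reached``.
    """
    thr = thr or CascadeThresholds()
    out = records.copy()
    hc = hc_hq_filter(out, thr)
    out["pass_hc_hq"] = hc
    out["bin"] = out["consequence"].map(bin_consequence)
    delet = hc & deleterious_filter(out, thr)
    out["pass_deleterious"] = delet
    out["pass_cancer"] = delet & cancer_filter(out, thr)
    out["pass_fertility"] = delet & fertility_filter(out, thr)
    out["pass_disease"] = delet & disease_filter(out, thr)
    stage = np.select(
        [
            out["pass_cancer"] | out["pass_fertility"] | out["pass_disease"],
            delet,
            hc,
        ],
        ["shortlist", "deleterious", "hc_hq"],
        default="removed",
    )
    out["stage_reached"] = stage
    return out


def burden_summary(cascade: pd.DataFrame, sample_col: str = "sample") -> pd.DataFrame:
    """Per-sample counts by consequence bin (among HC-HQ survivors) and
    by shortlist, plus cohort mean/SD rows in ``attrs``."""
    cols = ["lof", "missense", "synonymous", "deleterious", "cancer", "fertility", "disease"]
    if len(cascade) == 0:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="sample"), dtype=int)
    samples = sorted(cascade[sample_col].unique())
    rows = []
    for s in samples:
        sub = cascade[cascade[sample_col] == s]
        hq = sub[sub["pass_hc_hq"]]
        rows.append(
            {
                "sample": s,
                "lof": int((hq["bin"] == "lof").sum()),
                "missense": int((hq["bin"] == "missense").sum()),
                "synonymous": int((hq["bin"] == "synonymous").sum()),
                "deleterious": int(sub["pass_deleterious"].sum()),
                "cancer": int(sub["pass_cancer"].sum()),
                "fertility": int(sub["pass_fertility"].sum()),
                "disease": int(sub["pass_disease"].sum()),
            }
        )
    out = pd.DataFrame(rows).set_index("sample")
    out.attrs["cohort_mean"] = out.mean().to_dict()
    out.attrs["cohort_sd"] = out.std(ddof=1).to_dict()
    return out
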