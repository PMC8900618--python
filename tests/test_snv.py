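"""SNV cascade filters: stage rules, monotonicity, truth agreement."""

import numpy as np
import pandas as pd
import pytest

from stemqc.sim import SimConfig, gen_variant_table
from stemqc.snv import (
    bin_consequence,
    burden_summary,
    cancer_filter,
    deleterious_filter,
    disease_filter,
    fertility_filter,
    hc_hq_filter,
    run_cascade,
)


def record(**kw):
    base = dict(
        chrom="chr5",
        pos=1000,
        ref="A",
        alt="T",
        gene="GENE1",
        sample="S000",
        filter="PASS",
        dp=30,
        gq=60,
        allele_fraction=0.45,
        low_complexity=False,
        segdup=False,
        gnomad_pass_or_missing=True,
        consequence="missense_variant",
        exac_af=1e-4,
        cadd_phred=25.0,
        dann=0.995,
        fathmm_xf=0.5,
        fathmm_cancer=False,
        cosmic_count=0,
        cosmic_tier1=False,
        loeuf=1.0,
        cgd_inheritance="none",
        fertility_gene=False,
    )
    base.update(kw)
    return base


class TestHcHq:
    def test_low_depth_removed(self):
        df = pd.DataFrame([record(dp=9)])
        assert not hc_hq_filter(df).iloc[0]

    def test_clean_record_with_missing_gnomad_retained(self):
        df = pd.DataFrame([record(dp=30, gq=40, allele_fraction=0.45)])
        assert hc_hq_filter(df).iloc[0]

    def test_engineered_failures(self):
        rows = [record() for _ in range(14)]
        rows += [
            record(filter="VQSR"),
            record(dp=5),
            record(gq=10),
            record(allele_fraction=0.1),
            record(low_complexity=True),
            record(gnomad_pass_or_missing=False),
        ]
        df = pd.DataFrame(rows)
        assert int(hc_hq_filter(df).sum()) == 14


class TestConsequenceBins:
    @pytest.mark.parametrize(
        "csq,expected",
        [
            ("stop_gained", "lof"),
            ("frameshift_variant", "lof"),
            ("inframe_deletion", "missense"),
            ("missense_variant", "missense"),
            ("synonymous_variant", "synonymous"),
            ("intron_variant", "other"),
            ("", "other"),
        ],
    )
    def test_membership(self, csq, expected):
        assert bin_consequence(csq) == expected


class TestDeleterious:
    def test_qualifying_record_kept(self):
        df = pd.DataFrame([record(exac_af=5e-4, cadd_phred=25, dann=0.995)])
        assert deleterious_filter(df).iloc[0]

    @pytest.mark.parametrize(
        "kw",
        [
            {"exac_af": 0.002},
            {"cadd_phred": 20.0},  # strict inequality
            {"dann": 0.99},  # strict inequality
            {"consequence": "synonymous_variant"},
            {"exac_af": np.nan},  # missing annotation fails
        ],
    )
    def test_disqualifiers(self, kw):
        assert not deleterious_filter(pd.DataFrame([record(**kw)])).iloc[0]

    def test_engineered_pass_count(self):
        rng = np.random.default_rng(0)
        rows = []
        n_pass = 0
        for i in range(50):
            if i < 12:
                rows.append(record(exac_af=1e-5, cadd_phred=30, dann=0.999))
                n_pass += 1
            else:
                bad = rng.choice(["af", "cadd", "dann"])
                kw = {"af": {"exac_af": 0.01}, "cadd": {"cadd_phred": 5.0}, "dann": {"dann": 0.5}}[bad]
                rows.append(record(**kw))
        assert int(deleterious_filter(pd.DataFrame(rows)).sum()) == 12


class TestCancerFertilityDisease:
    def test_cancer_rules(self):
        yes = record(cosmic_tier1=True, cosmic_count=3, fathmm_cancer=True)
        low_count = record(cosmic_tier1=True, cosmic_count=1, fathmm_cancer=True)
        no_tier = record(cosmic_tier1=False, cosmic_count=10, fathmm_cancer=True)
        df = pd.DataFrame([yes, low_count, no_tier])
        assert list(cancer_filter(df)) == [True, False, False]

    def test_fertility_rules(self):
        yes = record(fertility_gene=True, loeuf=0.2, cgd_inheritance="AD")
        edge = record(fertility_gene=True, loeuf=0.33, cgd_inheritance="AD")  # inclusive
        high_loeuf = record(fertility_gene=True, loeuf=0.4, cgd_inheritance="AD")
        recessive = record(fertility_gene=True, loeuf=0.2, cgd_inheritance="AR")
        df = pd.DataFrame([yes, edge, high_loeuf, recessive])
        assert list(fertility_filter(df)) == [True, True, False, False]

    def test_disease_rules(self):
        good = record(
            loeuf=0.2, cgd_inheritance="AD", fathmm_xf=0.9, dann=0.9995, exac_af=1e-6
        )
        weak_fathmm = record(
            loeuf=0.2, cgd_inheritance="AD", fathmm_xf=0.7, dann=0.9991, exac_af=1e-6
        )
        loeuf_edge = record(  # strict: 0.33 itself fails the disease stage
            loeuf=0.33, cgd_inheritance="AD", fathmm_xf=0.9, dann=0.9995, exac_af=1e-6
        )
        x_linked = record(
            chrom="chrX", loeuf=0.2, cgd_inheritance="AD", fathmm_xf=0.9,
            dann=0.9995, exac_af=1e-6,
        )
        df = pd.DataFrame([good, weak_fathmm, loeuf_edge, x_linked])
        assert list(disease_filter(df)) == [True, False, False, False]

    def test_sequential_survivor_counts_non_increasing(self):
        vt = gen_variant_table(SimConfig(seed=20, n_variants=3000))
        df = run_cascade(vt)
        counts = [
            len(df),
            int(df["pass_hc_hq"].sum()),
            int(df["pass_deleterious"].sum()),
            int((df["pass_cancer"] | df["pass_fertility"] | df["pass_disease"]).sum()),
        ]
        assert counts == sorted(counts, reverse=True)


class TestCascadeProperties:
    def test_monotone_stage_containment(self):
        df = run_cascade(gen_variant_table(SimConfig(seed=21, n_variants=2000)))
        assert not (df["pass_deleterious"] & ~df["pass_hc_hq"]).any()
        for short in ("pass_cancer", "pass_fertility", "pass_disease"):
            assert not (df[short] & ~df["pass_deleterious"]).any()

    def test_idempotence(self):
        vt = gen_variant_table(SimConfig(seed=22, n_variants=1000))
        once = run_cascade(vt)
        survivors = vt[once["pass_hc_hq"]].reset_index(drop=True)
        again = hc_hq_filter(survivors)
        assert again.all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_agreement_with_independent_truth(self, seed):
        vt = gen_variant_table(SimConfig(seed=seed, n_variants=3000))
        df = run_cascade(vt)
        pairs = [
            ("pass_hc_hq", "truth_hc_hq"),
            ("pass_deleterious", "truth_deleterious"),
            ("pass_cancer", "truth_cancer"),
            ("pass_fertility", "truth_fertility"),
            ("pass_disease", "truth_disease"),
        ]
        for got, want in pairs:
            assert (df[got] == vt[want]).all(), got


class TestBurden:
    def test_empty_set_all_zero(self):
        vt = gen_variant_table(SimConfig(seed=23, n_variants=50))
        df = run_cascade(vt.iloc[0:0])
        out = burden_summary(df)
        assert out.empty

    def test_counts_equal_truth_tallies(self):
        vt = gen_variant_table(SimConfig(seed=24, n_variants=3000))
        df = run_cascade(vt)
        out = burden_summary(df)
        for s in out.index:
            sub = vt[vt["sample"] == s]
            assert out.loc[s, "deleterious"] == int(sub["truth_deleterious"].sum())
            assert out.loc[s, "cancer"] == int(sub["truth_cancer"].sum())

    def test_shared_lof_mean_burden(self):
        rows = [
            record(sample=f"S{i:03d}", consequence="stop_gained") for i in range(10)
        ]
        df = run_cascade(pd.DataFrame(rows))
        out = burden_summary(df)
        assert out["lof"].mean() == 1.0
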