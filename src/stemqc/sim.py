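"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be emulated here from a seeded
:class:`SimConfig`: binned normalized coverage with implanted fixed or
mosaic copy-number events, phased heterozygous allele depths with
imbalance segments, pedigree genotypes by gene drop, annotated variant
tables with pre-computed filter-cascade truth, and array probe
intensities with carrier shifts.

Design notes
------------
* Read counts per 100-kbp bin are Poisson by default (negative binomial
  optionally, for over-dispersion), at an expected count of
  ``mean_depth * bin_size / read_length`` scaled by true copy number / 2.
  Normalization divides by the sample mean and then by the across-sample
  per-bin median, matching how normalized depth-of-coverage inputs are
  produced upstream of the CNV scan.
* Mixture expectations: a cell fraction ``f`` event of integer copy
  number ``c`` has expected normalized CN ``2 + f*(c - 2)``; phased BAF
  on the affected haplotype is ``(1+f)/2`` for CN-LOH,
  ``(1+f*(c-2)) / (2+f*(c-2))`` for gains and ``1/(2-f)`` for
  single-copy losses.
* Determinism: each generator derives its own random stream from
  ``(cfg.seed, stream_id)``, so outputs are reproducible regardless of
  the order generators are called in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CoverageMatrix

__all__ = [
    "TruthEvent",
    "SimConfig",
    "gen_coverage",
    "gen_phased_counts",
    "gen_pedigree_genotypes",
    "gen_variant_table",
    "gen_array_intensities",
]

# distinct sub-stream ids so generators are order-independent
_STREAM_COVERAGE = 1
_STREAM_BAF = 2
_STREAM_PEDIGREE = 3
_STREAM_VARIANTS = 4
_STREAM_ARRAY = 5


@dataclass
class TruthEvent:
    """Latent truth for one implanted copy-number / CN-LOH event.

    ``start_bin``/``end_bin`` are 0-based half-open bin indices into the
    simulated genome. ``cell_fraction`` is the fraction of cells carrying
    the event (1.0 = fixed).
    """

    sample: str
    chrom: str
    start_bin: int
    end_bin: int
    integer_cn: int
    cell_fraction: float
    kind: str  # "dup" | "del" | "cnloh"

    def __post_init__(self) -> None:
        if not 0 < self.cell_fraction <= 1:
            raise ValueError("cell_fraction must be in (0, 1]")
        if self.kind == "cnloh" and self.integer_cn != 2:
            raise ValueError("cnloh events are copy-neutral (integer_cn=2)")
        if self.kind == "del" and self.integer_cn >= 2:
            raise ValueError("del events require integer_cn < 2")
        if self.kind == "dup" and self.integer_cn <= 2:
            raise ValueError("dup events require integer_cn > 2")

    @property
    def expected_cn(self) -> float:
        return 2.0 + self.cell_fraction * (self.integer_cn - 2)


@dataclass
class SimConfig:
    """Configuration for all synthetic generators. Same config (including
    seed) always yields identical outputs."""

    seed: int = 0
    n_samples: int = 20
    n_bins: int = 1000
    bin_size: int = 100_000
    mean_depth: float = 30.0
    read_length: int = 150
    noise_model: str = "poisson"  # "poisson" | "negbinom"
    dispersion: float = 0.01  # NB: var = mu + dispersion * mu^2
    events: list = field(default_factory=list)
    chrom: str = "chr1"
    # het-site / genotype generation
    n_het_sites: int = 2000
    n_snps: int = 10_000
    maf_floor: float = 0.01
    pedigree: list = field(default_factory=list)  # (child, parent1, parent2)
    ld_block_size: int = 1  # >1 tiles perfect-LD blocks for pruning tests
    # variant table
    n_variants: int = 2000
    # array intensities
    probes_per_bin: float = 0.5
    array_effect_sd: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.maf_floor <= 0.5:
            raise ValueError("maf_floor must be a frequency in [0, 0.5]")

    def sample_ids(self) -> list:
        return [f"S{i:03d}" for i in range(self.n_samples)]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.noise_model == "poisson":
        return rng.poisson(mu).astype(float)
    if cfg.noise_model == "negbinom":
        # var = mu + dispersion * mu^2 ; gamma-Poisson mixture
        shape = 1.0 / cfg.dispersion
        lam = rng.gamma(shape, mu / shape)
        return rng.poisson(lam).astype(float)
    raise ValueError(f"unknown noise model {cfg.noise_model!r}")


def normalize_counts(counts: np.ndarray) -> np.ndarray:
    """Normalize raw per-bin read counts to the copy-number scale.

    Each sample is divided by its median bin count (robust to event
    bins), each bin by its across-sample median, and the result scaled
    so the diploid baseline sits at 2. Scaling any sample's raw counts
    by a constant leaves its normalized values unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    per_sample = counts / np.median(counts, axis=1, keepdims=True)
    bin_median = np.median(per_sample, axis=0)
    bin_median = np.where(bin_median <= 0, np.nan, bin_median)
    cn = 2.0 * per_sample / bin_median
    return np.nan_to_num(cn, nan=0.0)


def gen_coverage(cfg: SimConfig) -> tuple[CoverageMatrix, list]:
    """Simulate a binned normalized-coverage matrix with implanted events.

    Returns the :class:`CoverageMatrix` (samples x bins, copy-number
    scale) and the list of implanted :class:`TruthEvent`. At least 5
    samples are required so that across-sample medians and MADs are
    meaningful downstream.
    """
    if cfg.n_samples < 5:
        raise ValueError("need at least 5 samples for cohort-relative CNV calling")
    rng = cfg._rng(_STREAM_COVERAGE)
    samples = cfg.sample_ids()
    sample_pos = {s: i for i, s in enumerate(samples)}

    true_cn = np.full((cfg.n_samples, cfg.n_bins), 2.0)
    for ev in cfg.events:
        if not isinstance(ev, TruthEvent):
            raise TypeError("events must be TruthEvent instances")
        if ev.sample not in sample_pos:
            raise ValueError(f"event sample {ev.sample!r} not in cohort")
        if not (0 <= ev.start_bin < ev.end_bin <= cfg.n_bins):
            raise ValueError("event bin range outside genome")
        if ev.kind != "cnloh":  # CN-LOH leaves depth untouched
            true_cn[sample_pos[ev.sample], ev.start_bin:ev.end_bin] = ev.expected_cn

    base = cfg.mean_depth * cfg.bin_size / cfg.read_length  # expected reads/bin
    mu = base * true_cn / 2.0
    counts = _draw_counts(rng, mu, cfg)
    cn = normalize_counts(counts)

    starts = np.arange(cfg.n_bins, dtype=np.int64) * cfg.bin_size
    bins = pd.DataFrame(
        {"chrom": cfg.chrom, "start": starts, "end": starts + cfg.bin_size}
    )
    return CoverageMatrix(bins=bins, samples=samples, cn=cn), list(cfg.events)


# ---------------------------------------------------------------------------
# phased allele counts
# ---------------------------------------------------------------------------


def expected_baf(kind: str, integer_cn: int, f: float) -> float:
    """Expected phased B-allele frequency on the affected haplotype."""
    if kind == "cnloh":
        return (1 + f) / 2.0
    if kind == "dup":
        extra = f * (integer_cn - 2)
        return (1 + extra) / (2 + extra)
    if kind == "del":
        if integer_cn != 1:
            raise ValueError("only single-copy losses have a defined phased BAF")
        return 1.0 / (2.0 - f)
    raise ValueError(f"unknown event kind {kind!r}")


def gen_phased_counts(
    cfg: SimConfig, events: Optional[Sequence[TruthEvent]] = None
) -> pd.DataFrame:
    """Simulate phased REF/ALT depths at heterozygous sites.

    Sites are placed uniformly over the genome; per-site total depth is
    drawn from the noise model at ``mean_depth`` scaled by local copy
    number, and hap1 depth is binomial at the event-dependent expected
    BAF (0.5 outside events).

    Returns a DataFrame with columns ``chrom, pos, sample, hap1_depth,
    hap2_depth, phase_set``; positions are 1-based.
    """
    if events is None:
        events = cfg.events
    rng = cfg._rng(_STREAM_BAF)
    genome_len = cfg.n_bins * cfg.bin_size
    pos = np.sort(rng.choice(genome_len, size=cfg.n_het_sites, replace=False)) + 1

    frames = []
    for sample in cfg.sample_ids():
        p = np.full(cfg.n_het_sites, 0.5)
        cn = np.full(cfg.n_het_sites, 2.0)
        for ev in events:
            if ev.sample != sample:
                continue
            lo = ev.start_bin * cfg.bin_size
            hi = ev.end_bin * cfg.bin_size
            inside = (pos > lo) & (pos <= hi)
            p[inside] = expected_baf(ev.kind, ev.integer_cn, ev.cell_fraction)
            cn[inside] = ev.expected_cn
        depth = _draw_counts(rng, cfg.mean_depth * cn / 2.0, cfg).astype(int)
        depth = np.maximum(depth, 1)
        hap1 = rng.binomial(depth, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": cfg.chrom,
                    "pos": pos,
                    "sample": sample,
                    "hap1_depth": hap1,
                    "hap2_depth": depth - hap1,
                    "phase_set": 1,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# pedigree genotypes
# ---------------------------------------------------------------------------


def _pedigree_order(pedigree: Sequence[tuple]) -> list:
    """Topological order of pedigree members; raises on cycles."""
    parents = {c: (p1, p2) for c, p1, p2 in pedigree}
    order: list = []
    state: dict = {}  # 0=visiting, 1=done

    def visit(node, stack):
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            raise ValueError(f"pedigree cycle involving {node!r}")
        state[node] = 0
        for par in parents.get(node, ()):  # founders have no parents
            visit(par, stack)
        state[node] = 1
        order.append(node)

    everyone = set(parents)
    for _, p1, p2 in pedigree:
        everyone.update((p1, p2))
    for node in sorted(everyone):
        visit(node, [])
    return order


def gen_pedigree_genotypes(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-drop biallelic genotypes through a pedigree.

    Founder allele frequencies are uniform on [maf_floor, 0.5]; founders
    carry uniquely labeled allele copies and offspring receive one
    random copy per parent per site (independent sites: every site is an
    independent meiosis unless ``ld_block_size`` > 1, which tiles blocks
    of perfectly correlated sites).

    Returns
    -------
    geno : DataFrame, index = sample id, columns = site ids; dosage 0/1/2.
    truth : DataFrame with one row per sample pair: ``sample1, sample2,
        relationship`` ("full_sibling", "parent_child", "half_sibling",
        "unrelated") and the realized fractions of sites sharing 0/1/2
        alleles identical by descent (``ibd0``, ``ibd1``, ``ibd2``).
    """
    rng = cfg._rng(_STREAM_PEDIGREE)
    if cfg.pedigree:
        order = _pedigree_order(cfg.pedigree)
        parents = {c: (p1, p2) for c, p1, p2 in cfg.pedigree}
    else:
        order = cfg.sample_ids()
        parents = {}

    k = max(1, int(cfg.ld_block_size))
    n_core = -(-cfg.n_snps // k)  # independent sites before block tiling
    freqs = rng.uniform(cfg.maf_floor, 0.5, size=n_core)

    # allele labels: (founder_index, copy) packed into ints
    labels: dict = {}
    alleles: dict = {}
    founder_count = 0
    for ind in order:
        if ind not in parents:
            a = rng.random((2, n_core)) < freqs  # True = alt allele
            lab = np.empty((2, n_core), dtype=np.int64)
            lab[0] = 2 * founder_count
            lab[1] = 2 * founder_count + 1
            founder_count += 1
        else:
            p1, p2 = parents[ind]
            pick1 = rng.integers(0, 2, size=n_core)
            pick2 = rng.integers(0, 2, size=n_core)
            a = np.stack(
                [
                    alleles[p1][pick1, np.arange(n_core)],
                    alleles[p2][pick2, np.arange(n_core)],
                ]
            )
            lab = np.stack(
                [
                    labels[p1][pick1, np.arange(n_core)],
                    labels[p2][pick2, np.arange(n_core)],
                ]
            )
        alleles[ind] = a
        labels[ind] = lab

    def tile(x):
        return np.repeat(x, k, axis=-1)[..., : cfg.n_snps]

    site_ids = [f"snp{i}" for i in range(cfg.n_snps)]
    geno = pd.DataFrame(
        {ind: tile(alleles[ind].sum(axis=0)) for ind in order}, index=site_ids
    ).T
    geno.columns.name = "site"

    rel_rows = []
    anc = _ancestor_founders(order, parents)
    for i, s1 in enumerate(order):
        for s2 in order[i + 1 :]:
            l1, l2 = labels[s1], labels[s2]
            shared = (l1[0] == l2[0]).astype(int) + (l1[1] == l2[1]).astype(int)
            alt = (l1[0] == l2[1]).astype(int) + (l1[1] == l2[0]).astype(int)
            ibd = np.maximum(shared, alt)
            rel_rows.append(
                {
                    "sample1": s1,
                    "sample2": s2,
                    "relationship": _relationship(s1, s2, parents, anc),
                    "ibd0": float(np.mean(ibd == 0)),
                    "ibd1": float(np.mean(ibd == 1)),
                    "ibd2": float(np.mean(ibd == 2)),
                }
            )
    truth = pd.DataFrame(rel_rows)
    return geno, truth


def _ancestor_founders(order, parents):
    """Map individual -> set of founder ancestors (founders map to selves)."""
    anc = {}
    for ind in order:
        if ind not in parents:
            anc[ind] = {ind}
        else:
            p1, p2 = parents[ind]
            anc[ind] = anc[p1] | anc[p2]
    return anc


def _relationship(s1, s2, parents, anc):
    p1 = set(parents.get(s1, ()))
    p2 = set(parents.get(s2, ()))
    if s1 in p2 or s2 in p1:
        return "parent_child"
    if p1 and p1 == p2:
        return "full_sibling"
    if p1 & p2:
        return "half_sibling"
    if anc[s1] & anc[s2]:
        return "other_related"
    return "unrelated"


def gen_population_genotypes(
    cfg: SimConfig,
    pop_sizes: dict,
    fst: float = 0.1,
    admixed: Optional[dict] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotypes for divergent populations plus optional admixed samples.

    Population allele frequencies follow the Balding-Nichols model
    around a shared ancestral frequency (uniform on [maf_floor, 0.5])
    with divergence ``fst``. ``admixed`` maps sample id -> {population:
    fraction}; each admixed site draws its two allele copies from the
    mixture of population frequencies.

    Returns (geno, labels): geno samples x sites dosage; labels has one
    row per sample with the true ancestry fractions per population.
    """
    rng = cfg._rng(_STREAM_PEDIGREE + 100)
    n_sites = cfg.n_snps
    anc = rng.uniform(cfg.maf_floor, 0.5, size=n_sites)
    a = (1 - fst) / fst
    pop_freqs = {
        pop: np.clip(rng.beta(anc * a, (1 - anc) * a), 1e-4, 1 - 1e-4)
        for pop in pop_sizes
    }
    rows, labels = [], []
    ids = []
    for pop, n in pop_sizes.items():
        for i in range(n):
            g = rng.binomial(2, pop_freqs[pop])
            sid = f"{pop}_{i:03d}"
            ids.append(sid)
            rows.append(g)
            labels.append({"sample": sid, **{p: float(p == pop) for p in pop_sizes}})
    for sid, mix in (admixed or {}).items():
        p_mix = sum(frac * pop_freqs[pop] for pop, frac in mix.items())
        rows.append(rng.binomial(2, p_mix))
        ids.append(sid)
        labels.append({"sample": sid, **{p: float(mix.get(p, 0.0)) for p in pop_sizes}})
    geno = pd.DataFrame(rows, index=ids, columns=[f"snp{i}" for i in range(n_sites)])
    return geno, pd.DataFrame(labels).set_index("sample")


# ---------------------------------------------------------------------------
# annotated variant tables with cascade truth
# ---------------------------------------------------------------------------

_LOF = ("frameshift_variant", "splice_acceptor_variant", "splice_donor_variant", "stop_gained")
_MISSENSE = (
    "inframe_deletion",
    "inframe_insertion",
    "missense_variant",
    "start_lost",
    "stop_lost",
    "protein_altering_variant",
)
_SYNONYMOUS = (
    "synonymous_variant",
    "stop_retained_variant",
    "incomplete_terminal_codon_variant",
)
_OTHER = ("intron_variant", "3_prime_UTR_variant", "upstream_gene_variant")


def _truth_flags(df: pd.DataFrame) -> pd.DataFrame:
    """Independent, deliberately plain re-application of the cascade
    thresholds used to label each simulated record with the stages it
    should pass. Kept free of any code shared with the cascade module so
    the two can be checked against each other."""
    out = {}
    hc = []
    for _, r in df.iterrows():
        ok = (
            r["filter"] == "PASS"
            and r["dp"] >= 10
            and r["gq"] >= 20
            and r["allele_fraction"] >= 0.2
            and not r["low_complexity"]
            and not r["segdup"]
            and r["gnomad_pass_or_missing"]
        )
        hc.append(bool(ok))
    out["truth_hc_hq"] = hc

    delet, cancer, fert, disease = [], [], [], []
    for (_, r), ok in zip(df.iterrows(), hc):
        is_coding = r["consequence"] in _LOF or r["consequence"] in _MISSENSE
        d = (
            ok
            and is_coding
            and r["exac_af"] < 0.001
            and r["cadd_phred"] > 20
            and r["dann"] > 0.99
        )
        delet.append(bool(d))
        cancer.append(
            bool(d and r["cosmic_tier1"] and r["cosmic_count"] >= 2 and r["fathmm_cancer"])
        )
        fert.append(
            bool(
                d
                and r["fertility_gene"]
                and r["loeuf"] <= 0.33
                and r["cgd_inheritance"] == "AD"
            )
        )
        disease.append(
            bool(
                d
                and r["chrom"] not in ("chrX", "chrY", "X", "Y")
                and r["loeuf"] < 0.33
                and r["cgd_inheritance"] == "AD"
                and r["fathmm_xf"] > 0.75
                and r["dann"] > 0.999
                and r["exac_af"] < 1e-5
            )
        )
    out["truth_deleterious"] = delet
    out["truth_cancer"] = cancer
    out["truth_fertility"] = fert
    out["truth_disease"] = disease
    return pd.DataFrame(out, index=df.index)


def gen_variant_table(cfg: SimConfig) -> pd.DataFrame:
    """Simulate an annotated SNV/indel table with cascade ground truth.

    Annotation values are drawn so that a realistic trickle of records
    survives each prioritization stage; the ``truth_*`` columns record
    which stages each record should pass, computed by an independent
    straightforward re-application of the thresholds.
    """
    rng = cfg._rng(_STREAM_VARIANTS)
    n = cfg.n_variants
    samples = cfg.sample_ids()

    chroms = rng.choice(
        [f"chr{i}" for i in range(1, 23)] + ["chrX"],
        size=n,
        p=[0.95 / 22] * 22 + [0.05],
    )
    consequence = rng.choice(
        list(_LOF + _MISSENSE + _SYNONYMOUS + _OTHER),
        size=n,
        p=[0.02] * 4 + [0.40 / 6] * 6 + [0.30 / 3] * 3 + [0.22 / 3] * 3,
    )
    # allele frequency: half rare (log-uniform down to 1e-8), half common
    af = np.where(
        rng.random(n) < 0.5,
        10 ** rng.uniform(-8, -3, size=n),
        10 ** rng.uniform(-3, -0.3, size=n),
    )
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": rng.integers(1, 2.5e8, size=n),
            "ref": rng.choice(list("ACGT"), size=n),
            "alt": rng.choice(list("ACGT"), size=n),
            "gene": [f"GENE{i % 500}" for i in rng.integers(0, 500, size=n)],
            "sample": rng.choice(samples, size=n),
            "filter": np.where(rng.random(n) < 0.9, "PASS", "VQSRTrancheSNP"),
            "dp": rng.poisson(30, size=n),
            "gq": rng.integers(5, 100, size=n),
            "allele_fraction": rng.beta(8, 8, size=n),
            "low_complexity": rng.random(n) < 0.05,
            "segdup": rng.random(n) < 0.05,
            "gnomad_pass_or_missing": rng.random(n) < 0.95,
            "consequence": consequence,
            "exac_af": af,
            "cadd_phred": rng.uniform(0, 45, size=n),
            "dann": 1 - 10 ** rng.uniform(-4.5, -0.3, size=n),
            "fathmm_xf": rng.uniform(0, 1, size=n),
            "fathmm_cancer": rng.random(n) < 0.3,
            "cosmic_count": rng.poisson(1.0, size=n),
            "cosmic_tier1": rng.random(n) < 0.2,
            "loeuf": rng.uniform(0.05, 2.0, size=n),
            "cgd_inheritance": rng.choice(["AD", "AR", "none"], size=n, p=[0.25, 0.25, 0.5]),
            "fertility_gene": rng.random(n) < 0.15,
            "p53_pathway": rng.random(n) < 0.05,
        }
    )
    df["pos"] = df["pos"].astype(np.int64)
    return pd.concat([df, _truth_flags(df)], axis=1)


# ---------------------------------------------------------------------------
# array probe intensities
# ---------------------------------------------------------------------------


def gen_array_intensities(
    cnv_calls: Sequence,
    is_true_call: Sequence[bool],
    cfg: SimConfig,
    effect_sd: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate array probe intensities around a set of CNV calls.

    Probes are placed uniformly at ``probes_per_bin`` density over the
    simulated genome. For TRUE calls, carrier intensities at probes
    inside the call shift by ``effect_sd`` standard deviations (down for
    deletions, up for duplications); for FALSE calls carriers are i.i.d.
    with non-carriers.

    Parameters
    ----------
    cnv_calls : sequence of SmallCnv/CnvCall-like
        Must expose ``chrom, start, end, kind`` and either ``sample``
        (single carrier) or ``samples`` (list of carriers).
    is_true_call : sequence of bool, parallel to ``cnv_calls``.

    Returns (intensities, probes): intensities is probes x samples,
    probes has chrom/pos.
    """
    if effect_sd is None:
        effect_sd = cfg.array_effect_sd
    rng = cfg._rng(_STREAM_ARRAY)
    samples = cfg.sample_ids()
    genome_len = cfg.n_bins * cfg.bin_size
    n_probes = max(1, int(round(cfg.probes_per_bin * cfg.n_bins)))
    pos = np.sort(rng.choice(genome_len, size=n_probes, replace=False)) + 1

    x = rng.normal(0.0, 1.0, size=(n_probes, len(samples)))
    sidx = {s: i for i, s in enumerate(samples)}
    for call, true in zip(cnv_calls, is_true_call):
        if not true:
            continue
        carriers = getattr(call, "samples", None) or [call.sample]
        inside = (pos > call.start) & (pos <= call.end)
        sign = -1.0 if call.kind == "del" else 1.0
        for c in carriers:
            x[inside, sidx[c]] += sign * effect_sd
    probes = pd.DataFrame({"chrom": cfg.chrom, "pos": pos})
    intensities = pd.DataFrame(x, columns=samples)
    return intensities, probes
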