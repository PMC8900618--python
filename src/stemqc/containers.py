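"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Genomic bins are 0-based, half-open, constant width per chromosome.
* Normalized depth of coverage ("CN") is on a copy-number scale where a
  diploid locus is 2.
* Exported BED is 0-based half-open; human-readable reports are 1-based
  inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CoverageMatrix",
    "IntervalStats",
    "CnvCall",
    "SmallCnv",
    "ImbalanceSegment",
]


@dataclass
class CoverageMatrix:
    """Normalized depth of coverage for a cohort over fixed-width genome bins.

    Attributes
    ----------
    bins : pandas.DataFrame
        Columns ``chrom``, ``start``, ``end``; sorted by (chrom, start);
        constant bin width per chromosome.
    samples : list of str
        Sample identifiers, one per row of ``cn``.
    cn : numpy.ndarray, shape (n_samples, n_bins)
        Normalized depth on the copy-number scale (diploid = 2).
    """

    bins: pd.DataFrame
    samples: list
    cn: np.ndarray

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn, dtype=float)
        if self.cn.shape != (len(self.samples), len(self.bins)):
            raise ValueError(
                f"cn shape {self.cn.shape} does not match "
                f"{len(self.samples)} samples x {len(self.bins)} bins"
            )
        if (self.cn < 0).any():
            raise ValueError("normalized coverage must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def chrom_slices(self) -> dict:
        """Map chromosome name -> slice of contiguous bin indices."""
        out = {}
        chroms = self.bins["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def to_tsv(self, path) -> None:
        df = self.bins.copy()
        for i, s in enumerate(self.samples):
            df[s] = self.cn[i]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CoverageMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = ["chrom", "start", "end"]
        samples = [c for c in df.columns if c not in meta]
        return cls(
            bins=df[meta].reset_index(drop=True),
            samples=samples,
            cn=df[samples].to_numpy().T,
        )


@dataclass
class IntervalStats:
    """Across-sample robust statistics for one sample over one bin interval.

    ``z`` is |coverage(S, I) - median(I)| / MAD(I); when the across-sample
    MAD is zero the interval is flagged ``degenerate`` and ``z`` is +inf
    (never NaN).
    """

    sample: str
    start_bin: int
    end_bin: int  # half-open
    coverage: float
    median: float
    mad: float
    z: float
    degenerate: bool = False


@dataclass
class CnvCall:
    """A reported large copy-number variant for one sample."""

    sample: str
    chrom: str
    start: int  # 0-based, half-open, base coordinates
    end: int
    kind: str  # "dup" | "del"
    z: float
    mean_cn: float
    n_bins: int
    status: str = "fixed"  # "fixed" | "mosaic"
    p_mosaic: float = float("nan")
    cell_fraction: Optional[float] = None
    start_bin: int = -1
    end_bin: int = -1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SmallCnv:
    """A small (< 1 Mbp) CNV call, typically from an external genotyper."""

    sample: str
    chrom: str
    start: int
    end: int
    kind: str  # "dup" | "del"
    copy_number: Optional[float] = None
    probe_count: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ImbalanceSegment:
    """A segment of consistent phased allelic imbalance in one sample.

    ``deviation`` is d = |mean(hap1 / (hap1 + hap2)) - 0.5|; ``lod`` is the
    base-10 log likelihood ratio of the imbalanced binomial model vs. the
    balanced one, summed over sites with phase orientation.
    """

    sample: str
    chrom: str
    start: int  # 1-based position of first site
    end: int  # 1-based position of last site
    n_sites: int
    deviation: float
    lod: float
    orientation: int = 1  # +1: hap1 over-represented, -1: hap2
    klass: str = "ambiguous"  # "dup" | "del" | "cnloh" | "ambiguous"
    mosaic_fraction: float = float("nan")
    mean_cn: float = float("nan")
    telomeric: bool = False
    low_fraction: bool = False
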