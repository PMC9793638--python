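"""Sliding-window detection of runs of homozygosity (ROH) and F_ROH.

The scan mirrors the classical genotype-tool procedure: a window of
``window_snps`` consecutive SNPs is called homozygous when it contains at most
``window_het_allowance`` heterozygotes and ``window_missing_allowance`` missing
calls; a SNP is flagged when the proportion of homozygous windows covering it
reaches ``window_hit_threshold``.  Maximal runs of flagged SNPs are split at
inter-SNP gaps above ``max_gap_kb`` and kept only if they satisfy the SNP
count, physical length and SNP density thresholds.  ``min_length_kb`` selects
the ROH>1 Mb versus ROH>5 Mb variants.

F_ROH is the summed length of an individual's ROH divided by genome length,
an identity-by-descent proxy whose reference "base" is set implicitly by the
length threshold (long ROH reflect recent inbreeding only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["RohParams", "RohSegment", "detect_roh", "f_roh", "f_roh_matrix"]


@dataclass(frozen=True)
class RohParams:
    """Scan parameters; defaults are the cited genotype tool's defaults.

    ``pig()`` returns the relaxed thresholds used for SNP-chip data on the
    pig pedigree (30 SNPs minimum, 100 kb/SNP density).
    """

    window_snps: int = 50
    window_het_allowance: int = 1
    window_missing_allowance: int = 5
    window_hit_threshold: float = 0.05
    min_snps: int = 100
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    min_length_kb: float = 1000.0

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_snps < 1:
            raise ValueError("window_snps and min_snps must be positive")
        for name in ("window_hit_threshold", "min_density_kb_per_snp",
                     "max_gap_kb", "min_length_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_het_allowance < 0 or self.window_missing_allowance < 0:
            raise ValueError("window allowances must be >= 0")

    @classmethod
    def pig(cls) -> "RohParams":
        return cls(min_snps=30, min_density_kb_per_snp=100.0)

    def variant(self, min_length_kb: float) -> "RohParams":
        return replace(self, min_length_kb=min_length_kb)


@dataclass(frozen=True)
class RohSegment:
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _flag_snps(x: np.ndarray, params: RohParams) -> np.ndarray:
    """Per-SNP flag from the window scan (one chromosome, sorted positions)."""
    n = x.shape[0]
    w = params.window_snps
    flagged = np.zeros(n, bool)
    if n < w:
        return flagged
    het = (x == 1).astype(np.int64)
    miss = (x < 0).astype(np.int64)
    cs_het = np.concatenate([[0], np.cumsum(het)])
    cs_miss = np.concatenate([[0], np.cumsum(miss)])
    starts = np.arange(n - w + 1)
    hom_window = (
        (cs_het[starts + w] - cs_het[starts] <= params.window_het_allowance)
        & (cs_miss[starts + w] - cs_miss[starts] <= params.window_missing_allowance)
    ).astype(np.int64)
    cs_hom = np.concatenate([[0], np.cumsum(hom_window)])
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n - w)
    n_windows = hi - lo + 1
    n_hits = cs_hom[hi + 1] - cs_hom[lo]
    return n_hits / n_windows >= params.window_hit_threshold


def detect_roh(
    genotypes: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    params: RohParams | None = None,
) -> list[RohSegment]:
    """ROH segments of one individual's 0/1/2 genotype row (-1 = missing)."""
    if params is None:
        params = RohParams()
    genotypes = np.asarray(genotypes)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, np.int64)
    if genotypes.ndim != 1:
        raise ValueError("detect_roh expects a single genotype row")
    segments: list[RohSegment] = []
    max_gap_bp = params.max_gap_kb * 1000.0
    for c in np.unique(chrom):
        sel = chrom == c
        p_c = pos[sel]
        if np.any(np.diff(p_c) < 0):
            raise ValueError(f"positions on chromosome {c} are not sorted")
        flagged = _flag_snps(genotypes[sel], params)
        # maximal flagged runs, split where consecutive SNPs are too far apart
        start = None
        for j in range(len(p_c) + 1):
            end_of_run = j == len(p_c) or not flagged[j]
            gap_break = (
                start is not None
                and j < len(p_c)
                and j > 0
                and p_c[j] - p_c[j - 1] > max_gap_bp
            )
            if start is not None and (end_of_run or gap_break):
                segments.extend(_finish(int(c), p_c, start, j - 1, params))
                start = None
            if j < len(p_c) and flagged[j] and start is None:
                start = j
    return segments


def _finish(c: int, p_c: np.ndarray, i0: int, i1: int, params: RohParams):
    n = i1 - i0 + 1
    length = int(p_c[i1] - p_c[i0] + 1)
    if n < params.min_snps:
        return []
    if length < params.min_length_kb * 1000.0:
        return []
    if (length / 1000.0) / n > params.min_density_kb_per_snp:
        return []
    return [RohSegment(c, int(p_c[i0]), int(p_c[i1]), n)]


def f_roh(segments: list[RohSegment], genome_length_bp: int) -> float:
    """Summed ROH length over genome length."""
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    return sum(seg.length_bp for seg in segments) / genome_length_bp


def f_roh_matrix(
    x: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    genome_length_bp: int,
    params: RohParams | None = None,
) -> np.ndarray:
    """F_ROH for every row of a genotype matrix."""
    x = np.atleast_2d(x)
    return np.array([
        f_roh(detect_roh(row, chrom, pos, params), genome_length_bp) for row in x
    ])
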