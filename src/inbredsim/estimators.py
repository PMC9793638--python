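"""Marker-, pedigree- and IBD-based measures of the inbreeding coefficient.

Six SNP-frequency-based estimators are implemented from their closed formulas,
with ``x_k`` the 0/1/2 count of the counted allele at SNP ``k`` and ``p_k`` its
frequency in a chosen reference set (base generation, current generation, or a
constant 0.5):

=====  ==============================================================
VR1    sum_k (x-2p)^2 / sum_k 2pq - 1          (ratio of sums)
VR2    mean_k [ (x-2p)^2 / 2pq - 1 ]           (mean of ratios)
YA1    sum_k [x^2-(1+2p)x+2p^2] / sum_k 2pq    (ratio of sums)
YA2    mean_k [x^2-(1+2p)x+2p^2] / 2pq         (correlation of uniting gametes)
LH1    1 - sum_k x(2-x) / sum_k 2pq            (heterozygosity deficit)
LH2    1 - mean_k [ x(2-x) / 2pq ]
=====  ==============================================================

plus F_HOM (observed homozygote fraction), F_q05 (any of the six at p = 0.5,
equal to 2 F_HOM - 1), Wright's pedigree coefficient F_PED, and F_IBD measured
on multiallelic tracer loci whose base-generation alleles are all distinct, so
label identity is identity-by-descent by construction.

The suffix-1 estimators are ratios of sums over loci and are insensitive to
rare alleles and MAF filtering; the suffix-2 estimators average per-locus
ratios and weight rare alleles heavily (VR2 and LH2 can leave [-1, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "METHODS",
    "FrequencySet",
    "FrequencyError",
    "allele_frequencies",
    "compute_freq_F",
    "f_hom",
    "f_q05",
    "f_ped",
    "kinship",
    "f_ibd",
    "apply_maf_filter",
    "segregating",
    "f_table",
]

METHODS = ("VR1", "VR2", "YA1", "YA2", "LH1", "LH2")


class FrequencyError(ValueError):
    """A reference frequency of 0 or 1 entered an estimator denominator."""


@dataclass(frozen=True)
class FrequencySet:
    """Per-SNP reference frequencies with provenance ('base'|'current'|'half')."""

    p: np.ndarray
    provenance: str = "current"

    def __post_init__(self) -> None:
        if self.provenance not in ("base", "current", "half"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "half" and not np.all(self.p == 0.5):
            raise ValueError("provenance 'half' requires p = 0.5 everywhere")

    @property
    def usable(self) -> np.ndarray:
        return (self.p > 0) & (self.p < 1)


def allele_frequencies(x: np.ndarray, provenance: str = "current") -> FrequencySet:
    """Counted-allele frequencies of a 0/1/2 genotype matrix."""
    x = np.atleast_2d(x)
    if x.size == 0 and x.shape[0] == 0:
        raise ValueError("empty genotype matrix")
    return FrequencySet(x.mean(axis=0) / 2.0, provenance)


def segregating(x: np.ndarray) -> np.ndarray:
    """Mask of SNPs polymorphic among the given individuals."""
    x = np.atleast_2d(x)
    tot = x.sum(axis=0)
    return (tot > 0) & (tot < 2 * x.shape[0])


def _as_p(freqs) -> np.ndarray:
    return freqs.p if isinstance(freqs, FrequencySet) else np.asarray(freqs, float)


def compute_freq_F(x: np.ndarray, freqs, method: str) -> np.ndarray:
    """Per-individual inbreeding coefficient by one of the six formulas.

    Every SNP column must have a reference frequency strictly inside (0, 1);
    enforcing the panel policy (base-segregating SNPs for base frequencies,
    currently segregating SNPs otherwise) is the caller's responsibility and
    violations raise :class:`FrequencyError`.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    x = np.atleast_2d(np.asarray(x, np.float64))
    p = _as_p(freqs)
    if x.shape[1] != p.shape[0]:
        raise ValueError("genotype matrix and frequency vector disagree on SNP count")
    if x.shape[1] == 0:
        raise ValueError("empty SNP panel")
    if np.any((p <= 0) | (p >= 1)):
        raise FrequencyError("reference frequencies must lie strictly in (0, 1)")
    twopq = 2.0 * p * (1.0 - p)
    if method == "VR1":
        return ((x - 2 * p) ** 2).sum(axis=1) / twopq.sum() - 1.0
    if method == "VR2":
        return (((x - 2 * p) ** 2) / twopq - 1.0).mean(axis=1)
    ya = x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p
    if method == "YA1":
        return ya.sum(axis=1) / twopq.sum()
    if method == "YA2":
        return (ya / twopq).mean(axis=1)
    het = x * (2.0 - x)
    if method == "LH1":
        return 1.0 - het.sum(axis=1) / twopq.sum()
    return 1.0 - (het / twopq).mean(axis=1)  # LH2


def f_hom(x: np.ndarray) -> np.ndarray:
    """Observed homozygote fraction, 1 - (1/S) sum x(2-x).

    The panel should contain only SNPs segregating among the scored
    individuals (monomorphic SNPs would inflate homozygosity trivially).
    """
    x = np.atleast_2d(np.asarray(x, np.float64))
    if x.shape[1] == 0:
        raise ValueError("empty SNP panel")
    return 1.0 - (x * (2.0 - x)).mean(axis=1)


def f_q05(x: np.ndarray) -> np.ndarray:
    """All six estimators coincide at p = 0.5; equals 2 F_HOM - 1."""
    return 2.0 * f_hom(x) - 1.0


def apply_maf_filter(p: np.ndarray, threshold: float) -> np.ndarray:
    """Mask of SNPs retained: minor-allele frequency strictly above threshold."""
    if not 0.0 <= threshold < 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    p = np.asarray(p, float)
    return np.minimum(p, 1.0 - p) > threshold


# ---------------------------------------------------------------------------
# pedigree inbreeding (Wright's F via recursive kinship)


class _Kinship:
    """Memoized kinship recursion; ids must be recorded parents-first."""

    def __init__(self, sire: dict[int, int], dam: dict[int, int], rank: dict[int, int]):
        self.sire = sire
        self.dam = dam
        self.rank = rank
        self.memo: dict[tuple[int, int], float] = {}

    def phi(self, a: int, b: int) -> float:
        if a <= 0 or b <= 0:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        got = self.memo.get(key)
        if got is not None:
            return got
        if a == b:
            val = 0.5 * (1.0 + self.phi(self.sire[a], self.dam[a]))
        else:
            # recurse on the younger individual (parents precede offspring)
            if self.rank[a] < self.rank[b]:
                a, b = b, a
            val = 0.5 * (self.phi(self.sire[a], b) + self.phi(self.dam[a], b))
        self.memo[key] = val
        return val

    def inbreeding(self, i: int) -> float:
        return self.phi(self.sire[i], self.dam[i])


def kinship(ids, sires, dams) -> _Kinship:
    """Build a kinship calculator from parallel id/sire/dam sequences.

    Parent id 0 (or negative) means unknown/founder.  Parents must appear
    before their offspring; a violation (which would also cover cycles) raises
    ``ValueError``.
    """
    sire_of: dict[int, int] = {}
    dam_of: dict[int, int] = {}
    rank: dict[int, int] = {}
    for r, (i, s, d) in enumerate(zip(ids, sires, dams)):
        i, s, d = int(i), int(s), int(d)
        if i <= 0:
            raise ValueError(f"individual ids must be positive (got {i})")
        if i in rank:
            raise ValueError(f"duplicate individual id {i}")
        for par in (s, d):
            if par > 0 and par not in rank:
                raise ValueError(
                    f"parent {par} of individual {i} not recorded earlier "
                    "(missing, out of order, or a pedigree cycle)"
                )
        sire_of[i] = max(s, 0)
        dam_of[i] = max(d, 0)
        rank[i] = r
    return _Kinship(sire_of, dam_of, rank)


def f_ped(ids, sires, dams, query_ids=None) -> np.ndarray:
    """Wright's inbreeding coefficient for ``query_ids`` (default: all ids)."""
    calc = kinship(ids, sires, dams)
    if query_ids is None:
        query_ids = list(ids)
    return np.array([calc.inbreeding(int(i)) for i in query_ids])


# ---------------------------------------------------------------------------
# IBD from tracer loci


def f_ibd(tracer: np.ndarray) -> np.ndarray:
    """Fraction of tracer loci at which an individual's two labels coincide.

    ``tracer`` has one row per haplotype (2N x loci); base-generation labels
    are unique per locus, so identical labels are identical by descent.
    """
    tracer = np.atleast_2d(tracer)
    if tracer.shape[0] % 2:
        raise ValueError("tracer matrix must have an even number of haplotype rows")
    if tracer.shape[1] == 0:
        raise ValueError("tracer panel is empty")
    return (tracer[0::2] == tracer[1::2]).mean(axis=1)


# ---------------------------------------------------------------------------
# combined per-individual table


def f_table(
    x: np.ndarray,
    p_base: np.ndarray | None = None,
    tracer: np.ndarray | None = None,
    pedigree: tuple | None = None,
    roh: dict | None = None,
) -> pd.DataFrame:
    """Per-individual values of every applicable measure, one column each.

    Columns are named ``<METHOD>_<provenance>`` for the frequency-based
    estimators plus ``HOM``, ``q05`` and optionally ``IBD``, ``PED``,
    ``ROH1``/``ROH5``.  Panel policy: base-frequency columns use all SNPs of
    the (base-segregating) panel; current and p=0.5 columns use the SNPs still
    segregating among the scored individuals.

    ``pedigree`` is ``(ids, sires, dams, query_ids)``; ``roh`` is a mapping
    with keys ``chrom``, ``pos``, ``genome_length_bp`` and optional
    ``params`` understood by :mod:`inbredsim.roh`.
    """
    x = np.atleast_2d(x)
    out: dict[str, np.ndarray] = {}
    if tracer is not None:
        out["IBD"] = f_ibd(tracer)
    if pedigree is not None:
        ids, sires, dams, query = pedigree
        out["PED"] = f_ped(ids, sires, dams, query)
    if x.shape[1]:
        cur = segregating(x)
        if p_base is not None:
            for m in METHODS:
                out[f"{m}_base"] = compute_freq_F(x, p_base, m)
        if cur.any():
            xc = x[:, cur]
            p_cur = allele_frequencies(xc).p
            for m in METHODS:
                out[f"{m}_current"] = compute_freq_F(xc, p_cur, m)
            out["HOM"] = f_hom(xc)
            out["q05"] = f_q05(xc)
    if roh is not None:
        from .roh import RohParams, f_roh_matrix

        params = roh.get("params", RohParams())
        for name, min_len in (("ROH1", 1000.0), ("ROH5", 5000.0)):
            import dataclasses as _dc

            pr = _dc.replace(params, min_length_kb=min_len)
            out[name] = f_roh_matrix(
                x, roh["chrom"], roh["pos"], roh["genome_length_bp"], pr
            )
    return pd.DataFrame(out)
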