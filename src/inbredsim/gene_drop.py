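"""Gene dropping of simulated founder genomes through an arbitrary pedigree.

Founders of a user-supplied pedigree receive genomes sampled from a simulated
equilibrium population; every non-founder is formed from one recombinant
gamete of each recorded parent, with neither mutation nor selection.  Repeated
over replicates this yields the Monte-Carlo distribution of genotypes — and of
every inbreeding measure — for each cohort of the pedigree, the standard way
to put molecular estimates from a real pedigreed population in their expected
context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sim_core import ConfigurationError, GenomeSpec, PopulationState, transmit
from . import estimators

__all__ = [
    "Pedigree",
    "GeneDropResult",
    "gene_drop",
    "cohort_summaries",
    "generate_test_pedigree",
]


@dataclass(frozen=True)
class Pedigree:
    """Validated pedigree rows (id, sire, dam, cohort); 0 = unknown parent."""

    ids: np.ndarray
    sires: np.ndarray
    dams: np.ndarray
    cohorts: np.ndarray
    sex: np.ndarray | None = None   # optional: 1 = male, 2 = female

    def __post_init__(self) -> None:
        ids = self.ids
        if len(set(ids.tolist())) != ids.size:
            raise ValueError("duplicate ids in pedigree")
        if np.any(ids <= 0):
            raise ValueError("ids must be positive")
        if np.any(self.cohorts < 0):
            raise ValueError("cohorts must be nonnegative")
        seen: set[int] = set()
        for row, (i, s, d) in enumerate(zip(ids, self.sires, self.dams)):
            for par in (int(s), int(d)):
                if par > 0 and par not in seen:
                    raise ValueError(
                        f"row {row}: parent {par} of {int(i)} does not precede it "
                        "(missing parent, forward reference, or cycle)"
                    )
            seen.add(int(i))
        if self.sex is not None:
            sex_of = dict(zip(ids.tolist(), self.sex.tolist()))
            for i, s, d in zip(ids, self.sires, self.dams):
                if int(s) > 0 and sex_of[int(s)] == 2:
                    raise ValueError(f"sire {int(s)} of {int(i)} is recorded female")
                if int(d) > 0 and sex_of[int(d)] == 1:
                    raise ValueError(f"dam {int(d)} of {int(i)} is recorded male")

    @property
    def n(self) -> int:
        return self.ids.size

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sires <= 0) & (self.dams <= 0)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        sex = None
        if "sex" in frame.columns:
            sex = frame["sex"].to_numpy(np.int64)
        return cls(
            ids=frame["id"].to_numpy(np.int64),
            sires=frame["sire"].to_numpy(np.int64),
            dams=frame["dam"].to_numpy(np.int64),
            cohorts=frame["cohort"].to_numpy(np.int64),
            sex=sex,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.ids, "sire": self.sires, "dam": self.dams,
                "cohort": self.cohorts}
        if self.sex is not None:
            data["sex"] = self.sex
        return pd.DataFrame(data)


@dataclass
class GeneDropResult:
    pedigree: Pedigree
    genome: GenomeSpec
    chrom: np.ndarray
    pos: np.ndarray
    s: np.ndarray
    h: np.ndarray
    H: np.ndarray             # (2 * n_ped, S) in pedigree row order
    tracer_chrom: np.ndarray
    tracer_pos: np.ndarray
    T: np.ndarray             # (2 * n_ped, L)

    def genotypes(self, rows: np.ndarray | None = None) -> np.ndarray:
        H = self.H if rows is None else self.H[_hap_rows(rows)]
        return H[0::2].astype(np.int64) + H[1::2]


def _hap_rows(idx: np.ndarray) -> np.ndarray:
    rows = np.empty(2 * idx.size, np.int64)
    rows[0::2] = 2 * idx
    rows[1::2] = 2 * idx + 1
    return rows


def gene_drop(
    pedigree: Pedigree,
    founder_pool: PopulationState,
    rng: np.random.Generator | int | None = None,
    replace: bool = False,
    tracer_spacing_bp: int = 500_000,
) -> GeneDropResult:
    """Drop pool genomes through the pedigree (no mutation, no selection).

    Founders draw whole individuals from the pool (without replacement unless
    ``replace``); every founder haplotype also gets a unique tracer label so
    F_IBD is measured relative to the founding cohort.  Rows are processed in
    pedigree order (parents are guaranteed to precede offspring), batched per
    cohort for speed.
    """
    from .breeding import _tracer_grid

    rng = np.random.default_rng(rng)
    founders = np.nonzero(pedigree.founder_mask)[0]
    n_f = founders.size
    if not replace and n_f > founder_pool.n_individuals:
        raise ConfigurationError("founder pool smaller than the founder count")
    pool_idx = rng.choice(founder_pool.n_individuals, size=n_f, replace=replace)

    counts = founder_pool.H[_hap_rows(pool_idx)].sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < 2 * n_f)
    chrom = founder_pool.chrom[seg]
    pos = founder_pool.pos[seg]
    genome = founder_pool.genome
    tr_chrom, tr_pos = _tracer_grid(genome, tracer_spacing_bp)

    n_ped = pedigree.n
    H = np.zeros((2 * n_ped, int(seg.sum())), np.uint8)
    T = np.zeros((2 * n_ped, tr_pos.size), np.int32)
    H[_hap_rows(founders)] = founder_pool.H[_hap_rows(pool_idx)][:, seg]
    T[_hap_rows(founders)] = np.arange(2 * n_f, dtype=np.int32)[:, None].repeat(
        tr_pos.size, axis=1)

    row_of = {int(i): r for r, i in enumerate(pedigree.ids)}
    gpos = chrom.astype(np.int64) * genome.chrom_length_bp + pos
    tr_gpos = tr_chrom.astype(np.int64) * genome.chrom_length_bp + tr_pos
    chrom64 = chrom.astype(np.int64)
    tr_chrom64 = tr_chrom.astype(np.int64)

    # batch maximal runs of rows whose parents are all already materialized;
    # a batch is flushed as soon as a row needs a parent from the open batch
    # (row order has parents-first, so every row lands in some batch)
    materialized = set(int(pedigree.ids[r]) for r in founders.tolist())
    batch: list[int] = []
    batches: list[list[int]] = []
    for r in np.nonzero(~pedigree.founder_mask)[0]:
        s_id, d_id = int(pedigree.sires[r]), int(pedigree.dams[r])
        if not (s_id in materialized and d_id in materialized):
            if batch:
                batches.append(batch)
                materialized.update(int(pedigree.ids[rr]) for rr in batch)
                batch = []
            if not (s_id in materialized and d_id in materialized):
                raise ValueError(
                    f"parents of individual {int(pedigree.ids[r])} unresolved")
        batch.append(int(r))
    if batch:
        batches.append(batch)

    for rows in batches:
        rows_a = np.array(rows)
        sire_rows = np.array([row_of[int(pedigree.sires[r])] for r in rows])
        dam_rows = np.array([row_of[int(pedigree.dams[r])] for r in rows])
        par0 = np.empty(2 * rows_a.size, np.int64)
        par0[0::2] = 2 * sire_rows
        par0[1::2] = 2 * dam_rows
        par1 = par0 + 1
        H_new, T_new = transmit(
            [(H, gpos, chrom64), (T, tr_gpos, tr_chrom64)],
            par0, par1, genome, rng,
        )
        H[_hap_rows(rows_a)] = H_new
        T[_hap_rows(rows_a)] = T_new

    return GeneDropResult(
        pedigree=pedigree, genome=genome, chrom=chrom, pos=pos,
        s=founder_pool.s[seg], h=founder_pool.h[seg], H=H,
        tracer_chrom=tr_chrom, tracer_pos=tr_pos, T=T,
    )


def cohort_summaries(
    result: GeneDropResult,
    reference: int | str = "first",
    methods: tuple[str, ...] = estimators.METHODS,
) -> pd.DataFrame:
    """Per-cohort mean and variance of the inbreeding measures.

    ``reference`` selects the frequency provenance: a cohort number (its
    frequencies, computed over that cohort, applied to all cohorts on the
    SNPs it segregates for), ``"first"``/``"last"`` for the earliest or most
    recent cohort, ``"current"`` (each cohort's own frequencies) or
    ``"half"`` (p = 0.5).  Empty cohorts are skipped.
    """
    ped = result.pedigree
    cohorts = np.unique(ped.cohorts)
    book = (ped.ids, ped.sires, ped.dams)

    ref_p = None
    if reference not in ("current", "half"):
        if reference == "first":
            ref_cohort = int(cohorts.min())
        elif reference == "last":
            ref_cohort = int(cohorts.max())
        else:
            ref_cohort = int(reference)
        rows = np.nonzero(ped.cohorts == ref_cohort)[0]
        if rows.size == 0:
            raise ValueError(f"reference cohort {ref_cohort} is empty")
        x_ref = result.genotypes(rows)
        p_all = x_ref.mean(axis=0) / 2.0
        ref_panel = (p_all > 0) & (p_all < 1)
        ref_p = p_all[ref_panel]

    records = []
    for c in cohorts:
        rows = np.nonzero(ped.cohorts == c)[0]
        if rows.size == 0:
            continue
        x = result.genotypes(rows)
        tracer = result.T[_hap_rows(rows)]
        rec: dict[str, float] = {"cohort": int(c), "n": int(rows.size)}
        for name, vec in _cohort_measures(
            x, tracer, book, ped.ids[rows], ref_p,
            ref_panel if ref_p is not None else None, reference, methods,
        ).items():
            rec[f"{name}_mean"] = float(np.mean(vec))
            rec[f"{name}_var"] = float(np.var(vec, ddof=1)) if len(vec) > 1 else np.nan
        records.append(rec)
    return pd.DataFrame(records).set_index("cohort")


def _cohort_measures(x, tracer, book, ids, ref_p, ref_panel, reference, methods):
    out = {
        "IBD": estimators.f_ibd(tracer),
        "PED": estimators.f_ped(*book, ids),
    }
    if x.shape[1] == 0:
        return out
    if ref_p is not None:
        xr = x[:, ref_panel]
        for m in methods:
            out[m] = estimators.compute_freq_F(xr, ref_p, m)
    else:
        cur = estimators.segregating(x)
        if cur.any():
            xc = x[:, cur]
            if reference == "half":
                out["q05"] = estimators.f_q05(xc)
            else:
                p_cur = estimators.allele_frequencies(xc).p
                for m in methods:
                    out[m] = estimators.compute_freq_F(xc, p_cur, m)
            out["HOM"] = estimators.f_hom(xc)
    return out


def generate_test_pedigree(
    rng: np.random.Generator | int | None = None,
    n_founders: int = 20,
    n_cohorts: int = 23,
    litter_size: int = 2,
    parent_overlap: int = 2,
) -> Pedigree:
    """Synthetic pig-like pedigree: many cohorts, parents reused across cohorts.

    A stand-in fixture for a real livestock pedigree (which is not shipped):
    each cohort draws sires and dams from the previous ``parent_overlap``
    cohorts, so generations overlap as they do in a herd book.
    """
    rng = np.random.default_rng(rng)
    ids = list(range(1, n_founders + 1))
    sires = [0] * n_founders
    dams = [0] * n_founders
    cohorts = [0] * n_founders
    pools = [list(ids)]
    next_id = n_founders + 1
    for c in range(1, n_cohorts + 1):
        recent = [i for pool in pools[-parent_overlap:] for i in pool]
        new: list[int] = []
        n_matings = max(2, n_founders // 2)
        for _ in range(n_matings):
            s, d = rng.choice(recent, size=2, replace=False)
            for _ in range(litter_size):
                ids.append(next_id)
                sires.append(int(s))
                dams.append(int(d))
                cohorts.append(c)
                new.append(next_id)
                next_id += 1
        pools.append(new)
    return Pedigree(
        ids=np.array(ids, np.int64),
        sires=np.array(sires, np.int64),
        dams=np.array(dams, np.int64),
        cohorts=np.array(cohorts, np.int64),
    )
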