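"""Small-population breeding schemes founded from the large initial population.

A line is founded by sampling individuals from an equilibrium ancestral
population.  The founding generation (t = 0) is the base population: only SNPs
segregating among the founders form the frozen marker panel, mutation is
switched off, base allele frequencies are stored, and every founder receives
two unique alleles at each of a grid of multiallelic IBD-tracer loci, so that
label identity in later generations is identity-by-descent relative to t = 0.

Three schemes propagate the line with discrete generations and no selfing:

* RC — random contributions: every offspring draws two distinct parents, each
  slot fitness-proportional (natural selection on the deleterious mutations).
* EC — equalized contributions: random monogamous couples, exactly two
  offspring each; natural selection can act only within family and is applied
  as offspring viability (accept with probability w, redraw on rejection).
* SEL — truncation selection on own phenotype for a neutral quantitative
  trait: each generation the N parents produce T candidates and the top
  N = 20% of T are selected.

A neutral additive trait (a random 5% of panel SNPs as QTL, effects
N(0, 0.1²), environmental variance 2) provides the selection criterion; QTL
and fitness loci are excluded from the marker panel used by the estimators.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .sim_core import (
    ConfigurationError,
    ExtinctionError,
    GenomeSpec,
    PopulationState,
    draw_parent_pairs,
    fitness_from_genotypes,
    transmit,
)

__all__ = [
    "SchemeConfig",
    "TraitArchitecture",
    "PedigreeBook",
    "LineState",
    "ReplicateResult",
    "sample_base",
    "define_trait",
    "phenotype",
    "propagate_rc",
    "propagate_ec",
    "propagate_sel",
    "select_individuals",
    "marker_indices",
    "run_scenario",
]

DEFAULT_TRACER_SPACING_BP = 500_000  # one multiallelic locus per 0.5 Mb


@dataclass(frozen=True)
class SchemeConfig:
    """Scheme, census and duration of one simulated scenario."""

    scheme: str = "RC"
    n: int = 20
    t: int = 10
    candidates: int | None = None           # T, SEL only
    selected_proportion: float = 0.2        # SEL only
    natural_selection: bool = True
    tracer_spacing_bp: int = DEFAULT_TRACER_SPACING_BP
    qtl_fraction: float = 0.05
    qtl_effect_sd: float = 0.1
    environmental_variance: float = 2.0

    def __post_init__(self) -> None:
        if self.scheme not in ("RC", "EC", "SEL"):
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        if self.n < 2:
            raise ConfigurationError("n must be >= 2")
        if self.t < 0:
            raise ConfigurationError("t must be >= 0")
        if self.scheme == "EC" and self.n % 2:
            raise ConfigurationError("EC requires an even number of breeders")
        if self.scheme == "SEL":
            if not 0.0 < self.selected_proportion <= 1.0:
                raise ConfigurationError("selected_proportion must be in (0, 1]")
            t_cand = self.n_candidates
            if round(t_cand * self.selected_proportion) != self.n:
                raise ConfigurationError(
                    "SEL requires n = selected_proportion * candidates"
                )

    @property
    def n_candidates(self) -> int:
        if self.candidates is not None:
            return self.candidates
        return round(self.n / self.selected_proportion)


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive QTL architecture on the frozen SNP panel."""

    qtl_idx: np.ndarray       # column indices into the panel
    effects: np.ndarray       # per-QTL effect of the derived allele
    v_e: float

    def genotypic_values(self, x: np.ndarray) -> np.ndarray:
        if self.qtl_idx.size == 0:
            return np.zeros(np.atleast_2d(x).shape[0])
        return np.atleast_2d(x)[:, self.qtl_idx].astype(float) @ self.effects


def phenotype(x: np.ndarray, trait: TraitArchitecture,
              rng: np.random.Generator) -> np.ndarray:
    """Genotypic value plus a Normal(0, V_E) environmental deviation."""
    g = trait.genotypic_values(x)
    if trait.v_e > 0:
        g = g + rng.normal(0.0, np.sqrt(trait.v_e), size=g.shape)
    return g


class PedigreeBook:
    """Append-only record of (id, sire, dam, generation); 0 = unknown parent."""

    def __init__(self) -> None:
        self.ids: list[int] = []
        self.sires: list[int] = []
        self.dams: list[int] = []
        self.generations: list[int] = []
        self._next = 1

    def add(self, sire: int, dam: int, generation: int) -> int:
        new_id = self._next
        self._next += 1
        self.ids.append(new_id)
        self.sires.append(sire)
        self.dams.append(dam)
        self.generations.append(generation)
        return new_id

    def add_founders(self, n: int, generation: int = 0) -> np.ndarray:
        return np.array([self.add(0, 0, generation) for _ in range(n)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"id": self.ids, "sire": self.sires, "dam": self.dams,
             "generation": self.generations}
        )


@dataclass
class LineState:
    """One generation of a breeding line over the frozen base panel."""

    genome: GenomeSpec
    generation: int
    chrom: np.ndarray
    pos: np.ndarray
    s: np.ndarray
    h: np.ndarray
    H: np.ndarray              # (2n, S) uint8 over the frozen panel
    tracer_chrom: np.ndarray
    tracer_pos: np.ndarray
    T: np.ndarray              # (2n, L) int32 tracer labels
    p_base: np.ndarray         # base-generation frequency per panel SNP
    ids: np.ndarray            # pedigree ids of current individuals
    book: PedigreeBook
    fixed_log_w: float = 0.0

    @property
    def n_individuals(self) -> int:
        return self.H.shape[0] // 2

    @property
    def gpos(self) -> np.ndarray:
        return self.chrom.astype(np.int64) * self.genome.chrom_length_bp + self.pos

    @property
    def tracer_gpos(self) -> np.ndarray:
        return (self.tracer_chrom.astype(np.int64) * self.genome.chrom_length_bp
                + self.tracer_pos)

    def genotypes(self) -> np.ndarray:
        return self.H[0::2].astype(np.int64) + self.H[1::2]

    def fitness(self) -> np.ndarray:
        """Fitness relative to the best genotype at segregating panel loci."""
        return fitness_from_genotypes(self.genotypes(), self.s, self.h)


def _tracer_grid(genome: GenomeSpec, spacing_bp: int):
    """Uniformly spaced tracer loci: one per ``spacing_bp`` on each chromosome."""
    per_chrom = genome.chrom_length_bp // spacing_bp
    if per_chrom < 1:
        raise ConfigurationError("tracer spacing larger than a chromosome")
    offs = spacing_bp // 2 + spacing_bp * np.arange(per_chrom)
    chrom = np.repeat(np.arange(genome.n_chromosomes, dtype=np.int32), per_chrom)
    pos = np.tile(offs, genome.n_chromosomes).astype(np.int64)
    return chrom, pos


def sample_base(
    ancestral: PopulationState,
    n: int,
    rng: np.random.Generator,
    tracer_spacing_bp: int = DEFAULT_TRACER_SPACING_BP,
    book: PedigreeBook | None = None,
) -> LineState:
    """Found a line: sample n individuals, freeze the panel, label tracers.

    The SNP panel keeps only sites segregating among the sampled founders;
    deleterious sites fixed in the sample are folded into a constant fitness
    factor.  Tracer loci get 2n distinct labels (one per founder haplotype).
    """
    if n > ancestral.n_individuals:
        raise ConfigurationError("cannot sample more founders than the census")
    idx = rng.choice(ancestral.n_individuals, size=n, replace=False)
    hap_rows = np.empty(2 * n, np.int64)
    hap_rows[0::2] = 2 * idx
    hap_rows[1::2] = 2 * idx + 1
    H = np.ascontiguousarray(ancestral.H[hap_rows])
    counts = H.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < 2 * n)
    fixed_log_w = ancestral.fixed_log_w
    fixed_del = (~seg) & (counts == 2 * n) & (ancestral.s > 0)
    if fixed_del.any():
        with np.errstate(divide="ignore"):
            fixed_log_w += float(np.log1p(-np.minimum(ancestral.s[fixed_del], 1.0)).sum())
    tr_chrom, tr_pos = _tracer_grid(ancestral.genome, tracer_spacing_bp)
    T = np.tile(np.arange(2 * n, dtype=np.int32)[:, None], (1, tr_pos.size))
    if book is None:
        book = PedigreeBook()
    ids = book.add_founders(n)
    return LineState(
        genome=ancestral.genome,
        generation=0,
        chrom=ancestral.chrom[seg],
        pos=ancestral.pos[seg],
        s=ancestral.s[seg],
        h=ancestral.h[seg],
        H=np.ascontiguousarray(H[:, seg]),
        tracer_chrom=tr_chrom,
        tracer_pos=tr_pos,
        T=T,
        p_base=counts[seg] / (2.0 * n),
        ids=ids,
        book=book,
        fixed_log_w=fixed_log_w,
    )


def define_trait(line: LineState, rng: np.random.Generator,
                 qtl_fraction: float = 0.05, effect_sd: float = 0.1,
                 v_e: float = 2.0) -> TraitArchitecture:
    """Pick a random fraction of panel SNPs as QTL with N(0, sd²) effects."""
    n_qtl = int(round(qtl_fraction * line.chrom.size))
    qtl = (rng.choice(line.chrom.size, size=n_qtl, replace=False)
           if n_qtl else np.empty(0, np.int64))
    return TraitArchitecture(
        qtl_idx=np.sort(qtl),
        effects=rng.normal(0.0, effect_sd, size=n_qtl),
        v_e=v_e,
    )


def marker_indices(line: LineState, trait: TraitArchitecture | None = None) -> np.ndarray:
    """Panel columns usable as markers: neutral and not QTL."""
    bad = line.s > 0
    if trait is not None and trait.qtl_idx.size:
        bad = bad.copy()
        bad[trait.qtl_idx] = True
    return np.nonzero(~bad)[0]


def _make_offspring(line: LineState, sires: np.ndarray, dams: np.ndarray,
                    rng: np.random.Generator):
    """Recombinant H and T rows for offspring of the given parent indices."""
    n_off = sires.size
    par0 = np.empty(2 * n_off, np.int64)
    par0[0::2] = 2 * sires
    par0[1::2] = 2 * dams
    par1 = par0 + 1
    chrom64 = line.chrom.astype(np.int64)
    tr_chrom64 = line.tracer_chrom.astype(np.int64)
    H_new, T_new = transmit(
        [(line.H, line.gpos, chrom64), (line.T, line.tracer_gpos, tr_chrom64)],
        par0, par1, line.genome, rng,
    )
    return H_new, T_new


def _advance(line: LineState, H_new, T_new, sires, dams, record: bool = True):
    if record:
        ids = np.array([
            line.book.add(int(line.ids[s]), int(line.ids[d]), line.generation + 1)
            for s, d in zip(sires, dams)
        ])
    else:
        ids = np.full(sires.size, -1, np.int64)
    return dataclasses.replace(
        line,
        generation=line.generation + 1,
        H=np.ascontiguousarray(H_new),
        T=np.ascontiguousarray(T_new),
        ids=ids,
    )


def propagate_rc(line: LineState, rng: np.random.Generator,
                 n_offspring: int | None = None,
                 natural_selection: bool = True) -> LineState:
    """Random contributions: polygamy allowed, selfing excluded."""
    n_off = line.n_individuals if n_offspring is None else n_offspring
    weights = line.fitness() if natural_selection else None
    sires, dams = draw_parent_pairs(rng, line.n_individuals, n_off, weights)
    H_new, T_new = _make_offspring(line, sires, dams, rng)
    return _advance(line, H_new, T_new, sires, dams)


def propagate_ec(line: LineState, rng: np.random.Generator,
                 natural_selection: bool = True,
                 max_rounds: int = 200) -> LineState:
    """Equalized contributions: random couples, exactly two offspring each.

    Natural selection acts within family as offspring viability: a candidate
    offspring is accepted with probability equal to its relative fitness and
    its gametes are redrawn on rejection.
    """
    n = line.n_individuals
    if n % 2:
        raise ConfigurationError("EC requires an even number of breeders")
    perm = rng.permutation(n)
    sires = np.repeat(perm[0::2], 2)
    dams = np.repeat(perm[1::2], 2)
    H_new, T_new = _make_offspring(line, sires, dams, rng)
    if natural_selection:
        pending = np.arange(n)
        for _ in range(max_rounds):
            x = (H_new[2 * pending].astype(np.int64) + H_new[2 * pending + 1])
            w = fitness_from_genotypes(x, line.s, line.h)
            accept = rng.random(pending.size) < w
            pending = pending[~accept]
            if pending.size == 0:
                break
            H_re, T_re = _make_offspring(
                line, sires[pending], dams[pending], rng)
            rows = np.empty(2 * pending.size, np.int64)
            rows[0::2] = 2 * pending
            rows[1::2] = 2 * pending + 1
            H_new[rows] = H_re.reshape(2 * pending.size, -1)
            T_new[rows] = T_re.reshape(2 * pending.size, -1)
        else:
            raise ExtinctionError(
                f"couples {sorted(set(sires[pending]))} produced no viable "
                f"offspring in {max_rounds} rounds"
            )
    return _advance(line, H_new, T_new, sires, dams)


def select_individuals(line: LineState, idx: np.ndarray) -> LineState:
    """Restrict a line to the given individuals (e.g. after selection)."""
    idx = np.asarray(idx)
    rows = np.empty(2 * idx.size, np.int64)
    rows[0::2] = 2 * idx
    rows[1::2] = 2 * idx + 1
    return dataclasses.replace(
        line,
        H=np.ascontiguousarray(line.H[rows]),
        T=np.ascontiguousarray(line.T[rows]),
        ids=line.ids[idx],
    )


def _truncate_by_phenotype(phen: np.ndarray, n_keep: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Indices of the top n_keep phenotypes, ties broken at random."""
    order = np.lexsort((rng.random(phen.size), -phen))
    return np.sort(order[:n_keep])


def propagate_sel(line: LineState, config: SchemeConfig,
                  trait: TraitArchitecture,
                  rng: np.random.Generator) -> LineState:
    """Truncation selection on own phenotype, constant selected proportion.

    The current N parents produce T candidates exactly as under RC; the top
    N by phenotype become the next parents.  Only selected candidates enter
    the pedigree.
    """
    t_cand = config.n_candidates
    weights = line.fitness() if config.natural_selection else None
    sires, dams = draw_parent_pairs(rng, line.n_individuals, t_cand, weights)
    H_new, T_new = _make_offspring(line, sires, dams, rng)
    x = H_new[0::2].astype(np.int64) + H_new[1::2]
    phen = phenotype(x, trait, rng)
    keep = _truncate_by_phenotype(phen, config.n, rng)
    candidate_line = _advance(line, H_new, T_new, sires, dams, record=False)
    # record only the selected candidates
    selected = select_individuals(candidate_line, keep)
    ids = np.array([
        line.book.add(int(line.ids[sires[i]]), int(line.ids[dams[i]]),
                      line.generation + 1)
        for i in keep
    ])
    selected.ids = ids
    return selected


# ---------------------------------------------------------------------------
# replicate driver


@dataclass
class ReplicateResult:
    """Final-generation measurements of one replicate line."""

    config: SchemeConfig
    line: LineState
    trait: TraitArchitecture
    marker_idx: np.ndarray       # panel columns used as markers
    genotypes: np.ndarray        # individuals x markers
    p_base: np.ndarray           # base frequency of each marker
    fitness: np.ndarray
    f_ibd: np.ndarray
    f_ped: np.ndarray
    base_h2: float

    @property
    def marker_chrom(self) -> np.ndarray:
        return self.line.chrom[self.marker_idx]

    @property
    def marker_pos(self) -> np.ndarray:
        return self.line.pos[self.marker_idx]


def run_scenario(
    config: SchemeConfig,
    ancestral: PopulationState,
    rng: np.random.Generator | int | None = None,
) -> ReplicateResult:
    """Found a line, run t generations of the configured scheme, measure.

    Under SEL the base population is the T random founders, from which the
    first N parents are selected on phenotype; the base panel, frequencies and
    tracer labels refer to the T founders.
    """
    from .estimators import f_ibd as _f_ibd
    from .estimators import f_ped as _f_ped

    rng = np.random.default_rng(rng)
    n_found = config.n_candidates if config.scheme == "SEL" else config.n
    line = sample_base(ancestral, n_found, rng,
                       tracer_spacing_bp=config.tracer_spacing_bp)
    trait = define_trait(line, rng, config.qtl_fraction,
                         config.qtl_effect_sd, config.environmental_variance)
    # realized base heritability of the neutral trait
    x0 = line.genotypes()
    g0 = trait.genotypic_values(x0)
    v_g = float(np.var(g0, ddof=1)) if g0.size > 1 else 0.0
    base_h2 = v_g / (v_g + trait.v_e) if (v_g + trait.v_e) > 0 else 0.0

    if config.scheme == "SEL":
        phen0 = phenotype(x0, trait, rng)
        line = select_individuals(line, _truncate_by_phenotype(phen0, config.n, rng))
    for _ in range(config.t):
        if config.scheme == "RC":
            line = propagate_rc(line, rng, natural_selection=config.natural_selection)
        elif config.scheme == "EC":
            line = propagate_ec(line, rng, natural_selection=config.natural_selection)
        else:
            line = propagate_sel(line, config, trait, rng)

    marker_idx = marker_indices(line, trait)
    x = line.genotypes()
    book = line.book
    return ReplicateResult(
        config=config,
        line=line,
        trait=trait,
        marker_idx=marker_idx,
        genotypes=x[:, marker_idx],
        p_base=line.p_base[marker_idx],
        fitness=line.fitness(),
        f_ibd=_f_ibd(line.T),
        f_ped=_f_ped(book.ids, book.sires, book.dams, line.ids),
        base_h2=base_h2,
    )
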