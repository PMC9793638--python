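"""Forward-in-time Wright--Fisher engine with partially recessive deleterious mutations.

The engine simulates a diploid, monoecious, randomly mating population with
discrete generations under an infinite-sites mutation model.  Each new mutation
is neutral or deleterious; deleterious mutations draw a homozygous selection
coefficient ``s`` from an exponential distribution and a dominance coefficient
``h`` uniform on ``(0, e^(-k s))``, so that rarer, more damaging mutations tend
to be more recessive.  Fitness is multiplicative across loci with genotype
values 1, 1-sh and 1-s, and acts through fitness-proportional sampling of
parents.  Recombination is Poisson without interference, uniform along each
chromosome, with free assortment between chromosomes.

A long burn-in of a moderately large population produces the mutation--
selection--drift equilibrium "large initial population" from which small lines
are founded (see :mod:`inbredsim.breeding`).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numba
import numpy as np

__all__ = [
    "GenomeSpec",
    "EffectModel",
    "ModelPreset",
    "PRESETS",
    "PopulationState",
    "ExtinctionError",
    "ConfigurationError",
    "calibrate_k",
    "draw_mutation_effects",
    "fitness_from_genotypes",
    "make_gamete",
    "draw_parent_pairs",
    "transmit",
    "wf_generation",
    "burn_in",
    "empty_population",
    "save_population",
    "load_population",
    "sites_table",
]

logger = logging.getLogger("inbredsim")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class ExtinctionError(RuntimeError):
    """Every candidate parent (or offspring) has fitness zero."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome layout and per-bp rates.

    Defaults describe a pig-like genome: 18 chromosomes of 125 Mb, 0.8 cM/Mb
    (about one crossover per chromosome per meiosis) and a mutation rate that
    yields on the order of 10^5 segregating SNPs in a population of 500 at
    equilibrium.  Scaled-down genomes (fewer or shorter chromosomes, same
    per-bp rates) are used for desk-scale runs.
    """

    n_chromosomes: int = 18
    chrom_length_bp: int = 125_000_000
    recomb_rate: float = 8e-9
    mut_rate: float = 4e-9
    deleterious_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        if self.chrom_length_bp < 1:
            raise ConfigurationError("chrom_length_bp must be >= 1")
        for name in ("recomb_rate", "mut_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.deleterious_fraction <= 1.0:
            raise ConfigurationError("deleterious_fraction must be in [0, 1]")

    @property
    def total_length_bp(self) -> int:
        return self.n_chromosomes * self.chrom_length_bp

    def scaled(self, n_chromosomes: int | None = None,
               chrom_length_bp: int | None = None) -> "GenomeSpec":
        """Return a copy with a smaller genome but identical per-bp rates."""
        return dataclasses.replace(
            self,
            n_chromosomes=n_chromosomes if n_chromosomes is not None else self.n_chromosomes,
            chrom_length_bp=chrom_length_bp if chrom_length_bp is not None else self.chrom_length_bp,
        )


def calibrate_k(mean_s: float, mean_h: float) -> float:
    """Decay constant of the h--s relationship.

    With ``s ~ Exponential(mean_s)`` and ``h | s ~ Uniform(0, e^(-k s))`` the
    expected dominance coefficient is ``E[h] = 1 / (2 (1 + k mean_s))``;
    solving for ``k`` gives the closed form below.  ``mean_h`` may not exceed
    0.5 (the mean of a Uniform(0, 1) draw, reached at k = 0).
    """
    if mean_s <= 0:
        raise ConfigurationError("mean_s must be > 0")
    if not 0.0 < mean_h <= 0.5:
        raise ConfigurationError("mean_h must be in (0, 0.5]")
    return (1.0 / (2.0 * mean_h) - 1.0) / mean_s


@dataclass(frozen=True)
class EffectModel:
    """Mutation-effect model: exponential s, h uniform on (0, e^(-k s)).

    ``k`` is derived from the target mean dominance coefficient; draws of s
    exceeding 1 are capped at 1 (lethal), which affects <0.005% of draws at
    the default mean.
    """

    mean_s: float = 0.1
    mean_h: float = 0.2
    k: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", calibrate_k(self.mean_s, self.mean_h))


@dataclass(frozen=True)
class ModelPreset:
    name: str
    genome: GenomeSpec
    effects: EffectModel


#: The three mutation models: default, a higher SNP density (same deleterious
#: genomic rate, achieved by a larger total rate with a smaller deleterious
#: fraction), and an alternative with weaker, more numerous deleterious
#: mutations (double the deleterious mutation rate at the default total rate).
PRESETS: dict[str, ModelPreset] = {
    "default": ModelPreset("default", GenomeSpec(), EffectModel(0.1, 0.2)),
    "high_density": ModelPreset(
        "high_density",
        GenomeSpec(mut_rate=9e-9, deleterious_fraction=0.0222),
        EffectModel(0.1, 0.2),
    ),
    "alternative": ModelPreset(
        "alternative",
        GenomeSpec(deleterious_fraction=0.10),
        EffectModel(0.025, 0.2),
    ),
}


def draw_mutation_effects(
    rng: np.random.Generator,
    model: EffectModel,
    fraction: float,
    size: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw mutation classes and effects for ``size`` new mutations.

    Returns ``(deleterious, s, h)``: a boolean mask and the per-site selection
    and dominance coefficients.  Neutral sites have s = 0 (h is irrelevant and
    set to 0.5).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("deleterious fraction must be in [0, 1]")
    deleterious = rng.random(size) < fraction
    s = np.zeros(size)
    h = np.full(size, 0.5)
    n_del = int(deleterious.sum())
    if n_del:
        sd = np.minimum(rng.exponential(model.mean_s, n_del), 1.0)
        hd = rng.uniform(0.0, np.exp(-model.k * sd))
        s[deleterious] = sd
        h[deleterious] = hd
    return deleterious, s, h


# ---------------------------------------------------------------------------
# fitness


def fitness_from_genotypes(
    x: np.ndarray,
    s: np.ndarray,
    h: np.ndarray,
    fixed_log_w: float = 0.0,
) -> np.ndarray:
    """Multiplicative fitness of genotype rows over the deleterious sites.

    ``x`` holds 0/1/2 derived-allele counts (individuals x sites).  Genotype
    factors are 1, 1-sh and 1-s; neutral sites (s = 0) contribute factor 1.
    ``fixed_log_w`` accumulates the log-fitness of deleterious sites fixed in
    the whole population (a constant factor shared by everyone).
    """
    x = np.atleast_2d(x)
    dele = s > 0
    if not dele.any():
        return np.exp(np.full(x.shape[0], fixed_log_w))
    xd = x[:, dele]
    f_het = 1.0 - s[dele] * h[dele]
    f_hom = 1.0 - s[dele]
    het = (xd == 1)
    hom = (xd == 2)
    dead = (het & (f_het <= 0)).any(axis=1) | (hom & (f_hom <= 0)).any(axis=1)
    with np.errstate(divide="ignore"):
        log_het = np.where(f_het > 0, np.log(np.maximum(f_het, 1e-300)), 0.0)
        log_hom = np.where(f_hom > 0, np.log(np.maximum(f_hom, 1e-300)), 0.0)
    logw = het.astype(np.float64) @ log_het + hom.astype(np.float64) @ log_hom
    w = np.exp(logw + fixed_log_w)
    w[dead] = 0.0
    return w


# ---------------------------------------------------------------------------
# population state


@dataclass
class PopulationState:
    """One generation of a simulated population.

    Haplotypes are stored as a dense 0/1 matrix ``H`` of shape
    ``(2 N, n_sites)`` over the currently segregating sites, sorted by
    (chromosome, position); individual ``i`` owns rows ``2i`` and ``2i+1``.
    ``sire``/``dam`` index the previous generation (-1 for founders).
    """

    genome: GenomeSpec
    effects: EffectModel
    generation: int
    chrom: np.ndarray   # (S,) int32
    pos: np.ndarray     # (S,) int64, 1-based within chromosome
    s: np.ndarray       # (S,) float64
    h: np.ndarray       # (S,) float64
    H: np.ndarray       # (2N, S) uint8
    sire: np.ndarray    # (N,) int64
    dam: np.ndarray     # (N,) int64
    fixed_log_w: float = 0.0

    @property
    def n_individuals(self) -> int:
        return self.H.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.H.shape[1]

    @property
    def gpos(self) -> np.ndarray:
        """Global coordinate: chromosome index * chromosome length + position."""
        return self.chrom.astype(np.int64) * self.genome.chrom_length_bp + self.pos

    def derived_counts(self) -> np.ndarray:
        return self.H.sum(axis=0, dtype=np.int64)

    def frequencies(self) -> np.ndarray:
        return self.derived_counts() / self.H.shape[0]

    def genotypes(self) -> np.ndarray:
        """Individuals x sites matrix of 0/1/2 derived-allele counts."""
        return (self.H[0::2].astype(np.int64) + self.H[1::2])

    def fitness(self, include_fixed: bool = False) -> np.ndarray:
        """Per-individual fitness over segregating deleterious sites.

        By default the constant factor from fixed deleterious sites is left
        out: selection and the regression of log fitness on F are invariant
        to it, and it keeps fitness interpretable as relative to the best
        segregating genotype.
        """
        return fitness_from_genotypes(
            self.genotypes(), self.s, self.h,
            self.fixed_log_w if include_fixed else 0.0,
        )


def empty_population(genome: GenomeSpec, effects: EffectModel, n: int) -> PopulationState:
    """Founders with no segregating variation (mutation happens in meiosis)."""
    if n < 2:
        raise ConfigurationError("population size must be >= 2")
    return PopulationState(
        genome=genome,
        effects=effects,
        generation=0,
        chrom=np.empty(0, np.int32),
        pos=np.empty(0, np.int64),
        s=np.empty(0, np.float64),
        h=np.empty(0, np.float64),
        H=np.zeros((2 * n, 0), np.uint8),
        sire=np.full(n, -1, np.int64),
        dam=np.full(n, -1, np.int64),
    )


def sites_table(state: PopulationState):
    """Segregating sites as a DataFrame (chrom, pos, s, h, derived count)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": state.chrom,
            "pos": state.pos,
            "s": state.s,
            "h": state.h,
            "derived_count": state.derived_counts(),
        }
    )


# ---------------------------------------------------------------------------
# meiosis


@numba.njit(cache=True)
def _transmit_kernel(M, gpos, chrom_of, par0, par1, phases, co, co_off, chrom_len, out):  # pragma: no cover - numba
    n_gam = par0.shape[0]
    n_sites = gpos.shape[0]
    for g in range(n_gam):
        k = co_off[g]
        k_end = co_off[g + 1]
        cur_chrom = -1
        cur = np.uint8(0)
        r0 = par0[g]
        r1 = par1[g]
        for j in range(n_sites):
            c = chrom_of[j]
            if c != cur_chrom:
                cur_chrom = c
                cur = phases[g, c]
            while k < k_end and co[k] < gpos[j]:
                if np.int64(co[k] // chrom_len) == c:
                    cur ^= np.uint8(1)
                k += 1
            if cur == 0:
                out[g, j] = M[r0, j]
            else:
                out[g, j] = M[r1, j]


def _draw_meiosis(rng: np.random.Generator, n_gametes: int, genome: GenomeSpec):
    """Crossover coordinates and starting phases shared by all site panels."""
    n_chrom = genome.n_chromosomes
    lam = genome.chrom_length_bp * genome.recomb_rate
    counts = rng.poisson(lam, size=(n_gametes, n_chrom))
    phases = rng.integers(0, 2, size=(n_gametes, n_chrom), dtype=np.uint8)
    per_gamete = counts.sum(axis=1)
    total = int(per_gamete.sum())
    if total:
        gamete_of = np.repeat(np.arange(n_gametes), per_gamete)
        chrom_of = np.repeat(np.tile(np.arange(n_chrom), n_gametes), counts.ravel())
        coords = chrom_of * float(genome.chrom_length_bp) + rng.random(total) * genome.chrom_length_bp
        order = np.lexsort((coords, gamete_of))
        co = coords[order]
    else:
        co = np.empty(0, np.float64)
    co_off = np.zeros(n_gametes + 1, np.int64)
    np.cumsum(per_gamete, out=co_off[1:])
    return co, co_off, phases


def transmit(
    panels: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    par0: np.ndarray,
    par1: np.ndarray,
    genome: GenomeSpec,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Form one recombinant gamete per (par0, par1) haplotype-row pair.

    ``panels`` is a list of ``(matrix, gpos, chrom_of)`` triples sharing the
    same haplotype rows (e.g. the SNP matrix and the IBD-tracer matrix); all
    panels use the same crossovers and chromosome phases, so linked loci in
    different panels co-segregate correctly.
    """
    par0 = np.ascontiguousarray(par0, dtype=np.int64)
    par1 = np.ascontiguousarray(par1, dtype=np.int64)
    co, co_off, phases = _draw_meiosis(rng, len(par0), genome)
    outs = []
    for M, gpos, chrom_of in panels:
        out = np.empty((len(par0), M.shape[1]), dtype=M.dtype)
        _transmit_kernel(
            np.ascontiguousarray(M),
            np.ascontiguousarray(gpos, dtype=np.int64),
            np.ascontiguousarray(chrom_of, dtype=np.int64),
            par0, par1, phases, co, co_off,
            float(genome.chrom_length_bp), out,
        )
        outs.append(out)
    return outs


def make_gamete(
    haplotype_pair: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    genome: GenomeSpec,
    rng: np.random.Generator,
    effects: EffectModel | None = None,
):
    """One gamete from a (2, S) haplotype pair.

    Returns ``(gamete, new_sites)`` where ``new_sites`` is a list of
    ``(chrom, pos, s, h)`` tuples for fresh mutations (empty when the genome's
    mutation rate is zero).  Batch reproduction uses :func:`transmit` plus
    generation-level mutation instead.
    """
    gpos = chrom.astype(np.int64) * genome.chrom_length_bp + pos
    (gam,) = transmit(
        [(np.ascontiguousarray(haplotype_pair), gpos, chrom.astype(np.int64))],
        np.array([0]), np.array([1]), genome, rng,
    )
    new_sites: list[tuple[int, int, float, float]] = []
    if genome.mut_rate > 0:
        n_new = rng.poisson(genome.mut_rate * genome.total_length_bp)
        if n_new:
            model = effects if effects is not None else EffectModel()
            taken = set(gpos.tolist())
            _, s_new, h_new = draw_mutation_effects(
                rng, model, genome.deleterious_fraction, n_new)
            for i in range(n_new):
                while True:
                    c = int(rng.integers(genome.n_chromosomes))
                    p = int(rng.integers(1, genome.chrom_length_bp + 1))
                    g = c * genome.chrom_length_bp + p
                    if g not in taken:
                        taken.add(g)
                        break
                new_sites.append((c, p, float(s_new[i]), float(h_new[i])))
    return gam[0], new_sites


# ---------------------------------------------------------------------------
# reproduction


def draw_parent_pairs(
    rng: np.random.Generator,
    n_parents: int,
    n_offspring: int,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fitness-proportional sampling of two distinct parents per offspring.

    Each parental slot is drawn independently proportional to ``weights``
    (uniform when None); dams colliding with their sire are redrawn, which
    makes ordered distinct pairs equiprobable under equal weights.
    """
    if n_parents < 2:
        raise ConfigurationError("need at least two parents (no selfing)")
    p = None
    if weights is not None:
        total = weights.sum()
        if total <= 0:
            raise ExtinctionError("all parental fitness values are zero")
        p = weights / total
        if (p > 0).sum() < 2:
            raise ExtinctionError("fewer than two parents with positive fitness")
    sires = rng.choice(n_parents, size=n_offspring, p=p)
    dams = rng.choice(n_parents, size=n_offspring, p=p)
    clash = sires == dams
    while clash.any():
        dams[clash] = rng.choice(n_parents, size=int(clash.sum()), p=p)
        clash = sires == dams
    return sires, dams


def _apply_mutations(state_H, chrom, pos, s, h, gpos, genome, effects, rng):
    """Append Poisson new mutations as fresh singleton columns (infinite sites)."""
    n_hap = state_H.shape[0]
    n_new = rng.poisson(genome.mut_rate * genome.total_length_bp * n_hap)
    if n_new == 0:
        return state_H, chrom, pos, s, h
    rows = rng.integers(0, n_hap, n_new)
    sorted_gpos = np.sort(gpos)
    new_gpos = np.empty(n_new, np.int64)
    taken: set[int] = set()
    for i in range(n_new):
        while True:
            c = int(rng.integers(genome.n_chromosomes))
            p = int(rng.integers(1, genome.chrom_length_bp + 1))
            g = c * genome.chrom_length_bp + p
            j = np.searchsorted(sorted_gpos, g)
            collided = (j < len(sorted_gpos) and sorted_gpos[j] == g) or g in taken
            if not collided:
                taken.add(g)
                new_gpos[i] = g
                break
    _, s_new, h_new = draw_mutation_effects(rng, effects, genome.deleterious_fraction, n_new)
    cols = np.zeros((n_hap, n_new), np.uint8)
    cols[rows, np.arange(n_new)] = 1
    H2 = np.concatenate([state_H, cols], axis=1)
    chrom2 = np.concatenate([chrom, (new_gpos // genome.chrom_length_bp).astype(np.int32)])
    pos2 = np.concatenate([pos, new_gpos % genome.chrom_length_bp])
    s2 = np.concatenate([s, s_new])
    h2 = np.concatenate([h, h_new])
    return H2, chrom2, pos2, s2, h2


def wf_generation(
    state: PopulationState,
    n_offspring: int,
    rng: np.random.Generator,
    selection: bool = True,
) -> PopulationState:
    """One Wright--Fisher generation: sample parents, recombine, mutate, prune.

    Lost columns are dropped; fixed columns are dropped with fixed deleterious
    sites folded into ``fixed_log_w``.
    """
    n_par = state.n_individuals
    weights = state.fitness() if (selection and state.n_sites) else None
    sires, dams = draw_parent_pairs(rng, n_par, n_offspring, weights)

    par0 = np.empty(2 * n_offspring, np.int64)
    par0[0::2] = 2 * sires
    par0[1::2] = 2 * dams
    par1 = par0 + 1
    gpos = state.gpos
    (H_child,) = transmit(
        [(state.H, gpos, state.chrom.astype(np.int64))], par0, par1, state.genome, rng
    )

    chrom, pos, s, h = state.chrom, state.pos, state.s, state.h
    fixed_log_w = state.fixed_log_w
    if state.genome.mut_rate > 0:
        H_child, chrom, pos, s, h = _apply_mutations(
            H_child, chrom, pos, s, h, gpos, state.genome, state.effects, rng
        )

    counts = H_child.sum(axis=0, dtype=np.int64)
    n_hap = H_child.shape[0]
    fixed = counts == n_hap
    if fixed.any():
        s_fixed = s[fixed]
        if (s_fixed >= 1.0).any():
            raise ExtinctionError("a lethal mutation reached fixation")
        fixed_log_w += float(np.log1p(-s_fixed).sum())
    keep = (counts > 0) & ~fixed
    g2 = chrom[keep].astype(np.int64) * state.genome.chrom_length_bp + pos[keep]
    order = np.argsort(g2, kind="stable")
    return PopulationState(
        genome=state.genome,
        effects=state.effects,
        generation=state.generation + 1,
        chrom=chrom[keep][order],
        pos=pos[keep][order],
        s=s[keep][order],
        h=h[keep][order],
        H=np.ascontiguousarray(H_child[:, keep][:, order]),
        sire=sires.astype(np.int64),
        dam=dams.astype(np.int64),
        fixed_log_w=fixed_log_w,
    )


def burn_in(
    genome: GenomeSpec,
    n: int,
    generations: int,
    effects: EffectModel | None = None,
    rng: np.random.Generator | int | None = None,
    selection: bool = True,
) -> PopulationState:
    """Evolve an initially variation-free population to (near-)equilibrium.

    With ``generations`` of order 10 N the segregating-site count and pairwise
    diversity settle at mutation--(selection)--drift equilibrium; the returned
    state is the "large initial population" from which lines are founded.
    """
    if generations < 0:
        raise ConfigurationError("generations must be >= 0")
    if effects is None:
        effects = EffectModel()
    rng = np.random.default_rng(rng)
    state = empty_population(genome, effects, n)
    log_every = max(1, generations // 10)
    for t in range(generations):
        state = wf_generation(state, n, rng, selection=selection)
        if (t + 1) % log_every == 0 or t + 1 == generations:
            dele = state.s > 0
            q = state.frequencies()[dele]
            d = state.s[dele] * (1 - 2 * state.h[dele]) / 2.0
            b = float((2 * d * (1 - q) * q).sum())
            logger.info(
                "burn-in generation %d/%d: %d segregating sites, mean w=%.4f, B=%.4f",
                t + 1, generations, state.n_sites,
                float(state.fitness().mean()) if state.n_sites else 1.0, b,
            )
    return state


# ---------------------------------------------------------------------------
# serialization


def save_population(path, state: PopulationState) -> None:
    """Archive a population snapshot as a compressed ``.npz`` container."""
    np.savez_compressed(
        path,
        n_chromosomes=state.genome.n_chromosomes,
        chrom_length_bp=state.genome.chrom_length_bp,
        recomb_rate=state.genome.recomb_rate,
        mut_rate=state.genome.mut_rate,
        deleterious_fraction=state.genome.deleterious_fraction,
        mean_s=state.effects.mean_s,
        mean_h=state.effects.mean_h,
        generation=state.generation,
        chrom=state.chrom,
        pos=state.pos,
        s=state.s,
        h=state.h,
        H=state.H,
        sire=state.sire,
        dam=state.dam,
        fixed_log_w=state.fixed_log_w,
    )


def load_population(path) -> PopulationState:
    with np.load(path) as z:
        genome = GenomeSpec(
            n_chromosomes=int(z["n_chromosomes"]),
            chrom_length_bp=int(z["chrom_length_bp"]),
            recomb_rate=float(z["recomb_rate"]),
            mut_rate=float(z["mut_rate"]),
            deleterious_fraction=float(z["deleterious_fraction"]),
        )
        effects = EffectModel(float(z["mean_s"]), float(z["mean_h"]))
        return PopulationState(
            genome=genome,
            effects=effects,
            generation=int(z["generation"]),
            chrom=z["chrom"],
            pos=z["pos"],
            s=z["s"],
            h=z["h"],
            H=z["H"],
            sire=z["sire"],
            dam=z["dam"],
            fixed_log_w=float(z["fixed_log_w"]),
        )
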