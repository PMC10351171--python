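"""Forward-in-time simulation of a breeding population and an additive trait.

The simulator produces, from a single configuration object:

* a historical random-mating population run over a schedule of population
  sizes (drift + recurrent mutation, no selection),
* a recent pedigreed population bred from a fixed number of sires and dams
  with age-based replacement of breeders,
* a genome map of biallelic loci split into neutral markers (SNP) and
  causal variants (QTN) after a minor-allele-frequency filter,
* gamma-distributed QTN effects rescaled to an exact additive variance, and
* phenotypes = mean + true breeding value + normal residual.

Meiosis follows the Haldane model (Poisson crossovers, no interference),
implemented as the equivalent two-state Markov chain over loci so whole
cohorts of gametes are produced in one vectorized pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import as_rng, spawn_rng

__all__ = [
    "SimConfig",
    "GenomeMap",
    "Population",
    "TraitArchitecture",
    "PhenotypeSet",
    "SimResult",
    "ConfigError",
    "SimulationError",
    "random_genome_map",
    "recombine_gamete",
    "simulate_historical",
    "select_founders",
    "simulate_recent",
    "filter_segregating_maf",
    "sample_qtn_effects",
    "assign_phenotypes",
    "simulate",
]

MALE, FEMALE = 1, 2

FULL_GENOME_MORGANS = 23.19
FULL_N_CHROMOSOMES = 29


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class SimulationError(RuntimeError):
    """The simulation cannot proceed (e.g. not enough replacement animals)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulation; defaults reproduce the full-scale design.

    ``scale_factor`` < 1 shrinks the genome (chromosome count and lengths),
    the marker/QTN targets and the historical schedule proportionally so the
    whole pipeline runs at desk scale; the breeding design (sires, dams,
    recent generations) is left untouched because it controls the effective
    population size.
    """

    n_chromosomes: int = FULL_N_CHROMOSOMES
    chrom_lengths: tuple[float, ...] | None = None  # Morgans; default: equal split
    total_length: float = FULL_GENOME_MORGANS
    n_snp_target: int = 500_000
    n_qtn_target: int = 200
    maf_min: float = 0.05
    mutation_rate: float = 2.5e-5
    hist_schedule: tuple[tuple[int, int], ...] = (
        (-2000, 1_000),
        (-1000, 50_000),
        (0, 20_000),
    )
    n_sires: int = 50
    n_dams: int = 15_000
    n_generations_recent: int = 20
    replacement_sire: float = 0.80
    replacement_dam: float = 0.30
    genotyped_generations: tuple[int, ...] = (16, 17, 18, 19, 20)
    phenotyped_generations: tuple[int, ...] = tuple(range(11, 21))
    h2: float = 0.3
    mean: float = 1.0
    phenotypic_variance: float = 1.0
    qtn_gamma_shape: float = 0.4
    chip_step: int = 10
    candidate_factor: float = 1.5
    seed: int = 0
    scale_factor: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.maf_min < 0.5):
            raise ConfigError(f"maf_min must be in (0, 0.5), got {self.maf_min}")
        if not (0.0 < self.h2 <= 1.0):
            raise ConfigError(f"h2 must be in (0, 1], got {self.h2}")
        if self.n_sires < 1 or self.n_dams < 1:
            raise ConfigError("need at least one sire and one dam")
        gens = [g for g, _ in self.hist_schedule]
        if sorted(gens) != gens or len(set(gens)) != len(gens):
            raise ConfigError("hist_schedule generations must be strictly increasing")
        if any(n < 2 for _, n in self.hist_schedule):
            raise ConfigError("historical population size must be >= 2")
        if self.n_chromosomes < 1:
            raise ConfigError("need at least one chromosome")

    @property
    def lengths(self) -> np.ndarray:
        """Per-chromosome genetic lengths in Morgans."""
        if self.chrom_lengths is not None:
            if len(self.chrom_lengths) != self.n_chromosomes:
                raise ConfigError("chrom_lengths does not match n_chromosomes")
            return np.asarray(self.chrom_lengths, dtype=float)
        return np.full(self.n_chromosomes, self.total_length / self.n_chromosomes)

    @property
    def sigma_u2(self) -> float:
        """Target additive variance; equals h2 when phenotypic variance is 1."""
        return self.h2 * self.phenotypic_variance

    def scaled(self) -> "SimConfig":
        """Apply ``scale_factor`` to genome size, marker targets and history."""
        s = self.scale_factor
        if s == 1.0:
            return self
        if not (0 < s <= 1):
            raise ConfigError("scale_factor must be in (0, 1]")
        n_chrom = max(1, round(self.n_chromosomes * s))
        gens = [round(g * s) if g != 0 else 0 for g, _ in self.hist_schedule]
        for i in range(len(gens) - 2, -1, -1):  # keep strictly increasing
            if gens[i] >= gens[i + 1]:
                gens[i] = gens[i + 1] - 1
        sched = tuple(
            (g, max(4, round(n * s))) for g, (_, n) in zip(gens, self.hist_schedule)
        )
        return replace(
            self,
            scale_factor=1.0,
            n_chromosomes=n_chrom,
            total_length=self.total_length * s,
            chrom_lengths=None,
            n_snp_target=max(10, round(self.n_snp_target * s)),
            n_qtn_target=max(2, round(self.n_qtn_target * s)),
            hist_schedule=sched,
        )


# ---------------------------------------------------------------------------
# genome map
# ---------------------------------------------------------------------------


@dataclass
class GenomeMap:
    """Ordered biallelic loci: (chromosome, genetic position, id, class)."""

    table: pd.DataFrame  # columns: chrom, pos, locus_id, cls

    def __post_init__(self):
        t = self.table
        required = {"chrom", "pos", "locus_id", "cls"}
        if not required.issubset(t.columns):
            raise ValueError(f"genome map needs columns {sorted(required)}")
        self.table = t.reset_index(drop=True)
        self._validate()

    def _validate(self):
        t = self.table
        if t["locus_id"].duplicated().any():
            raise ValueError("duplicate locus ids in genome map")
        for _, grp in t.groupby("chrom", sort=False):
            d = np.diff(grp["pos"].to_numpy())
            if np.any(d < 0):
                raise ValueError("positions must be non-decreasing within chromosome")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def locus_ids(self) -> np.ndarray:
        return self.table["locus_id"].to_numpy()

    @property
    def cls(self) -> np.ndarray:
        return self.table["cls"].to_numpy()

    @property
    def snp_mask(self) -> np.ndarray:
        return self.cls == "SNP"

    @property
    def qtn_mask(self) -> np.ndarray:
        return self.cls == "QTN"

    def switch_probs(self) -> np.ndarray:
        """Per adjacent locus pair: probability the gamete switches parental
        haplotype (Haldane map function within a chromosome, 1/2 across
        chromosome boundaries = independent assortment)."""
        chrom, pos = self.chrom, self.pos
        if len(pos) < 2:
            return np.empty(0)
        d = np.diff(pos)
        p = 0.5 * (1.0 - np.exp(-2.0 * d))
        p[chrom[1:] != chrom[:-1]] = 0.5
        return p


def random_genome_map(
    config: SimConfig, rng=None, n_loci: int | None = None, cls: str = "SNP"
) -> GenomeMap:
    """Place ``n_loci`` candidate loci uniformly at random on the genome.

    Loci are allocated to chromosomes with probability proportional to
    genetic length and sorted by position; ids follow genome order.
    """
    rng = as_rng(rng)
    lengths = config.lengths
    if n_loci is None:
        n_loci = math.ceil(
            (config.n_snp_target + config.n_qtn_target) * config.candidate_factor
        )
    counts = rng.multinomial(n_loci, lengths / lengths.sum())
    rows = []
    for c, (n_c, length) in enumerate(zip(counts, lengths), start=1):
        pos = np.sort(rng.uniform(0.0, length, size=n_c))
        rows.append(pd.DataFrame({"chrom": c, "pos": pos}))
    table = pd.concat(rows, ignore_index=True)
    table["locus_id"] = np.arange(len(table))
    table["cls"] = cls
    return GenomeMap(table)


# ---------------------------------------------------------------------------
# population container
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """Pedigree plus phased haplotypes over a genome map.

    ``pedigree`` columns: id, sire, dam, sex, generation, genotyped.
    Row order is the id order and is topological (parents precede offspring;
    0 denotes an unknown parent).  ``haplotypes`` has shape
    (n_individuals, 2, n_loci) with 0/1 alleles.
    """

    pedigree: pd.DataFrame
    haplotypes: np.ndarray
    genome_map: GenomeMap

    def __post_init__(self):
        self.pedigree = self.pedigree.reset_index(drop=True)
        n = len(self.pedigree)
        if self.haplotypes.shape != (n, 2, len(self.genome_map)):
            raise ValueError(
                f"haplotype array shape {self.haplotypes.shape} does not match "
                f"{n} individuals x 2 x {len(self.genome_map)} loci"
            )
        self._id_to_row = pd.Series(
            np.arange(n), index=self.pedigree["id"].to_numpy()
        )

    def __len__(self) -> int:
        return len(self.pedigree)

    @property
    def ids(self) -> np.ndarray:
        return self.pedigree["id"].to_numpy()

    def rows_of(self, ids) -> np.ndarray:
        return self._id_to_row.loc[np.asarray(ids)].to_numpy()

    def genotypes(self, ids=None, loci=None) -> np.ndarray:
        """Dosage matrix (0/1/2) for the given animals and locus indices."""
        h = self.haplotypes
        if ids is not None:
            h = h[self.rows_of(ids)]
        g = h.sum(axis=1, dtype=np.int16)
        if loci is not None:
            g = g[:, np.asarray(loci)]
        return g

    def allele_freqs(self, ids=None) -> np.ndarray:
        g = self.genotypes(ids=ids)
        return g.mean(axis=0) / 2.0

    def founder_ids(self) -> np.ndarray:
        gmin = self.pedigree["generation"].min()
        return self.pedigree.loc[self.pedigree["generation"] == gmin, "id"].to_numpy()

    def genotyped_ids(self) -> np.ndarray:
        return self.pedigree.loc[self.pedigree["genotyped"], "id"].to_numpy()

    def subset_loci(self, genome_map: GenomeMap) -> "Population":
        """Restrict haplotypes to the loci of ``genome_map`` (matched by id)."""
        pos = pd.Series(
            np.arange(len(self.genome_map)), index=self.genome_map.locus_ids
        )
        idx = pos.loc[genome_map.locus_ids].to_numpy()
        return Population(
            self.pedigree.copy(), np.ascontiguousarray(self.haplotypes[:, :, idx]),
            genome_map,
        )

    def subset_individuals(self, ids) -> "Population":
        rows = self.rows_of(ids)
        return Population(
            self.pedigree.iloc[rows].copy(), self.haplotypes[rows], self.genome_map
        )


def _empty_pedigree(n: int) -> dict:
    return {
        "id": np.arange(1, n + 1, dtype=np.int64),
        "sire": np.zeros(n, dtype=np.int64),
        "dam": np.zeros(n, dtype=np.int64),
        "sex": np.zeros(n, dtype=np.int8),
        "generation": np.zeros(n, dtype=np.int32),
        "genotyped": np.zeros(n, dtype=bool),
    }


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _gamete_batch(
    parent_haps: np.ndarray,
    genome_map: GenomeMap,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
    switch_p: np.ndarray | None = None,
) -> np.ndarray:
    """One gamete per parent, shape (m, n_loci).

    The Poisson crossover process with no interference is marginally a
    two-state Markov chain over loci: the parental haplotype in use starts
    uniformly and switches between adjacent loci with probability
    c = (1 - exp(-2d))/2 (d in Morgans), or 1/2 across chromosomes.
    """
    m, two, n_loci = parent_haps.shape
    if two != 2:
        raise ValueError("parent haplotypes must have shape (m, 2, n_loci)")
    if n_loci == 0:
        return np.empty((m, 0), dtype=parent_haps.dtype)
    if switch_p is None:
        switch_p = genome_map.switch_probs()
    start = rng.integers(0, 2, size=(m, 1), dtype=np.int8)
    if n_loci > 1:
        switches = (rng.random((m, n_loci - 1)) < switch_p).astype(np.int8)
        state = (start + np.cumsum(switches, axis=1, dtype=np.int32) % 2) % 2
        state = np.concatenate([start, state.astype(np.int8)], axis=1)
    else:
        state = start
    gamete = np.take_along_axis(parent_haps, state[:, None, :], axis=1)[:, 0, :]
    if mutation_rate > 0.0:
        flips = rng.random((m, n_loci)) < mutation_rate
        gamete = gamete ^ flips
    return gamete


def recombine_gamete(
    parent_haplotypes: np.ndarray,
    genome_map: GenomeMap,
    rng=None,
    mutation_rate: float = 0.0,
) -> np.ndarray:
    """Single gamete from a (2, n_loci) pair of parental haplotypes."""
    rng = as_rng(rng)
    return _gamete_batch(
        parent_haplotypes[None, :, :], genome_map, rng, mutation_rate
    )[0]


# ---------------------------------------------------------------------------
# historical population
# ---------------------------------------------------------------------------


def _schedule_sizes(schedule) -> np.ndarray:
    """Per-generation population size, linearly interpolated between anchors."""
    gens = np.array([g for g, _ in schedule])
    sizes = np.array([n for _, n in schedule], dtype=float)
    grid = np.arange(gens[0], gens[-1] + 1)
    out = np.rint(np.interp(grid, gens, sizes)).astype(int)
    if np.any(out < 2):
        raise ConfigError("interpolated historical size fell below 2")
    return out


def simulate_historical(
    config: SimConfig, rng=None, genome_map: GenomeMap | None = None
) -> Population:
    """Random union of gametes over the historical schedule; returns the final
    generation (generation 0) only.  Founder allele frequencies are 0.5."""
    rng = as_rng(rng)
    if genome_map is None:
        genome_map = random_genome_map(config, rng)
    sizes = _schedule_sizes(config.hist_schedule)
    n_loci = len(genome_map)
    haps = rng.integers(0, 2, size=(sizes[0], 2, n_loci), dtype=np.int8)
    switch_p = genome_map.switch_probs()
    for n_next in sizes[1:]:
        n_cur = haps.shape[0]
        p1 = rng.integers(0, n_cur, size=n_next)
        p2 = rng.integers(0, n_cur - 1, size=n_next)
        p2[p2 >= p1] += 1  # two distinct parents
        g1 = _gamete_batch(haps[p1], genome_map, rng, config.mutation_rate, switch_p)
        g2 = _gamete_batch(haps[p2], genome_map, rng, config.mutation_rate, switch_p)
        haps = np.stack([g1, g2], axis=1)
    ped = pd.DataFrame(_empty_pedigree(haps.shape[0]))
    return Population(ped, haps, genome_map)


# ---------------------------------------------------------------------------
# recent population
# ---------------------------------------------------------------------------


def select_founders(pool: Population, config: SimConfig, rng=None) -> Population:
    """Draw the recent-population founders (sires first, then dams) from a
    historical cohort and assign sexes."""
    rng = as_rng(rng)
    n_need = config.n_sires + config.n_dams
    if len(pool) < n_need:
        raise SimulationError(
            f"historical cohort of {len(pool)} cannot supply "
            f"{config.n_sires} sires + {config.n_dams} dams"
        )
    rows = rng.permutation(len(pool))[:n_need]
    founders = Population(
        pool.pedigree.iloc[rows].copy(), pool.haplotypes[rows], pool.genome_map
    )
    ped = founders.pedigree
    ped["id"] = np.arange(1, n_need + 1, dtype=np.int64)
    ped["sire"] = 0
    ped["dam"] = 0
    ped["generation"] = 0
    sex = np.full(n_need, FEMALE, dtype=np.int8)
    sex[: config.n_sires] = MALE
    ped["sex"] = sex
    ped["genotyped"] = 0 in config.genotyped_generations
    return Population(ped, founders.haplotypes, founders.genome_map)


def simulate_recent(founders: Population, config: SimConfig, rng=None) -> Population:
    """Breed ``n_generations_recent`` discrete generations from the founders.

    Every dam produces exactly one offspring per generation with a uniformly
    chosen sire.  After each generation the stated fraction of breeders is
    replaced by randomly chosen same-sex offspring of that generation; the
    culled breeders are the oldest, ties broken at random.  Generations in
    ``genotyped_generations`` are flagged genotyped.
    """
    rng = as_rng(rng)
    ns, nd = config.n_sires, config.n_dams
    sex_col = founders.pedigree["sex"].to_numpy()
    if (sex_col == MALE).sum() == ns and (sex_col == FEMALE).sum() == nd:
        fpop = founders
    else:
        fpop = select_founders(founders, config, rng)

    gmap = fpop.genome_map
    n_loci = len(gmap)
    switch_p = gmap.switch_probs()
    n_gen = config.n_generations_recent
    n_founders = ns + nd
    total = n_founders + n_gen * nd

    haps = np.empty((total, 2, n_loci), dtype=np.int8)
    haps[:n_founders] = fpop.haplotypes
    ped = _empty_pedigree(total)
    fped = fpop.pedigree
    ped["sex"][:n_founders] = fped["sex"].to_numpy()
    ped["generation"][:n_founders] = 0
    ped["genotyped"][:n_founders] = 0 in config.genotyped_generations

    # breeder state: row indices into the population arrays + entry generation
    sire_rows = np.flatnonzero(fped["sex"].to_numpy() == MALE)
    dam_rows = np.flatnonzero(fped["sex"].to_numpy() == FEMALE)
    sire_entry = np.zeros(ns, dtype=np.int32)
    dam_entry = np.zeros(nd, dtype=np.int32)

    n_rep_s = int(round(config.replacement_sire * ns))
    n_rep_d = int(round(config.replacement_dam * nd))
    cursor = n_founders

    for g in range(1, n_gen + 1):
        chosen_sires = sire_rows[rng.integers(0, ns, size=nd)]
        pat = _gamete_batch(haps[chosen_sires], gmap, rng, config.mutation_rate, switch_p)
        mat = _gamete_batch(haps[dam_rows], gmap, rng, config.mutation_rate, switch_p)
        rows = np.arange(cursor, cursor + nd)
        haps[rows, 0] = pat
        haps[rows, 1] = mat
        sex = rng.integers(MALE, FEMALE + 1, size=nd).astype(np.int8)
        ped["sire"][rows] = chosen_sires + 1  # row index -> id (ids are 1-based rows)
        ped["dam"][rows] = dam_rows + 1
        ped["sex"][rows] = sex
        ped["generation"][rows] = g
        ped["genotyped"][rows] = g in config.genotyped_generations
        cursor += nd

        if g == n_gen:
            break
        sire_rows, sire_entry = _replace_breeders(
            sire_rows, sire_entry, rows[sex == MALE], n_rep_s, g, rng, "sire"
        )
        dam_rows, dam_entry = _replace_breeders(
            dam_rows, dam_entry, rows[sex == FEMALE], n_rep_d, g, rng, "dam"
        )

    pop = Population(pd.DataFrame(ped), haps, gmap)
    return pop


def _replace_breeders(rows, entry, candidates, n_rep, gen, rng, label):
    if n_rep == 0:
        return rows, entry
    if len(candidates) < n_rep:
        raise SimulationError(
            f"generation {gen}: only {len(candidates)} {label} candidates for "
            f"{n_rep} replacements"
        )
    # cull the oldest first, random tie-breaking within an entry generation
    order = np.lexsort((rng.random(len(rows)), entry))
    keep = order[n_rep:]
    new_rows = rng.choice(candidates, size=n_rep, replace=False)
    rows = np.concatenate([rows[keep], new_rows])
    entry = np.concatenate([entry[keep], np.full(n_rep, gen, dtype=entry.dtype)])
    return rows, entry


# ---------------------------------------------------------------------------
# MAF filter and locus classing
# ---------------------------------------------------------------------------


def filter_segregating_maf(
    pop: Population,
    maf_min: float,
    n_snp: int | None = None,
    n_qtn: int | None = None,
    rng=None,
) -> GenomeMap:
    """Keep loci with minor-allele frequency strictly above ``maf_min`` in the
    founder cohort of ``pop``; optionally sample SNP/QTN target counts from
    the survivors (without replacement, classes assigned at random)."""
    freqs = pop.allele_freqs(ids=pop.founder_ids())
    maf = np.minimum(freqs, 1.0 - freqs)
    keep = np.flatnonzero(maf > maf_min)
    table = pop.genome_map.table.iloc[keep].copy()
    if n_snp is None and n_qtn is None:
        return GenomeMap(table)
    n_snp = int(n_snp or 0)
    n_qtn = int(n_qtn or 0)
    if len(table) < n_snp + n_qtn:
        raise ConfigError(
            f"only {len(table)} loci with MAF > {maf_min} but "
            f"{n_snp} SNP + {n_qtn} QTN requested"
        )
    rng = as_rng(rng)
    chosen = rng.choice(len(table), size=n_snp + n_qtn, replace=False)
    qtn_local = rng.choice(n_snp + n_qtn, size=n_qtn, replace=False)
    cls = np.full(n_snp + n_qtn, "SNP", dtype=object)
    cls[qtn_local] = "QTN"
    sub = table.iloc[np.sort(chosen)].copy()
    cls_by_index = dict(zip(chosen, cls))
    sub["cls"] = [cls_by_index[i] for i in np.sort(chosen)]
    return GenomeMap(sub)


# ---------------------------------------------------------------------------
# trait architecture and phenotypes
# ---------------------------------------------------------------------------


@dataclass
class TraitArchitecture:
    """QTN effects scaled so the founder-cohort TBV variance is exact."""

    qtn_ids: np.ndarray
    beta: np.ndarray
    sigma_u2: float
    mu: float = 1.0
    tbv_offset: float = 0.0  # founder-mean raw TBV, subtracted so E[TBV]=0

    def tbv(self, qtn_genotypes: np.ndarray) -> np.ndarray:
        """True breeding values from a (n, n_qtn) dosage matrix."""
        return qtn_genotypes @ self.beta - self.tbv_offset


def sample_qtn_effects(
    founder_genotypes: np.ndarray,
    sigma_u2: float,
    shape: float = 0.4,
    rng=None,
    qtn_ids=None,
    mu: float = 1.0,
) -> TraitArchitecture:
    """Gamma(shape) effect sizes with random sign, rescaled by one constant so
    var(TBV) over the founder cohort equals ``sigma_u2`` exactly."""
    rng = as_rng(rng)
    founder_genotypes = np.asarray(founder_genotypes, dtype=float)
    n_qtn = founder_genotypes.shape[1]
    if n_qtn < 1:
        raise ConfigError("need at least one QTN")
    raw = rng.gamma(shape, 1.0, size=n_qtn)
    raw *= rng.choice([-1.0, 1.0], size=n_qtn)
    tbv_raw = founder_genotypes @ raw
    v = tbv_raw.var()
    if v == 0.0:
        raise SimulationError("raw TBV variance is zero (all QTN monomorphic?)")
    beta = raw * math.sqrt(sigma_u2 / v)
    if qtn_ids is None:
        qtn_ids = np.arange(n_qtn)
    offset = float((founder_genotypes @ beta).mean())
    return TraitArchitecture(
        qtn_ids=np.asarray(qtn_ids),
        beta=beta,
        sigma_u2=float(sigma_u2),
        mu=mu,
        tbv_offset=offset,
    )


@dataclass
class PhenotypeSet:
    """Per-animal trait records: phenotype = mu + tbv + residual."""

    table: pd.DataFrame  # columns: id, generation, tbv, residual, phenotype

    def __len__(self):
        return len(self.table)

    def phenotypes_of(self, ids) -> np.ndarray:
        s = self.table.set_index("id")["phenotype"]
        return s.loc[np.asarray(ids)].to_numpy()

    def tbv_of(self, ids) -> np.ndarray:
        s = self.table.set_index("id")["tbv"]
        return s.loc[np.asarray(ids)].to_numpy()


def assign_phenotypes(
    arch: TraitArchitecture,
    pop: Population,
    rng=None,
    generations=None,
    phenotypic_variance: float = 1.0,
) -> PhenotypeSet:
    """Phenotypes for the given generations (default: all)."""
    rng = as_rng(rng)
    sigma_e2 = phenotypic_variance - arch.sigma_u2
    if sigma_e2 < 0:
        raise ConfigError(
            f"additive variance {arch.sigma_u2} exceeds phenotypic variance "
            f"{phenotypic_variance}"
        )
    ped = pop.pedigree
    if generations is not None:
        mask = ped["generation"].isin(list(generations)).to_numpy()
    else:
        mask = np.ones(len(ped), dtype=bool)
    ids = ped.loc[mask, "id"].to_numpy()
    qtn_idx = np.flatnonzero(pop.genome_map.qtn_mask)
    geno = pop.genotypes(ids=ids, loci=qtn_idx)
    tbv = arch.tbv(geno)
    resid = rng.normal(0.0, math.sqrt(sigma_e2), size=len(ids)) if sigma_e2 > 0 else np.zeros(len(ids))
    phen = arch.mu + tbv + resid
    table = pd.DataFrame(
        {
            "id": ids,
            "generation": ped.loc[mask, "generation"].to_numpy(),
            "tbv": tbv,
            "residual": resid,
            "phenotype": phen,
        }
    )
    return PhenotypeSet(table)


# ---------------------------------------------------------------------------
# end-to-end simulation
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    """Everything downstream stages consume."""

    config: SimConfig
    population: Population
    genome_map: GenomeMap
    architecture: TraitArchitecture
    phenotypes: PhenotypeSet

    def tbv_of(self, ids) -> np.ndarray:
        qtn_idx = np.flatnonzero(self.genome_map.qtn_mask)
        geno = self.population.genotypes(ids=ids, loci=qtn_idx)
        return self.architecture.tbv(geno)


def simulate(config: SimConfig, seed: int | None = None) -> SimResult:
    """Run the whole synthetic-data stage: historical drift, founder
    selection, MAF filtering + locus classing, recent breeding, QTN effects
    and phenotypes.  Deterministic given (config, seed)."""
    config = config.scaled()
    seed = config.seed if seed is None else seed
    rng_map = spawn_rng(seed, "genome-map")
    rng_hist = spawn_rng(seed, "historical")
    rng_found = spawn_rng(seed, "founders")
    rng_recent = spawn_rng(seed, "recent")
    rng_arch = spawn_rng(seed, "architecture")
    rng_phen = spawn_rng(seed, "phenotypes")

    candidates = random_genome_map(config, rng_map)
    hist = simulate_historical(config, rng_hist, genome_map=candidates)
    founders = select_founders(hist, config, rng_found)
    gmap = filter_segregating_maf(
        founders, config.maf_min, config.n_snp_target, config.n_qtn_target, rng_found
    )
    founders = founders.subset_loci(gmap)
    recent = simulate_recent(founders, config, rng_recent)

    qtn_idx = np.flatnonzero(gmap.qtn_mask)
    founder_geno = recent.genotypes(ids=recent.founder_ids(), loci=qtn_idx)
    arch = sample_qtn_effects(
        founder_geno,
        sigma_u2=config.sigma_u2,
        shape=config.qtn_gamma_shape,
        rng=rng_arch,
        qtn_ids=gmap.locus_ids[qtn_idx],
        mu=config.mean,
    )
    phen = assign_phenotypes(
        arch,
        recent,
        rng_phen,
        generations=config.phenotyped_generations,
        phenotypic_variance=config.phenotypic_variance,
    )
    return SimResult(config, recent, gmap, arch, phen)
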