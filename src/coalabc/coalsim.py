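"""Coalescent simulation of unlinked loci under a :class:`DemographicModel`.

Simulation is delegated to msprime (structured Kingman coalescent with
population splits, piecewise-constant diploid sizes, continuous migration
and admixture pulses); genealogies are tskit tree sequences, one
non-recombining tree per locus.  Mutations follow the infinite-sites model
(Poisson number on branches, uniform placement, every site biallelic).

Loci are unlinked and internally non-recombining; a locus doubles as the
block unit for jackknifing downstream.  Genealogies for the loci of one
dataset are drawn from a single replicate stream (much cheaper than one
simulation call per locus); mutation streams are derived per locus by
counter.  A dataset is fully reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import msprime
import numpy as np
import tskit

from .demography import DemographicModel, DEFAULT_CONTINENTS
from .errors import InputError

#: diploid sample sizes of the emulated cohort (89 Australian individuals in
#: four communities plus 25 Highland PNG), with a small outgroup panel
DEFAULT_DIPLOIDS = {"TIW": 34, "GAL": 17, "TIJ": 7, "YAR": 31, "PNG": 25, "OUT": 5}


@dataclass
class SampleConfig:
    diploids: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DIPLOIDS))
    ploidy: int = 2  # fixed

    def __post_init__(self):
        if self.ploidy != 2:
            raise InputError("only diploid sampling is supported")
        if any(c < 0 for c in self.diploids.values()):
            raise InputError("sample counts must be non-negative")
        if 2 * sum(self.diploids.values()) < 2:
            raise InputError("need at least 2 haplotypes in total")

    def sampled_pops(self) -> list[str]:
        return [p for p, c in self.diploids.items() if c > 0]


@dataclass
class LocusConfig:
    n_loci: int = 100
    length_bp: int = 100_000
    mu: float = 1.25e-8  # mutations / bp / generation

    def __post_init__(self):
        if self.n_loci < 0 or self.length_bp <= 0 or self.mu < 0:
            raise InputError("locus configuration values must be positive")


@dataclass
class HaplotypeDataset:
    """Biallelic 0/1 haplotypes over unlinked loci (0 = ancestral, -1 = missing).

    ``genotypes[l]`` is an int8 array of shape (n_sites, n_haplotypes);
    haplotypes ``2i`` and ``2i+1`` belong to diploid individual ``i``.
    ``positions[l]`` holds 1-based integer positions, strictly increasing.
    ``masks`` maps sample id -> per-locus list of (start, end) 0-based
    half-open masked intervals applying to both haplotypes of the individual.
    """

    positions: list[np.ndarray]
    genotypes: list[np.ndarray]
    locus_lengths: np.ndarray
    sample_ids: list[str]
    sample_pops: list[str]
    continents: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CONTINENTS))
    masks: dict[str, list[list[tuple[int, int]]]] | None = None

    # -- basic shape ------------------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.genotypes)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_samples

    @property
    def total_length(self) -> float:
        return float(np.sum(self.locus_lengths))

    @property
    def populations(self) -> list[str]:
        seen = dict.fromkeys(self.sample_pops)
        return list(seen)

    def sample_indices(self, pop: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.sample_pops) == pop)

    def hap_indices(self, pop: str) -> np.ndarray:
        ind = self.sample_indices(pop)
        return np.sort(np.concatenate([2 * ind, 2 * ind + 1])) if ind.size else ind

    # -- stacked views (cached) ------------------------------------------
    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(all-sites genotype matrix, per-site locus index)."""
        cached = getattr(self, "_stacked", None)
        if cached is None:
            if self.n_loci and any(g.size for g in self.genotypes):
                G = np.concatenate(
                    [g for g in self.genotypes], axis=0) if self.n_loci else \
                    np.empty((0, self.n_haplotypes), dtype=np.int8)
                blocks = np.concatenate(
                    [np.full(g.shape[0], l, dtype=np.int32)
                     for l, g in enumerate(self.genotypes)])
            else:
                G = np.empty((0, self.n_haplotypes), dtype=np.int8)
                blocks = np.empty(0, dtype=np.int32)
            cached = (G, blocks)
            self._stacked = cached
        return cached

    def invalidate_caches(self) -> None:
        for attr in ("_stacked", "_counts", "_freq_cache"):
            if hasattr(self, attr):
                delattr(self, attr)

    def pop_site_counts(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """Per stacked site: derived-allele count and called-haplotype count."""
        cache = getattr(self, "_counts", None)
        if cache is None:
            cache = {}
            self._counts = cache
        if pop not in cache:
            G, _ = self.stacked()
            H = G[:, self.hap_indices(pop)]
            called = (H >= 0).sum(axis=1)
            der = (H == 1).sum(axis=1)
            cache[pop] = (der.astype(np.int64), called.astype(np.int64))
        return cache[pop]


# ---------------------------------------------------------------------------
# msprime bridge
# ---------------------------------------------------------------------------

def to_msprime_demography(model: DemographicModel) -> msprime.Demography:
    dem = msprime.Demography()
    exist = model.existence()
    for p in model.populations:
        eps = model.epochs_of(p.name)
        dem.add_population(name=p.name, initial_size=eps[0].ne)
        for e in eps[1:]:
            dem.add_population_parameters_change(
                time=e.start_gen, population=p.name, initial_size=e.ne)
    for s in sorted(model.splits, key=lambda s: s.time_gen):
        dem.add_population_split(time=s.time_gen,
                                 derived=[s.child_a, s.child_b], ancestral=s.parent)
    for m in model.migrations:
        # our convention: a lineage in `dest` traces to `source`; msprime's
        # backward-time convention moves lineages from its `source` to `dest`
        if m.start_gen == 0.0:
            dem.set_migration_rate(source=m.dest, dest=m.source, rate=m.rate)
        else:
            dem.add_migration_rate_change(time=m.start_gen, source=m.dest,
                                          dest=m.source, rate=m.rate)
        if math.isfinite(m.end_gen) and m.end_gen < exist[m.dest][1]:
            dem.add_migration_rate_change(time=m.end_gen, source=m.dest,
                                          dest=m.source, rate=0.0)
    for p in model.pulses:
        dem.add_mass_migration(time=p.time_gen, source=p.into_pop,
                               dest=p.from_pop, proportion=p.proportion)
    dem.sort_events()
    return dem


def _locus_seed(seed: int, locus: int) -> int:
    """Stable per-locus stream, independent of how many loci are simulated."""
    ss = np.random.SeedSequence([int(seed), int(locus)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 2)) + 1


def simulate_genealogy(model: DemographicModel, samples: SampleConfig,
                       seed: int, length_bp: int = 100_000) -> tskit.TreeSequence:
    """One locus genealogy (single tree, no mutations); deterministic given seed."""
    dem = to_msprime_demography(model)
    sampled = {p: n for p, n in samples.diploids.items() if n > 0}
    return msprime.sim_ancestry(
        samples=sampled, demography=dem, sequence_length=length_bp,
        ploidy=2, random_seed=_locus_seed(seed, 0))


def simulate_genealogies(model: DemographicModel, samples: SampleConfig,
                         n_loci: int, seed: int,
                         length_bp: int = 100_000) -> list[tskit.TreeSequence]:
    dem = to_msprime_demography(model)
    sampled = {p: n for p, n in samples.diploids.items() if n > 0}
    return list(msprime.sim_ancestry(
        samples=sampled, demography=dem, sequence_length=length_bp,
        ploidy=2, num_replicates=n_loci, random_seed=_locus_seed(seed, 0)))


def drop_mutations(tree: tskit.TreeSequence, locus: LocusConfig,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Infinite-sites mutations on a genealogy.

    Returns (1-based integer positions ascending, int8 site x haplotype
    matrix).  Continuous positions are floored onto the integer grid; in the
    rare event of a collision only the first site at a position is kept.
    """
    mts = msprime.sim_mutations(
        tree, rate=locus.mu, random_seed=max(int(seed), 1),
        discrete_genome=False)
    if mts.num_sites == 0:
        return (np.empty(0, dtype=np.int64),
                np.empty((0, tree.num_samples), dtype=np.int8))
    G = mts.genotype_matrix().astype(np.int8)
    pos = np.floor(mts.sites_position).astype(np.int64) + 1  # 1-based
    keep = np.concatenate([[True], np.diff(pos) > 0])
    return pos[keep], G[keep]


def simulate_dataset(model: DemographicModel, samples: SampleConfig | None = None,
                     locus: LocusConfig | None = None, seed: int = 1,
                     keep_trees: bool = False,
                     ) -> HaplotypeDataset | tuple[HaplotypeDataset, list[tskit.TreeSequence]]:
    """Simulate ``n_loci`` independent genealogy + mutation draws.

    Haplotypes are paired into diploid individuals within populations, in
    sampling order; individual ids are ``<POP>_<k>``.
    """
    samples = samples or SampleConfig()
    locus = locus or LocusConfig()
    dem = to_msprime_demography(model)
    sampled = {p: n for p, n in samples.diploids.items() if n > 0}

    positions, genotypes, trees = [], [], []
    n_haps = 2 * sum(sampled.values())
    replicates = msprime.sim_ancestry(
        samples=sampled, demography=dem, sequence_length=locus.length_bp,
        ploidy=2, num_replicates=locus.n_loci,
        random_seed=_locus_seed(seed, 0)) if locus.n_loci else []
    for l, ts in enumerate(replicates):
        pos, G = drop_mutations(ts, locus, seed=_locus_seed(seed, l + 1))
        positions.append(pos)
        genotypes.append(G if G.size else np.empty((0, n_haps), dtype=np.int8))
        if keep_trees:
            trees.append(ts)

    sample_ids, sample_pops = [], []
    for p, n in sampled.items():
        for k in range(n):
            sample_ids.append(f"{p}_{k:03d}")
            sample_pops.append(p)

    ds = HaplotypeDataset(
        positions=positions, genotypes=genotypes,
        locus_lengths=np.full(locus.n_loci, locus.length_bp, dtype=np.int64),
        sample_ids=sample_ids, sample_pops=sample_pops,
        continents={p: DEFAULT_CONTINENTS.get(p, "NA") for p in sampled})
    return (ds, trees) if keep_trees else ds


# ---------------------------------------------------------------------------
# pairwise coalescence times from genealogies
# ---------------------------------------------------------------------------

def _pop_samples(ts: tskit.TreeSequence, pop: str) -> np.ndarray:
    for p in ts.populations():
        name = (p.metadata or {}).get("name")
        if name == pop:
            return ts.samples(population=p.id)
    raise InputError(f"population {pop!r} not present in genealogy")


def pair_coalescence_times(trees: Iterable[tskit.TreeSequence], popA: str, popB: str,
                           max_pairs_per_locus: int | None = None,
                           seed: int | None = None) -> np.ndarray:
    """TMRCA (generations) of haplotype pairs across loci.

    For ``popA == popB`` all within-population pairs are used; otherwise all
    cross pairs, optionally subsampled to ``max_pairs_per_locus`` to bound
    cost.
    """
    rng = np.random.default_rng(seed)
    times: list[float] = []
    for ts in trees:
        a = _pop_samples(ts, popA)
        b = _pop_samples(ts, popB)
        if popA == popB:
            pairs = [(a[i], a[j]) for i in range(len(a)) for j in range(i + 1, len(a))]
        else:
            pairs = [(u, v) for u in a for v in b]
        if not pairs:
            raise InputError("no haplotype pairs available")
        if max_pairs_per_locus is not None and len(pairs) > max_pairs_per_locus:
            idx = rng.choice(len(pairs), size=max_pairs_per_locus, replace=False)
            pairs = [pairs[i] for i in idx]
        tree = ts.first()
        times.extend(tree.tmrca(u, v) for u, v in pairs)
    return np.asarray(times, dtype=float)
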