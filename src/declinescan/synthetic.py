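"""Synthetic-data generators.

Every input the pipeline consumes can be generated here with the statistical
structure the downstream analyses assume:

* a structured-coalescent simulator (independent non-recombining loci,
  infinite-sites mutations, piecewise-constant population sizes, population
  splits, asymmetric migration) — this is also the engine behind the
  demographic-inference stage;
* a pedigree simulator with Poisson crossovers that returns exact autozygous
  (IBD) tracts, giving ground truth for ROH detection and the inbreeding-age
  formula g = 100/(2 * length_cM);
* a sequencing-noise layer adding per-genotype allele depths and site
  base/mapping qualities;
* mtDNA haplotype sets with star-like or multi-cluster structure;
* gene models with planted coding variants of known effect class.

Time is measured in generations throughout; population sizes are diploid
effective sizes.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
import math
import random
from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import GeneModel, GenotypeMatrix, HET, HOM_ALT, MISSING

DEFAULT_MUTATION_RATE = 1.47e-8  # per site per generation
DEFAULT_GENERATION_TIME_YEARS = 1.0

BASES = "ACGT"


# ===========================================================================
# Population model specification
# ===========================================================================

@dataclass(frozen=True)
class PopulationModelSpec:
    """Demographic model: epochs, splits and migration, in generations.

    Parameters
    ----------
    populations
        Population labels; index order is the matrix order for migration.
    epochs
        Per population, ``((t_start, N_diploid), ...)`` with t_start
        non-negative and strictly increasing, first entry at t=0.  Sizes are
        constant within an epoch (backwards in time from t_start).
    splits
        ``(time, derived_pop, ancestral_pop)``: at ``time`` (pastwards) all
        lineages of ``derived_pop`` join ``ancestral_pop``.
    migration
        Migration epochs ``((t_start, matrix), ...)``; ``matrix[i][j]`` is the
        per-generation probability that a lineage of population ``i`` traces
        its parent to population ``j`` (backwards in time).
    mutation_rate
        Per-site per-generation mutation rate.
    generation_time_years
        Used only when reporting times in years.
    """

    populations: tuple[str, ...]
    epochs: Mapping[str, tuple[tuple[float, float], ...]]
    splits: tuple[tuple[float, str, str], ...] = ()
    migration: tuple[tuple[float, tuple[tuple[float, ...], ...]], ...] = ()
    mutation_rate: float = DEFAULT_MUTATION_RATE
    generation_time_years: float = DEFAULT_GENERATION_TIME_YEARS

    def __post_init__(self) -> None:
        pops = self.populations
        if len(set(pops)) != len(pops):
            raise ValueError("duplicate population labels")
        for p in pops:
            ep = self.epochs.get(p)
            if not ep:
                raise ValueError(f"population {p!r} has no epochs")
            times = [t for t, _ in ep]
            if times[0] != 0:
                raise ValueError(f"{p}: first epoch must start at t=0")
            if any(t < 0 for t in times) or any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"{p}: epoch times must be non-negative and strictly increasing")
            if any(n <= 0 for _, n in ep):
                raise ValueError(f"{p}: population sizes must be > 0")
        derived = [d for _, d, _ in self.splits]
        if len(set(derived)) != len(derived):
            raise ValueError("a derived population may have only one split event")
        for t, d, a in self.splits:
            if t < 0:
                raise ValueError("split times must be non-negative")
            if d not in pops or a not in pops:
                raise ValueError(f"split references unknown population: {d!r} or {a!r}")
        for t, mat in self.migration:
            if len(mat) != len(pops) or any(len(row) != len(pops) for row in mat):
                raise ValueError("migration matrix shape must match population count")
            for row in mat:
                if any(not (0 <= m < 1) for m in row):
                    raise ValueError("migration entries must lie in [0, 1)")

    # -- convenience constructors ------------------------------------------

    @staticmethod
    def single_population(n_e: float, label: str = "pop0", *,
                          size_changes: Sequence[tuple[float, float]] = (),
                          mutation_rate: float = DEFAULT_MUTATION_RATE) -> "PopulationModelSpec":
        epochs = ((0.0, float(n_e)),) + tuple((float(t), float(n)) for t, n in size_changes)
        return PopulationModelSpec((label,), {label: epochs}, mutation_rate=mutation_rate)

    @staticmethod
    def two_population_split(n1: float, n2: float, n_anc: float, t_split: float,
                             m12: float = 0.0, m21: float = 0.0,
                             labels: tuple[str, str] = ("pop1", "pop2"),
                             mutation_rate: float = DEFAULT_MUTATION_RATE) -> "PopulationModelSpec":
        """Two populations split from a common ancestor at ``t_split``.

        Population 2 merges into population 1 at the split; the ancestral
        size ``n_anc`` applies to population 1 pastwards of the split.
        ``m12``/``m21`` are backwards lineage-migration rates between the
        populations before the split.
        """
        l1, l2 = labels
        mig = ()
        if m12 or m21:
            mig = ((0.0, ((0.0, float(m12)), (float(m21), 0.0))),)
        return PopulationModelSpec(
            (l1, l2),
            {l1: ((0.0, float(n1)), (float(t_split), float(n_anc))),
             l2: ((0.0, float(n2)),)},
            splits=((float(t_split), l2, l1),),
            migration=mig,
            mutation_rate=mutation_rate,
        )


class UnreachableCoalescenceError(ValueError):
    """Raised when some populations can never share a common ancestor."""


def _check_reachable(spec: PopulationModelSpec) -> None:
    pops = spec.populations
    parent = {p: p for p in pops}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for _, d, a in spec.splits:
        union(d, a)
    for _, mat in spec.migration:
        for i, row in enumerate(mat):
            for j, m in enumerate(row):
                if m > 0:
                    union(pops[i], pops[j])
    roots = {find(p) for p in pops}
    if len(roots) > 1:
        groups = {}
        for p in pops:
            groups.setdefault(find(p), []).append(p)
        raise UnreachableCoalescenceError(
            "populations can never coalesce (no migration or split connects them): "
            + " | ".join(",".join(g) for g in groups.values())
        )


# ===========================================================================
# Structured-coalescent engine
# ===========================================================================

class _CompiledDemography:
    """Flat arrays for the event loop; label lookups resolved to indices."""

    __slots__ = ("npop", "epoch_times", "epoch_sizes", "mig_times", "mig_mats",
                 "splits", "change_times", "mutation_rate")

    def __init__(self, spec: PopulationModelSpec):
        _check_reachable(spec)
        idx = {p: i for i, p in enumerate(spec.populations)}
        self.npop = len(spec.populations)
        self.epoch_times = []
        self.epoch_sizes = []
        for p in spec.populations:
            ep = spec.epochs[p]
            self.epoch_times.append([t for t, _ in ep])
            self.epoch_sizes.append([n for _, n in ep])
        if spec.migration:
            self.mig_times = [t for t, _ in spec.migration]
            self.mig_mats = [[list(row) for row in m] for _, m in spec.migration]
        else:
            zero = [[0.0] * self.npop for _ in range(self.npop)]
            self.mig_times, self.mig_mats = [0.0], [zero]
        self.splits = sorted((t, idx[d], idx[a]) for t, d, a in spec.splits)
        self.mutation_rate = spec.mutation_rate
        changes = set(self.mig_times) | {t for t, _, _ in self.splits}
        for times in self.epoch_times:
            changes.update(times)
        self.change_times = sorted(t for t in changes if t > 0)

    def size_at(self, pop: int, t: float) -> float:
        k = bisect_right(self.epoch_times[pop], t) - 1
        return self.epoch_sizes[pop][k]

    def migration_at(self, t: float) -> list[list[float]]:
        k = bisect_right(self.mig_times, t) - 1
        return self.mig_mats[max(k, 0)]


def _simulate_genealogy(rnd: random.Random, dem: _CompiledDemography,
                        leaf_pops: Sequence[int]) -> list[tuple[float, int]]:
    """One coalescent genealogy; returns branches as (length, leaf-bitmask).

    The root branch is excluded.  ``leaf_pops[i]`` is the population index of
    haploid leaf ``i``; bit ``i`` of a branch mask marks descent of leaf ``i``.
    """
    npop = dem.npop
    pop_of: list[int] = []
    mask_of: list[int] = []
    born: list[float] = []
    by_pop: list[list[int]] = [[] for _ in range(npop)]
    for i, p in enumerate(leaf_pops):
        pop_of.append(p)
        mask_of.append(1 << i)
        born.append(0.0)
        by_pop[p].append(i)
    alive = len(leaf_pops)
    if alive < 2:
        raise ValueError("need at least 2 haploid samples")
    branches: list[tuple[float, int]] = []
    t = 0.0
    split_i = 0
    # a derived population stops existing pastwards of its split: no
    # migration into or out of it afterwards
    inactive = [False] * npop
    # apply any splits at t == 0
    while split_i < len(dem.splits) and dem.splits[split_i][0] <= 0.0:
        _, d, a = dem.splits[split_i]
        for lin in by_pop[d]:
            pop_of[lin] = a
            by_pop[a].append(lin)
        by_pop[d] = []
        inactive[d] = True
        split_i += 1
    change_i = bisect_right(dem.change_times, 0.0)
    expovariate = rnd.expovariate
    uniform = rnd.random
    # piecewise-constant parameters: cache between boundary crossings
    inv4n = [0.25 / dem.size_at(p, t) for p in range(npop)]
    mig = dem.migration_at(t)
    mig_out = [sum(m for j, m in enumerate(mig[p]) if not inactive[j])
               for p in range(npop)]
    coal_rates = [0.0] * npop
    mig_rates = [0.0] * npop
    while alive > 1:
        total = 0.0
        for p in range(npop):
            k = len(by_pop[p])
            r = k * (k - 1) * inv4n[p] if k > 1 else 0.0
            coal_rates[p] = r
            total += r
            r = k * mig_out[p] if (k and not inactive[p]) else 0.0
            mig_rates[p] = r
            total += r
        boundary = dem.change_times[change_i] if change_i < len(dem.change_times) else math.inf
        if total <= 0.0:
            if boundary is math.inf:
                raise UnreachableCoalescenceError(
                    "no coalescence or migration possible among remaining lineages"
                )
            t = boundary
        else:
            dt = expovariate(total)
            if t + dt >= boundary:
                t = boundary
            else:
                t += dt
                u = uniform() * total
                event_done = False
                for p in range(npop):
                    if u < coal_rates[p]:
                        lins = by_pop[p]
                        i1 = rnd.randrange(len(lins))
                        a_id = lins[i1]
                        lins[i1] = lins[-1]
                        lins.pop()
                        i2 = rnd.randrange(len(lins))
                        b_id = lins[i2]
                        branches.append((t - born[a_id], mask_of[a_id]))
                        branches.append((t - born[b_id], mask_of[b_id]))
                        # reuse b_id's slot for the parent lineage
                        mask_of[b_id] = mask_of[a_id] | mask_of[b_id]
                        born[b_id] = t
                        alive -= 1
                        event_done = True
                        break
                    u -= coal_rates[p]
                if not event_done:
                    for p in range(npop):
                        if u < mig_rates[p]:
                            lins = by_pop[p]
                            i1 = rnd.randrange(len(lins))
                            lin = lins[i1]
                            lins[i1] = lins[-1]
                            lins.pop()
                            row = [0.0 if inactive[j] else mj
                                   for j, mj in enumerate(mig[p])]
                            v = uniform() * sum(row)
                            dest = 0
                            for j, mj in enumerate(row):
                                if v < mj:
                                    dest = j
                                    break
                                v -= mj
                            pop_of[lin] = dest
                            by_pop[dest].append(lin)
                            break
                        u -= mig_rates[p]
                continue
        # crossed a boundary: apply splits scheduled at exactly this time
        while split_i < len(dem.splits) and dem.splits[split_i][0] <= t:
            _, d, a = dem.splits[split_i]
            for lin in by_pop[d]:
                pop_of[lin] = a
                by_pop[a].append(lin)
            by_pop[d] = []
            inactive[d] = True
            split_i += 1
        change_i = bisect_right(dem.change_times, t)
        inv4n = [0.25 / dem.size_at(p, t) for p in range(npop)]
        mig = dem.migration_at(t)
        mig_out = [sum(m for j, m in enumerate(mig[p]) if not inactive[j])
                   for p in range(npop)]
    return branches


def joint_branch_lengths(spec: PopulationModelSpec,
                         sample_sizes: Mapping[str, int],
                         n_sims: int, seed: int) -> np.ndarray:
    """Monte-Carlo mean branch length subtending (i, j) derived-leaf classes.

    Entry ``(i, j)`` is the mean (over ``n_sims`` genealogies) total branch
    length carrying exactly ``i`` of population 1's and ``j`` of population
    2's haploid leaves; with one sampled population the result is a column
    vector.  Multiplying by mutation rate x locus length gives expected
    per-locus SNP counts per joint-SFS cell.
    """
    dem = _CompiledDemography(spec)
    pops = [p for p in spec.populations if sample_sizes.get(p, 0) > 0]
    if not 1 <= len(pops) <= 2:
        raise ValueError("sample_sizes must name one or two populations")
    idx = {p: i for i, p in enumerate(spec.populations)}
    leaf_pops = []
    for p in pops:
        leaf_pops.extend([idx[p]] * (2 * sample_sizes[p]))
    n1h = 2 * sample_sizes[pops[0]]
    n2h = 2 * sample_sizes[pops[1]] if len(pops) == 2 else 0
    mask1 = (1 << n1h) - 1
    acc = np.zeros((n1h + 1, n2h + 1))
    rnd = random.Random(seed)
    for _ in range(n_sims):
        for length, mask in _simulate_genealogy(rnd, dem, leaf_pops):
            i = (mask & mask1).bit_count()
            j = (mask >> n1h).bit_count()
            acc[i, j] += length
    acc /= n_sims
    return acc


def simulate_coalescent(spec: PopulationModelSpec,
                        sample_sizes: Mapping[str, int],
                        n_loci: int, locus_length_bp: int,
                        seed: int) -> GenotypeMatrix:
    """Simulate biallelic SNPs on independent non-recombining loci.

    Infinite-sites mutations are dropped on each locus genealogy; the
    ancestral allele is recorded per site (``sites['ancestral']``, equal to
    REF).  Loci appear as scaffolds ``locus000...``; identical (spec, seed)
    give identical output.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    dem = _CompiledDemography(spec)
    idx = {p: i for i, p in enumerate(spec.populations)}
    pops = [p for p in spec.populations if sample_sizes.get(p, 0) > 0]
    leaf_pops = []
    samples = []
    for p in pops:
        nd = sample_sizes[p]
        leaf_pops.extend([idx[p]] * (2 * nd))
        samples.extend(f"{p}_{k}" for k in range(nd))
    if len(leaf_pops) < 2:
        raise ValueError("total haploid sample must be >= 2")
    rnd = random.Random(seed)
    np_rng = np.random.default_rng(seed + 1)
    mu_l = spec.mutation_rate * locus_length_bp
    site_rows = []
    gt_rows = []
    n_dip = len(samples)
    width = max(3, len(str(n_loci - 1)))
    for locus in range(n_loci):
        branches = _simulate_genealogy(rnd, dem, leaf_pops)
        total_len = sum(b for b, _ in branches)
        n_mut = np_rng.poisson(mu_l * total_len) if mu_l > 0 else 0
        if n_mut == 0:
            continue
        n_mut = min(n_mut, locus_length_bp)  # infinite-sites cap
        lengths = np.array([b for b, _ in branches])
        probs = lengths / total_len
        which = np_rng.choice(len(branches), size=n_mut, p=probs)
        positions = np_rng.choice(locus_length_bp, size=n_mut, replace=False) + 1
        positions.sort()
        scaffold = f"locus{locus:0{width}d}"
        for pos, bi in zip(positions, which):
            mask = branches[bi][1]
            ref = BASES[rnd.randrange(4)]
            alt = rnd.choice([b for b in BASES if b != ref])
            row = [scaffold, int(pos), ref, alt, 60.0, 60.0, ref]
            gts = np.empty(n_dip, np.int8)
            for d in range(n_dip):
                gts[d] = ((mask >> (2 * d)) & 1) + ((mask >> (2 * d + 1)) & 1)
            site_rows.append(row)
            gt_rows.append(gts)
    cols = ["scaffold", "pos", "ref", "alt", "qual", "mq", "ancestral"]
    sites = pd.DataFrame(site_rows, columns=cols)
    gt = np.array(gt_rows, np.int8) if gt_rows else np.zeros((0, n_dip), np.int8)
    return GenotypeMatrix(samples, sites, gt)


# ===========================================================================
# Pedigree simulator (Poisson crossovers, exact IBD tracts)
# ===========================================================================

@dataclass(frozen=True)
class PedigreeSpec:
    """A pedigree with an explicit mating plan.

    ``mating_plan`` rows are ``(generation_index, parent_a, parent_b,
    offspring_id)``; parents must exist (as founders ``F0..F{k-1}`` or
    earlier offspring) before the offspring.  ``map_length_cM`` gives the
    genetic length of each of ``chromosome_count`` chromosomes; physical
    coordinates follow from ``cM_per_Mb`` (default 1, mirroring the use of
    physical ROH length as an approximation for genetic length).
    """

    founder_count: int
    mating_plan: tuple[tuple[int, str, str, str], ...]
    map_length_cM: tuple[float, ...]
    chromosome_count: int
    marker_spacing_bp: int = 20_000
    cM_per_Mb: float = 1.0

    def __post_init__(self) -> None:
        if self.founder_count < 1:
            raise ValueError("founder_count must be >= 1")
        if len(self.map_length_cM) != self.chromosome_count:
            raise ValueError("map_length_cM must have one entry per chromosome")
        if any(l <= 0 for l in self.map_length_cM):
            raise ValueError("map lengths must be > 0")
        if self.cM_per_Mb <= 0:
            raise ValueError("cM_per_Mb must be > 0")
        known = {f"F{i}" for i in range(self.founder_count)}
        for gen, pa, pb, off in self.mating_plan:
            if pa not in known or pb not in known:
                raise ValueError(f"offspring {off!r}: parent {pa!r}/{pb!r} not yet defined")
            if off in known:
                raise ValueError(f"duplicate individual id {off!r}")
            known.add(off)

    @property
    def depth(self) -> int:
        return max((g for g, *_ in self.mating_plan), default=0)

    @staticmethod
    def consanguineous_loop(g: int, *, chromosome_count: int = 1,
                            map_length_cM: float = 100.0,
                            marker_spacing_bp: int = 20_000,
                            cM_per_Mb: float = 1.0) -> "PedigreeSpec":
        """A pedigree whose final offspring closes a g-generation loop.

        ``g`` is the number of generations from the offspring up to the
        shared ancestor(s): g=1 is selfing, g=2 a full-sib mating, g=3 a
        first-cousin mating, and so on.  The common-ancestor loop contains
        2g meioses, so autozygous tracts have expected length 100/(2g) cM.
        """
        if g < 1:
            raise ValueError("g must be >= 1")
        plan: list[tuple[int, str, str, str]] = []
        if g == 1:
            return PedigreeSpec(1, (((1, "F0", "F0", "X")),),
                                (map_length_cM,) * chromosome_count,
                                chromosome_count, marker_spacing_bp, cM_per_Mb)
        # founders F0 x F1 are the shared ancestor couple; two descent lines
        n_founders = 2 + 2 * (g - 2)
        plan.append((1, "F0", "F1", "A1"))
        plan.append((1, "F0", "F1", "B1"))
        fi = 2
        for k in range(2, g):
            plan.append((k, f"A{k-1}", f"F{fi}", f"A{k}"))
            fi += 1
            plan.append((k, f"B{k-1}", f"F{fi}", f"B{k}"))
            fi += 1
        plan.append((g, f"A{g-1}", f"B{g-1}", "X"))
        return PedigreeSpec(max(n_founders, 2), tuple(plan),
                            (map_length_cM,) * chromosome_count,
                            chromosome_count, marker_spacing_bp, cM_per_Mb)


# a haplotype along one chromosome: segment starts (cM) + founder-hap labels
_Hap = tuple[list[float], list[int]]


def _meiosis(rnd: random.Random, hap_a: _Hap, hap_b: _Hap, length_cM: float) -> _Hap:
    n_x = np.random.default_rng(rnd.getrandbits(32)).poisson(length_cM / 100.0)
    cuts = sorted(rnd.uniform(0.0, length_cM) for _ in range(n_x))
    cur = rnd.randrange(2)
    haps = (hap_a, hap_b)
    starts: list[float] = []
    labels: list[int] = []
    prev = 0.0
    for cut in cuts + [length_cM]:
        st, lb = haps[cur]
        i = bisect_right(st, prev) - 1
        while i < len(st) and st[i] < cut:
            s = max(st[i], prev)
            lab = lb[i]
            if labels and labels[-1] == lab:
                pass  # merge with previous segment
            else:
                starts.append(s)
                labels.append(lab)
            i += 1
        prev = cut
        cur = 1 - cur
    return starts, labels


def _hap_label_at(hap: _Hap, pos: float) -> int:
    starts, labels = hap
    return labels[bisect_right(starts, pos) - 1]


def _ibd_tracts(pat: _Hap, mat: _Hap, length_cM: float) -> list[tuple[float, float]]:
    """Intervals (cM) where paternal and maternal founder-hap labels agree."""
    bounds = sorted(set(pat[0]) | set(mat[0]) | {0.0, length_cM})
    tracts: list[tuple[float, float]] = []
    for a, b in zip(bounds, bounds[1:]):
        if b <= a:
            continue
        if _hap_label_at(pat, a) == _hap_label_at(mat, a):
            if tracts and tracts[-1][1] == a:
                tracts[-1] = (tracts[-1][0], b)
            else:
                tracts.append((a, b))
    return tracts


def simulate_pedigree(spec: PedigreeSpec, g_loop: int, seed: int
                      ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop genomes through a pedigree and return genotypes + true IBD tracts.

    Returns ``(gm, ibd)`` where ``ibd`` has columns ``individual, scaffold,
    start_bp, end_bp, length_cM`` (half-open bp intervals) listing the exact
    autozygous tracts of every non-founder.  Founder haplotypes are unique,
    so label equality is identity by descent.
    """
    if g_loop > spec.depth:
        raise ValueError(f"g_loop={g_loop} exceeds pedigree depth {spec.depth}")
    rnd = random.Random(seed)
    # genomes[ind] = per chromosome (paternal hap, maternal hap)
    genomes: dict[str, list[tuple[_Hap, _Hap]]] = {}
    next_hap = 0
    for i in range(spec.founder_count):
        chroms = []
        for _ in range(spec.chromosome_count):
            chroms.append((([0.0], [next_hap]), ([0.0], [next_hap + 1])))
            next_hap += 2
        genomes[f"F{i}"] = chroms
    for _, pa, pb, off in spec.mating_plan:
        chroms = []
        for c in range(spec.chromosome_count):
            L = spec.map_length_cM[c]
            hp = _meiosis(rnd, *genomes[pa][c], L)
            hm = _meiosis(rnd, *genomes[pb][c], L)
            chroms.append((hp, hm))
        genomes[off] = chroms

    bp_per_cM = 1e6 / spec.cM_per_Mb
    ibd_rows = []
    offspring_ids = [off for *_, off in spec.mating_plan]
    for ind in offspring_ids:
        for c in range(spec.chromosome_count):
            pat, mat = genomes[ind][c]
            for a, b in _ibd_tracts(pat, mat, spec.map_length_cM[c]):
                ibd_rows.append({
                    "individual": ind, "scaffold": f"chr{c + 1}",
                    "start_bp": int(a * bp_per_cM), "end_bp": int(b * bp_per_cM),
                    "length_cM": b - a,
                })
    ibd = pd.DataFrame(ibd_rows,
                       columns=["individual", "scaffold", "start_bp", "end_bp", "length_cM"])

    # markers: founder-haplotype alleles at evenly spaced positions
    np_rng = np.random.default_rng(seed + 7)
    individuals = [f"F{i}" for i in range(spec.founder_count)] + offspring_ids
    site_rows, gt_rows = [], []
    for c in range(spec.chromosome_count):
        L = spec.map_length_cM[c]
        chrom_bp = int(L * bp_per_cM)
        positions = np.arange(spec.marker_spacing_bp, chrom_bp, spec.marker_spacing_bp)
        freqs = np_rng.uniform(0.05, 0.95, size=len(positions))
        alleles = np_rng.random((len(positions), next_hap)) < freqs[:, None]
        for mi, pos in enumerate(positions):
            cm = pos / bp_per_cM
            gts = np.empty(len(individuals), np.int8)
            for k, ind in enumerate(individuals):
                pat, mat = genomes[ind][c]
                a1 = alleles[mi, _hap_label_at(pat, cm)]
                a2 = alleles[mi, _hap_label_at(mat, cm)]
                gts[k] = int(a1) + int(a2)
            ref = BASES[int(np_rng.integers(4))]
            alt = BASES[(BASES.index(ref) + 1 + int(np_rng.integers(3))) % 4]
            site_rows.append([f"chr{c + 1}", int(pos), ref, alt, 60.0, 60.0])
            gt_rows.append(gts)
    sites = pd.DataFrame(site_rows, columns=["scaffold", "pos", "ref", "alt", "qual", "mq"])
    gt = np.array(gt_rows, np.int8) if gt_rows else np.zeros((0, len(individuals)), np.int8)
    return GenotypeMatrix(individuals, sites, gt), ibd


def autozygous_fraction(ibd: pd.DataFrame, individual: str, genome_cM: float) -> float:
    sub = ibd[ibd["individual"] == individual]
    return float(sub["length_cM"].sum()) / genome_cM


# ===========================================================================
# Sequencing-noise layer
# ===========================================================================

@dataclass(frozen=True)
class NoiseSpec:
    """Read-depth and quality model for per-genotype annotations.

    Depth per genotype is a gamma-Poisson mixture with mean ``mean_depth``
    and variance ``mean_depth * (1 + depth_dispersion)``; allele depths at
    heterozygotes are binomial around one half; sequencing errors flip reads
    with probability ``base_error_rate``.
    """

    mean_depth: float = 15.0
    depth_dispersion: float = 0.5
    base_error_rate: float = 0.001
    mapq_distribution: tuple[tuple[int, float], ...] = ((60, 0.95), (30, 0.03), (10, 0.02))

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.base_error_rate < 0.5:
            raise ValueError("base_error_rate must lie in [0, 0.5)")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")


def add_sequencing_noise(gm: GenotypeMatrix, noise: NoiseSpec, seed: int) -> GenotypeMatrix:
    """Annotate genotypes with depths and qualities; zero depth -> missing."""
    if gm.has_depths:
        raise ValueError("genotype matrix already carries depth annotations")
    rng = np.random.default_rng(seed)
    n_sites, n_samp = gm.gt.shape
    if noise.depth_dispersion > 0:
        shape = noise.mean_depth / noise.depth_dispersion
        lam = rng.gamma(shape, noise.depth_dispersion, size=(n_sites, n_samp))
    else:
        lam = np.full((n_sites, n_samp), noise.mean_depth)
    depth = rng.poisson(lam)

    e = noise.base_error_rate
    gt = gm.gt.copy()
    p_alt = np.where(gt == HET, 0.5, np.where(gt == HOM_ALT, 1.0 - e, e))
    ad_alt = rng.binomial(depth, np.clip(p_alt, 0.0, 1.0))
    # at heterozygotes, errors flip reads symmetrically
    if e > 0:
        het = gt == HET
        flips_to_ref = rng.binomial(ad_alt, e) * het
        flips_to_alt = rng.binomial(depth - ad_alt, e) * het
        ad_alt = ad_alt - flips_to_ref + flips_to_alt
    ad_ref = depth - ad_alt
    gt[depth == 0] = MISSING

    bq = min(60.0, -10.0 * math.log10(max(e, 1e-6)))
    sites = gm.sites.copy()
    sites["qual"] = np.round(bq - rng.uniform(0.0, 2.0, size=n_sites), 1)
    mq_vals = np.array([v for v, _ in noise.mapq_distribution])
    mq_p = np.array([p for _, p in noise.mapq_distribution], dtype=float)
    mq_p /= mq_p.sum()
    sites["mq"] = rng.choice(mq_vals, size=n_sites, p=mq_p).astype(float)
    return GenotypeMatrix(list(gm.samples), sites, gt, ad_ref.astype(int), ad_alt.astype(int))


# ===========================================================================
# mtDNA haplotypes
# ===========================================================================

def simulate_mtdna(cluster_centers: int, divergence_steps: int, n_per_cluster: int,
                   seq_length: int, seed: int) -> tuple[dict[str, str], dict[str, int]]:
    """Haplotype set with known cluster structure.

    Cluster centers form a chain, adjacent centers separated by
    ``divergence_steps`` substitutions at positions used nowhere else;
    members differ from their center at <= 2 further positions.  Returns
    ``(sequences, cluster_of)``.
    """
    if divergence_steps < 1:
        raise ValueError("divergence_steps must be >= 1")
    need = (cluster_centers - 1) * divergence_steps + cluster_centers * n_per_cluster * 2
    if need > seq_length:
        raise ValueError(
            f"seq_length={seq_length} too short for {need} distinct mutated positions"
        )
    rnd = random.Random(seed)
    base = [BASES[rnd.randrange(4)] for _ in range(seq_length)]
    free = list(range(seq_length))
    rnd.shuffle(free)

    def mutate(seq: list[str], k: int) -> list[str]:
        out = list(seq)
        for _ in range(k):
            pos = free.pop()
            out[pos] = rnd.choice([b for b in BASES if b != out[pos]])
        return out

    centers = [base]
    for _ in range(cluster_centers - 1):
        centers.append(mutate(centers[-1], divergence_steps))
    seqs: dict[str, str] = {}
    cluster_of: dict[str, int] = {}
    for c, center in enumerate(centers):
        for i in range(n_per_cluster):
            # the first member is the center itself (star-like structure);
            # the rest drift 1-2 private steps from it
            hap = center if i == 0 else mutate(center, 1 + rnd.randrange(2))
            name = f"c{c}_h{i}"
            seqs[name] = "".join(hap)
            cluster_of[name] = c
    return seqs, cluster_of


# ===========================================================================
# Gene models with planted coding variants
# ===========================================================================

#: (ref_codon, within-codon position, alt transcript base) per effect class
_PLANT_CATALOG = {
    "synonymous": ("CTG", 2, "C"),   # Leu -> Leu
    "missense": ("GAT", 2, "A"),     # Asp -> Glu
    "nonsense": ("CGA", 0, "T"),     # Arg -> Stop (TGA)
}

_SAFE_CODONS = ["GCT", "GGC", "ACC", "TTC", "GTG", "AAG", "GAG", "CCT",
                "ATC", "CAC", "AGC", "TGC"]  # no single-base adjacency games needed

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_gene_models(n_genes: int, cds_length_codons: int,
                         variant_plan: Sequence[tuple[str, int]], seed: int
                         ) -> tuple[list[GeneModel], dict[str, str], pd.DataFrame]:
    """Gene models + reference scaffolds + planted variants with truth labels.

    One two-exon gene per scaffold; strands alternate so both orientations
    are exercised.  ``variant_plan`` lists ``(effect_class, count)`` over
    {synonymous, missense, nonsense, splice_disrupting}.  Returns
    ``(genes, ref_seqs, planted)``; ``planted`` columns are
    ``scaffold, pos (1-based), ref, alt, gene_id, true_effect``.
    """
    rnd = random.Random(seed)
    if cds_length_codons < 4:
        raise ValueError("cds_length_codons must be >= 4")
    n_slots = n_genes * (cds_length_codons - 2)  # interior codons only
    coding_needed = sum(c for eff, c in variant_plan if eff != "splice_disrupting")
    splice_needed = sum(c for eff, c in variant_plan if eff == "splice_disrupting")
    if coding_needed > n_slots:
        raise ValueError(f"plan needs {coding_needed} codon slots, only {n_slots} available")
    if splice_needed > 2 * n_genes:
        raise ValueError(f"plan needs {splice_needed} splice sites, only {2 * n_genes} available")
    for eff, _ in variant_plan:
        if eff not in set(_PLANT_CATALOG) | {"splice_disrupting"}:
            raise ValueError(f"unknown effect class {eff!r}")

    up, down, intron_len = 100, 100, 30
    genes: list[GeneModel] = []
    ref_seqs: dict[str, str] = {}
    transcripts: list[list[str]] = []
    for g in range(n_genes):
        codons = [rnd.choice(_SAFE_CODONS) for _ in range(cds_length_codons)]
        codons[0] = "ATG"
        transcripts.append(codons)

    # assign coding variants to (gene, codon) slots and splice variants to introns
    slot_iter = itertools.cycle(range(n_genes))
    used: set[tuple[int, int]] = set()
    coding_assign: list[tuple[int, int, str]] = []  # (gene, codon_idx, effect)
    for eff, count in variant_plan:
        if eff == "splice_disrupting":
            continue
        for _ in range(count):
            for _ in range(n_genes * cds_length_codons):
                g = next(slot_iter)
                ci = rnd.randrange(1, cds_length_codons - 1)
                if (g, ci) not in used:
                    used.add((g, ci))
                    coding_assign.append((g, ci, eff))
                    break
            else:
                raise ValueError("could not place all planned coding variants")
    for g, ci, eff in coding_assign:
        transcripts[g][ci] = _PLANT_CATALOG[eff][0]

    planted_rows = []
    splice_budget = splice_needed
    for g in range(n_genes):
        codons = transcripts[g]
        t_seq = "".join(codons)
        L = len(t_seq)
        L1 = (cds_length_codons // 2) * 3  # exon boundary on a codon edge is fine
        strand = "+" if g % 2 == 0 else "-"
        scaffold = f"gene_scaffold_{g}"
        intron = "GT" + "".join(rnd.choice(BASES) for _ in range(intron_len - 4)) + "AG"
        flank_u = "".join(rnd.choice(BASES) for _ in range(up))
        flank_d = "".join(rnd.choice(BASES) for _ in range(down))
        if strand == "+":
            seq = flank_u + t_seq[:L1] + intron + t_seq[L1:] + flank_d
            e1 = (up, up + L1)
            e2 = (up + L1 + intron_len, up + L1 + intron_len + (L - L1))
            exons = (e1, e2)
        else:
            rc = lambda s: s.translate(_COMPLEMENT)[::-1]
            seq = flank_u + rc(t_seq[L1:]) + rc(intron) + rc(t_seq[:L1]) + flank_d
            e2 = (up, up + (L - L1))                       # 3' exon, left in genome
            e1 = (up + (L - L1) + intron_len,
                  up + (L - L1) + intron_len + L1)         # 5' exon, right in genome
            exons = (e1, e2)
        gene = GeneModel(f"gene{g}", scaffold, strand, exons)
        genes.append(gene)
        ref_seqs[scaffold] = seq

        for gg, ci, eff in coding_assign:
            if gg != g:
                continue
            codon, off, alt_t = _PLANT_CATALOG[eff]
            cds_pos = ci * 3 + off
            gpos = gene.genomic_position(cds_pos)
            ref_b = seq[gpos]
            alt_b = alt_t if strand == "+" else alt_t.translate(_COMPLEMENT)
            assert ref_b == (codon[off] if strand == "+" else codon[off].translate(_COMPLEMENT))
            planted_rows.append([scaffold, gpos + 1, ref_b, alt_b, gene.gene_id, eff])

        # splice variants: hit the donor GT (+1 intronic base after the 5' exon)
        if splice_budget > 0:
            if strand == "+":
                donor = up + L1  # first intron base (the G of GT)
            else:
                donor = up + (L - L1) + intron_len - 1  # transcript-first intron base
            ref_b = seq[donor]
            alt_b = rnd.choice([b for b in BASES if b != ref_b])
            planted_rows.append([scaffold, donor + 1, ref_b, alt_b, gene.gene_id,
                                 "splice_disrupting"])
            splice_budget -= 1
    if splice_budget > 0:
        raise ValueError("could not place all planned splice variants")
    planted = pd.DataFrame(planted_rows,
                           columns=["scaffold", "pos", "ref", "alt", "gene_id", "true_effect"])
    return genes, ref_seqs, planted
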