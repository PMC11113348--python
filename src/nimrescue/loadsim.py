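"""Forward-in-time Wright–Fisher simulator of deleterious and neutral variation.

The simulated genome is an exome of nine autosome pairs, each carrying 1000
genes of 1500 bp (13.5 Mb total).  Genes are non-recombining blocks: the
within-gene rate (1e-9/bp over 1500 bp) is negligible, so crossovers are
placed only between adjacent genes (probability 1e-3 per gap per meiosis) and
chromosomes assort freely.  New deleterious mutations arise at 2.4e-8 per bp
per generation and neutral ones at 1.6e-8 (a 3:2 ratio).  Each deleterious
mutation carries a selection coefficient s (stored as a positive magnitude)
and dominance h; fitness is multiplicative across sites,
``w = prod (1 - h s)^het * (1 - s)^hom``, with soft selection inside a fixed-N
Wright–Fisher scheme (parents sampled proportional to fitness within sexes).

The exact distribution of fitness effects is not observable for the leopard;
the default is a gamma DFE (shape 0.2, mean |s| 0.03) plus a 1% recessive
lethal class (s = 1, h = 0.02), with ``h = 0.5 / (1 + 7071 |s|)`` for
non-lethals.  :func:`calibrate_dfe` rescales the gamma mean so that the
equilibrium *masked* load of a reference population hits a target expressed in
lethal equivalents (~6 LE by default), which makes downstream conclusions
insensitive to the unknown DFE details.

The long neutral phase that would be needed to equilibrate neutral diversity
is replaced by a coalescent initialization (msprime) of the neutral variation
at the start of the selection phase; neutral mutations then continue to arise
forward in time.

Load accounting (per individual, linear lethal-equivalents scale):
``realized = sum_hom s + sum_het h s``; ``total = sum_hom s + sum_het s``;
``masked = total - realized`` (heterozygous-only, the hidden load).
Population values are means over individuals.  Mutations fixed in all tracked
populations are pruned from genotypes and accumulated separately as drift load.

Populations are stored columnar: all haplotypes concatenated into one sorted
int64 id array with an offsets vector, so a whole generation is produced by a
single compiled kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "GenomeConfig",
    "DFE",
    "SimPopulation",
    "LoadMetrics",
    "ForwardSimulator",
    "CalibrationResult",
    "calibrate_dfe",
    "run_burnin",
    "run_decline_and_split",
    "run_rescue_scenario",
    "compute_load_metrics",
    "compute_pi",
]


@dataclass(frozen=True)
class GenomeConfig:
    n_chromosomes: int = 9
    genes_per_chromosome: int = 1000
    gene_length_bp: int = 1500
    recomb_between_genes: float = 1e-3
    recomb_within_gene: float = 1e-9          # folded into the gene-block approximation
    mu_deleterious: float = 2.4e-8
    mu_neutral: float = 1.6e-8

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome

    @property
    def exome_bp(self) -> int:
        return self.n_genes * self.gene_length_bp

    @property
    def u_deleterious(self) -> float:
        """Expected deleterious mutations per gamete per generation."""
        return self.mu_deleterious * self.exome_bp

    @property
    def u_neutral(self) -> float:
        return self.mu_neutral * self.exome_bp

    def rescaled(self, factor: float) -> "GenomeConfig":
        """Scale mutation and recombination rates up by ``factor`` (for runs
        that scale N and time down by the same factor, preserving N*mu, N*r)."""
        return replace(
            self,
            mu_deleterious=self.mu_deleterious * factor,
            mu_neutral=self.mu_neutral * factor,
            recomb_between_genes=min(self.recomb_between_genes * factor, 0.5),
        )


@dataclass(frozen=True)
class DFE:
    """Gamma DFE for non-lethals plus a discrete recessive-lethal class."""

    gamma_shape: float = 0.2
    gamma_mean_s: float = 0.03
    lethal_fraction: float = 0.01
    lethal_s: float = 1.0
    lethal_h: float = 0.02
    h_scale: float = 7071.0       # h = 0.5 / (1 + h_scale * s)
    scale: float = 1.0            # multiplier on gamma_mean_s set by calibration

    def draw(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw (s, h) for ``n`` new deleterious mutations."""
        mean = self.gamma_mean_s * self.scale
        if mean <= 0:
            return np.zeros(n), np.full(n, 0.5)
        s = np.empty(n)
        h = np.empty(n)
        lethal = rng.random(n) < self.lethal_fraction
        k = int((~lethal).sum())
        s[~lethal] = np.minimum(rng.gamma(self.gamma_shape, mean / self.gamma_shape, k), 1.0)
        h[~lethal] = 0.5 / (1.0 + self.h_scale * s[~lethal])
        s[lethal] = self.lethal_s
        h[lethal] = self.lethal_h
        return s, h

    def rescaled(self, factor: float) -> "DFE":
        return replace(self, gamma_mean_s=min(self.gamma_mean_s * factor, 1.0))


@dataclass
class SimPopulation:
    """A diploid population, haplotypes stored columnar.

    ``flat`` concatenates all haplotype mutation-id arrays (each id-sorted);
    ``offsets`` has length ``2n + 1`` and haplotype k is
    ``flat[offsets[k]:offsets[k+1]]``.  Haplotypes 2i and 2i+1 belong to
    individual i.
    """

    flat: np.ndarray
    offsets: np.ndarray
    sexes: np.ndarray          # 0 = female, 1 = male
    label: str = "ancestral"
    generation: int = 0
    drift_load_le: float = 0.0  # fixed (pruned) deleterious load, linear LE scale

    @property
    def n(self) -> int:
        return (len(self.offsets) - 1) // 2

    def hap(self, k: int) -> np.ndarray:
        return self.flat[self.offsets[k]:self.offsets[k + 1]]

    def copy(self) -> "SimPopulation":
        return SimPopulation(flat=self.flat.copy(), offsets=self.offsets.copy(),
                             sexes=self.sexes.copy(), label=self.label,
                             generation=self.generation,
                             drift_load_le=self.drift_load_le)

    @classmethod
    def from_haplotype_list(cls, haps: list[np.ndarray], sexes: np.ndarray,
                            **kw) -> "SimPopulation":
        offsets = np.zeros(len(haps) + 1, dtype=np.int64)
        np.cumsum([len(h) for h in haps], out=offsets[1:])
        flat = np.concatenate(haps) if haps and offsets[-1] else np.empty(0, np.int64)
        return cls(flat=flat.astype(np.int64), offsets=offsets, sexes=sexes, **kw)


@dataclass
class LoadMetrics:
    mean_fitness: float
    total_le: float
    realized_le: float
    masked_le: float
    drift_load_le: float
    pi: float
    n: int
    per_individual: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# compiled kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _generation_kernel(flat, offsets, parents2, gene_of, new_flat, new_offsets,
                       n_chrom, genes_per_chrom, r_between, seed):
    """Produce all gametes of one generation.

    ``parents2[g]`` is the parent of gamete g.  Recombination: side at gene
    ``x`` equals the parity of switch points <= x, where switch points are
    crossovers between adjacent genes (probability ``r_between`` per gap) plus
    a fair-coin flip at each chromosome start (free assortment).  New-mutation
    ids for gamete g, already generated by the caller, are
    ``new_flat[new_offsets[g]:new_offsets[g+1]]`` (ascending, above all old
    ids) and are appended to keep haplotypes id-sorted.
    """
    np.random.seed(seed)
    n_g = parents2.size
    gaps = (genes_per_chrom - 1) * n_chrom
    total = 0
    for g in range(n_g):
        p = parents2[g]
        total += (offsets[2 * p + 2] - offsets[2 * p]) \
            + (new_offsets[g + 1] - new_offsets[g])
    out = np.empty(total, dtype=np.int64)
    child_offsets = np.empty(n_g + 1, dtype=np.int64)
    child_offsets[0] = 0
    k = 0
    buf = np.empty(64, dtype=np.int64)
    for g in range(n_g):
        # switch points for this meiosis
        n_xo = np.random.binomial(gaps, r_between)
        n_sw = 0
        if n_xo + n_chrom > buf.size:
            buf = np.empty(n_xo + n_chrom, dtype=np.int64)
        for _ in range(n_xo):
            pos = np.random.randint(0, gaps)
            buf[n_sw] = (pos // (genes_per_chrom - 1)) * genes_per_chrom \
                + pos % (genes_per_chrom - 1) + 1
            n_sw += 1
        for c in range(n_chrom):
            if np.random.random() < 0.5:
                buf[n_sw] = c * genes_per_chrom
                n_sw += 1
        sw = np.sort(buf[:n_sw])

        p = parents2[g]
        a0, a1 = offsets[2 * p], offsets[2 * p + 1]
        b0, b1 = offsets[2 * p + 1], offsets[2 * p + 2]
        # filter each parental haplotype by inheritance side, then merge the
        # two id-sorted runs in place
        start = k
        for idx in range(a0, a1):
            v = flat[idx]
            if (np.searchsorted(sw, gene_of[v], side="right") & 1) == 0:
                out[k] = v
                k += 1
        mid = k
        for idx in range(b0, b1):
            v = flat[idx]
            if (np.searchsorted(sw, gene_of[v], side="right") & 1) == 1:
                out[k] = v
                k += 1
        end = k
        merged = np.empty(end - start, dtype=np.int64)
        i, j, m = start, mid, 0
        while i < mid and j < end:
            if out[i] < out[j]:
                merged[m] = out[i]; i += 1
            else:
                merged[m] = out[j]; j += 1
            m += 1
        while i < mid:
            merged[m] = out[i]; i += 1; m += 1
        while j < end:
            merged[m] = out[j]; j += 1; m += 1
        out[start:end] = merged
        for t in range(new_offsets[g], new_offsets[g + 1]):
            out[k] = new_flat[t]
            k += 1
        child_offsets[g + 1] = k
    return out[:k], child_offsets


@njit(cache=True)
def _fitness_all(flat, offsets, log_het, log_hom):
    n = (offsets.size - 1) // 2
    logw = np.zeros(n)
    for ind in range(n):
        a0, a1 = offsets[2 * ind], offsets[2 * ind + 1]
        b0, b1 = offsets[2 * ind + 1], offsets[2 * ind + 2]
        tot = 0.0
        i, j = a0, b0
        while i < a1 and j < b1:
            va, vb = flat[i], flat[j]
            if va == vb:
                tot += log_hom[va]; i += 1; j += 1
            elif va < vb:
                tot += log_het[va]; i += 1
            else:
                tot += log_het[vb]; j += 1
        while i < a1:
            tot += log_het[flat[i]]; i += 1
        while j < b1:
            tot += log_het[flat[j]]; j += 1
        logw[ind] = tot
    return logw


@njit(cache=True)
def _load_all(flat, offsets, s, h):
    """Per-individual (realized, total) load on the linear LE scale."""
    n = (offsets.size - 1) // 2
    realized = np.zeros(n)
    total = np.zeros(n)
    for ind in range(n):
        a0, a1 = offsets[2 * ind], offsets[2 * ind + 1]
        b0, b1 = offsets[2 * ind + 1], offsets[2 * ind + 2]
        r = t = 0.0
        i, j = a0, b0
        while i < a1 and j < b1:
            va, vb = flat[i], flat[j]
            if va == vb:
                r += s[va]; t += s[va]; i += 1; j += 1
            elif va < vb:
                r += h[va] * s[va]; t += s[va]; i += 1
            else:
                r += h[vb] * s[vb]; t += s[vb]; j += 1
        while i < a1:
            v = flat[i]; r += h[v] * s[v]; t += s[v]; i += 1
        while j < b1:
            v = flat[j]; r += h[v] * s[v]; t += s[v]; j += 1
        realized[ind] = r
        total[ind] = t
    return realized, total


@njit(cache=True)
def _load_all_log(flat, offsets, log_het, log_hom):
    """Per-individual (realized, total) load on the exact -ln(fitness) scale.

    ``realized`` is -ln w; ``total`` treats every carried site as if
    homozygous.  Homozygous recessive lethals make both infinite.
    """
    n = (offsets.size - 1) // 2
    realized = np.zeros(n)
    total = np.zeros(n)
    for ind in range(n):
        a0, a1 = offsets[2 * ind], offsets[2 * ind + 1]
        b0, b1 = offsets[2 * ind + 1], offsets[2 * ind + 2]
        r = t = 0.0
        i, j = a0, b0
        while i < a1 and j < b1:
            va, vb = flat[i], flat[j]
            if va == vb:
                r -= log_hom[va]; t -= log_hom[va]; i += 1; j += 1
            elif va < vb:
                r -= log_het[va]; t -= log_hom[va]; i += 1
            else:
                r -= log_het[vb]; t -= log_hom[vb]; j += 1
        while i < a1:
            v = flat[i]; r -= log_het[v]; t -= log_hom[v]; i += 1
        while j < b1:
            v = flat[j]; r -= log_het[v]; t -= log_hom[v]; j += 1
        realized[ind] = r
        total[ind] = t
    return realized, total


@njit(cache=True)
def _drop_ids(flat, offsets, drop):
    """Remove the sorted id set ``drop`` from every haplotype."""
    out = np.empty(flat.size, dtype=np.int64)
    new_offsets = np.empty(offsets.size, dtype=np.int64)
    new_offsets[0] = 0
    k = 0
    for hp in range(offsets.size - 1):
        for idx in range(offsets[hp], offsets[hp + 1]):
            v = flat[idx]
            pos = np.searchsorted(drop, v)
            if pos >= drop.size or drop[pos] != v:
                out[k] = v
                k += 1
        new_offsets[hp + 1] = k
    return out[:k], new_offsets


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

class _MutationTable:
    """Growable per-mutation effect arrays indexed by mutation id."""

    def __init__(self, capacity: int = 1 << 16):
        self.n = 0
        self.s = np.zeros(capacity)
        self.h = np.full(capacity, 0.5)
        self.gene = np.zeros(capacity, dtype=np.int64)
        self.log_het = np.zeros(capacity)
        self.log_hom = np.zeros(capacity)

    def _grow(self, need: int) -> None:
        cap = len(self.s)
        if self.n + need <= cap:
            return
        new_cap = cap
        while new_cap < self.n + need:
            new_cap *= 2
        for name in ("s", "h", "gene", "log_het", "log_hom"):
            arr = getattr(self, name)
            new = np.zeros(new_cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)

    def append(self, s: np.ndarray, h: np.ndarray, gene: np.ndarray) -> np.ndarray:
        k = len(s)
        self._grow(k)
        ids = np.arange(self.n, self.n + k, dtype=np.int64)
        self.s[ids] = s
        self.h[ids] = h
        self.gene[ids] = gene
        with np.errstate(divide="ignore"):
            self.log_het[ids] = np.log1p(-h * s)
            self.log_hom[ids] = np.log1p(-s)       # -inf for recessive lethals
        self.n += k
        return ids


class ForwardSimulator:
    """Wright–Fisher engine shared by burn-in, decline/split and rescue runs."""

    def __init__(self, config: GenomeConfig | None = None, dfe: DFE | None = None,
                 seed: int = 0):
        self.config = config or GenomeConfig()
        self.dfe = dfe or DFE()
        self.rng = np.random.default_rng(seed)
        self.table = _MutationTable()
        self._n_del_input = 0
        self._n_neu_input = 0

    # -- initialization ----------------------------------------------------
    def init_population(self, n: int, label: str = "ancestral",
                        neutral_init: bool = True) -> SimPopulation:
        """A population of ``n`` diploids, optionally seeded with equilibrium
        neutral variation from a coalescent simulation."""
        per_hap: list[list[int]] = [[] for _ in range(2 * n)]
        if neutral_init:
            import msprime

            cfg = self.config
            r_bp = cfg.recomb_between_genes / cfg.gene_length_bp
            ts = msprime.sim_ancestry(
                samples=n, population_size=n, ploidy=2,
                sequence_length=cfg.exome_bp, recombination_rate=r_bp,
                random_seed=int(self.rng.integers(1, 2**31 - 1)),
            )
            ts = msprime.sim_mutations(
                ts, rate=cfg.mu_neutral,
                random_seed=int(self.rng.integers(1, 2**31 - 1)),
            )
            for var in ts.variants():
                gene = int(var.site.position) // cfg.gene_length_bp
                genotypes = np.asarray(var.genotypes)
                for allele in range(1, len(var.alleles)):
                    carriers = np.flatnonzero(genotypes == allele)
                    if carriers.size == 0 or carriers.size == 2 * n:
                        continue
                    mid = int(self.table.append(
                        np.zeros(1), np.full(1, 0.5), np.array([gene]))[0])
                    for c in carriers:
                        per_hap[c].append(mid)
        haps = [np.array(sorted(v), dtype=np.int64) for v in per_hap]
        return SimPopulation.from_haplotype_list(
            haps, self._balanced_sexes(n), label=label)

    def _balanced_sexes(self, n: int) -> np.ndarray:
        sexes = np.zeros(n, dtype=np.int64)
        sexes[n // 2:] = 1
        self.rng.shuffle(sexes)
        return sexes

    # -- per-generation machinery ------------------------------------------
    def log_fitness(self, pop: SimPopulation) -> np.ndarray:
        t = self.table
        return _fitness_all(pop.flat, pop.offsets, t.log_het, t.log_hom)

    def _pick_parents(self, pop: SimPopulation, n_off: int) -> np.ndarray:
        """Interleaved (mother, father) pairs as a 2*n_off parent vector."""
        logw = self.log_fitness(pop)
        finite = np.isfinite(logw)
        w = np.zeros(pop.n)
        if finite.any():
            w[finite] = np.exp(logw[finite] - logw[finite].max())
        females = np.flatnonzero(pop.sexes == 0)
        males = np.flatnonzero(pop.sexes == 1)
        if females.size == 0 or males.size == 0:
            raise RuntimeError("population lost one sex entirely")
        wf, wm = w[females], w[males]
        if wf.sum() <= 0 or wm.sum() <= 0:
            raise RuntimeError("mean fitness underflow: no viable parents")
        mothers = self.rng.choice(females, size=n_off, p=wf / wf.sum())
        fathers = self.rng.choice(males, size=n_off, p=wm / wm.sum())
        parents2 = np.empty(2 * n_off, dtype=np.int64)
        parents2[0::2] = mothers
        parents2[1::2] = fathers
        return parents2

    def _new_mutation_ids(self, n_gametes: int) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        u_tot = cfg.u_deleterious + cfg.u_neutral
        counts = self.rng.poisson(u_tot, size=n_gametes)
        total = int(counts.sum())
        new_offsets = np.zeros(n_gametes + 1, dtype=np.int64)
        np.cumsum(counts, out=new_offsets[1:])
        if total == 0:
            return np.empty(0, dtype=np.int64), new_offsets
        p_del = cfg.u_deleterious / u_tot if u_tot > 0 else 0.0
        is_del = self.rng.random(total) < p_del
        s = np.zeros(total)
        h = np.full(total, 0.5)
        n_del = int(is_del.sum())
        if n_del:
            s_d, h_d = self.dfe.draw(self.rng, n_del)
            s[is_del] = s_d
            h[is_del] = h_d
        genes = self.rng.integers(0, cfg.n_genes, size=total)
        ids = self.table.append(s, h, genes)
        self._n_del_input += n_del
        self._n_neu_input += total - n_del
        return ids, new_offsets

    def _make_gametes(self, pop: SimPopulation, parents2: np.ndarray,
                      label: str, generation: int) -> SimPopulation:
        cfg = self.config
        new_flat, new_offsets = self._new_mutation_ids(parents2.size)
        kseed = int(self.rng.integers(0, 2**31 - 1))
        flat, offsets = _generation_kernel(
            pop.flat, pop.offsets, parents2, self.table.gene,
            new_flat, new_offsets, cfg.n_chromosomes, cfg.genes_per_chromosome,
            cfg.recomb_between_genes, kseed)
        return SimPopulation(flat=flat, offsets=offsets,
                             sexes=self._balanced_sexes(parents2.size // 2),
                             label=label, generation=generation,
                             drift_load_le=pop.drift_load_le)

    def step(self, pop: SimPopulation, n_offspring: int | None = None) -> SimPopulation:
        """Produce the next non-overlapping generation."""
        n_off = pop.n if n_offspring is None else n_offspring
        if n_off < 2:
            raise ValueError("population schedule requires N >= 2")
        parents2 = self._pick_parents(pop, n_off)
        return self._make_gametes(pop, parents2, pop.label, pop.generation + 1)

    def make_offspring(self, pop: SimPopulation, k: int,
                       label: str = "released") -> SimPopulation:
        """``k`` extra offspring (1:1 sex ratio) bred from ``pop`` without
        advancing it — used for release cohorts."""
        if k > pop.n:
            raise ValueError("release cohort exceeds the captive population size")
        parents2 = self._pick_parents(pop, k)
        return self._make_gametes(pop, parents2, label, pop.generation)

    def run(self, pop: SimPopulation, generations: int,
            prune_interval: int = 25) -> SimPopulation:
        for g in range(generations):
            pop = self.step(pop)
            if (g + 1) % prune_interval == 0:
                self.prune_fixed([pop])
        self.prune_fixed([pop])
        return pop

    def sample_founders(self, pop: SimPopulation, n: int, label: str) -> SimPopulation:
        idx = self.rng.choice(pop.n, size=n, replace=False)
        haps = []
        for i in idx:
            haps.append(pop.hap(2 * i).copy())
            haps.append(pop.hap(2 * i + 1).copy())
        return SimPopulation.from_haplotype_list(
            haps, self._balanced_sexes(n), label=label,
            generation=pop.generation, drift_load_le=pop.drift_load_le)

    def merge_into(self, pop: SimPopulation, extra: SimPopulation) -> SimPopulation:
        """Append the individuals of ``extra`` to ``pop`` (releases)."""
        flat = np.concatenate([pop.flat, extra.flat])
        offsets = np.concatenate([pop.offsets, extra.offsets[1:] + pop.offsets[-1]])
        return SimPopulation(flat=flat, offsets=offsets,
                             sexes=np.concatenate([pop.sexes, extra.sexes]),
                             label=pop.label, generation=pop.generation,
                             drift_load_le=pop.drift_load_le)

    def prune_fixed(self, pops: list[SimPopulation]) -> int:
        """Remove mutations fixed across every haplotype of every listed
        population; their deleterious effect accumulates as drift load."""
        if all(p.flat.size == 0 for p in pops):
            return 0
        all_ids = np.concatenate([p.flat for p in pops])
        total_haps = sum(len(p.offsets) - 1 for p in pops)
        uniq, counts = np.unique(all_ids, return_counts=True)
        fixed = uniq[counts == total_haps]
        if fixed.size == 0:
            return 0
        add = float(self.table.s[fixed].sum())
        for p in pops:
            p.flat, p.offsets = _drop_ids(p.flat, p.offsets, fixed)
            p.drift_load_le += add
        return int(fixed.size)

    @property
    def mutation_input_ratio(self) -> float:
        """Realized deleterious:neutral input ratio (expected 3:2)."""
        if self._n_neu_input == 0:
            return float("inf")
        return self._n_del_input / self._n_neu_input

    # -- metrics -----------------------------------------------------------
    def metrics(self, pop: SimPopulation, per_individual: bool = False,
                scale: str = "linear") -> LoadMetrics:
        """Load metrics per individual, averaged over the population.

        ``scale='linear'`` counts lethal equivalents as plain sums of
        selection coefficients (a homozygous lethal contributes 1); it is the
        default because it stays finite in the presence of homozygous
        lethals.  ``scale='log'`` uses the exact -ln(fitness) decomposition
        (realized = -ln w), under which masked + realized = total is an exact
        identity but homozygous lethals contribute infinity.
        """
        t = self.table
        if scale == "linear":
            real, tot = _load_all(pop.flat, pop.offsets, t.s, t.h)
        elif scale == "log":
            real, tot = _load_all_log(pop.flat, pop.offsets, t.log_het, t.log_hom)
        else:
            raise ValueError("scale must be 'linear' or 'log'")
        logw = _fitness_all(pop.flat, pop.offsets, t.log_het, t.log_hom)
        w = np.exp(logw)
        detail = None
        if per_individual:
            detail = pd.DataFrame({"realized_le": real, "total_le": tot,
                                   "masked_le": tot - real, "fitness": w})
        return LoadMetrics(
            mean_fitness=float(w.mean()),
            total_le=float(tot.mean()),
            realized_le=float(real.mean()),
            masked_le=float((tot - real).mean()),
            drift_load_le=pop.drift_load_le,
            pi=self.pi(pop),
            n=pop.n,
            per_individual=detail,
        )

    def pi(self, pop: SimPopulation) -> float:
        """Neutral nucleotide diversity per site:
        ``sum 2 p (1-p) * n/(n-1) / L`` over segregating neutral sites,
        with n = the number of haplotypes."""
        n_hap = len(pop.offsets) - 1
        if n_hap < 2:
            raise ValueError("pi needs at least two haplotypes")
        if pop.flat.size == 0:
            return 0.0
        uniq, counts = np.unique(pop.flat, return_counts=True)
        neutral = self.table.s[uniq] == 0.0
        p = counts[neutral] / n_hap
        return float(np.sum(2 * p * (1 - p)) * n_hap / (n_hap - 1) / self.config.exome_bp)


# ---------------------------------------------------------------------------
# high-level operations
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    dfe: DFE
    achieved_masked_le: float
    target_masked_le: float
    trace: list = field(default_factory=list)


def _equilibrium_masked_load(config: GenomeConfig, dfe: DFE, n: int,
                             generations: int, seed: int,
                             sample_every: int = 25) -> float:
    """Masked load averaged over the final third of a pilot run."""
    sim = ForwardSimulator(config, dfe, seed=seed)
    pop = sim.init_population(n, neutral_init=False)
    records = []
    start_avg = generations * 2 // 3
    for g in range(generations):
        pop = sim.step(pop)
        if (g + 1) % sample_every == 0:
            sim.prune_fixed([pop])
            if g >= start_avg:
                records.append(sim.metrics(pop).masked_le)
    return float(np.mean(records))


def calibrate_dfe(
    config: GenomeConfig | None = None,
    target_masked_le: float = 6.0,
    n_cal: int = 200,
    seed: int = 0,
    dfe: DFE | None = None,
    pilot_generations: int | None = None,
    rel_tol: float = 0.05,
    max_iter: int = 8,
) -> CalibrationResult:
    """Rescale the DFE so the equilibrium masked load hits the target.

    Runs pilot Wright–Fisher simulations of ``n_cal`` diploids and bisects (in
    log space) on the scale factor multiplying the gamma mean |s|; masked load
    is monotone in the scale over the relevant range because stronger
    mutations are more recessive under the h–s map and contribute more
    heterozygous load.  The same pilot seed is reused across evaluations
    (common random numbers) so the bisection sees a quasi-deterministic
    function.
    """
    if target_masked_le < 0:
        raise ValueError("target must be >= 0")
    config = config or GenomeConfig()
    base = dfe or DFE()
    if target_masked_le == 0:
        return CalibrationResult(dfe=replace(base, scale=0.0),
                                 achieved_masked_le=0.0,
                                 target_masked_le=0.0)
    gens = pilot_generations or 10 * n_cal

    def measure(scale: float) -> float:
        return _equilibrium_masked_load(config, replace(base, scale=scale),
                                        n_cal, gens, seed=seed)

    trace: list[tuple[float, float]] = []
    scale = base.scale
    val = measure(scale)
    trace.append((scale, val))
    lo = hi = None
    grow = 0
    while val < target_masked_le and grow < 6:
        lo = (scale, val)
        scale *= 2.0
        val = measure(scale)
        trace.append((scale, val))
        grow += 1
    if val < target_masked_le:
        raise RuntimeError(f"calibration failed to bracket target; trace={trace}")
    hi = (scale, val)
    if lo is None:
        shrink = 0
        while val > target_masked_le and shrink < 6:
            hi = (scale, val)
            scale /= 2.0
            val = measure(scale)
            trace.append((scale, val))
            shrink += 1
        if val > target_masked_le:
            raise RuntimeError(f"calibration failed to bracket target; trace={trace}")
        lo = (scale, val)

    best = min(trace, key=lambda t: abs(t[1] - target_masked_le))
    for _ in range(max_iter):
        if abs(best[1] - target_masked_le) / target_masked_le <= rel_tol:
            break
        mid = float(np.sqrt(lo[0] * hi[0]))
        val = measure(mid)
        trace.append((mid, val))
        if val < target_masked_le:
            lo = (mid, val)
        else:
            hi = (mid, val)
        if abs(val - target_masked_le) < abs(best[1] - target_masked_le):
            best = (mid, val)
    return CalibrationResult(dfe=replace(base, scale=best[0]),
                             achieved_masked_le=best[1],
                             target_masked_le=target_masked_le, trace=trace)


def run_burnin(
    config: GenomeConfig,
    dfe: DFE,
    n_ancestral: int,
    selection_generations: int,
    seed: int = 0,
    neutral_init: bool = True,
) -> tuple[ForwardSimulator, SimPopulation]:
    """Two-stage burn-in: coalescent neutral initialization (standing in for
    the long neutral phase) followed by ``selection_generations`` of forward
    Wright–Fisher evolution with the full mutational process."""
    if selection_generations < 10 * n_ancestral:
        warnings.warn(
            "selection phase shorter than 10N generations; load may not be at "
            "mutation-selection-drift equilibrium", stacklevel=2)
    sim = ForwardSimulator(config, dfe, seed=seed)
    pop = sim.init_population(n_ancestral, label="ancestral", neutral_init=neutral_init)
    pop = sim.run(pop, selection_generations)
    return sim, pop


def run_decline_and_split(
    sim: ForwardSimulator,
    pop: SimPopulation,
    wild_schedule: list[int] | None = None,
    captive_n: int = 64,
    captive_generations: int = 24,
) -> tuple[SimPopulation, SimPopulation]:
    """Found a captive line and let wild and captive evolve independently.

    Default wild schedule: linear decline from 1000 to 110 over the captive
    generations.  The captive line is founded from the ancestral population at
    the split and held at ``captive_n`` breeders.
    """
    if wild_schedule is None:
        wild_schedule = [int(round(x)) for x in
                         np.linspace(1000, 110, captive_generations)]
    if any(n < 2 for n in wild_schedule):
        raise ValueError("wild schedule must keep N >= 2")
    captive = sim.sample_founders(pop, captive_n, label="captive")
    wild = pop.copy()
    wild.label = "wild"
    for g in range(max(len(wild_schedule), captive_generations)):
        if g < len(wild_schedule):
            wild = sim.step(wild, n_offspring=wild_schedule[g])
        if g < captive_generations:
            captive = sim.step(captive)
        if (g + 1) % 10 == 0:
            sim.prune_fixed([wild, captive])
    sim.prune_fixed([wild, captive])
    return wild, captive


def run_rescue_scenario(
    sim: ForwardSimulator,
    wild: SimPopulation,
    captive: SimPopulation,
    k_released: int,
    horizon: int = 20,
    record_every: int = 1,
) -> pd.DataFrame:
    """Release ``k_released`` captive-born individuals into the wild breeding
    pool each generation for ``horizon`` generations.

    Released individuals join the wild pool as adults before reproduction and
    count toward that generation's breeding pool; the number of wild offspring
    is held at its contemporary value.  The captive line is maintained at its
    own size in parallel.  Returns a tidy per-generation metric table.
    """
    if k_released > captive.n:
        raise ValueError("k exceeds captive population size")
    wild = wild.copy()
    captive = captive.copy()
    n_wild = wild.n
    rows = []

    def record(gen: int) -> None:
        m = sim.metrics(wild)
        rows.append({"generation": gen, "k": k_released,
                     "total_le": m.total_le, "realized_le": m.realized_le,
                     "masked_le": m.masked_le, "mean_fitness": m.mean_fitness,
                     "pi": m.pi, "drift_load_le": m.drift_load_le})

    record(0)
    for g in range(1, horizon + 1):
        if k_released > 0:
            cohort = sim.make_offspring(captive, k_released)
            wild = sim.merge_into(wild, cohort)
        wild = sim.step(wild, n_offspring=n_wild)
        captive = sim.step(captive)
        if g % 5 == 0:
            sim.prune_fixed([wild, captive])
        if g % record_every == 0 or g == horizon:
            record(g)
    return pd.DataFrame(rows).drop_duplicates("generation").reset_index(drop=True)


# module-level conveniences mirroring the simulator methods ------------------

def compute_load_metrics(sim: ForwardSimulator, pop: SimPopulation,
                         per_individual: bool = False,
                         scale: str = "linear") -> LoadMetrics:
    if pop.n == 0:
        raise ValueError("empty population")
    return sim.metrics(pop, per_individual=per_individual, scale=scale)


def compute_pi(sim: ForwardSimulator, pop: SimPopulation) -> float:
    return sim.pi(pop)
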