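"""Identity and diversity statistics for multilocus microsatellite data.

Implements the noninvasive-genotyping workflow (probability of identity for
siblings, consensus genotyping, individual matching with the sex locus as a
verification marker) and the population-genetic summaries used to compare
wild and captive leopard populations: allele counts, effective allele numbers,
unbiased expected heterozygosity, rarefied allelic richness, distance-based
AMOVA with a Phi-statistic reported as F_ST, Mantel isolation-by-distance and
Smouse–Peakall multilocus spatial autocorrelation.

Individual-level genetic distances follow the squared allele-count metric used
for codominant data in GenAlEx: encoding a single-locus genotype as the vector
``y`` of allele copy numbers, ``d^2 = 0.5 * ||y_i - y_j||^2`` (0 for identical
genotypes, 1 hom vs het sharing an allele, 2 disjoint hets, 3 hom vs disjoint
het, 4 opposite homozygotes), summed over co-typed loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import f_oneway

from .synthetic_data import GenotypeDataset

__all__ = [
    "PidSibResult",
    "MatchReport",
    "DiversitySummary",
    "AmovaResult",
    "Correlogram",
    "pid_sib",
    "consensus_and_match",
    "diversity_summary",
    "amova_fst",
    "mantel_ibd",
    "spatial_autocorrelation",
    "genetic_distance_matrix",
    "species_assay_summary",
]


# ---------------------------------------------------------------------------
# probability of identity (siblings)
# ---------------------------------------------------------------------------

@dataclass
class PidSibResult:
    per_locus: dict[str, float]
    cumulative: list[float]          # product over loci in the given order
    locus_order: list[str]
    threshold: float
    min_loci: int | None             # fewest loci with cumulative <= threshold


def pid_sib(freqs: dict, order: list[str] | None = None,
            threshold: float = 0.05) -> PidSibResult:
    """Probability that two full siblings share a multilocus genotype.

    Per locus, ``PIDsib = 0.25 + 0.5*S2 + 0.5*S2^2 - 0.25*S4`` with
    ``S2 = sum(p^2)`` and ``S4 = sum(p^4)`` (Evett–Weir form); the cumulative
    value is the product over loci in the given order.  Also reports the
    minimum number of loci needed to push the cumulative value below
    ``threshold`` (the criterion for distinguishing close relatives).
    """
    order = list(freqs.keys()) if order is None else list(order)
    per_locus = {}
    for locus in order:
        f = freqs[locus]
        p = np.array(list(f.values()) if isinstance(f, dict) else f, dtype=float)
        p = p[p > 0]
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"{locus}: allele frequencies sum to {p.sum():.6f}, not 1")
        s2, s4 = float(np.sum(p ** 2)), float(np.sum(p ** 4))
        per_locus[locus] = 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4
    cumulative = list(itertools.accumulate((per_locus[l] for l in order),
                                           lambda a, b: a * b))
    min_loci = next((i + 1 for i, c in enumerate(cumulative) if c <= threshold), None)
    return PidSibResult(per_locus=per_locus, cumulative=cumulative,
                        locus_order=order, threshold=threshold, min_loci=min_loci)


# ---------------------------------------------------------------------------
# consensus genotyping and individual matching
# ---------------------------------------------------------------------------

@dataclass
class MatchReport:
    assignment: dict[str, str]                    # sample_id -> individual label
    consensus: dict[str, dict[str, tuple[str, str]]]
    n_individuals: int
    recaptures: dict[str, list[str]]              # individuals with >= 2 samples
    sex: dict[str, str]
    sex_conflicts: list[str]
    low_confidence: dict[str, list[str]]          # individual -> unconfirmed loci
    excluded_samples: list[str]
    by_region: pd.DataFrame | None = None
    pid_sib: PidSibResult | None = None


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _compare(g1: dict, g2: dict, directional: bool = False) -> tuple[int, int, int]:
    """Return (co-typed loci, hard mismatches, dropout-explainable mismatches).

    A mismatch is dropout-explainable when one genotype is a homozygote for an
    allele carried by the other (heterozygous) genotype — the signature of
    allelic dropout in scat DNA.  With ``directional=True`` only ``g1`` may be
    the dropout victim (g1 homozygous, g2 heterozygous); the reverse direction
    counts as a hard mismatch.
    """
    co = mis = expl = 0
    for locus, a in g1.items():
        b = g2.get(locus)
        if b is None:
            continue
        co += 1
        if a == b:
            continue
        sa, sb = set(a), set(b)
        if len(sa) == 1 and sa <= sb:
            expl += 1
        elif not directional and len(sb) == 1 and sb <= sa:
            expl += 1
        else:
            mis += 1
    return co, mis, expl


def _consensus_of(genos: list[dict], loci) -> tuple[dict, list[str]]:
    cons, flagged = {}, []
    for locus in loci:
        calls = [g[locus] for g in genos if locus in g]
        if not calls:
            continue
        alleles = sorted({a for c in calls for a in c})
        if len(alleles) == 1:
            cons[locus] = (alleles[0], alleles[0])
        else:
            # keep the two most frequently observed alleles
            counts = pd.Series([a for c in calls for a in c]).value_counts()
            top = sorted(counts.index[:2])
            cons[locus] = (top[0], top[1])
            if len(alleles) > 2:
                flagged.append(locus)
            # multi-tube confirmation: a het call needs >= 2 replicates
            if len(calls) < 2:
                flagged.append(locus)
    return cons, sorted(set(flagged))


def consensus_and_match(
    ds: GenotypeDataset,
    min_loci: int = 5,
    max_mismatch: int = 0,
    use_sex: bool = True,
    use_region: bool = True,
    rescue_dropout: bool = True,
    max_dropout_loci: int = 2,
) -> MatchReport:
    """Merge replicate samples into individuals and build consensus genotypes.

    Samples typed at fewer than ``min_loci`` loci are excluded.  Matching runs
    in two passes: (1) samples identical at all co-typed loci (up to
    ``max_mismatch`` genotype mismatches; the default 0 is the strict 100%
    match rule) and with consistent sex calls are merged; (2) optionally
    (``rescue_dropout``), clusters whose consensus differs from another
    cluster's consensus only by dropout-explainable homozygote/heterozygote
    discordances (at most ``max_dropout_loci`` loci, every other co-typed
    locus identical, same sex, and — with ``use_region`` — the same sampling
    region, since replicates of one animal come from one region) are merged
    into their unique closest match: the multi-tube safeguard against allelic
    dropout splitting one animal into several.  Set ``rescue_dropout=False``
    for the strict rule only.
    """
    if min_loci > len(ds.loci):
        raise ValueError("min_loci exceeds the number of loci")
    wide = ds.genotypes_wide()
    meta = ds.sample_table().set_index("sample_id")
    usable = [s for s, g in wide.items() if len(g) >= min_loci]
    excluded = [s for s in wide if s not in set(usable)]
    if not usable:
        raise ValueError("no samples typed at enough loci")
    sex_call = meta["sex_call"].to_dict()
    region = meta["region"].to_dict()

    uf = _UnionFind(usable)
    for s1, s2 in itertools.combinations(usable, 2):
        if use_sex and sex_call.get(s1) and sex_call.get(s2) and sex_call[s1] != sex_call[s2]:
            continue
        co, mis, expl = _compare(wide[s1], wide[s2])
        if co >= min_loci and mis + expl <= max_mismatch:
            uf.union(s1, s2)

    clusters: dict[str, list[str]] = {}
    for s in usable:
        clusters.setdefault(uf.find(s), []).append(s)

    if rescue_dropout:
        merged = True
        while merged:
            merged = False
            cons = {r: _consensus_of([wide[s] for s in mem], ds.loci)[0]
                    for r, mem in clusters.items()}
            # try to fold small clusters into larger ones
            for r in sorted(clusters, key=lambda k: len(clusters[k])):
                candidates = []
                for t in clusters:
                    if t == r:
                        continue
                    if use_sex and sex_call.get(r) and sex_call.get(t) \
                            and sex_call[r] != sex_call[t]:
                        continue
                    if use_region and region.get(r) != region.get(t):
                        continue
                    co, mis, expl = _compare(cons[r], cons[t], directional=True)
                    if co >= min_loci and mis == 0 and 1 <= expl <= max_dropout_loci:
                        candidates.append((expl, -len(clusters[t]), t))
                if candidates:
                    # fewest dropout loci first; ties resolved toward the
                    # better-replicated cluster, ambiguity beyond that blocks
                    candidates.sort(key=lambda c: c[:2])
                    best = [t for e, sz, t in candidates if (e, sz) == candidates[0][:2]]
                    if len(best) == 1:
                        clusters[best[0]].extend(clusters.pop(r))
                        merged = True
                        break

    # label individuals deterministically by first sample id
    assignment, consensus, low_conf, sexes, conflicts, recaps = {}, {}, {}, {}, [], {}
    for k, members in enumerate(sorted(clusters.values(), key=lambda m: sorted(m)[0])):
        label = f"L{k + 1:03d}"
        members = sorted(members)
        for s in members:
            assignment[s] = label
        cons, flagged = _consensus_of([wide[s] for s in members], ds.loci)
        consensus[label] = cons
        if flagged:
            low_conf[label] = flagged
        sx = [sex_call[s] for s in members if sex_call.get(s)]
        if sx:
            vals = pd.Series(sx).value_counts()
            sexes[label] = vals.index[0]
            if len(vals) > 1:
                conflicts.append(label)
        else:
            sexes[label] = ""
        if len(members) > 1:
            recaps[label] = members

    by_region = (
        pd.DataFrame(
            {"individual": lab, "region": meta.loc[s, "region"], "sex": sexes[lab]}
            for s, lab in assignment.items()
        )
        .drop_duplicates("individual")
        .groupby(["region", "sex"]).size().rename("n").reset_index()
    )

    # cumulative PID(sib) from consensus allele frequencies
    freqs: dict[str, dict[str, float]] = {}
    for locus in ds.loci:
        counts: dict[str, int] = {}
        for cons in consensus.values():
            if locus in cons:
                for a in cons[locus]:
                    counts[a] = counts.get(a, 0) + 1
        tot = sum(counts.values())
        if tot:
            freqs[locus] = {a: c / tot for a, c in counts.items()}
    pid = pid_sib(freqs) if freqs else None

    return MatchReport(
        assignment=assignment, consensus=consensus, n_individuals=len(clusters),
        recaptures=recaps, sex=sexes, sex_conflicts=conflicts,
        low_confidence=low_conf, excluded_samples=sorted(excluded),
        by_region=by_region, pid_sib=pid,
    )


# ---------------------------------------------------------------------------
# diversity summaries
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    table: pd.DataFrame        # per group: N, Na, Ne, He, uHe, Ar with SEs
    per_locus: pd.DataFrame    # group x locus detail
    anova_p: dict[str, float]  # one-way test across groups on per-locus values


def _allele_counts(long: pd.DataFrame, loci) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {l: {} for l in loci}
    for row in long.itertuples(index=False):
        if row.allele1 and row.allele2:
            for a in (row.allele1, row.allele2):
                out[row.locus][a] = out[row.locus].get(a, 0) + 1
    return out


def _rarefied_richness(counts: dict[str, int], g: int) -> float:
    """El Mousadik–Petit rarefaction: expected allele count in ``g`` gene copies."""
    n = sum(counts.values())
    if g > n:
        g = n
    ar = 0.0
    for c in counts.values():
        if n - c < g:
            ar += 1.0
        else:
            log_num = gammaln(n - c + 1) - gammaln(g + 1) - gammaln(n - c - g + 1)
            log_den = gammaln(n + 1) - gammaln(g + 1) - gammaln(n - g + 1)
            ar += 1.0 - float(np.exp(log_num - log_den))
    return ar


def diversity_summary(ds: GenotypeDataset, group_by: str = "region",
                      rarefaction_size: int | None = None) -> DiversitySummary:
    """Per-group Na, effective alleles, He, uHe and rarefied allelic richness.

    ``uHe = He * 2N / (2N - 1)`` with N the number of genotyped individuals at
    the locus.  Allelic richness is rarefied to the smallest per-locus number
    of gene copies across the compared groups (override with
    ``rarefaction_size``).  Group summaries are means with standard errors
    across loci; a one-way test across groups on per-locus values is included.
    """
    groups = {g: sub for g, sub in ds.long.groupby(group_by, sort=False)}
    per_group_counts = {g: _allele_counts(sub, ds.loci) for g, sub in groups.items()}

    rows = []
    for g, counts in per_group_counts.items():
        for locus in ds.loci:
            c = counts[locus]
            n2 = sum(c.values())          # gene copies
            if n2 == 0:
                continue
            p = np.array(list(c.values())) / n2
            he = 1.0 - float(np.sum(p ** 2))
            uhe = he * n2 / (n2 - 1) if n2 > 2 else float("nan")
            if rarefaction_size is not None:
                gsize = rarefaction_size
            else:
                sizes = [sum(pc[locus].values()) for pc in per_group_counts.values()]
                gsize = min(s for s in sizes if s > 0)
            rows.append({
                group_by: g, "locus": locus, "N": n2 / 2, "Na": len(c),
                "Ne": 1.0 / float(np.sum(p ** 2)), "He": he, "uHe": uhe,
                "Ar": _rarefied_richness(c, gsize),
            })
    per_locus = pd.DataFrame(rows)

    summaries = []
    for g, sub in per_locus.groupby(group_by, sort=False):
        row = {group_by: g, "N": sub["N"].max()}
        for stat in ("Na", "Ne", "He", "uHe", "Ar"):
            x = sub[stat].dropna()
            row[stat] = x.mean()
            row[f"{stat}_se"] = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan
        summaries.append(row)
    table = pd.DataFrame(summaries)

    anova_p = {}
    if len(groups) > 1:
        for stat in ("uHe", "Ar", "Na"):
            arrays = [sub[stat].dropna().to_numpy()
                      for _, sub in per_locus.groupby(group_by, sort=False)]
            arrays = [a for a in arrays if len(a) > 1]
            if len(arrays) > 1:
                anova_p[stat] = float(f_oneway(*arrays).pvalue)
    return DiversitySummary(table=table, per_locus=per_locus, anova_p=anova_p)


# ---------------------------------------------------------------------------
# distance-based AMOVA / F_ST
# ---------------------------------------------------------------------------

def genetic_distance_matrix(ds: GenotypeDataset) -> tuple[np.ndarray, list[str]]:
    """Pairwise squared genetic distance (allele-count metric) between samples.

    Loci missing in either member of a pair do not contribute to that pair.
    """
    samples = ds.sample_ids
    sidx = {s: i for i, s in enumerate(samples)}
    n = len(samples)
    D = np.zeros((n, n))
    for locus in ds.loci:
        sub = ds.long[(ds.long["locus"] == locus) & (ds.long["allele1"] != "")]
        if sub.empty:
            continue
        alleles = sorted(set(sub[["allele1", "allele2"]].to_numpy().ravel()))
        aidx = {a: j for j, a in enumerate(alleles)}
        Y = np.zeros((n, len(alleles)))
        typed = np.zeros(n, dtype=bool)
        for row in sub.itertuples(index=False):
            i = sidx[row.sample_id]
            Y[i, aidx[row.allele1]] += 1
            Y[i, aidx[row.allele2]] += 1
            typed[i] = True
        diff = 0.5 * ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
        both = typed[:, None] & typed[None, :]
        D += np.where(both, diff, 0.0)
    return D, samples


@dataclass
class AmovaResult:
    table: pd.DataFrame            # df, SS, MS, variance component, %
    phi_pt: float                  # among-population Phi, reported as F_ST
    p_value: float
    pairwise_fst: pd.DataFrame
    pairwise_p: pd.DataFrame
    dropped_loci: dict = field(default_factory=dict)


def _amova_from_distance(D: np.ndarray, labels: np.ndarray) -> tuple[float, pd.DataFrame]:
    n = len(labels)
    groups = pd.unique(labels)
    k = len(groups)
    ss_total = D[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    sizes = []
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sizes.append(len(idx))
        sub = D[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    sizes = np.array(sizes)
    n0 = (n - (sizes ** 2).sum() / n) / (k - 1)
    var_within = ms_within
    var_among = max((ms_among - ms_within) / n0, 0.0)
    total_var = var_among + var_within
    phi = var_among / total_var if total_var > 0 else 0.0
    table = pd.DataFrame({
        "source": ["Among Pops", "Within Pops", "Total"],
        "df": [df_among, df_within, n - 1],
        "SS": [ss_among, ss_within, ss_total],
        "MS": [ms_among, ms_within, np.nan],
        "var": [var_among, var_within, total_var],
        "pct": [100 * var_among / total_var if total_var else 0.0,
                100 * var_within / total_var if total_var else 100.0, 100.0],
    })
    return phi, table


def amova_fst(ds: GenotypeDataset, group_by: str = "region",
              permutations: int = 999, seed: int = 0) -> AmovaResult:
    """Two-level distance AMOVA with permutation tests and pairwise F_ST.

    The among-population Phi-statistic on squared allele-count distances (the
    GenAlEx Phi_PT analog for codominant data) is reported as F_ST; p-values
    come from permuting individuals among groups (at least 999 permutations).
    """
    D, samples = genetic_distance_matrix(ds)
    meta = ds.sample_table().set_index("sample_id")
    labels = meta.loc[samples, group_by].to_numpy()
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")

    rng = np.random.default_rng(seed)
    phi, table = _amova_from_distance(D, labels)
    null = np.empty(permutations)
    for b in range(permutations):
        null[b] = _amova_from_distance(D, rng.permutation(labels))[0]
    p = (1 + np.sum(null >= phi - 1e-12)) / (permutations + 1)

    fst = pd.DataFrame(0.0, index=groups, columns=groups)
    pmat = pd.DataFrame(1.0, index=groups, columns=groups)
    for g1, g2 in itertools.combinations(groups, 2):
        idx = np.flatnonzero((labels == g1) | (labels == g2))
        sub, lab = D[np.ix_(idx, idx)], labels[idx]
        ph, _ = _amova_from_distance(sub, lab)
        nullp = np.empty(permutations)
        for b in range(permutations):
            nullp[b] = _amova_from_distance(sub, rng.permutation(lab))[0]
        pp = (1 + np.sum(nullp >= ph - 1e-12)) / (permutations + 1)
        fst.loc[g1, g2] = fst.loc[g2, g1] = ph
        pmat.loc[g1, g2] = pmat.loc[g2, g1] = pp
    return AmovaResult(table=table, phi_pt=phi, p_value=float(p),
                       pairwise_fst=fst, pairwise_p=pmat)


# ---------------------------------------------------------------------------
# Mantel test and spatial autocorrelation
# ---------------------------------------------------------------------------

def mantel_ibd(genetic: np.ndarray, geographic: np.ndarray,
               permutations: int = 999, seed: int = 0) -> tuple[float, float]:
    """Standardized Mantel correlation between two distance matrices.

    The p-value is one-sided (observed or larger), obtained by permuting the
    row/column order of one matrix.
    """
    G = np.asarray(genetic, float)
    X = np.asarray(geographic, float)
    if G.shape != X.shape or G.shape[0] != G.shape[1]:
        raise ValueError("matrices must be square and of equal order")
    iu = np.triu_indices(G.shape[0], 1)
    g, x = G[iu], X[iu]
    if g.std() == 0 or x.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r = float(np.corrcoef(g, x)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(G.shape[0])
        gp = G[np.ix_(perm, perm)][iu]
        if np.corrcoef(gp, x)[0, 1] >= r - 1e-12:
            count += 1
    return r, (count + 1) / (permutations + 1)


@dataclass
class Correlogram:
    classes: pd.DataFrame      # bin edges, n pairs, r, null envelope, bootstrap CI
    permutations: int
    skipped_classes: list[int]


def spatial_autocorrelation(
    ds: GenotypeDataset,
    bin_edges: np.ndarray | None = None,
    n_classes: int = 10,
    permutations: int = 999,
    bootstraps: int = 200,
    seed: int = 0,
) -> Correlogram:
    """Multilocus spatial autocorrelation correlogram (Smouse–Peakall form).

    The genetic distance matrix is double-centered into a covariance matrix C;
    the autocorrelation coefficient for a distance class is the mean
    off-diagonal cross-product within the class divided by the mean diagonal
    term (so the null expectation is close to ``-1/(n-1)``, not exactly zero).
    The null envelope comes from permuting individual locations; bootstrap CIs
    from resampling pairs within each class.  Default bins: ``n_classes``
    equal-count classes of the pairwise geographic distances.
    """
    D, samples = genetic_distance_matrix(ds)
    meta = ds.sample_table().set_index("sample_id")
    xy = meta.loc[samples, ["x_km", "y_km"]].to_numpy(dtype=float)
    geo = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    n = len(samples)
    iu = np.triu_indices(n, 1)
    if bin_edges is None:
        bin_edges = np.quantile(geo[iu], np.linspace(0, 1, n_classes + 1))
        bin_edges = np.asarray(bin_edges, dtype=float)
        bin_edges[-1] += 1e-9
    counts_per_class = [
        int(((geo[iu] >= lo) & (geo[iu] < hi)).sum())
        for lo, hi in zip(bin_edges[:-1], bin_edges[1:])
    ]
    if all(c == 0 for c in counts_per_class):
        raise ValueError("no pairs fall in any distance class")

    J = np.eye(n) - np.ones((n, n)) / n
    C = -0.5 * J @ D @ J
    diag_mean = float(np.mean(np.diag(C)))

    def class_r(dg):
        rs = []
        for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
            sel = (dg[iu] >= lo) & (dg[iu] < hi)
            rs.append(float(np.mean(C[iu][sel]) / diag_mean) if sel.any() else np.nan)
        return np.array(rs)

    r_obs = class_r(geo)
    skipped = [i for i, m in enumerate(counts_per_class) if m == 0]

    rng = np.random.default_rng(seed)
    null = np.empty((permutations, len(r_obs)))
    for b in range(permutations):
        perm = rng.permutation(n)
        null[b] = class_r(geo[np.ix_(perm, perm)])
    lo_env = np.nanpercentile(null, 2.5, axis=0)
    hi_env = np.nanpercentile(null, 97.5, axis=0)

    boot_lo = np.full(len(r_obs), np.nan)
    boot_hi = np.full(len(r_obs), np.nan)
    cvals = C[iu]
    for ci, (lo, hi) in enumerate(zip(bin_edges[:-1], bin_edges[1:])):
        sel = np.flatnonzero((geo[iu] >= lo) & (geo[iu] < hi))
        if len(sel) < 2:
            continue
        reps = np.array([
            np.mean(cvals[rng.choice(sel, size=len(sel), replace=True)]) / diag_mean
            for _ in range(bootstraps)
        ])
        boot_lo[ci], boot_hi[ci] = np.percentile(reps, [2.5, 97.5])

    classes = pd.DataFrame({
        "lo_km": bin_edges[:-1], "hi_km": bin_edges[1:], "n_pairs": counts_per_class,
        "r": r_obs, "null_lo": lo_env, "null_hi": hi_env,
        "boot_lo": boot_lo, "boot_hi": boot_hi,
    })
    return Correlogram(classes=classes, permutations=permutations, skipped_classes=skipped)


# ---------------------------------------------------------------------------
# small accounting helpers
# ---------------------------------------------------------------------------

def species_assay_summary(n_confirmed: int, n_collected: int) -> dict:
    """Bookkeeping for the mtDNA species-confirmation assay on field scats."""
    if not 0 <= n_confirmed <= n_collected:
        raise ValueError("confirmed count must be between 0 and collected count")
    pct = 100.0 * n_confirmed / n_collected
    return {"n_confirmed": n_confirmed, "n_collected": n_collected,
            "percent_confirmed": pct, "percent_rounded": round(pct)}
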