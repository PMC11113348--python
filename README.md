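# nimrescue

Genetic-rescue analysis toolkit for the Arabian leopard (*Panthera pardus
nimr*) — and, more generally, for any critically small wild population with a
captive reserve.  Fewer than ~120 Arabian leopards survive in the wild, while
the captive population carries microsatellite alleles no longer detected in
the wild (8 of 25 captive alleles, two of them tracing to founders
wild-sourced from Yemen).  The package implements the quantitative machinery
needed to ask whether releasing captive animals would help or harm:

- **`synthetic_data`** — generators for multilocus microsatellite datasets
  (replicate scat genotypes with allelic dropout, a sex locus, Genepop/CSV
  output) and spatially explicit capture histories from known density and
  detection parameters, so every estimator is testable without field data.
- **`msat_stats`** — PID(sib), consensus genotyping and individual matching,
  Na / effective alleles / He / uHe / rarefied allelic richness, distance
  AMOVA with pairwise F_ST, Mantel isolation-by-distance, Smouse–Peakall
  spatial autocorrelation.
- **`rescue_alleles`** — Monte-Carlo tally of the unique alleles a rescued
  population would carry as a function of the number of released individuals
  and the source population.
- **`secr`** — maximum-likelihood spatially explicit capture–recapture for
  binary proximity detectors (cameras and scat search grids) with half-normal
  detection `g0 · exp(−d²/2σ²)`, sex covariates, AIC ranking, and
  density-to-abundance extrapolation with lognormal intervals.
- **`loadsim`** — forward-in-time Wright–Fisher simulator of deleterious and
  neutral variation over a 13.5 Mb exome (gamma DFE with dominance,
  recessive-lethal class, lethal-equivalents calibration, coalescent neutral
  initialization), with decline/captive-split and release scenarios tracking
  genetic load, realized load (`Σ_hom s + Σ_het h·s`), masked load, mean
  fitness and neutral π.
- **`pva`** — individual-based, pedigree-tracked population viability
  analysis with inbreeding depression on first-year survival
  (`S = S₀ · e^{−F·LE}`), carrying capacity, and periodic supplementation.
- **`cli`** — a thin `nimr-rescue` command wrapping the pipeline
  (`nimr-rescue run --config pipeline.yaml`) and the individual stages.

## Worked example

How many distinct microsatellite alleles would the wild population carry
after releasing `n` captive animals, and how many leopards does the estimated
density imply?

```python
from nimrescue import synthetic_data as sd, rescue_alleles as ra, secr

spec = sd.canonical_allele_spec()          # 27 alleles: wild 19, captive 25
pools = {
    "oman_captive": ra.sample_pool(spec, "captive_oman", 20, seed=1),
    "yemen_captive": ra.sample_pool(spec, "captive_yemen", 8, seed=2),
}
table = ra.summarize_scenarios(spec, pools, n_values=[0, 2, 4, 6],
                               reps=100, seed=3)
print(table.round(2).to_string(index=False))

est = secr.extrapolate_abundance(2.30, 2213.0, se=0.53)
print(f"\nabundance over 2213 km^2: {est.n_hat} "
      f"(95% interval {est.ci[0]:.0f}-{est.ci[1]:.0f})")
```

```
       source  n  mean  q05  q95  pct_increase
 oman_captive  0 19.00 19.0 19.0          0.00
 oman_captive  2 23.93 22.0 25.0         25.95
 oman_captive  4 24.63 24.0 25.0         29.63
 oman_captive  6 24.85 24.0 25.0         30.79
yemen_captive  0 19.00 19.0 19.0          0.00
yemen_captive  2 23.41 21.0 25.0         23.21
yemen_captive  4 25.29 24.0 26.0         33.11
yemen_captive  6 25.71 25.0 26.0         35.32

abundance over 2213 km^2: 51 (95% interval 33-79)
```

Reading the table: with no releases the wild population keeps its 19-allele
baseline (zero variance); six Oman-sourced captive releases raise the mean to
~24.9 alleles (≈30% more), and the Yemen-sourced pool — which concentrates
the alleles missing from the wild — pushes it to ~25.7.  The `q05`/`q95`
columns are the empirical 5%–95% band over 100 Monte-Carlo replicates.  The
abundance line converts a density of 2.30 leopards/100 km² (SE 0.53) over
2213 km² of core habitat into a point estimate of 51 animals with a lognormal
interval.

The forward load simulator is driven the same way (see `docs/methods.md` for
the model):

```python
from nimrescue import loadsim

cal = loadsim.calibrate_dfe(target_masked_le=6.0, n_cal=200, seed=1)
sim, pop = loadsim.run_burnin(loadsim.GenomeConfig(), cal.dfe,
                              n_ancestral=200, selection_generations=2000,
                              seed=1)
print(loadsim.compute_load_metrics(sim, pop))
```

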