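# rguc

Selection of **relevant genetic units for conservation (RGUCs)** from
dominant-marker population data.

Conservation programmes for fragmented plant species rarely can protect
every population. Given a binary presence/absence matrix of dominant
markers (AFLP bands or similar) for individuals sampled from populations
grouped into geographic regions, this package answers, reproducibly:

1. **How many** populations must be protected to represent a target share
   of the species' among-population genetic diversity?
2. **Which** populations carry the rare allelic variation, and how should
   the protection effort be split among regions?

It is written for conservation geneticists working with dominant
multilocus data (AFLPs, ISSRs, ...) plus optional plastid haplotypes.

## The model

- **Diversity and rarity per population.** Nei's gene diversity
  `h = mean_markers 2f(1−f)` on band-phenotype frequencies `f`;
  frequency down-weighted marker values
  `DW = (1/n) Σ_markers (carriers in pop / carriers overall)`; and the
  number of **rare bands** `N_r` — bands with overall frequency < 10%
  present in < 20% of the populations.
- **AMOVA.** Variance in the pairwise squared Euclidean distances
  (number of differing bands) partitioned among/within populations, and
  hierarchically among regions, with permutation tests and a
  marker-bootstrap confidence interval for `F_ST`.
- **Sampling equation.** The share of among-population diversity held by
  `n` populations is `P = 1 − F_ST^n`; the minimum population number is
  `n* = ⌈ln(1−P)/ln(F_ST)⌉`.
- **Loss of rare alleles.** A rare band at mean carrier frequency `p`
  present in `N` populations is lost with probability `L = (1−p)^{2N}`.
  Regressing `−log L` on `p` for the observed `N` and for the
  single-population reference `N = 1` gives slopes whose ratio
  `R = m_e/m_o` is the proportion of rare alleles captured by sampling
  one population.
- **Preferred sampling areas and apportionment.** Each rare band is
  assigned to the region where one uniformly drawn population is most
  likely to capture it; regional shares apportion `n*` protected slots
  by largest remainder; populations are ranked within regions by a
  composite of normalized `h`, `DW`, `N_r` plus conservation-attribute
  bonuses, with a greedy pass flagging extra populations needed to cover
  endemic haplotypes.
- **Haplotype-sampling completeness.** For `n` sequenced individuals
  showing `k` haplotypes, `P(k|n,θ) = θ!/(θ−k)!·S(n,k)/θ^n` (Stirling
  numbers of the second kind, equal haplotype frequencies) gives a
  posterior over the true haplotype number `θ` under a uniform prior.

A seeded generator (`rguc.simulate`) draws matrices under the
Balding–Nichols F-model, whose parameter `F` is exactly the quantity
AMOVA's `F_ST` estimates, and can inject regionally restricted rare
bands with a recoverable truth record.

## Worked example

A study-shaped synthetic dataset — 17 populations in 3 regions, 10
individuals each, 574 markers including 24 injected region-restricted
rare bands, differentiation `F = 0.29`:

```python
from rguc import AnalysisConfig, HaplotypeSample, simulate_matrix
from rguc.pipeline import analyze
from rguc.simulate import study_like_spec

spec = study_like_spec(rng_seed=1, scale=0.5)
matrix, truth = simulate_matrix(spec)
cfg = AnalysisConfig(n_permutations=199, n_bootstrap=200, rng_seed=1)
report = analyze(matrix, spec.region_partition(), {}, HaplotypeSample(61, 7), cfg)
```

Key numbers this run prints (from `report`):

```
F_ST 0.286  p 0.005  CI [0.278, 0.296]     # recovers the generating F = 0.29
among-population variance 28.63 %
n_required 6   (real-valued 5.52)          # 1 − 0.286^6 ≥ 0.999
rare bands 38
R 0.377                                    # one population captures ~38% of rare bands
PSA counts {'R1': 12, 'R2': 16, 'R3': 10}  → shares {'R1': 0.32, 'R2': 0.42, 'R3': 0.26}
allocation {'R1': 2, 'R2': 2, 'R3': 2}
dixon posterior_mean 7.002  p_complete 0.998
```

Reading: the 17 populations are strongly differentiated (`F_ST ≈ 0.29`),
so 6 populations suffice to represent 99.9% of among-population
diversity; the rare-band loss analysis says a single population would
capture only ~38% of the rare variation; the preferred-sampling-area
shares split the 6 slots 2/2/2 across the regions; and a 61-sequence
haplotype sample showing 7 haplotypes is almost certainly complete
(posterior mean 7.002).

The same pipeline runs from files:

```sh
rguc simulate --seed 1 --out sim/
rguc run --matrix sim/matrix.tsv --regions sim/regions.tsv --out report/
rguc dixon -n 61 -k 7
```

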