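# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, the places where the methodology is genuinely
convention-dependent, and what the synthetic generator does and does not
emulate.

## Data model

The central object is a binary individuals × markers matrix of dominant
marker phenotypes (band present/absent), with each individual assigned
to one population and each population to one geographic region.
Dominant markers hide heterozygotes, so every statistic here is defined
on band-phenotype frequencies, never on inferred allele frequencies.
Missing calls are permitted (configurable token, stored as NaN) and all
frequencies use complete-case denominators per population; nothing is
imputed. Population codes are opaque strings and the region partition is
always supplied separately — it is never parsed out of the codes.

Two file orientations are read: individuals as rows (id, population,
bands…) or markers as rows with one column per individual (population
labels then supplied separately), since published band matrices come in
both layouts.

## Diversity and rarity descriptors

**Nei's gene diversity.** `h = mean over dataset-polymorphic markers of
2f(1−f)`, with `f` the band frequency in the population. This is the
*phenotypic* estimator: no Hardy–Weinberg square-root transform to
allele frequencies and, by default, no small-sample `n/(n−1)` correction
(a config switch adds it). Rationale: for dominant data the
square-root transform requires an inbreeding assumption the data cannot
check; the phenotypic estimator is the simplest defensible choice and
is isolated behind one function. Consequently absolute `h` values are
comparable *within* an analysis but not necessarily with other software
that applies the transform.

**Frequency down-weighted marker values (DW).** For each band carried
anywhere, the ratio (carriers in the population)/(carriers in the whole
dataset) is summed and divided by the population's sample size.
Populations carrying globally scarce bands score high. The division by
individuals (rather than by markers, or not at all) is a documented
convention; the unnormalized sum is available by config. DW values are
therefore rank-meaningful within an analysis, not absolute quantities.

**Rare bands.** Overall frequency (carriers over all individuals)
strictly below `rare_freq_threshold` (default 0.10) *and* carrier
populations strictly below `rare_popfrac_threshold` (default 0.20) of
all populations. The frequency attached to a rare band downstream,
`p`, is the *unweighted mean of its per-carrier-population
frequencies* — deliberately distinct from the overall frequency used by
the filter, because the loss probability concerns the band's frequency
where it actually occurs.

## AMOVA

Distances are squared Euclidean on band profiles, i.e. the count of
differing markers (missing calls skipped pairwise). Sums of squares
come from the distance-matrix identities `SS_total = Σ_{i<j} d_ij / N`
and `SS_level = Σ_groups Σ_{i<j∈g} d_ij / n_g`; variance components from
the expected mean squares with unequal sample sizes (coefficients
`n0 = (N − Σn_p²/N)/(P−1)` for one level and the standard `n'`, `n''`,
`n'''` for the three-level design). Fixation indices are component
ratios: `F_ST = σ²_a/(σ²_a+σ²_w)` one-level;
`F_CT`, `F_SC`, `F_ST` hierarchical.

Numerical/reporting choices:

- Negative variance components are reported as-is with a warning;
  truncation at zero is a config switch, not the default, so the
  decomposition always sums exactly.
- Permutation tests (default 1023 replicates) preserve sample sizes;
  `p = (b+1)/(n+1)`. Schemes per statistic: one-level and hierarchical
  `F_ST` permute individuals among populations; `F_CT` permutes whole
  populations among regions; `F_SC` permutes individuals among
  populations within their region.
- The 95% CI for `F_ST` is a percentile bootstrap over marker columns
  (default 1000 replicates). Bootstrapping over markers (not
  individuals) was chosen because the sampling unit of uncertainty for
  a genome-wide differentiation summary is the locus; this is a
  documented choice, not a claim about how any particular published
  interval was obtained.

## Sampling equation and rare-allele loss

The share of among-population diversity represented by `n` populations
is modelled as `P = 1 − F_ST^n`; the requirement is
`n* = max(1, ⌈ln(1−P)/ln(F_ST)⌉)` — a ceiling, because conservation
targets are lower bounds. The real-valued solution is reported alongside
as a diagnostic. `F_ST = 0` returns 1 with a note; `F_ST ≥ 1` is an
error (the equation has no solution).

For each rare band, `Lo = (1−p)^{2N}` with `N` its carrier-population
count, and `Le = (1−p)^2` — the loss probability when a *single*
population is sampled. The `N = 1` reference is forced by the meaning of
the summary statistic: `R = m(−log Le)/m(−log Lo)`, the ratio of the
fitted slopes of `−log L` against `p`, is interpreted as the proportion
of rare alleles captured by sampling one population, and equals 1
exactly when every rare band is private to one population. Both
regressions are ordinary least squares *with* intercept by default
(through-origin by config); `R` is invariant to the logarithm base since
a common factor cancels.

## Preferred sampling areas, apportionment, prioritization

A region `g` with `K_g` populations captures a given rare band with
probability `P_g = (1/K_g) Σ_{j∈g} [1 − (1−p_j)^{2n_j}]` when one of its
populations is drawn uniformly (`p_j` = the band's frequency in
population `j`, `n_j` its sample size). Each band is assigned to the
argmax region; ties break toward the higher mean carrier frequency,
then label order (logged). A simpler carrier-fraction rule is available
by config flag. Dividing by `K_g` means a band held by 1 of 2
populations in a small region beats the same band held by 1 of 4 in a
large one — concentration, not just presence, drives the assignment.

Regional PSA shares apportion `n*` protected slots by largest remainder
(Hamilton); unrounded shares are used by default, with a config option
to force reported 2-decimal shares. Within regions, populations are
ranked by the mean of min-max-normalized `h`, `DW`, `N_r` (a metric
constant within a region contributes 0.5), plus additive bonuses
(default 0.05 each, fully config-driven) for stable/acceptable
vulnerability, protected status, large occupation area and large
population size. The final expert step — making sure endemic haplotypes
are represented — is made explicit: after the top-`k` choice a greedy
pass flags further populations, best-ranked first, until every endemic
haplotype recorded for the region is covered. The bonuses make the
judgment reproducible; they are not estimates of anything.

## Haplotype collapsing and sampling completeness

Aligned sequences are collapsed by exact identity after indel recoding:
each contiguous gap run longer than one base becomes a single
mutational-step token (identified by its alignment span), and a
single-base gap is kept as a fifth character state. Two sequences
differing only by a 3-bp gap therefore differ by exactly one coded
character. Ambiguity codes either raise (default) or are kept as
distinct states.

Completeness uses the Stirling likelihood
`P(k|n,θ) = θ!/(θ−k)!·S(n,k)/θ^n` — the probability that `n` draws from
`θ` *equally frequent* haplotypes show exactly `k` distinct ones —
with `log S(n,k)` computed by the stable log-space recurrence
`S(n,k) = k·S(n−1,k) + S(n−1,k−1)`. A uniform prior on
`θ ∈ {k..θ_max}` (default `θ_max = 100`) yields the posterior, its mean
(reported to 3 decimals) and `p_complete`, the mass at `θ = k`. The
result is checked for insensitivity to `θ_max` (tail mass beyond ~3k
triggers a warning), and highly skewed observed haplotype counts
trigger a caveat since the equal-frequency assumption then overstates
completeness. For 61 sequences and 7 haplotypes this model gives a
posterior mean of 7.002 and `p_complete ≈ 0.998`.

## Synthetic data

The generator draws, per marker, an ancestral frequency
π ~ Uniform(0.05, 0.95) and per population a frequency from
Beta(π(1−F)/F, (1−π)(1−F)/F) — the Balding–Nichols F-model, chosen
because its `F` is exactly the quantity AMOVA's `F_ST` estimates:
E[f] = π and Var[f] = F·π(1−π), so parameter recovery is a meaningful
end-to-end check (the suite verifies recovery within ±0.05 at the
17 × 21 × 1000 scale; observed error is ~±0.01). `F = 0` is handled as
the no-variance limit. Individuals are Bernoulli draws.

Injected rare bands are laid down deterministically —
`max(1, round(p·n))` carriers in each chosen population, absent
elsewhere — rather than by Bernoulli sampling, so the truth record is
exactly recoverable by the rare-band filter (Bernoulli injection would
leave a carrier population empty with non-trivial probability at these
frequencies). Realized frequencies are recorded in the truth record.

The default study-shaped specification (`study_like_spec`) is 17
populations in 3 regions, 21 individuals per population, ~1100 F-model
markers with `F = 0.29`, plus 8 injected region-restricted rare bands
per region at frequencies 0.04–0.09 with 1–2 carrier populations,
mirroring a dataset in which roughly a quarter of bands are rare and
regionally confined. A `scale` argument shrinks individuals and markers
proportionally for quick runs; tests use `scale` 0.1–0.5 and the
parameter-recovery checks run at full scale (they take seconds).

What the generator does **not** emulate: among-*region* structure
(population frequencies are exchangeable across regions, so simulated
`F_CT ≈ 0` — regional signal enters only through the injected restricted
bands); linkage between markers; scoring error and size homoplasy of
real AFLP data; unequal sample sizes per population. Passing tests on
synthetic data therefore validate the estimators and the pipeline
plumbing, not robustness to those real-data features. Haplotype samples
are multinomial draws from a stated pool, not coalescent simulations.

## Numerical and degenerate-input policy

- Frequencies and components are float64 throughout; the Stirling
  recurrence runs entirely in log space and is stable to n of a few
  hundred.
- Populations with a single individual are rejected by the diversity
  and AMOVA stages with an explicit message (exclude them upstream).
- An empty rare-band set is valid; the capture/PSA stages are skipped
  with a warning when fewer than two rare bands exist, and the capture
  regression refuses all-equal frequencies (undefined slope).
- Dice similarity of two all-zero profiles is an error (undefined), and
  the sampling equation refuses `F_ST ≥ 1`.
- Report JSON is seed-deterministic; wall-clock stage timings are
  diverted to a separate manifest file so reruns are byte-identical.

## Known limitations

- Absolute `h` and `DW` values depend on the documented estimator
  conventions (above); compare them only within one analysis.
- The equal-frequency assumption of the completeness model is
  optimistic for skewed haplotype pools; the warning threshold (one
  haplotype holding > 50% of draws) is a heuristic.
- The AMOVA permutation loop for the hierarchical design re-evaluates
  the full decomposition three times per replicate; at the default 1023
  replicates and a few hundred individuals this takes tens of seconds —
  reduce `n_permutations` for exploratory runs (stage caching avoids
  repeat cost across reruns).
- The prioritization bonuses are policy knobs. Different weightings can
  reorder closely ranked populations; the report records every score so
  the ordering is auditable.
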