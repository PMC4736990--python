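"""Per-population diversity and rarity descriptors for dominant markers.

Dominant markers (AFLP bands and the like) are scored as band
presence/absence per individual, so only the band-phenotype frequency
``f`` is observable per population. The descriptors here are:

* Nei's gene diversity ``h``, averaged over the dataset's polymorphic
  markers: the per-marker term is ``1 - f^2 - (1-f)^2 = 2 f (1-f)``,
  computed on phenotype frequencies directly (no Hardy-Weinberg
  square-root transform; see docs/methods.md for the rationale and the
  optional small-sample correction).
* Frequency down-weighted marker values (DW): for each band carried by
  the population, the ratio of its carriers in the population to its
  carriers in the whole dataset, summed and divided by the population's
  sample size. Populations carrying globally scarce bands score high.
* Rare alleles: bands whose overall frequency is below a threshold
  (default 10%) and which occur in fewer than a threshold fraction of
  populations (default 20%) — both strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnalysisConfig, MarkerMatrix, PopulationProfile

__all__ = [
    "RareAllele",
    "band_frequencies",
    "nei_diversity",
    "dw_rarity",
    "find_rare_alleles",
    "n_rare_per_population",
    "dice_similarity",
    "nei_li_distance",
    "population_profiles",
]


@dataclass(frozen=True)
class RareAllele:
    """One rare band: mean carrier-population frequency and carrier set.

    ``p`` is the unweighted mean of the band's frequency over the
    populations that carry it (not the overall frequency used by the
    rarity filter); ``n_carriers`` is the N of the loss probability
    L = (1 - p)^(2N).
    """

    marker_id: str
    p: float
    carrier_pops: frozenset[str]
    overall_freq: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"mean carrier frequency must lie in (0,1), got {self.p}")
        if not self.carrier_pops:
            raise ValueError("a rare allele needs at least one carrier population")

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_pops)


def band_frequencies(matrix: MarkerMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Per-population and overall band frequencies.

    Returns ``(per_pop, overall)`` where ``per_pop`` is populations x
    markers and ``overall`` is indexed by marker. Missing calls are
    excluded from each denominator (complete-case within population).
    """
    grouped = matrix.values.groupby(matrix.pop_of_individual, sort=False)
    per_pop = grouped.mean().reindex(matrix.populations)
    overall = matrix.values.mean(axis=0, skipna=True)
    return per_pop, overall


def nei_diversity(
    matrix: MarkerMatrix,
    population: str,
    config: AnalysisConfig | None = None,
) -> float:
    """Nei's gene diversity of one population over dataset-polymorphic markers."""
    config = config or AnalysisConfig()
    individuals = matrix.individuals_in(population)
    if len(individuals) < 2:
        raise ValueError(
            f"population {population!r} has a single individual; "
            "exclude it from diversity estimation"
        )
    poly = matrix.polymorphic_markers()
    if not poly:
        raise ValueError("no polymorphic markers in the dataset")
    sub = matrix.values.loc[individuals, poly]
    f = sub.mean(axis=0, skipna=True)
    h = 2.0 * f * (1.0 - f)
    if config.nei_sample_size_correction:
        n = sub.notna().sum(axis=0)
        h = h * n / (n - 1)
    return float(h.mean())


def dw_rarity(
    matrix: MarkerMatrix,
    population: str,
    config: AnalysisConfig | None = None,
) -> float:
    """Frequency down-weighted marker value of one population.

    Sum over markers of (carriers in the population / carriers in the
    whole dataset), divided by the population's sample size; markers with
    no carrier anywhere are skipped. The unnormalized sum is available
    via ``dw_normalize_by_individuals=False``.
    """
    config = config or AnalysisConfig()
    individuals = matrix.individuals_in(population)
    carriers_pop = matrix.values.loc[individuals].sum(axis=0, skipna=True)
    carriers_all = matrix.values.sum(axis=0, skipna=True)
    present = carriers_all > 0
    total = float((carriers_pop[present] / carriers_all[present]).sum())
    if config.dw_normalize_by_individuals:
        total /= len(individuals)
    return total


def find_rare_alleles(
    matrix: MarkerMatrix, config: AnalysisConfig | None = None
) -> list[RareAllele]:
    """Bands passing both rarity criteria (strict inequalities).

    Overall frequency below ``rare_freq_threshold`` and carrier-population
    fraction below ``rare_popfrac_threshold``.
    """
    config = config or AnalysisConfig()
    pops = matrix.populations
    if len(pops) < 2:
        raise ValueError("rare-allele criteria need at least 2 populations")
    per_pop, overall = band_frequencies(matrix)
    out: list[RareAllele] = []
    n_pops = len(pops)
    for marker in matrix.marker_ids:
        f_all = overall[marker]
        if not 0.0 < f_all < config.rare_freq_threshold:
            continue
        freqs = per_pop[marker]
        carriers = freqs.index[freqs > 0]
        if len(carriers) / n_pops >= config.rare_popfrac_threshold:
            continue
        out.append(
            RareAllele(
                marker_id=marker,
                p=float(freqs[carriers].mean()),
                carrier_pops=frozenset(carriers),
                overall_freq=float(f_all),
            )
        )
    return out


def n_rare_per_population(rare_alleles: list[RareAllele], population: str, *, populations: list[str] | None = None) -> int:
    """Count of rare alleles whose carrier set includes ``population``."""
    if populations is not None and population not in populations:
        raise KeyError(f"unknown population {population!r}")
    return sum(1 for ra in rare_alleles if population in ra.carrier_pops)


def dice_similarity(a: np.ndarray | pd.Series, b: np.ndarray | pd.Series) -> float:
    """Dice band-sharing coefficient 2|a∩b| / (|a| + |b|) of two profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must cover the same marker set")
    ok = ~(np.isnan(a) | np.isnan(b))
    na, nb = a[ok].sum(), b[ok].sum()
    if na + nb == 0:
        raise ValueError("Dice similarity undefined for two all-zero profiles")
    shared = float((a[ok] * b[ok]).sum())
    return 2.0 * shared / float(na + nb)


def nei_li_distance(a, b) -> float:
    """Genetic distance 1 - Dice similarity."""
    return 1.0 - dice_similarity(a, b)


def population_profiles(
    matrix: MarkerMatrix,
    rare_alleles: list[RareAllele] | None = None,
    config: AnalysisConfig | None = None,
) -> list[PopulationProfile]:
    """h_Nei, DW and N_r for every population, in matrix order."""
    config = config or AnalysisConfig()
    if rare_alleles is None:
        rare_alleles = find_rare_alleles(matrix, config)
    out = []
    for pop in matrix.populations:
        out.append(
            PopulationProfile(
                population=pop,
                h_nei=nei_diversity(matrix, pop, config),
                dw=dw_rarity(matrix, pop, config),
                n_r=n_rare_per_population(rare_alleles, pop),
                n_individuals=len(matrix.individuals_in(pop)),
            )
        )
    return out
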