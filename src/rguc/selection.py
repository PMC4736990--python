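"""Selection of relevant genetic units for conservation (RGUCs).

The workflow answers two questions. First, *how many* populations must
be protected so that a target proportion P of the among-population
genetic diversity is represented: with population differentiation F_ST,
the proportion captured by n populations is 1 - F_ST^n, so the minimum
n solves 1 - F_ST^n >= P. Second, *which* populations: rare bands carry
the singular variation, and for each rare band with mean carrier
frequency p present in N populations the probability that protecting
those N populations still loses the band is L = (1 - p)^(2N)
(two genomes sampled per population). Comparing the observed loss
(N = carrier count) against the expected loss when a single population
is sampled (N = 1) over all rare bands — via the slopes of the
-log L vs p regressions — yields R, the proportion of rare alleles
captured by sampling one population. Each rare band is then assigned to
the geographic region where one randomly sampled population is most
likely to capture it (its preferred sampling area, PSA); the regional
PSA shares apportion the protected-population quota, and populations are
ranked within regions by a composite of diversity and rarity plus
conservation attributes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    VULNERABILITY_GOOD,
    AnalysisConfig,
    MarkerMatrix,
    PopulationAttributes,
    PopulationProfile,
    RegionPartition,
)
from .diversity import RareAllele

log = logging.getLogger("rguc")

__all__ = [
    "SamplingRequirement",
    "LossProbabilities",
    "CaptureRegression",
    "PsaAssignment",
    "RgucSelection",
    "populations_needed",
    "loss_probabilities",
    "capture_R",
    "assign_psa",
    "apportion",
    "prioritize",
]


@dataclass(frozen=True)
class SamplingRequirement:
    """Minimum number of populations capturing a target diversity share."""

    target_p: float
    fst: float
    n_real: float
    n_required: int

    def __post_init__(self) -> None:
        if self.n_required < 1:
            raise ValueError("n_required must be >= 1")


@dataclass(frozen=True)
class AlleleLoss:
    marker_id: str
    p: float
    n_carriers: int
    lo: float
    le: float

    @property
    def neg_log_lo(self) -> float:
        return -math.log(self.lo)

    @property
    def neg_log_le(self) -> float:
        return -math.log(self.le)


@dataclass(frozen=True)
class LossProbabilities:
    """Observed and single-population loss probabilities per rare allele.

    lo = (1-p)^(2N) with N the carrier-population count; le = (1-p)^2,
    the loss probability when only one population is sampled.
    """

    alleles: tuple[AlleleLoss, ...]

    def __iter__(self):
        return iter(self.alleles)

    def __len__(self):
        return len(self.alleles)


@dataclass(frozen=True)
class CaptureRegression:
    """Slopes of -log L vs p and their ratio R = m_e / m_o.

    R is the proportion of rare alleles captured by sampling a single
    population; R = 1 exactly when every rare allele is private to one
    population.
    """

    slope_obs: float
    slope_exp: float
    intercept_obs: float
    intercept_exp: float

    @property
    def R(self) -> float:
        return self.slope_exp / self.slope_obs


@dataclass(frozen=True)
class PsaAssignment:
    """Preferred sampling area of each rare allele, with regional shares."""

    region_of_allele: dict[str, str]
    counts: dict[str, int]
    proportions: dict[str, float]

    def rounded(self, decimals: int = 2) -> dict[str, float]:
        return {r: round(v, decimals) for r, v in self.proportions.items()}


@dataclass(frozen=True)
class RankedPopulation:
    population: str
    score: float
    genetic_score: float
    bonus: float
    selected: bool
    also_recommended_for: tuple[str, ...] = ()


@dataclass(frozen=True)
class RgucSelection:
    allocation: dict[str, int]
    ranked_populations: dict[str, tuple[RankedPopulation, ...]]

    def selected(self, region: str | None = None) -> list[str]:
        regions = [region] if region else list(self.ranked_populations)
        return [
            rp.population
            for g in regions
            for rp in self.ranked_populations[g]
            if rp.selected
        ]

    def also_recommended(self, region: str | None = None) -> list[str]:
        regions = [region] if region else list(self.ranked_populations)
        return [
            rp.population
            for g in regions
            for rp in self.ranked_populations[g]
            if not rp.selected and rp.also_recommended_for
        ]


# ---------------------------------------------------------------------------

def populations_needed(target_p: float, fst: float) -> SamplingRequirement:
    """Smallest integer n with 1 - fst**n >= target_p.

    Also reports the real-valued solution n = ln(1 - P)/ln(F_ST). The
    ceiling (not rounding) is deliberate: the requirement is a lower
    bound on protection effort.
    """
    if not 0.0 < target_p < 1.0:
        raise ValueError(f"target_p must lie in (0,1), got {target_p}")
    if fst >= 1.0:
        raise ValueError("fst >= 1 leaves the diversity target unreachable")
    if fst < 0.0:
        raise ValueError("fst must be nonnegative")
    if fst == 0.0:
        log.info("fst = 0: a single population carries all diversity")
        return SamplingRequirement(target_p, fst, 1.0, 1)
    n_real = math.log(1.0 - target_p) / math.log(fst)
    n_req = max(1, math.ceil(n_real))
    # guard against ceil(x) == x - epsilon artifacts
    if n_req > 1 and 1.0 - fst ** (n_req - 1) >= target_p:
        n_req -= 1
    return SamplingRequirement(target_p, fst, n_real, n_req)


def loss_probabilities(rare_alleles: list[RareAllele]) -> LossProbabilities:
    """Lo = (1-p)^(2N) and Le = (1-p)^2 per rare allele."""
    out = []
    for ra in rare_alleles:
        if not 0.0 < ra.p < 1.0:
            raise ValueError(f"degenerate frequency p={ra.p} for {ra.marker_id}")
        out.append(
            AlleleLoss(
                marker_id=ra.marker_id,
                p=ra.p,
                n_carriers=ra.n_carriers,
                lo=(1.0 - ra.p) ** (2 * ra.n_carriers),
                le=(1.0 - ra.p) ** 2,
            )
        )
    return LossProbabilities(tuple(out))


def capture_R(
    loss: LossProbabilities, config: AnalysisConfig | None = None
) -> CaptureRegression:
    """OLS fits of -log Lo and -log Le on p; R = slope ratio.

    R does not depend on the logarithm base (a common factor cancels in
    the ratio). Requires at least two distinct p values.
    """
    config = config or AnalysisConfig()
    if len(loss) < 2:
        raise ValueError("need at least 2 rare alleles for the regressions")
    p = np.array([a.p for a in loss])
    if np.allclose(p, p[0]):
        raise ValueError("all rare-allele frequencies equal; slope undefined")
    y_obs = np.array([a.neg_log_lo for a in loss])
    y_exp = np.array([a.neg_log_le for a in loss])
    if config.regression_through_origin:
        m_o = float(p @ y_obs / (p @ p))
        m_e = float(p @ y_exp / (p @ p))
        b_o = b_e = 0.0
    else:
        res_o = stats.linregress(p, y_obs)
        res_e = stats.linregress(p, y_exp)
        m_o, b_o = float(res_o.slope), float(res_o.intercept)
        m_e, b_e = float(res_e.slope), float(res_e.intercept)
    return CaptureRegression(m_o, m_e, b_o, b_e)


def assign_psa(
    rare_alleles: list[RareAllele],
    partition: RegionPartition,
    per_pop_freq: pd.DataFrame,
    pop_sizes: pd.Series | dict[str, int],
    config: AnalysisConfig | None = None,
) -> PsaAssignment:
    """Preferred sampling area per rare allele.

    A region g with K_g populations captures the allele with probability
    P_g = (1/K_g) * sum_{j in g} [1 - (1 - p_j)^(2 n_j)] when one of its
    populations is drawn uniformly (p_j = allele frequency in population
    j, n_j its sample size). Each allele goes to the argmax region; ties
    break toward the higher mean frequency among that region's carriers,
    then by region label order. A simpler carrier-fraction rule
    (K_g-carriers / K_g) is available by config.
    """
    config = config or AnalysisConfig()
    sizes = pd.Series(pop_sizes)
    regions = partition.regions
    assignment: dict[str, str] = {}
    for ra in rare_alleles:
        best: tuple | None = None
        for g in regions:
            pops_g = partition.populations_in(g)
            freqs = np.array([float(per_pop_freq.at[p, ra.marker_id]) for p in pops_g])
            freqs = np.nan_to_num(freqs)
            if config.psa_use_carrier_fractions:
                p_g = float((freqs > 0).sum()) / len(pops_g)
            else:
                n_j = sizes[pops_g].to_numpy(dtype=float)
                p_g = float(np.mean(1.0 - (1.0 - freqs) ** (2.0 * n_j)))
            carrier_freqs = freqs[freqs > 0]
            mean_f = float(carrier_freqs.mean()) if carrier_freqs.size else 0.0
            key = (p_g, mean_f, -regions.index(g))
            if best is None or key > best[0]:
                best = (key, g)
            elif key == best[0]:
                log.info("PSA tie for %s between %s and %s; keeping %s",
                         ra.marker_id, best[1], g, best[1])
        assignment[ra.marker_id] = best[1]
    counts = {g: 0 for g in regions}
    for g in assignment.values():
        counts[g] += 1
    total = max(1, len(assignment))
    proportions = {g: counts[g] / total for g in regions}
    return PsaAssignment(assignment, counts, proportions)


def apportion(n_required: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder (Hamilton) apportionment of n_required slots.

    Remainder ties break by label order (logged). Proportions need not
    sum exactly to 1; they are renormalized.
    """
    if n_required < 1:
        raise ValueError("n_required must be >= 1")
    labels = list(proportions)
    weights = np.array([proportions[g] for g in labels], dtype=float)
    if (weights < 0).any():
        raise ValueError("proportions must be nonnegative")
    if weights.sum() == 0:
        raise ValueError("all proportions are zero")
    quotas = n_required * weights / weights.sum()
    alloc = {g: int(math.floor(q)) for g, q in zip(labels, quotas)}
    remainders = {g: q - alloc[g] for g, q in zip(labels, quotas)}
    short = n_required - sum(alloc.values())
    order = sorted(labels, key=lambda g: (-remainders[g], labels.index(g)))
    tied = [g for g in labels if remainders[g] == remainders[order[short - 1]]] if short else []
    if len(tied) > 1:
        log.info("apportionment remainder tie among %s; label order decides", tied)
    for g in order[:short]:
        alloc[g] += 1
    return alloc


def prioritize(
    profiles: list[PopulationProfile],
    attributes: dict[str, PopulationAttributes],
    allocation: dict[str, int],
    partition: RegionPartition,
    config: AnalysisConfig | None = None,
) -> RgucSelection:
    """Rank populations within each region and pick the allocated number.

    The genetic score is the mean of the within-region min-max normalized
    h_Nei, DW and N_r (a metric constant within a region contributes
    0.5). Config-weighted bonuses reward favourable conservation
    attributes (stable vulnerability, protected area, large occupation
    area, large population size). After the top-k choice, a greedy
    coverage pass flags additional populations until every endemic
    haplotype recorded for the region is covered.
    """
    config = config or AnalysisConfig()
    prof_by_pop = {p.population: p for p in profiles}
    ranked: dict[str, tuple[RankedPopulation, ...]] = {}
    for region in partition.regions:
        pops = [p for p in partition.populations_in(region) if p in prof_by_pop]
        if not pops:
            continue
        metrics = pd.DataFrame(
            {
                "h_nei": [prof_by_pop[p].h_nei for p in pops],
                "dw": [prof_by_pop[p].dw for p in pops],
                "n_r": [float(prof_by_pop[p].n_r) for p in pops],
            },
            index=pops,
        )
        span = metrics.max() - metrics.min()
        norm = (metrics - metrics.min()).div(span.replace(0.0, np.nan))
        norm = norm.fillna(0.5)
        genetic = norm.mean(axis=1)

        bonuses = {}
        for p in pops:
            attr = attributes.get(p)
            if attr is None:
                log.warning("population %r lacks attributes; ranked on genetics only", p)
                bonuses[p] = 0.0
                continue
            b = 0.0
            if attr.vulnerability in VULNERABILITY_GOOD:
                b += config.bonus_vulnerability
            if attr.legal_status == "protected":
                b += config.bonus_protected
            if attr.occupation_area == "large":
                b += config.bonus_large_area
            if attr.population_size == "high":
                b += config.bonus_large_size
            bonuses[p] = b
        score = {p: float(genetic[p]) + bonuses[p] for p in pops}
        order = sorted(pops, key=lambda p: (-score[p], pops.index(p)))
        k = allocation.get(region, 0)
        chosen = set(order[:k])

        # greedy endemic-haplotype coverage
        covered: set[str] = set()
        endemics: set[str] = set()
        for p in pops:
            attr = attributes.get(p)
            if attr is None:
                continue
            endemics |= set(attr.endemic_haplotypes)
            if p in chosen:
                covered |= set(attr.haplotypes)
        flags: dict[str, tuple[str, ...]] = {p: () for p in pops}
        missing = endemics - covered
        for p in order:
            if not missing:
                break
            if p in chosen:
                continue
            attr = attributes.get(p)
            gain = (set(attr.haplotypes) & missing) if attr else set()
            if gain:
                flags[p] = tuple(sorted(gain))
                missing -= gain
        if missing:
            log.warning("region %r: endemic haplotypes %s not coverable", region, sorted(missing))

        ranked[region] = tuple(
            RankedPopulation(
                population=p,
                score=score[p],
                genetic_score=float(genetic[p]),
                bonus=bonuses[p],
                selected=p in chosen,
                also_recommended_for=flags[p],
            )
            for p in order
        )
    return RgucSelection(dict(allocation), ranked)
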