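"""Seeded generators for dominant-marker datasets with known structure.

Band frequencies follow the F-model (Balding–Nichols): each marker has
an ancestral frequency π ~ Uniform(0.05, 0.95) and each population draws
its own frequency from Beta(π(1-F)/F, (1-π)(1-F)/F), whose mean is π and
whose among-population variance is F·π(1-π) — so the F parameter is
exactly the quantity an AMOVA F_ST estimates, making parameter recovery
a meaningful check. Individuals are Bernoulli draws from the population
frequency. Rare bands can be injected at chosen frequencies into chosen
populations, with the realized layout returned as a truth record.

The default specification mirrors a 17-population, 3-region,
~21-individuals-per-population, ~1100-marker study layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HaplotypeSample, MarkerMatrix, RegionPartition

__all__ = ["SimSpec", "RareInjection", "SimTruth", "simulate_matrix", "simulate_haplotype_sample", "default_spec"]


@dataclass(frozen=True)
class RareInjection:
    """A rare band forced into specific populations at a target frequency."""

    target_p: float
    carrier_pops: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.target_p < 1.0:
            raise ValueError("target_p must lie in (0,1)")
        if not self.carrier_pops:
            raise ValueError("need at least one carrier population")


@dataclass(frozen=True)
class SimSpec:
    """Shape and structure of a simulated dominant-marker dataset."""

    n_populations: int = 17
    individuals_per_population: int = 21
    n_markers: int = 1100
    n_regions: int = 3
    structure_f: float = 0.29
    rare_injections: tuple[RareInjection, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_populations, self.individuals_per_population, self.n_markers, self.n_regions) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.structure_f < 1.0:
            raise ValueError("structure_f must lie in [0, 1)")
        if self.n_regions > self.n_populations:
            raise ValueError("more regions than populations")

    def population_codes(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_populations)]

    def region_partition(self) -> RegionPartition:
        pops = self.population_codes()
        bounds = np.linspace(0, self.n_populations, self.n_regions + 1).round().astype(int)
        mapping = {}
        for r in range(self.n_regions):
            for p in pops[bounds[r]:bounds[r + 1]]:
                mapping[p] = f"R{r + 1}"
        return RegionPartition(mapping)


@dataclass(frozen=True)
class SimTruth:
    """What the generator actually produced."""

    structure_f: float
    ancestral_freq: np.ndarray
    pop_freq: pd.DataFrame
    injected_markers: dict[str, dict]


def default_spec(**overrides) -> SimSpec:
    return SimSpec(**overrides)


def study_like_spec(
    rng_seed: int = 0,
    n_rare_per_region: int = 8,
    scale: float = 1.0,
) -> SimSpec:
    """A 17-population / 3-region layout with injected rare bands.

    Adds ``n_rare_per_region`` geographically restricted low-frequency
    bands per region (carrier counts 1-2, target frequencies 0.04-0.09),
    emulating datasets where a minority of bands is both scarce and
    regionally confined. ``scale`` < 1 shrinks markers and individuals
    proportionally for quick runs.
    """
    rng = np.random.default_rng(rng_seed)
    spec = SimSpec(
        n_populations=17,
        individuals_per_population=max(4, round(21 * scale)),
        n_markers=max(20, round(1100 * scale)),
        n_regions=3,
        structure_f=0.29,
        rng_seed=rng_seed,
    )
    partition = spec.region_partition()
    injections = []
    for region in partition.regions:
        pops = partition.populations_in(region)
        for _ in range(n_rare_per_region):
            n_carry = int(rng.integers(1, 3))
            carriers = tuple(rng.choice(pops, size=min(n_carry, len(pops)), replace=False))
            target_p = float(rng.uniform(0.04, 0.09))
            injections.append(RareInjection(target_p, carriers))
    return SimSpec(
        n_populations=spec.n_populations,
        individuals_per_population=spec.individuals_per_population,
        n_markers=spec.n_markers,
        n_regions=spec.n_regions,
        structure_f=spec.structure_f,
        rare_injections=tuple(injections),
        rng_seed=rng_seed,
    )


def simulate_matrix(spec: SimSpec) -> tuple[MarkerMatrix, SimTruth]:
    """Draw a binary marker matrix under the F-model.

    Injected rare markers are laid down deterministically: in each chosen
    carrier population, max(1, round(target_p · n)) individuals carry the
    band; everyone else lacks it. This makes the truth record exactly
    recoverable by the rare-band filter.
    """
    rng = np.random.default_rng(spec.rng_seed)
    pops = spec.population_codes()
    n_ind = spec.individuals_per_population
    F = spec.structure_f

    pi = rng.uniform(0.05, 0.95, size=spec.n_markers)
    if F == 0.0:
        pop_freq = np.tile(pi, (spec.n_populations, 1))
    else:
        a = pi * (1.0 - F) / F
        b = (1.0 - pi) * (1.0 - F) / F
        pop_freq = rng.beta(a, b, size=(spec.n_populations, spec.n_markers))

    blocks = []
    for i, _pop in enumerate(pops):
        blocks.append((rng.random((n_ind, spec.n_markers)) < pop_freq[i]).astype(float))
    values = np.vstack(blocks)

    marker_ids = [f"m{j + 1}" for j in range(spec.n_markers)]
    individual_ids = [f"{p}_{i + 1}" for p in pops for i in range(n_ind)]
    pop_of_ind = {f"{p}_{i + 1}": p for p in pops for i in range(n_ind)}

    injected: dict[str, dict] = {}
    pop_row = {p: slice(ix * n_ind, (ix + 1) * n_ind) for ix, p in enumerate(pops)}
    for k, inj in enumerate(spec.rare_injections):
        unknown = set(inj.carrier_pops) - set(pops)
        if unknown:
            raise ValueError(f"injection names unknown populations: {sorted(unknown)}")
        col = spec.n_markers + k
        marker_ids.append(f"rare{k + 1}")
        newcol = np.zeros((values.shape[0], 1))
        realized = {}
        for p in inj.carrier_pops:
            n_carry = max(1, round(inj.target_p * n_ind))
            rows = np.arange(pop_row[p].start, pop_row[p].stop)
            chosen = rng.choice(rows, size=n_carry, replace=False)
            newcol[chosen, 0] = 1.0
            realized[p] = n_carry / n_ind
        values = np.hstack([values, newcol])
        injected[f"rare{k + 1}"] = {
            "target_p": inj.target_p,
            "carrier_pops": tuple(inj.carrier_pops),
            "realized_freq": realized,
            "column": col,
        }

    matrix = MarkerMatrix(values, individual_ids, marker_ids, pop_of_ind)
    truth = SimTruth(
        structure_f=F,
        ancestral_freq=pi,
        pop_freq=pd.DataFrame(pop_freq, index=pops, columns=[f"m{j + 1}" for j in range(spec.n_markers)]),
        injected_markers=injected,
    )
    return matrix, truth


def simulate_haplotype_sample(
    pool_frequencies: "np.ndarray | list[float]", n: int, seed: int = 0
) -> HaplotypeSample:
    """Multinomial draw of n sequences from a haplotype pool."""
    freqs = np.asarray(pool_frequencies, dtype=float)
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError("pool frequencies must sum to 1")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, freqs)
    observed = draws[draws > 0]
    return HaplotypeSample(n=n, k=int((draws > 0).sum()), counts=tuple(int(x) for x in observed))
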