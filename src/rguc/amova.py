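"""Analysis of molecular variance (AMOVA) on binary marker phenotypes.

Variation is partitioned from the matrix of pairwise squared Euclidean
distances between individuals (for 0/1 band profiles this is simply the
number of markers at which two individuals differ). Sums of squares
follow the classical distance-matrix decomposition: the total sum of
squares is the sum of all pairwise distances divided by the number of
individuals, and each grouping level contributes the analogous
within-group sums. Variance components are obtained from the expected
mean squares with unequal sample sizes, and Phi/F statistics are ratios
of components. Significance comes from permutation tests that preserve
sample sizes; the F_ST confidence interval comes from a percentile
bootstrap over marker columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AnalysisConfig, MarkerMatrix, RegionPartition

log = logging.getLogger("rguc")

__all__ = ["AmovaResult", "pairwise_sq_distance", "amova_one_level", "amova_hierarchical"]


@dataclass(frozen=True)
class AmovaResult:
    """Variance decomposition at one or three levels.

    ``levels`` holds (source label, df, sum of squares, variance
    component, percentage of total); ``phi_statistics`` maps statistic
    name (F_ST, and F_CT / F_SC for the hierarchical design) to value;
    ``p_values`` holds permutation p per statistic; ``fst_ci`` is the
    bootstrap percentile interval for F_ST, when computed.
    """

    levels: tuple[tuple[str, int, float, float, float], ...]
    phi_statistics: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    fst_ci: tuple[float, float] | None = None

    @property
    def fst(self) -> float:
        return self.phi_statistics["F_ST"]

    def percentage(self, source: str) -> float:
        for label, *_rest, pct in self.levels:
            if label == source:
                return pct
        raise KeyError(source)


def pairwise_sq_distance(matrix: MarkerMatrix) -> np.ndarray:
    """Squared Euclidean distance = count of differing markers.

    Missing calls are skipped pairwise: a marker contributes to d(i,j)
    only when both individuals are scored there.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    obs = ~np.isnan(X)
    A = np.where(obs, X, 0.0)
    B = np.where(obs, 1.0 - X, 0.0)
    D = A @ B.T + B @ A.T
    np.fill_diagonal(D, 0.0)
    return D


def _group_ss(D: np.ndarray, members: list[np.ndarray]) -> float:
    """Sum over groups of (sum of within-group pairwise distances) / n_g."""
    total = 0.0
    for idx in members:
        if len(idx) > 1:
            sub = D[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * len(idx))
    return total


def _indices_by_label(labels: np.ndarray) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for lab in dict.fromkeys(labels):
        out[lab] = np.flatnonzero(labels == lab)
    return out


def _one_level_components(D: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float, int, int]:
    """(ss_among, ss_within, sigma_a, sigma_w, df_among, df_within)."""
    N = len(labels)
    groups = _indices_by_label(labels)
    P = len(groups)
    sizes = np.array([len(idx) for idx in groups.values()], dtype=float)
    ss_total = D.sum() / (2.0 * N)
    ss_within = _group_ss(D, list(groups.values()))
    ss_among = ss_total - ss_within
    df_among, df_within = P - 1, N - P
    ms_within = ss_within / df_within
    ms_among = ss_among / df_among
    n0 = (N - (sizes**2).sum() / N) / (P - 1)
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n0
    return ss_among, ss_within, sigma_a, sigma_w, df_among, df_within


def _fst_from(D: np.ndarray, labels: np.ndarray) -> float:
    _, _, sa, sw, _, _ = _one_level_components(D, labels)
    return sa / (sa + sw)


def amova_one_level(
    matrix: MarkerMatrix,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
    compute_ci: bool = True,
) -> AmovaResult:
    """Single-grouping AMOVA: among vs within populations.

    Permutation p-value from ``n_permutations`` random reassignments of
    individuals to populations (sizes preserved), computed as
    (b + 1)/(n_perm + 1). CI from a percentile bootstrap over markers.
    """
    config = config or AnalysisConfig()
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    labels = matrix.pop_of_individual.to_numpy()
    sizes = matrix.pop_sizes()
    if (sizes < 2).any():
        bad = list(sizes.index[sizes < 2])
        raise ValueError(f"populations with a single individual: {bad}")
    D = pairwise_sq_distance(matrix)
    ss_a, ss_w, sigma_a, sigma_w, df_a, df_w = _one_level_components(D, labels)
    if sigma_a < 0:
        log.warning("negative among-population variance component: %g", sigma_a)
        if config.truncate_negative_components:
            sigma_a = 0.0
    total = sigma_a + sigma_w
    fst = sigma_a / total

    perm_stats = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        perm_stats[b] = _fst_from(D, rng.permutation(labels))
    p = (np.count_nonzero(perm_stats >= fst) + 1) / (config.n_permutations + 1)

    ci = None
    if compute_ci:
        X = matrix.values.to_numpy(dtype=float)
        boots = np.empty(config.n_bootstrap)
        for b in range(config.n_bootstrap):
            cols = rng.integers(0, X.shape[1], size=X.shape[1])
            Xb = X[:, cols]
            obs = ~np.isnan(Xb)
            A = np.where(obs, Xb, 0.0)
            Bm = np.where(obs, 1.0 - Xb, 0.0)
            Db = A @ Bm.T + Bm @ A.T
            np.fill_diagonal(Db, 0.0)
            boots[b] = _fst_from(Db, labels)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(lo), float(hi))

    levels = (
        ("among_populations", df_a, ss_a, sigma_a, 100.0 * sigma_a / total),
        ("within_populations", df_w, ss_w, sigma_w, 100.0 * sigma_w / total),
    )
    return AmovaResult(levels, {"F_ST": float(fst)}, {"F_ST": float(p)}, ci)


def _hier_components(
    D: np.ndarray, pop_labels: np.ndarray, region_labels: np.ndarray
) -> dict:
    """Three-level sums of squares and variance components."""
    N = len(pop_labels)
    pops = _indices_by_label(pop_labels)
    regions = _indices_by_label(region_labels)
    P, G = len(pops), len(regions)
    ss_total = D.sum() / (2.0 * N)
    ss_wp = _group_ss(D, list(pops.values()))
    ss_wg = _group_ss(D, list(regions.values()))
    ss_ap = ss_wg - ss_wp          # among populations within groups
    ss_ag = ss_total - ss_wg       # among groups
    df_ag, df_ap, df_wp = G - 1, P - G, N - P

    pop_sizes = {p: len(idx) for p, idx in pops.items()}
    region_of_pop = {}
    for p, idx in pops.items():
        region_of_pop[p] = region_labels[idx[0]]
    region_sizes = {g: len(idx) for g, idx in regions.items()}

    sum_np2_over_ng = sum(
        sum(pop_sizes[p] ** 2 for p in pops if region_of_pop[p] == g) / region_sizes[g]
        for g in regions
    )
    sum_np2_over_N = sum(n**2 for n in pop_sizes.values()) / N
    sum_ng2_over_N = sum(n**2 for n in region_sizes.values()) / N

    ms_wp = ss_wp / df_wp
    ms_ap = ss_ap / df_ap if df_ap > 0 else np.nan
    ms_ag = ss_ag / df_ag

    n1 = (N - sum_np2_over_ng) / df_ap if df_ap > 0 else np.nan
    n2 = (sum_np2_over_ng - sum_np2_over_N) / df_ag
    n3 = (N - sum_ng2_over_N) / df_ag

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1 if df_ap > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return {
        "ss": (ss_ag, ss_ap, ss_wp),
        "df": (df_ag, df_ap, df_wp),
        "sigma": (sigma_a, sigma_b, sigma_c),
    }


def amova_hierarchical(
    matrix: MarkerMatrix,
    partition: RegionPartition,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA: among groups / among populations within groups /
    within populations, with F_CT, F_SC and F_ST.

    Permutation schemes per statistic: F_CT permutes whole populations
    among groups; F_SC permutes individuals among populations within
    their group; F_ST permutes individuals among populations everywhere.
    """
    config = config or AnalysisConfig()
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    partition.validate_against(matrix)
    pop_labels = matrix.pop_of_individual.to_numpy()
    region_labels = np.array(
        [partition.region_of_population[p] for p in pop_labels]
    )
    if len(set(region_labels)) < 2:
        raise ValueError("hierarchical design needs at least 2 regions")
    for g in partition.regions:
        pops_in_g = [p for p in matrix.populations if partition.region_of_population[p] == g]
        if len(pops_in_g) == 1:
            log.warning("region %r holds a single population; F_SC degenerate there", g)

    D = pairwise_sq_distance(matrix)
    comp = _hier_components(D, pop_labels, region_labels)
    sigma_a, sigma_b, sigma_c = comp["sigma"]
    if sigma_a < 0 or sigma_b < 0:
        log.warning("negative variance component(s): sigma_a=%g sigma_b=%g", sigma_a, sigma_b)
        if config.truncate_negative_components:
            sigma_a, sigma_b = max(sigma_a, 0.0), max(sigma_b, 0.0)
    total = sigma_a + sigma_b + sigma_c
    f_ct = sigma_a / total
    f_sc = sigma_b / (sigma_b + sigma_c)
    f_st = (sigma_a + sigma_b) / total

    # --- permutations ------------------------------------------------------
    pops = matrix.populations
    region_of_pop = dict(partition.region_of_population)
    pop_index = {p: np.flatnonzero(pop_labels == p) for p in pops}

    def stat_triplet(plab, rlab):
        s = _hier_components(D, plab, rlab)["sigma"]
        t = sum(s)
        return s[0] / t, s[1] / (s[1] + s[2]), (s[0] + s[1]) / t

    n_perm = config.n_permutations
    count_ct = count_sc = count_st = 0
    region_seq = [region_of_pop[p] for p in pops]
    for _ in range(n_perm):
        # F_CT: reassign whole populations to regions
        shuffled = rng.permutation(region_seq)
        rmap = dict(zip(pops, shuffled))
        rlab = np.array([rmap[p] for p in pop_labels])
        s = _hier_components(D, pop_labels, rlab)["sigma"]
        if s[0] / sum(s) >= f_ct:
            count_ct += 1
        # F_SC: permute individuals among populations within regions
        plab_sc = pop_labels.copy()
        for g in partition.regions:
            idx = np.flatnonzero(region_labels == g)
            plab_sc[idx] = rng.permutation(plab_sc[idx])
        s = _hier_components(D, plab_sc, region_labels)["sigma"]
        if s[1] / (s[1] + s[2]) >= f_sc:
            count_sc += 1
        # F_ST: permute individuals everywhere
        perm = rng.permutation(len(pop_labels))
        plab_st = pop_labels[perm]
        rlab_st = np.array([region_of_pop[p] for p in plab_st])
        s = _hier_components(D, plab_st, rlab_st)["sigma"]
        if (s[0] + s[1]) / sum(s) >= f_st:
            count_st += 1
    p_values = {
        "F_CT": (count_ct + 1) / (n_perm + 1),
        "F_SC": (count_sc + 1) / (n_perm + 1),
        "F_ST": (count_st + 1) / (n_perm + 1),
    }

    ss_ag, ss_ap, ss_wp = comp["ss"]
    df_ag, df_ap, df_wp = comp["df"]
    levels = (
        ("among_groups", df_ag, ss_ag, sigma_a, 100.0 * sigma_a / total),
        ("among_populations_within_groups", df_ap, ss_ap, sigma_b, 100.0 * sigma_b / total),
        ("within_populations", df_wp, ss_wp, sigma_c, 100.0 * sigma_c / total),
    )
    return AmovaResult(
        levels,
        {"F_CT": float(f_ct), "F_SC": float(f_sc), "F_ST": float(f_st)},
        {k: float(v) for k, v in p_values.items()},
        None,
    )
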