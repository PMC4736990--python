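"""Domain types, file readers/writers and configuration.

The central object is :class:`MarkerMatrix`, a binary presence/absence
matrix of dominant markers (e.g. AFLP bands) for individuals grouped into
populations. Populations may additionally be grouped into geographic
regions (:class:`RegionPartition`) and annotated with qualitative
conservation attributes (:class:`PopulationAttributes`).

All tabular input is delimited text (tab by default); configuration is a
flat YAML mapping loaded into :class:`AnalysisConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("rguc")

__all__ = [
    "MarkerMatrix",
    "RegionPartition",
    "PopulationAttributes",
    "PopulationProfile",
    "HaplotypeSample",
    "AnalysisConfig",
    "read_marker_matrix",
    "read_region_partition",
    "read_population_attributes",
    "write_report",
    "read_report",
]

OCCUPATION_LEVELS = frozenset({"small", "large"})
SIZE_LEVELS = frozenset({"reduced", "high"})
VULNERABILITY_LEVELS = frozenset(
    {"stable", "acceptable", "declining", "moderate", "critically-declining", "critical"}
)
#: levels counted as "not declining" when scoring populations
VULNERABILITY_GOOD = frozenset({"stable", "acceptable"})
LEGAL_LEVELS = frozenset({"protected", "unprotected"})


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds and counts for the whole pipeline.

    rare_freq_threshold
        A marker is a rarity candidate only if its overall band frequency
        (carriers over all individuals) is strictly below this value.
    rare_popfrac_threshold
        ... and if the fraction of populations carrying it is strictly
        below this value.
    target_p
        Proportion of among-population diversity the selected set of
        populations must represent (drives the minimum population count).
    n_permutations
        Replicates for AMOVA permutation tests.
    n_bootstrap
        Marker-bootstrap replicates for the F_ST confidence interval.
    dixon_theta_max
        Upper bound of the uniform prior on the true haplotype number.
    """

    rare_freq_threshold: float = 0.10
    rare_popfrac_threshold: float = 0.20
    target_p: float = 0.999
    n_permutations: int = 1023
    n_bootstrap: int = 1000
    rng_seed: int = 0
    dixon_theta_max: int = 100
    report_decimals: int = 2
    missing_token: str = "?"
    delimiter: str = "\t"
    #: "individuals-rows" (id, population, bands...) or "markers-rows"
    #: (marker id column, one column per individual; populations supplied
    #: separately)
    matrix_orientation: str = "individuals-rows"
    # estimator switches (see docs/methods.md)
    nei_sample_size_correction: bool = False
    dw_normalize_by_individuals: bool = True
    truncate_negative_components: bool = False
    regression_through_origin: bool = False
    psa_use_carrier_fractions: bool = False
    apportion_rounded_proportions: bool = False
    # prioritization bonus weights (added to the 0-1 composite genetic score)
    bonus_vulnerability: float = 0.05
    bonus_protected: float = 0.05
    bonus_large_area: float = 0.05
    bonus_large_size: float = 0.05

    def __post_init__(self) -> None:
        for name in ("rare_freq_threshold", "rare_popfrac_threshold", "target_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        for name in ("n_permutations", "n_bootstrap", "dixon_theta_max"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class MarkerMatrix:
    """Binary individuals x markers matrix with population labels.

    Cells are 0/1 (band absent/present); missing calls are allowed and
    stored as NaN — every frequency downstream uses complete-case
    denominators per population, never imputation.
    """

    def __init__(
        self,
        values: np.ndarray | pd.DataFrame,
        individual_ids: Iterable[str] | None = None,
        marker_ids: Iterable[str] | None = None,
        pop_of_individual: Mapping[str, str] | pd.Series | None = None,
    ) -> None:
        if isinstance(values, pd.DataFrame):
            df = values.astype(float)
        else:
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 2:
                raise ValueError("marker matrix must be 2-dimensional")
            individual_ids = list(individual_ids) if individual_ids is not None else [
                f"ind{i}" for i in range(arr.shape[0])
            ]
            marker_ids = list(marker_ids) if marker_ids is not None else [
                f"m{j}" for j in range(arr.shape[1])
            ]
            df = pd.DataFrame(arr, index=individual_ids, columns=marker_ids)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("empty marker matrix")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate individual ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate marker ids: {dups}")
        bad = ~(df.isna() | (df == 0.0) | (df == 1.0))
        if bad.to_numpy().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-binary cell at individual {df.index[i]!r}, "
                f"marker {df.columns[j]!r}: {df.iat[i, j]!r}"
            )
        if pop_of_individual is None:
            raise ValueError("pop_of_individual is required")
        pops = pd.Series(dict(pop_of_individual) if not isinstance(pop_of_individual, pd.Series) else pop_of_individual)
        missing = set(df.index) - set(pops.index)
        if missing:
            raise ValueError(f"individuals without a population label: {sorted(missing)}")
        self.values = df
        self.pop_of_individual = pops.reindex(df.index).astype(str)

    # -- convenience accessors ------------------------------------------------
    @property
    def individual_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_of_individual:
            seen.setdefault(p, None)
        return list(seen)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def individuals_in(self, population: str) -> list[str]:
        mask = self.pop_of_individual == population
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        return list(self.values.index[mask])

    def pop_sizes(self) -> pd.Series:
        return self.pop_of_individual.value_counts().reindex(self.populations)

    def polymorphic_markers(self) -> list[str]:
        """Markers with at least one carrier and one non-carrier overall."""
        f = self.values.mean(axis=0, skipna=True)
        return list(f.index[(f > 0) & (f < 1)])

    def subset_markers(self, marker_ids: Iterable[str]) -> "MarkerMatrix":
        return MarkerMatrix(self.values[list(marker_ids)], pop_of_individual=self.pop_of_individual)


@dataclass(frozen=True)
class RegionPartition:
    """Total map population code -> region code (e.g. IP / M / CI)."""

    region_of_population: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.region_of_population:
            raise ValueError("region partition is empty")

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.region_of_population.values():
            seen.setdefault(r, None)
        return list(seen)

    def populations_in(self, region: str) -> list[str]:
        return [p for p, r in self.region_of_population.items() if r == region]

    def validate_against(self, matrix: MarkerMatrix) -> None:
        missing = set(matrix.populations) - set(self.region_of_population)
        if missing:
            raise ValueError(f"populations without a region: {sorted(missing)}")


@dataclass(frozen=True)
class PopulationAttributes:
    """Qualitative conservation attributes of one population."""

    occupation_area: str
    population_size: str
    vulnerability: str
    legal_status: str
    haplotypes: frozenset[str] = frozenset()
    endemic_haplotypes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        checks = [
            ("occupation_area", OCCUPATION_LEVELS),
            ("population_size", SIZE_LEVELS),
            ("vulnerability", VULNERABILITY_LEVELS),
            ("legal_status", LEGAL_LEVELS),
        ]
        for name, levels in checks:
            v = getattr(self, name)
            if v not in levels:
                raise ValueError(
                    f"unknown {name} level {v!r}; allowed: {sorted(levels)}"
                )
        if not self.endemic_haplotypes <= self.haplotypes:
            raise ValueError("endemic haplotypes must be a subset of haplotypes")


@dataclass(frozen=True)
class PopulationProfile:
    """Per-population diversity/rarity descriptors."""

    population: str
    h_nei: float
    dw: float
    n_r: int
    n_individuals: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.h_nei <= 1.0:
            raise ValueError(f"h_nei outside [0,1]: {self.h_nei}")
        if self.dw < 0:
            raise ValueError("dw must be nonnegative")
        if self.n_r < 0:
            raise ValueError("n_r must be nonnegative")


@dataclass(frozen=True)
class HaplotypeSample:
    """n sequences sampled, k distinct haplotypes observed."""

    n: int
    k: int
    counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.n:
            raise ValueError(f"need 1 <= k <= n, got k={self.k}, n={self.n}")
        if self.counts is not None:
            c = tuple(int(x) for x in self.counts)
            if len(c) != self.k or any(x <= 0 for x in c) or sum(c) != self.n:
                raise ValueError("counts must be k positive integers summing to n")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_marker_matrix(
    path: str | Path,
    config: AnalysisConfig | None = None,
    pop_of_individual: Mapping[str, str] | None = None,
) -> MarkerMatrix:
    """Read a delimited presence/absence matrix.

    Default layout ("individuals-rows"): header row of marker ids; each
    data row starts with the individual id and its population code,
    followed by 0/1 calls (the configured missing token is allowed).
    With ``matrix_orientation="markers-rows"`` the file is transposed —
    first column marker id, one column per individual — and population
    codes must be supplied via ``pop_of_individual``. Non-binary tokens
    raise with the offending row/column named.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path, sep=config.delimiter, dtype=str, index_col=False)
    if config.matrix_orientation == "markers-rows":
        if pop_of_individual is None:
            raise ValueError(
                "markers-rows orientation carries no population column; "
                "pass pop_of_individual"
            )
        markers = df.iloc[:, 0].astype(str).tolist()
        individuals = [str(c) for c in df.columns[1:]]
        raw = df.iloc[:, 1:].T
        raw.columns = markers
        pops = dict(pop_of_individual)
    elif config.matrix_orientation != "individuals-rows":
        raise ValueError(f"unknown matrix_orientation {config.matrix_orientation!r}")
    else:
        if df.shape[1] < 3:
            raise ValueError("expected columns: individual, population, >=1 marker")
        ind_col, pop_col = df.columns[:2]
        individuals = df[ind_col].astype(str).tolist()
        pops = dict(zip(individuals, df[pop_col].astype(str)))
        raw = df.iloc[:, 2:]

    def parse_cell(tok: object) -> float:
        s = str(tok).strip()
        if s == config.missing_token or s.lower() in ("nan", ""):
            return np.nan
        if s in ("0", "0.0"):
            return 0.0
        if s in ("1", "1.0"):
            return 1.0
        raise ValueError(s)

    values = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy()
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            try:
                values[i, j] = parse_cell(arr[i, j])
            except ValueError:
                raise ValueError(
                    f"non-binary value {arr[i, j]!r} at individual "
                    f"{individuals[i]!r}, marker {raw.columns[j]!r}"
                ) from None
    matrix = MarkerMatrix(values, individuals, list(raw.columns), pops)
    log.info(
        "read marker matrix: %d individuals, %d populations, %d markers (%d polymorphic)",
        matrix.n_individuals,
        len(matrix.populations),
        matrix.n_markers,
        len(matrix.polymorphic_markers()),
    )
    return matrix


def write_marker_matrix(
    matrix: MarkerMatrix, path: str | Path, config: AnalysisConfig | None = None
) -> None:
    config = config or AnalysisConfig()
    out = matrix.values.copy()
    cols = {}
    for m in out.columns:
        col = out[m]
        cols[m] = col.map(
            lambda v: config.missing_token if pd.isna(v) else str(int(v))
        )
    table = pd.DataFrame(cols, index=out.index)
    table.insert(0, "population", matrix.pop_of_individual)
    table.index.name = "individual"
    table.to_csv(path, sep=config.delimiter)


def read_region_partition(
    path: str | Path, config: AnalysisConfig | None = None
) -> RegionPartition:
    """Two-column table: population, region."""
    config = config or AnalysisConfig()
    df = pd.read_csv(path, sep=config.delimiter, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("expected columns: population, region")
    return RegionPartition(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def read_population_attributes(
    path: str | Path,
    config: AnalysisConfig | None = None,
    matrix: MarkerMatrix | None = None,
) -> dict[str, PopulationAttributes]:
    """One row per population with the enumerated qualitative levels.

    Columns: population, occupation_area, population_size, vulnerability,
    legal_status, and optionally haplotypes — a comma-separated list in
    which endemic haplotypes carry a ``*`` suffix (e.g. ``I,V*``).
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path, sep=config.delimiter, dtype=str).fillna("")
    required = {"population", "occupation_area", "population_size", "vulnerability", "legal_status"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"attribute table missing columns: {sorted(missing_cols)}")
    out: dict[str, PopulationAttributes] = {}
    for _, row in df.iterrows():
        haps, endemics = set(), set()
        for tok in str(row.get("haplotypes", "")).split(","):
            tok = tok.strip()
            if not tok:
                continue
            if tok.endswith("*"):
                haps.add(tok[:-1])
                endemics.add(tok[:-1])
            else:
                haps.add(tok)
        out[str(row["population"])] = PopulationAttributes(
            occupation_area=row["occupation_area"].strip(),
            population_size=row["population_size"].strip(),
            vulnerability=row["vulnerability"].strip(),
            legal_status=row["legal_status"].strip(),
            haplotypes=frozenset(haps),
            endemic_haplotypes=frozenset(endemics),
        )
    if matrix is not None:
        extra = set(out) - set(matrix.populations)
        for p in sorted(extra):
            log.warning("attribute row for population %r not present in matrix", p)
        absent = set(matrix.populations) - set(out)
        for p in sorted(absent):
            log.warning("population %r has no attribute row", p)
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: Mapping, path: str | Path) -> Path:
    """Write the analysis report as JSON plus per-population TSV tables.

    ``path`` is a directory; ``report.json`` inside it holds every number,
    and any value under the key ``profiles`` is additionally emitted as
    ``profiles.tsv`` for spreadsheet use. Re-reading the JSON reproduces
    all numbers bit-identically (floats round-trip via repr).
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = _jsonable(report)
    # keys starting with "_" (e.g. stage timings) are run metadata, not
    # results: they go to manifest.json so report.json is seed-deterministic
    manifest = {k: payload.pop(k) for k in list(payload) if k.startswith("_")}
    if manifest:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    profiles = payload.get("profiles")
    if profiles:
        pd.DataFrame(profiles).to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    amova = payload.get("amova")
    if isinstance(amova, dict) and "levels" in amova:
        pd.DataFrame(
            amova["levels"],
            columns=["source", "df", "sum_of_squares", "variance", "percentage"],
        ).to_csv(outdir / "amova.tsv", sep="\t", index=False)
    return outdir / "report.json"


def read_report(path: str | Path) -> dict:
    p = Path(path)
    if p.is_dir():
        p = p / "report.json"
    return json.loads(p.read_text())
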