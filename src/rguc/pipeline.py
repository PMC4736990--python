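"""End-to-end orchestration: matrix -> profiles -> AMOVA -> rare bands ->
loss/R -> preferred sampling areas -> apportionment -> prioritization ->
haplotype completeness -> report.

Every stage result lands in one JSON report together with a manifest
(config echo, input digests, stage timings, seeds), so each number is
traceable. The AMOVA stage — the only expensive one — caches to disk
keyed by a digest of its inputs; rerunning with unchanged inputs reuses
the cached result unless ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .amova import amova_hierarchical, amova_one_level
from .diversity import band_frequencies, find_rare_alleles, population_profiles
from .haplotypes import collapse_haplotypes, dixon_completeness
from .io import (
    AnalysisConfig,
    HaplotypeSample,
    MarkerMatrix,
    RegionPartition,
    read_marker_matrix,
    read_population_attributes,
    read_region_partition,
    write_report,
)
from .selection import (
    apportion,
    assign_psa,
    capture_R,
    loss_probabilities,
    populations_needed,
    prioritize,
)

log = logging.getLogger("rguc")

__all__ = ["run_pipeline", "analyze", "validate_report"]


def _digest(*parts: bytes | str) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode() if isinstance(p, str) else p)
    return h.hexdigest()[:16]


def _matrix_digest(matrix: MarkerMatrix) -> str:
    return _digest(
        matrix.values.to_csv().encode(),
        ",".join(matrix.pop_of_individual),
    )


def analyze(
    matrix: MarkerMatrix,
    partition: RegionPartition,
    attributes: Mapping | None = None,
    haplotype_sample: HaplotypeSample | None = None,
    config: AnalysisConfig | None = None,
    cache_dir: str | Path | None = None,
    force: bool = False,
) -> dict:
    """Run the full analysis on in-memory objects and return the report dict."""
    config = config or AnalysisConfig()
    partition.validate_against(matrix)
    attributes = dict(attributes or {})
    timings: dict[str, float] = {}
    report: dict = {
        "config": config.to_dict(),
        "software_version": __version__,
        "inputs": {
            "matrix_digest": _matrix_digest(matrix),
            "n_individuals": matrix.n_individuals,
            "n_populations": len(matrix.populations),
            "n_markers": matrix.n_markers,
            "n_polymorphic_markers": len(matrix.polymorphic_markers()),
        },
    }

    t0 = time.perf_counter()
    rare = find_rare_alleles(matrix, config)
    profiles = population_profiles(matrix, rare, config)
    per_pop_freq, _overall = band_frequencies(matrix)
    timings["profiles"] = time.perf_counter() - t0
    report["profiles"] = [
        {
            "population": p.population,
            "region": partition.region_of_population[p.population],
            "h_nei": p.h_nei,
            "dw": p.dw,
            "n_r": p.n_r,
            "n_individuals": p.n_individuals,
        }
        for p in profiles
    ]
    report["rare_alleles"] = {
        "count": len(rare),
        "alleles": [
            {
                "marker_id": ra.marker_id,
                "p": ra.p,
                "overall_freq": ra.overall_freq,
                "carrier_pops": sorted(ra.carrier_pops),
            }
            for ra in rare
        ],
    }

    t0 = time.perf_counter()
    one = _cached_amova(matrix, None, config, cache_dir, force)
    hier = (
        _cached_amova(matrix, partition, config, cache_dir, force)
        if len(partition.regions) > 1
        else None
    )
    timings["amova"] = time.perf_counter() - t0
    report["amova"] = _amova_dict(one)
    if hier is not None:
        report["amova_hierarchical"] = _amova_dict(hier)

    req = populations_needed(config.target_p, one.fst)
    report["sampling_requirement"] = {
        "target_p": req.target_p,
        "fst": req.fst,
        "n_real": req.n_real,
        "n_required": req.n_required,
    }

    if len(rare) >= 2:
        loss = loss_probabilities(rare)
        try:
            reg = capture_R(loss, config)
            report["capture"] = {
                "R": reg.R,
                "slope_obs": reg.slope_obs,
                "slope_exp": reg.slope_exp,
            }
        except ValueError as exc:
            report["capture"] = {"error": str(exc)}
        psa = assign_psa(rare, partition, per_pop_freq, matrix.pop_sizes(), config)
        props = (
            psa.rounded(config.report_decimals)
            if config.apportion_rounded_proportions
            else psa.proportions
        )
        alloc = apportion(req.n_required, props)
        report["psa"] = {
            "counts": psa.counts,
            "proportions": psa.proportions,
            "proportions_rounded": psa.rounded(config.report_decimals),
            "region_of_allele": psa.region_of_allele,
        }
        selection = prioritize(profiles, attributes, alloc, partition, config)
        report["selection"] = {
            "allocation": alloc,
            "regions": {
                g: [
                    {
                        "population": rp.population,
                        "score": rp.score,
                        "genetic_score": rp.genetic_score,
                        "bonus": rp.bonus,
                        "selected": rp.selected,
                        "also_recommended_for": list(rp.also_recommended_for),
                    }
                    for rp in ranked
                ]
                for g, ranked in selection.ranked_populations.items()
            },
        }
    else:
        log.warning("fewer than 2 rare alleles; capture/PSA stages skipped")
        report["capture"] = {"error": "fewer than 2 rare alleles"}

    if haplotype_sample is not None:
        dix = dixon_completeness(haplotype_sample, config.dixon_theta_max)
        report["dixon"] = {
            "n": dix.n,
            "k": dix.k,
            "theta_max": dix.theta_max,
            "posterior_mean": round(dix.posterior_mean, 3),
            "p_complete": dix.p_complete,
        }
    else:
        report["dixon"] = {"status": "not computed"}

    # timings vary run to run; they ride along under a key the writer
    # diverts to manifest.json so report.json stays seed-deterministic
    report["_timings_s"] = {k: round(v, 4) for k, v in timings.items()}
    validate_report(report)
    return report


def _amova_dict(result) -> dict:
    return {
        "levels": [list(level) for level in result.levels],
        "phi_statistics": result.phi_statistics,
        "p_values": result.p_values,
        "fst_ci": list(result.fst_ci) if result.fst_ci else None,
    }


def _cached_amova(matrix, partition, config, cache_dir, force):
    from .amova import AmovaResult

    key = None
    if cache_dir is not None:
        part_part = (
            json.dumps(dict(partition.region_of_population), sort_keys=True)
            if partition
            else "one-level"
        )
        key = _digest(_matrix_digest(matrix), part_part, json.dumps(config.to_dict(), sort_keys=True))
        path = Path(cache_dir) / f"amova-{key}.json"
        if path.exists() and not force:
            log.info("amova cache hit: %s", path.name)
            d = json.loads(path.read_text())
            return AmovaResult(
                tuple(tuple(level) for level in d["levels"]),
                d["phi_statistics"],
                d["p_values"],
                tuple(d["fst_ci"]) if d["fst_ci"] else None,
            )
    rng = np.random.default_rng(config.rng_seed)
    result = (
        amova_one_level(matrix, config, rng)
        if partition is None
        else amova_hierarchical(matrix, partition, config, rng)
    )
    if key is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        (Path(cache_dir) / f"amova-{key}.json").write_text(json.dumps(_amova_dict(result)))
    return result


def validate_report(report: dict) -> None:
    """Cross-stage consistency: PSA counts partition the rare alleles,
    the allocation conserves the required population number, and AMOVA
    percentages sum to 100."""
    for key in ("amova", "amova_hierarchical"):
        if key in report:
            pct = sum(level[4] for level in report[key]["levels"])
            if abs(pct - 100.0) > 1e-6:
                raise AssertionError(f"{key} percentages sum to {pct}, not 100")
    if "psa" in report:
        n_rare = report["rare_alleles"]["count"]
        total = sum(report["psa"]["counts"].values())
        if total != n_rare:
            raise AssertionError(f"PSA counts sum to {total}, rare alleles {n_rare}")
    if "selection" in report:
        alloc = sum(report["selection"]["allocation"].values())
        need = report["sampling_requirement"]["n_required"]
        if alloc != need:
            raise AssertionError(f"allocation {alloc} != n_required {need}")


def run_pipeline(
    matrix_path: str | Path,
    regions_path: str | Path,
    attributes_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
    sequence_pops_path: str | Path | None = None,
    config: AnalysisConfig | None = None,
    out: str | Path = "rguc-report",
    cache_dir: str | Path | None = None,
    force: bool = False,
) -> Path:
    """File-based entry point; writes the report bundle and returns its path."""
    config = config or AnalysisConfig()
    matrix = read_marker_matrix(matrix_path, config)
    partition = read_region_partition(regions_path, config)
    attributes = (
        read_population_attributes(attributes_path, config, matrix)
        if attributes_path
        else {}
    )
    sample = None
    if fasta_path:
        pop_of_seq = None
        if sequence_pops_path:
            import pandas as pd

            df = pd.read_csv(sequence_pops_path, sep=config.delimiter, dtype=str)
            pop_of_seq = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        sample, _, _ = collapse_haplotypes(fasta_path, pop_of_seq)
    report = analyze(matrix, partition, attributes, sample, config, cache_dir, force)
    return write_report(report, out)
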