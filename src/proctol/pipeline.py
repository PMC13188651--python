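"""End-to-end analysis orchestration.

``run_analysis`` executes the full chain on one cohort: ingest (or
generate) -> pooled summary -> experience-threshold scan -> filter ->
filtered summary -> distribution fits -> exceedance limits (GPQ,
noncentral-t, binomial) per tolerance -> rank associations on the full
cohort.  The result is a JSON-serializable report in which every number
is re-derivable from the configuration plus the input, and identical
config + seed gives a byte-identical report (timestamp aside).

Per-stage seeds are derived from the single master seed by hashing the
stage name (CRC-32) into a SeedSequence spawn key, so adding a stage
never perturbs another stage's draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Sequence

import numpy as np

from . import __version__
from .association import kendall_tau_b, permutation_pvalue, spearman_rho
from .cohort import Cohort, SummaryStats, read_cohort, summarize
from .cohort import filter_by_experience
from .exceedance import (
    ExceedanceQuery,
    clopper_pearson_upper,
    exceedance_upper_noncentral_t,
    gpq_exceedance_upper,
    log_summary,
)
from .fit import compare_distributions
from .scan import scan_thresholds
from .simulate import GeneratorConfig, generate_cohort

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "count_exceedances"]

logger = logging.getLogger("proctol")


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the pipeline needs; echoed verbatim into the report."""

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    tolerances: tuple[float, ...] = (5.0, 4.0)
    level: float = 0.95
    replications_R: int = 2_999_999
    seed: int = 0
    alpha_fit: float = 0.05
    min_subset: int = 20
    permutations_M: int = 50_000
    threshold_override: int | None = None
    count_comparator: str = "ge"  # binomial event: time >= L ("ge") or > L ("gt")

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path or generator is required")
        if self.count_comparator not in ("ge", "gt"):
            raise ValueError("count_comparator must be 'ge' or 'gt'")


@dataclass(frozen=True)
class AnalysisReport:
    config: dict
    cohort_full: dict
    scan: dict
    cohort_filtered: dict
    fits: dict
    exceedance: list
    associations: list
    versions: dict
    seed: int
    timestamp: str

    def to_json(self, include_timestamp: bool = True) -> str:
        payload = dataclasses.asdict(self)
        if not include_timestamp:
            payload.pop("timestamp")
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_text(self) -> str:
        """Human-readable report following the analysis chain order."""
        lines = [f"proctol analysis report (seed {self.seed})", ""]
        cf = self.cohort_full["summary"]
        lines.append(
            f"Full cohort: n = {cf['n']}, mean {cf['mean']:.2f} min "
            f"(SD {cf['sd']:.2f}), median {cf['median']:.2f}"
        )
        sel = self.scan["selected_threshold"]
        lines.append(f"Selected experience threshold: {sel}")
        ff = self.cohort_filtered["summary"]
        lines.append(
            f"Filtered cohort: n = {ff['n']}, mean {ff['mean']:.2f} min "
            f"(SD {ff['sd']:.2f}), median {ff['median']:.2f}, CV {ff['cv'] * 100:.1f}%"
        )
        lines.append(f"Best-fitting distribution: {self.fits['winner']}")
        for entry in self.exceedance:
            lines.append(
                f"P(time > {entry['tolerance_L']:.1f} min): plug-in "
                f"{entry['gpq']['point_estimate'] * 100:.4f}%, GPQ "
                f"{entry['level'] * 100:.0f}% upper limit "
                f"{entry['gpq']['upper_limit'] * 100:.2f}% "
                f"(nct {entry['noncentral_t']['upper_limit'] * 100:.2f}%); "
                f"binomial {entry['count_x']}/{entry['count_n']} -> "
                f"{entry['clopper_pearson_upper'] * 100:.1f}%"
            )
        for assoc in self.associations:
            lines.append(
                f"{assoc['statistic_name']}({assoc['x']}, time): "
                f"{assoc['estimate']:.3f}"
                + (
                    f", permutation p = {assoc['p_value']:.4g}"
                    if assoc.get("p_value") is not None
                    else ""
                )
            )
        return "\n".join(lines) + "\n"


def count_exceedances(
    times, tolerance_L: float, comparator: str = "ge"
) -> tuple[int, int]:
    """Count times meeting the comparator against L: (x events, n total)."""
    x = np.asarray(times, dtype=float)
    if x.size == 0:
        raise ValueError("times must be non-empty")
    if comparator == "ge":
        events = int(np.sum(x >= tolerance_L))
    elif comparator == "gt":
        events = int(np.sum(x > tolerance_L))
    else:
        raise ValueError("comparator must be 'ge' or 'gt'")
    return events, int(x.size)


def _stage_seed(master_seed: int, stage: str) -> int:
    key = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence(master_seed, spawn_key=(key,)).generate_state(1)[0])


def _summary_dict(s: SummaryStats) -> dict:
    return dataclasses.asdict(s)


def _fit_report_dict(report) -> dict:
    entries = {}
    for label, (params, tests) in report.entries.items():
        if isinstance(params, tuple):
            params_dict = {"mean": params[0], "sd": params[1]}
        else:
            params_dict = dataclasses.asdict(params)
        entries[label] = {
            "params": params_dict,
            "tests": [dataclasses.asdict(t) for t in tests],
        }
    return {"n": report.n, "entries": entries, "winner": report.winner}


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the full pipeline; see the module docstring for the stage order."""
    t0 = time.perf_counter()

    def log_stage(name: str) -> None:
        logger.info("stage %-12s elapsed %.2fs", name, time.perf_counter() - t0)

    if config.input_path is not None:
        cohort = read_cohort(config.input_path)
    else:
        cohort = generate_cohort(config.generator)
    log_stage("ingest")

    full_summary = summarize(cohort.times())
    scan_result = scan_thresholds(
        cohort, alpha_fit=config.alpha_fit, min_subset=config.min_subset
    )
    log_stage("scan")

    threshold = (
        config.threshold_override
        if config.threshold_override is not None
        else scan_result.selected_threshold
    )
    if threshold is None:
        raise RuntimeError(
            "stage filter: no experience threshold selected and no override given"
        )
    filtered = filter_by_experience(cohort, threshold)
    filtered_times = filtered.times()
    filtered_summary = summarize(filtered_times)
    log_stage("filter")

    fit_report = compare_distributions(filtered_times)
    log_stage("fit")

    summary = log_summary(filtered_times)
    exceedance_entries = []
    for tol in config.tolerances:
        gpq = gpq_exceedance_upper(
            summary,
            ExceedanceQuery(
                tolerance_L=tol,
                level=config.level,
                replications_R=config.replications_R,
                seed=_stage_seed(config.seed, f"gpq:{tol}"),
            ),
        )
        nct = exceedance_upper_noncentral_t(summary, tol, config.level)
        x_count, n_count = count_exceedances(
            filtered_times, tol, config.count_comparator
        )
        exceedance_entries.append(
            {
                "tolerance_L": tol,
                "level": config.level,
                "gpq": dataclasses.asdict(gpq),
                "noncentral_t": dataclasses.asdict(nct),
                "count_x": x_count,
                "count_n": n_count,
                "count_comparator": config.count_comparator,
                "clopper_pearson_upper": clopper_pearson_upper(
                    x_count, n_count, 1.0 - config.level
                ),
            }
        )
    log_stage("exceedance")

    times_all = cohort.times()
    associations = [
        {
            "statistic_name": "kendall_tau_b",
            "x": "eti_prior_year",
            "estimate": kendall_tau_b(cohort.eti_counts(), times_all),
            "p_value": None,
        },
        {
            "statistic_name": "kendall_tau_b",
            "x": "dlt_prior_year",
            "estimate": kendall_tau_b(cohort.dlt_counts(), times_all),
            "p_value": None,
        },
    ]
    perm = permutation_pvalue(
        cohort.eti_counts(),
        times_all,
        spearman_rho,
        M=config.permutations_M,
        seed=_stage_seed(config.seed, "permutation"),
        exact=False,
    )
    associations.append(
        {
            "statistic_name": "spearman_rho",
            "x": "eti_prior_year",
            "estimate": perm.estimate,
            "p_value": perm.p_value,
            "n_permutations_M": perm.n_permutations_M,
        }
    )
    log_stage("associate")

    config_dict = dataclasses.asdict(config)
    return AnalysisReport(
        config=config_dict,
        cohort_full={
            "n": len(cohort),
            "n_completed": len(cohort.completed_records),
            "provenance": cohort.provenance,
            "summary": _summary_dict(full_summary),
        },
        scan={
            "selected_threshold": scan_result.selected_threshold,
            "alpha_fit": scan_result.alpha_fit,
            "min_subset": scan_result.min_subset,
            "rows": [dataclasses.asdict(r) for r in scan_result.rows],
            "warnings": list(scan_result.warnings),
        },
        cohort_filtered={
            "n": len(filtered),
            "threshold": threshold,
            "summary": _summary_dict(filtered_summary),
        },
        fits=_fit_report_dict(fit_report),
        exceedance=exceedance_entries,
        associations=associations,
        versions={"proctol": __version__, "numpy": np.__version__},
        seed=config.seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
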