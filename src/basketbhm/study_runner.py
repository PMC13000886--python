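"""Orchestration of the simulation study and the two-subtrial case analysis.

``run_study`` loops over (scenario, total n, allocation) cells; within a
cell it generates one dataset per replicate and fits *every* requested
method to that same dataset.  Sharing data across methods is what makes
RMSE-reduction comparisons paired, so their MCSEs can include the
covariance of per-replicate squared errors.  Per-replicate seeds are
derived deterministically from the base seed and the cell labels, so
adding or removing methods never changes the simulated data.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bhm_core import (
    BhmSpec,
    EffectEstimate,
    FitError,
    McmcConfig,
    decide_rejection,
    fit_bhm,
    summarize_posterior,
)
from .freq_models import FreqSpec, fit_random_effects, fit_stratified
from .metrics import MetricReport, ReplicateResults, compute_metrics
from .trial_data import (
    BasketTrialData,
    MajicConfig,
    ScenarioConfig,
    center_covariates,
    generate_majic_like,
    generate_scenario,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "METHOD_ROSTER",
    "run_study",
    "run_cell",
    "run_case_study",
    "fit_method",
    "plot_metric_curves",
]

#: all twelve analysis methods: Bayesian hierarchical models at two
#: half-t scales, stratified AN(C)OVAs and random-effect AN(C)OVAs.
METHOD_ROSTER: Mapping[str, dict] = {
    "BHM": {"kind": "bhm", "data_model": "UNADJUSTED", "sigma_ht": 2.0},
    "adjBHM": {"kind": "bhm", "data_model": "ANCOVA1", "sigma_ht": 2.0},
    "intBHM": {"kind": "bhm", "data_model": "ANCOVA2", "sigma_ht": 2.0},
    "BHM2": {"kind": "bhm", "data_model": "UNADJUSTED", "sigma_ht": 100.0},
    "adjBHM2": {"kind": "bhm", "data_model": "ANCOVA1", "sigma_ht": 100.0},
    "intBHM2": {"kind": "bhm", "data_model": "ANCOVA2", "sigma_ht": 100.0},
    "sANOVA": {"kind": "stratified", "adjustment": "NONE"},
    "sANCOVAI": {"kind": "stratified", "adjustment": "ANCOVA1"},
    "sANCOVAII": {"kind": "stratified", "adjustment": "ANCOVA2"},
    "reANOVA": {"kind": "random_effect", "adjustment": "NONE"},
    "reANCOVAI": {"kind": "random_effect", "adjustment": "ANCOVA1"},
    "reANCOVAII": {"kind": "random_effect", "adjustment": "ANCOVA2"},
}


@dataclass(frozen=True)
class StudyConfig:
    """Grid, roster and replication control for a simulation study."""

    scenarios: tuple[str, ...] = ("S1",)
    n_grid: tuple[int, ...] = tuple(range(56, 561, 56))
    allocation_fractions: tuple[float, ...] = (0.5,)
    methods: tuple[str, ...] = ("BHM", "adjBHM", "intBHM")
    B: int = 1000
    base_seed: int = 0
    reference_method: str = "BHM"
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    out_dir: str | None = None

    def __post_init__(self):
        unknown = set(self.methods) - set(METHOD_ROSTER)
        if unknown:
            raise ValueError(f"unknown method labels: {sorted(unknown)}")
        if self.B < 1:
            raise ValueError("B must be >= 1")


def _key_hash(*parts) -> int:
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def replicate_seed_sequence(base_seed: int, cell_key: tuple, b: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed: hash(base, cell labels, replicate)."""
    return np.random.SeedSequence([base_seed, _key_hash(*cell_key), b])


def _method_seed(base_seed: int, cell_key: tuple, b: int, method: str) -> int:
    ss = np.random.SeedSequence([base_seed, _key_hash(*cell_key), b, _key_hash(method)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def fit_method(
    data_centered: BasketTrialData,
    method: str,
    mcmc: McmcConfig,
    level: float = 0.95,
) -> EffectEstimate:
    """Fit one roster method to (already cluster-centered) trial data."""
    info = METHOD_ROSTER[method]
    if info["kind"] == "bhm":
        spec = BhmSpec(data_model=info["data_model"], sigma_ht=info["sigma_ht"])
        draws = fit_bhm(data_centered, spec, mcmc)
        return summarize_posterior(draws, level=level, method_label=method)
    fspec = FreqSpec(
        family="STRATIFIED" if info["kind"] == "stratified" else "RANDOM_EFFECT",
        adjustment=info["adjustment"],
        level=level,
    )
    if info["kind"] == "stratified":
        return fit_stratified(data_centered, fspec)
    return fit_random_effects(data_centered, fspec)


def run_cell(
    scenario: str,
    total_n: int,
    allocation: float,
    methods: Sequence[str],
    B: int,
    base_seed: int,
    mcmc: McmcConfig,
    reference_method: str = "BHM",
    theta_true: tuple[float, ...] | None = None,
) -> dict[str, MetricReport]:
    """Run all methods over B paired replicates of one study cell."""
    cell_key = (scenario, total_n, allocation)
    K = len(theta_true) if theta_true is not None else 4
    estimates = {m: np.full((B, K), np.nan) for m in methods}
    rejections = {m: np.zeros((B, K), dtype=bool) for m in methods}
    converged = {m: np.ones(B, dtype=bool) for m in methods}
    seeds = np.empty(B, dtype=np.int64)

    theta = None
    for b in range(B):
        ss = replicate_seed_sequence(base_seed, cell_key, b)
        seeds[b] = b
        cfg = ScenarioConfig(
            scenario_id=scenario,
            total_n=total_n,
            allocation_fraction=allocation,
            theta_true=theta_true,
            seed=ss,
        )
        theta = np.asarray(cfg.theta_true)
        data = center_covariates(generate_scenario(cfg))
        for m in methods:
            mseed = _method_seed(base_seed, cell_key, b, m)
            try:
                est = fit_method(data, m, McmcConfig(
                    n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, seed=mseed, thin=mcmc.thin
                ))
            except FitError as exc:  # unrecoverable for this replicate
                logger.warning("replicate %d seed %s method %s failed: %s", b, cell_key, m, exc)
                converged[m][b] = False
                continue
            if not est.converged:
                converged[m][b] = False
                continue
            estimates[m][b] = est.estimate
            rejections[m][b] = decide_rejection(est)

    results = {
        m: ReplicateResults(
            method=m,
            estimates=estimates[m],
            rejections=rejections[m],
            theta_true=theta,
            converged=converged[m],
            seeds=seeds,
        )
        for m in methods
    }
    reports = {}
    ref = results.get(reference_method)
    for m in methods:
        reports[m] = compute_metrics(results[m], None if ref is None or m == reference_method else ref)
    return reports


def run_study(config: StudyConfig) -> dict[tuple, dict[str, MetricReport]]:
    """Run the full (scenario x n x allocation) grid.

    Returns ``{(scenario, n, allocation): {method: MetricReport}}`` and,
    when ``config.out_dir`` is set, writes one tidy CSV per cell plus a
    combined ``study_results.csv``.
    """
    all_reports: dict[tuple, dict[str, MetricReport]] = {}
    tidy_frames = []
    for scenario in config.scenarios:
        for total_n in config.n_grid:
            for alloc in config.allocation_fractions:
                logger.info("cell scenario=%s n=%d allocation=%s", scenario, total_n, alloc)
                reports = run_cell(
                    scenario, total_n, alloc, config.methods, config.B,
                    config.base_seed, config.mcmc, config.reference_method,
                )
                all_reports[(scenario, total_n, alloc)] = reports
                for m, rep in reports.items():
                    tidy = rep.to_tidy()
                    tidy.insert(0, "scenario", scenario)
                    tidy.insert(1, "total_n", total_n)
                    tidy.insert(2, "allocation", alloc)
                    tidy_frames.append(tidy)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.concat(tidy_frames, ignore_index=True).to_csv(out / "study_results.csv", index=False)
    return all_reports


def run_case_study(
    config: MajicConfig,
    methods: Sequence[str] = ("BHM", "adjBHM", "intBHM"),
    mcmc: McmcConfig | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Fit the hierarchical models to one generated two-subtrial dataset.

    Returns a table with one row per (subtrial, method): point estimate
    (posterior mean), SE (posterior SD), credible interval, convergence
    flag, and the percent SE reduction relative to the unadjusted model.
    """
    mcmc = mcmc or McmcConfig()
    data = center_covariates(generate_majic_like(config))
    rows = []
    base_se = None
    ests: dict[str, EffectEstimate] = {}
    for m in methods:
        info = METHOD_ROSTER[m]
        if info["kind"] != "bhm":
            raise ValueError("the case study compares the hierarchical models only")
        spec = BhmSpec(
            data_model=info["data_model"],
            sigma_ht=info["sigma_ht"],
            outcome_model="logistic" if config.outcome_type == "binary" else "normal",
        )
        base = config.seed if isinstance(config.seed, int) else 0
        mseed = _method_seed(base, ("case",), 0, m)
        draws = fit_bhm(data, spec, McmcConfig(mcmc.n_iter, mcmc.burn_in, mseed, mcmc.thin))
        ests[m] = summarize_posterior(draws, level=level, method_label=m)
    if "BHM" in ests:
        base_se = ests["BHM"].se
    for m in methods:
        e = ests[m]
        for k in range(e.K):
            se_red = np.nan
            if base_se is not None:
                se_red = (1.0 - e.se[k] / base_se[k]) * 100.0
            rows.append(
                {
                    "subtrial": k + 1,
                    "method": m,
                    "estimate": e.estimate[k],
                    "se": e.se[k],
                    "lower": e.lower[k],
                    "upper": e.upper[k],
                    "se_reduction_pct": se_red,
                    "converged": e.converged,
                }
            )
    return pd.DataFrame(rows)


def plot_metric_curves(
    tidy: pd.DataFrame,
    metric: str,
    out_path: str | Path,
    *,
    scenario: str | None = None,
    allocation: float | None = None,
):
    """Plot a metric against total sample size, one line per method.

    For the trial-level rates the nominal 9.75% family-wise error level
    and the 80% power level are drawn as reference lines.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = tidy[tidy["metric"] == metric].copy()
    if scenario is not None:
        df = df[df["scenario"] == scenario]
    if allocation is not None:
        df = df[df["allocation"] == allocation]
    subtrials = sorted(df["subtrial"].unique())
    fig, axes = plt.subplots(
        1, len(subtrials), figsize=(4 * len(subtrials), 3.2), squeeze=False, sharey=True
    )
    for ax, k in zip(axes[0], subtrials):
        sub = df[df["subtrial"] == k]
        for m, g in sub.groupby("method"):
            g = g.sort_values("total_n")
            ax.plot(g["total_n"], g["estimate"], marker="o", ms=3, label=m)
        if metric == "fwer":
            ax.axhline(0.0975, ls="--", c="gray")
        if metric == "disjunctive_power":
            ax.axhline(0.80, ls="--", c="gray")
        ax.set_xlabel("total sample size")
        ax.set_title(f"subtrial {k}" if k else "trial-level")
    axes[0][0].set_ylabel(metric)
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
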