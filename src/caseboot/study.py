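"""Monte-Carlo study runner: repeated cohort generation, case-cohort
sampling, model fitting and variance estimation, aggregated into a
simulation-table summary (means, empirical SEs, mean estimated SEs and
Wald-interval coverage per variance estimator).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .casecohort import MODEL_COVARIATES, draw_case_cohort_sample
from .core_model import fit_logistic
from .errors import (
    NonConvergenceError,
    RankDeficiencyError,
    ReliabilityError,
    SchemaError,
    SingularityError,
)
from .resampling import naive_bootstrap, proposed_bootstrap, stratified_bootstrap
from .simulator import SimulationParams, generate_cohort

__all__ = [
    "StudyConfig",
    "StudySummary",
    "ReplicateRecord",
    "run_replicate",
    "run_study",
    "summarize_table",
    "render_table",
]

log = logging.getLogger("caseboot")

_BOOT_FNS = {
    "proposed": proposed_bootstrap,
    "naive": naive_bootstrap,
    "stratified": stratified_bootstrap,
}

#: Table row labels, in presentation order, per coefficient block.
_ROW_ORDER = (
    "Mean",
    "SE",
    "SE_robust",
    "SE_boot_naive",
    "SE_boot_proposed",
    "CP_robust",
    "CP_boot_naive",
    "CP_boot_proposed",
)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one simulation scenario.

    ``schemes`` lists the variance estimators to evaluate; ``"robust"`` is
    always computed from the primary fit, the bootstrap schemes each add a
    full resampling loop of ``bootstrap_replicates`` fits per replicate.
    """

    params: SimulationParams = field(default_factory=SimulationParams)
    n_replicates: int = 1000
    bootstrap_replicates: int = 200
    schemes: tuple[str, ...] = ("robust",)
    level: float = 0.95
    seed: int = 0
    workers: int = 1

    def __post_init__(self):
        if self.n_replicates < 2 or self.bootstrap_replicates < 2:
            raise ValueError("n_replicates and bootstrap_replicates must be >= 2")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        bad = [s for s in self.schemes if s not in ("robust",) + tuple(_BOOT_FNS)]
        if bad:
            raise ValueError(f"unknown variance schemes: {bad}")


@dataclass(frozen=True)
class ReplicateRecord:
    """Everything one simulation replicate contributes to the aggregate."""

    estimate: np.ndarray          # full coefficient vector, intercept first
    se: dict                      # scheme -> per-coefficient SE vector
    covers: dict                  # scheme -> per-slope 0/1 coverage indicators
    m: int
    boot_failures: dict           # scheme -> dropped bootstrap replicates


@dataclass(frozen=True)
class StudySummary:
    """Aggregate over converged replicates, one row block per slope."""

    table: pd.DataFrame           # index: covariate; columns: statistics
    mean_duplicates: float
    n_replicates: int
    n_failed: int
    coefficients: tuple[str, ...]
    config: StudyConfig | None = None


def _true_slopes(params: SimulationParams) -> np.ndarray:
    return np.array([params.beta1, params.beta2, params.beta3])


def run_replicate(
    params: SimulationParams,
    bootstrap_replicates: int,
    level: float,
    seed,
    schemes: tuple[str, ...] = ("robust",),
) -> ReplicateRecord:
    """One full pipeline pass: generate, sample, fit, estimate variances.

    Coverage indicators compare the Wald interval from each requested
    variance estimator against the true simulation slopes.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cohort, s_sample, s_prop, s_naive, s_strat = ss.spawn(5)
    boot_seeds = {"proposed": s_prop, "naive": s_naive, "stratified": s_strat}
    cohort = generate_cohort(params, s_cohort)
    sample = draw_case_cohort_sample(
        cohort,
        params.subcohort_fraction,
        params.case_fraction,
        rng_seed=s_sample,
    )
    fit = fit_logistic(sample.pseudo)
    z = norm.ppf(0.5 * (1.0 + level))
    truth = _true_slopes(params)
    ses, covers, boot_failures = {}, {}, {}

    def record(scheme, se_vec):
        ses[scheme] = se_vec
        slopes = fit.beta[1:]
        half = z * se_vec[1:]
        covers[scheme] = (
            (slopes - half <= truth) & (truth <= slopes + half)
        ).astype(int)

    for scheme in schemes:
        if scheme == "robust":
            record("robust", np.sqrt(np.diag(fit.robust_cov)))
        else:
            res = _BOOT_FNS[scheme](
                sample, bootstrap_replicates, rng_seed=boot_seeds[scheme]
            )
            record(scheme, res.se)
            boot_failures[scheme] = res.n_failed
    return ReplicateRecord(
        estimate=fit.beta,
        se=ses,
        covers=covers,
        m=sample.m,
        boot_failures=boot_failures,
    )


def _aggregate(records, config: StudyConfig, n_failed: int) -> StudySummary:
    coef_names = MODEL_COVARIATES
    est = np.array([r.estimate[1:] for r in records])  # slopes only
    data = {
        "mean": est.mean(axis=0),
        "empirical_se": est.std(axis=0, ddof=1),
    }
    for scheme in config.schemes:
        se = np.array([r.se[scheme][1:] for r in records])
        cov = np.array([r.covers[scheme] for r in records])
        data[f"mean_se_{scheme}"] = se.mean(axis=0)
        data[f"cp_{scheme}"] = cov.mean(axis=0)
    table = pd.DataFrame(data, index=pd.Index(coef_names, name="covariate"))
    return StudySummary(
        table=table,
        mean_duplicates=float(np.mean([r.m for r in records])),
        n_replicates=len(records),
        n_failed=n_failed,
        coefficients=coef_names,
        config=config,
    )


def run_study(config: StudyConfig) -> StudySummary:
    """Run ``config.n_replicates`` independent replicates and aggregate.

    Per-replicate seeds are spawned from the root seed, so results are
    reproducible and independent of the worker count; failed primary fits
    are excluded from every aggregate symmetrically and counted.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)

    def one(child):
        try:
            return run_replicate(
                config.params,
                config.bootstrap_replicates,
                config.level,
                child,
                config.schemes,
            )
        except (
            NonConvergenceError,
            SingularityError,
            RankDeficiencyError,
            ReliabilityError,
        ) as exc:
            log.debug("replicate failed: %s", exc)
            return None

    if config.workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=config.workers)(delayed(one)(c) for c in children)
    else:
        results = [one(c) for c in children]
    records = [r for r in results if r is not None]
    n_failed = config.n_replicates - len(records)
    frac = n_failed / config.n_replicates
    if frac > 0.10:
        raise NonConvergenceError(
            f"{n_failed}/{config.n_replicates} replicates failed; "
            "results would be unreliable"
        )
    if frac > 0.01:
        warnings.warn(
            f"{n_failed}/{config.n_replicates} replicates failed and were excluded",
            stacklevel=2,
        )
    return _aggregate(records, config, n_failed)


_STAT_TO_COLUMN = {
    "Mean": "mean",
    "SE": "empirical_se",
    "SE_robust": "mean_se_robust",
    "SE_boot_naive": "mean_se_naive",
    "SE_boot_proposed": "mean_se_proposed",
    "CP_robust": "cp_robust",
    "CP_boot_naive": "cp_naive",
    "CP_boot_proposed": "cp_proposed",
}


def summarize_table(summaries, scenario_labels=None) -> pd.DataFrame:
    """Arrange one or more study summaries as a simulation table.

    Scenarios are columns; rows are "Mean duplicated samples" followed by
    one block per coefficient in the order Mean, SE, SE_robust,
    SE_boot_naive, SE_boot_proposed, CP_robust, CP_boot_naive,
    CP_boot_proposed (rows for schemes that were not run are omitted).
    Values are rounded to 3 decimals.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("need at least one summary")
    if scenario_labels is None:
        scenario_labels = [f"scenario_{i + 1}" for i in range(len(summaries))]
    if len(scenario_labels) != len(summaries):
        raise ValueError("one label per summary required")
    coefs = summaries[0].coefficients
    for s in summaries[1:]:
        if s.coefficients != coefs:
            raise SchemaError("summaries have inconsistent coefficient sets")
    available = [
        stat
        for stat in _ROW_ORDER
        if all(_STAT_TO_COLUMN[stat] in s.table.columns for s in summaries)
    ]
    rows = [("Mean duplicated samples", "")]
    rows += [(c, stat) for c in coefs for stat in available]
    out = {}
    for label, s in zip(scenario_labels, summaries):
        col = [round(s.mean_duplicates, 3)]
        for c in coefs:
            for stat in available:
                col.append(round(float(s.table.loc[c, _STAT_TO_COLUMN[stat]]), 3))
        out[label] = col
    index = pd.MultiIndex.from_tuples(rows, names=["coefficient", "statistic"])
    return pd.DataFrame(out, index=index)


def render_table(table: pd.DataFrame) -> str:
    """Aligned-text rendering of a summarize_table frame."""
    return table.to_string(float_format=lambda v: f"{v:.3f}")
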