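"""Bootstrap variance estimation for case-cohort pseudo-likelihood fits.

Three resampling schemes for a drawn case-cohort sample with n1 case rows,
n0 subcohort rows and m participants duplicated between the two:

``proposed``
    The duplication-aware scheme: resample n1 cases with replacement;
    resample n0 - m of the non-case subcohort members with replacement;
    then pick m of the n1 bootstrap case draws (without replacement) and
    add them to the subcohort block — every bootstrap sample reproduces
    the overlap structure of the design.

``naive``
    Ordinary case-control bootstrap: resample the n1 cases and the full
    n0-member subcohort independently, ignoring duplication.  Its SEs
    track the robust sandwich estimator, bias included.

``stratified``
    Asymptotically equivalent alternative to ``proposed``: resample
    separately within the n1 - m unduplicated cases, the n0 - m non-case
    subcohort members, and the m duplicated participants (each duplicated
    draw contributes one D=1 and one D=0 row).

Every replicate preserves n1 and n0 exactly, m is held fixed at its
observed value, and each replicate draws from an independent child stream
of the root seed, so enlarging B never perturbs earlier replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .casecohort import CaseCohortSample
from .core_model import wald_interval
from .errors import (
    DegenerateDataError,
    NonConvergenceError,
    RankDeficiencyError,
    ReliabilityError,
    SingularityError,
)
from . import core_model

__all__ = [
    "BootstrapResult",
    "proposed_bootstrap",
    "naive_bootstrap",
    "stratified_bootstrap",
    "bootstrap_interval",
    "SCHEMES",
]

SCHEMES = ("proposed", "naive", "stratified")


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate coefficients and the derived bootstrap SEs for one scheme."""

    scheme: str
    replicates: np.ndarray  # (B_eff, p+1) converged replicate coefficients
    n_requested: int
    seed: object
    columns: tuple[str, ...] = ()

    @property
    def n_effective(self) -> int:
        return self.replicates.shape[0]

    @property
    def n_failed(self) -> int:
        return self.n_requested - self.n_effective

    @property
    def se(self) -> np.ndarray:
        """Per-coefficient bootstrap SE: sample SD over replicates (ddof=1)."""
        if self.n_effective < 2:
            raise ValueError("need at least two effective replicates for an SE")
        return self.replicates.std(axis=0, ddof=1)


class _Pools:
    """Row pools shared by all schemes, precomputed once per sample."""

    def __init__(self, sample: CaseCohortSample):
        ps = sample.pseudo
        n1, n0, m = sample.n1, sample.n0, sample.m
        if ps.ids is None:
            raise ValueError("bootstrap requires participant ids on the pseudo data")
        self.n1, self.n0, self.m = n1, n0, m
        # assembly convention: case rows first, subcohort rows after
        self.case_X = ps.X[:n1]
        self.sub_X = ps.X[n1:]
        sub_ids = ps.ids[n1:]
        case_ids = ps.ids[:n1]
        dup = np.isin(sub_ids, sample.duplicated_ids)
        self.noncase_X = self.sub_X[~dup]
        dup_case = np.isin(case_ids, sample.duplicated_ids)
        self.undup_case_X = self.case_X[~dup_case]
        self.dup_X = self.case_X[dup_case]
        self.d = np.concatenate([np.ones(n1), np.zeros(n0)])


def _draw_replicate(scheme: str, pools: _Pools, rng: np.random.Generator) -> np.ndarray:
    """One bootstrap design matrix; D is the constant [1]*n1 + [0]*n0.

    All schemes draw case-block indices first, then subcohort-block
    indices, then any duplication-related draws, so that at m = 0 the
    three schemes consume the stream identically and coincide row for row.
    """
    n1, n0, m = pools.n1, pools.n0, pools.m
    if scheme == "proposed":
        i1 = rng.integers(0, n1, size=n1)
        case_block = pools.case_X[i1]
        i0 = rng.integers(0, n0 - m, size=n0 - m)
        parts = [case_block, pools.noncase_X[i0]]
        if m:
            sel = rng.choice(n1, size=m, replace=False)
            parts.append(case_block[sel])
        return np.vstack(parts)
    if scheme == "naive":
        i1 = rng.integers(0, n1, size=n1)
        i0 = rng.integers(0, n0, size=n0)
        return np.vstack([pools.case_X[i1], pools.sub_X[i0]])
    if scheme == "stratified":
        i1 = rng.integers(0, n1 - m, size=n1 - m) if n1 > m else np.empty(0, int)
        i0 = rng.integers(0, n0 - m, size=n0 - m) if n0 > m else np.empty(0, int)
        if m:
            idup = rng.integers(0, m, size=m)
            dup_rows = pools.dup_X[idup]
            return np.vstack(
                [pools.undup_case_X[i1], dup_rows, pools.noncase_X[i0], dup_rows]
            )
        return np.vstack([pools.undup_case_X[i1], pools.noncase_X[i0]])
    raise ValueError(f"unknown scheme {scheme!r}")


def _run_bootstrap(
    sample: CaseCohortSample,
    n_replicates: int,
    rng_seed,
    scheme: str,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> BootstrapResult:
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    pools = _Pools(sample)
    if scheme in ("proposed", "stratified") and pools.m == pools.n0:
        raise DegenerateDataError(
            "every subcohort member is a duplicated case (m = n0); the "
            "duplication-aware schemes need at least one non-case subcohort member"
        )
    seed_seq = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    children = seed_seq.spawn(n_replicates)
    d = pools.d
    kept = []
    for child in children:
        rng = np.random.default_rng(child)
        Xb = _draw_replicate(scheme, pools, rng)
        try:
            beta, _, _, _ = core_model._irls(Xb, d, tol, max_iter)
        except (NonConvergenceError, SingularityError, RankDeficiencyError):
            continue
        kept.append(beta)
    n_eff = len(kept)
    floor = max(min(30, n_replicates), math.ceil(0.5 * n_replicates))
    if n_eff < floor:
        raise ReliabilityError(
            f"only {n_eff}/{n_replicates} bootstrap replicates converged "
            f"(minimum {floor}); the bootstrap SE would be unreliable"
        )
    return BootstrapResult(
        scheme=scheme,
        replicates=np.array(kept),
        n_requested=n_replicates,
        seed=rng_seed,
        columns=tuple(sample.pseudo.columns),
    )


def proposed_bootstrap(
    sample: CaseCohortSample, n_replicates: int = 2000, rng_seed=0, **fit_kwargs
) -> BootstrapResult:
    """Duplication-aware bootstrap (the recommended variance estimator)."""
    return _run_bootstrap(sample, n_replicates, rng_seed, "proposed", **fit_kwargs)


def naive_bootstrap(
    sample: CaseCohortSample, n_replicates: int = 2000, rng_seed=0, **fit_kwargs
) -> BootstrapResult:
    """Case-control bootstrap that ignores duplication (for comparison)."""
    return _run_bootstrap(sample, n_replicates, rng_seed, "naive", **fit_kwargs)


def stratified_bootstrap(
    sample: CaseCohortSample, n_replicates: int = 2000, rng_seed=0, **fit_kwargs
) -> BootstrapResult:
    """Three-stratum resampling, asymptotically equivalent to ``proposed``."""
    return _run_bootstrap(sample, n_replicates, rng_seed, "stratified", **fit_kwargs)


def bootstrap_interval(
    result: BootstrapResult, point_estimate: np.ndarray, level: float = 0.95
) -> np.ndarray:
    """Wald intervals ``estimate ± z · SE_boot``, one row per coefficient.

    A degenerate (zero) bootstrap SE yields a zero-width interval with a
    warning rather than an error, since it can legitimately arise from
    identical replicates at tiny B.
    """
    point = np.asarray(point_estimate, dtype=float)
    se = result.se
    if point.shape != se.shape:
        raise ValueError("point_estimate length must match the coefficient count")
    out = np.empty((point.size, 2))
    for j, (b, s) in enumerate(zip(point, se)):
        if s == 0.0:
            warnings.warn(
                f"degenerate bootstrap SE for coefficient {j}; zero-width interval",
                stacklevel=2,
            )
            out[j] = (b, b)
        else:
            out[j] = wald_interval(b, s, level)
    return out
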