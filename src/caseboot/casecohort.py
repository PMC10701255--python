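"""Case-cohort sample construction and pseudo-dataset assembly.

A case-cohort study measures the expensive covariate on (i) all — or a
random fraction of — the cases of a cohort and (ii) a simple random
subcohort drawn from the entire cohort regardless of outcome.  Because the
subcohort is drawn from everyone, some cases appear in both sets; the
pseudo-likelihood analysis stacks them as two distinct rows.  This module
draws such samples from a simulated cohort, builds them from user tables,
and detects the duplication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import PseudoDataset
from .errors import (
    DataIntegrityError,
    DegenerateDataError,
    MissingDataError,
    SchemaError,
)

__all__ = [
    "CohortData",
    "CaseCohortSample",
    "draw_case_cohort_sample",
    "assemble_pseudo_dataset",
    "detect_duplication",
    "sample_from_tables",
]

#: covariates entering the fitted model, in design-matrix order
MODEL_COVARIATES = ("z", "x2", "x3")


@dataclass(frozen=True)
class CohortData:
    """A full cohort: outcome, expensive covariate, dummies, auxiliaries.

    Fields are parallel arrays over participants: unique ``ids``, binary
    outcome ``y``, binary expensive covariate ``z``, trinomial-category
    dummies ``x2``/``x3`` (at most one of them 1), and the auxiliaries
    ``r1`` (binary) and ``r2`` (real) that drive ``z`` in the simulator.
    """

    ids: np.ndarray
    y: np.ndarray
    z: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    r1: np.ndarray
    r2: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        for name in ("y", "z", "x2", "x3", "r1", "r2"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"column {name!r} must have length {n}")
            object.__setattr__(self, name, arr)
        if np.unique(np.asarray(self.ids)).size != n:
            raise DataIntegrityError("cohort ids must be unique")
        for name in ("y", "z", "x2", "x3", "r1"):
            if not np.isin(getattr(self, name), (0, 1)).all():
                raise ValueError(f"column {name!r} must be binary")
        if (self.x2 * self.x3).any():
            raise ValueError("x2 and x3 are exclusive dummies (x2*x3 must be 0)")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.y))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "y": self.y.astype(int),
                "z": self.z.astype(int),
                "x2": self.x2.astype(int),
                "x3": self.x3.astype(int),
                "r1": self.r1.astype(int),
                "r2": self.r2,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortData":
        required = ("id", "y", "z", "x2", "x3", "r1", "r2")
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(f"cohort table is missing columns: {missing}")
        return cls(
            ids=frame["id"].to_numpy(),
            y=frame["y"].to_numpy(),
            z=frame["z"].to_numpy(),
            x2=frame["x2"].to_numpy(),
            x3=frame["x3"].to_numpy(),
            r1=frame["r1"].to_numpy(),
            r2=frame["r2"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class CaseCohortSample:
    """A drawn case-cohort design: case set, subcohort, overlap, pseudo data.

    The pseudo dataset is ordered with the ``n1`` case rows (D=1) first,
    followed by the ``n0`` subcohort rows (D=0); each of the ``m``
    duplicated participants contributes one row to each block.
    """

    case_ids: np.ndarray
    subcohort_ids: np.ndarray
    duplicated_ids: np.ndarray
    pseudo: PseudoDataset
    provenance: dict = field(default_factory=dict)

    @property
    def n1(self) -> int:
        return len(self.case_ids)

    @property
    def n0(self) -> int:
        return len(self.subcohort_ids)

    @property
    def m(self) -> int:
        return len(self.duplicated_ids)


def detect_duplication(
    cases: pd.DataFrame, subcohort: pd.DataFrame, id_column: str = "id"
):
    """Count participants present in both the case and subcohort tables.

    Returns ``(m, duplicated_id_set)``.  IDs must be unique within each
    table; a within-table duplicate is a data-integrity error, not design
    duplication.
    """
    for name, table in (("cases", cases), ("subcohort", subcohort)):
        if id_column not in table.columns:
            raise SchemaError(f"{name} table has no {id_column!r} column")
        dup = table[id_column][table[id_column].duplicated()]
        if not dup.empty:
            raise DataIntegrityError(
                f"duplicate ids within the {name} table: {sorted(set(dup))[:5]}"
            )
    shared = set(cases[id_column]) & set(subcohort[id_column])
    return len(shared), shared


def _assemble_arrays(
    case_X: np.ndarray,
    subcohort_X: np.ndarray,
    case_ids: np.ndarray,
    subcohort_ids: np.ndarray,
    columns: tuple[str, ...],
) -> PseudoDataset:
    """Fast assembly path used by the simulation pipeline (arrays in, no
    per-row validation beyond the PseudoDataset invariants)."""
    n1, n0 = case_X.shape[0], subcohort_X.shape[0]
    X = np.vstack([case_X, subcohort_X])
    d = np.concatenate([np.ones(n1), np.zeros(n0)])
    ids = np.concatenate([case_ids, subcohort_ids])
    return PseudoDataset(X=X, d=d, ids=ids, columns=columns)


def assemble_pseudo_dataset(
    cases: pd.DataFrame,
    subcohort: pd.DataFrame,
    covariates=MODEL_COVARIATES,
    id_column: str = "id",
) -> PseudoDataset:
    """Stack case rows (D=1) above subcohort rows (D=0), intercept first.

    Raises a schema error for missing covariate columns and a missing-data
    error for any NA covariate cell; no imputation is attempted.
    """
    covariates = tuple(covariates)
    if len(cases) == 0:
        raise DegenerateDataError("case set is empty")
    if len(subcohort) == 0:
        raise DegenerateDataError("subcohort set is empty")
    for name, table in (("cases", cases), ("subcohort", subcohort)):
        missing = [c for c in covariates if c not in table.columns]
        if missing:
            raise SchemaError(f"{name} table is missing covariates: {missing}")
        if id_column not in table.columns:
            raise SchemaError(f"{name} table has no {id_column!r} column")
        block = table.loc[:, list(covariates)]
        if block.isna().any().any():
            bad = block.columns[block.isna().any()].tolist()
            raise MissingDataError(
                f"missing values in {name} covariates {bad}; no imputation"
            )
    def block(table):
        mat = table.loc[:, list(covariates)].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(table)), mat])

    return _assemble_arrays(
        block(cases),
        block(subcohort),
        cases[id_column].to_numpy(),
        subcohort[id_column].to_numpy(),
        ("intercept",) + covariates,
    )


def sample_from_tables(
    cases: pd.DataFrame,
    subcohort: pd.DataFrame,
    covariates=MODEL_COVARIATES,
    id_column: str = "id",
    provenance: dict | None = None,
) -> CaseCohortSample:
    """Build a CaseCohortSample from user-supplied case/subcohort tables."""
    m, shared = detect_duplication(cases, subcohort, id_column)
    pseudo = assemble_pseudo_dataset(cases, subcohort, covariates, id_column)
    return CaseCohortSample(
        case_ids=cases[id_column].to_numpy(),
        subcohort_ids=subcohort[id_column].to_numpy(),
        duplicated_ids=np.array(sorted(shared)),
        pseudo=pseudo,
        provenance=provenance or {},
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def draw_case_cohort_sample(
    cohort: CohortData,
    subcohort_fraction: float,
    case_fraction: float = 1.0,
    rng_seed=0,
    covariates=MODEL_COVARIATES,
) -> CaseCohortSample:
    """Draw a case-cohort sample from a cohort.

    The case samples are a simple random sample (without replacement) of
    ``round(case_fraction · #cases)`` cases; the subcohort is a simple
    random sample of ``round(subcohort_fraction · N)`` participants from
    the *entire* cohort, cases included — overlap between the two sets is
    the duplication the design induces.

    Parameters
    ----------
    cohort
        The full cohort.
    subcohort_fraction, case_fraction
        Sampling fractions in (0, 1]; sizes are rounded half-up.
    rng_seed
        Integer seed or ``numpy.random.SeedSequence``.
    """
    if not 0.0 < subcohort_fraction <= 1.0:
        raise ValueError("subcohort_fraction must be in (0, 1]")
    if not 0.0 < case_fraction <= 1.0:
        raise ValueError("case_fraction must be in (0, 1]")
    n = cohort.n
    case_idx = np.flatnonzero(cohort.y == 1)
    if case_idx.size == 0 or case_idx.size == n:
        raise DegenerateDataError(
            "cohort must contain at least one case and one non-case"
        )
    n0 = _round_half_up(subcohort_fraction * n)
    n1 = _round_half_up(case_fraction * case_idx.size)
    if n0 == 0:
        raise DegenerateDataError("subcohort_fraction rounds to an empty subcohort")
    if n1 == 0:
        raise DegenerateDataError("case_fraction rounds to an empty case set")
    rng = np.random.default_rng(rng_seed)
    sampled_cases = np.sort(rng.choice(case_idx, size=n1, replace=False))
    subcohort = np.sort(rng.choice(n, size=n0, replace=False))

    covmat = np.column_stack(
        [np.ones(n)] + [np.asarray(getattr(cohort, c), dtype=float) for c in covariates]
    )
    ids = np.asarray(cohort.ids)
    pseudo = _assemble_arrays(
        covmat[sampled_cases],
        covmat[subcohort],
        ids[sampled_cases],
        ids[subcohort],
        ("intercept",) + tuple(covariates),
    )
    dup = np.intersect1d(ids[sampled_cases], ids[subcohort])
    return CaseCohortSample(
        case_ids=ids[sampled_cases],
        subcohort_ids=ids[subcohort],
        duplicated_ids=dup,
        pseudo=pseudo,
        provenance={
            "rng_seed": rng_seed,
            "subcohort_fraction": subcohort_fraction,
            "case_fraction": case_fraction,
            "cohort_size": n,
        },
    )
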