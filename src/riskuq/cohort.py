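"""Cohort container and delimited-file I/O.

A cohort is one row per individual: numeric predictor values, a binary
outcome (0/1), and optionally a categorical subgroup label used for
fairness comparisons. Missing values are rejected, not imputed: rows
containing them are dropped at load time and the count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

logger = logging.getLogger(__name__)


@dataclass
class CohortData:
    """Predictor matrix, binary outcomes, and optional subgroup labels.

    Parameters
    ----------
    X : (n, p) float array
        Predictor values, one column per predictor.
    y : (n,) int array
        Binary outcomes, each 0 or 1.
    predictor_names : sequence of str
        Unique column labels for ``X``.
    ids : sequence, optional
        Opaque row identifiers; defaults to ``0..n-1`` as strings.
    subgroup : sequence of str, optional
        Categorical label per row.
    n_dropped : int
        Rows removed (because of missing values) when the cohort was read
        from a file; informational only.
    """

    X: np.ndarray
    y: np.ndarray
    predictor_names: Sequence[str]
    ids: Optional[Sequence] = None
    subgroup: Optional[np.ndarray] = None
    n_dropped: int = field(default=0, compare=False)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InputError("X must be a 2-D matrix")
        n, p = self.X.shape
        if n < 1 or p < 1:
            raise InputError("cohort needs at least one row and one predictor")
        y = np.asarray(self.y)
        bad = ~np.isin(y, (0, 1))
        if bad.any():
            offending = sorted(set(np.asarray(y)[bad].tolist()))
            raise InputError(
                f"outcome must be binary 0/1; found offending values {offending}")
        self.y = y.astype(np.int64)
        if len(self.y) != n:
            raise InputError("X and y have different lengths")
        if not np.all(np.isfinite(self.X)):
            raise InputError("missing or non-finite predictor values are rejected")
        names = list(self.predictor_names)
        if len(names) != p:
            raise InputError(f"{len(names)} predictor names for {p} columns")
        if len(set(names)) != len(names):
            raise InputError("predictor_names must be unique")
        self.predictor_names = names
        if self.ids is None:
            self.ids = np.array([str(i) for i in range(n)])
        else:
            self.ids = np.asarray(self.ids)
            if len(self.ids) != n:
                raise InputError("ids length mismatch")
        if self.subgroup is not None:
            self.subgroup = np.asarray(self.subgroup)
            if len(self.subgroup) != n:
                raise InputError("subgroup length mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.y.sum())

    def to_frame(self, outcome_column: str = "outcome",
                 subgroup_column: str = "subgroup") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.predictor_names)
        df.insert(0, "id", np.asarray(self.ids))
        df[outcome_column] = self.y
        if self.subgroup is not None:
            df[subgroup_column] = self.subgroup
        return df


def load_cohort(path, outcome_column: str = "outcome",
                subgroup_column: Optional[str] = None,
                id_column: Optional[str] = None,
                delimiter: str = ",") -> CohortData:
    """Read a delimited cohort file (header row required).

    Rows with any missing value are dropped and the count logged; an outcome
    value outside {0, 1} is an error naming the offending values.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise InputError(f"empty cohort file: {path}") from None
    if df.shape[0] == 0:
        raise InputError(f"cohort file has no data rows: {path}")
    if outcome_column not in df.columns:
        raise InputError(f"outcome column {outcome_column!r} not found in {path}")

    n_raw = len(df)
    df = df.dropna()
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.warning("dropped %d of %d rows with missing values from %s",
                       n_dropped, n_raw, path)
    if len(df) == 0:
        raise InputError("all rows contained missing values")

    y_raw = df[outcome_column].to_numpy()
    bad = ~np.isin(y_raw, (0, 1))
    if bad.any():
        offending = sorted(set(np.asarray(y_raw)[bad].tolist()))
        raise InputError(
            f"outcome column {outcome_column!r} must be 0/1; "
            f"found offending values {offending}")

    special = {outcome_column}
    ids = None
    if id_column is not None:
        if id_column not in df.columns:
            raise InputError(f"id column {id_column!r} not found")
        ids = df[id_column].astype(str).to_numpy()
        special.add(id_column)
    subgroup = None
    if subgroup_column is not None:
        if subgroup_column not in df.columns:
            raise InputError(f"subgroup column {subgroup_column!r} not found")
        subgroup = df[subgroup_column].astype(str).to_numpy()
        special.add(subgroup_column)

    predictor_names = [c for c in df.columns if c not in special]
    if not predictor_names:
        raise InputError("no predictor columns left after removing "
                         "outcome/id/subgroup columns")
    try:
        X = df[predictor_names].to_numpy(dtype=float)
    except ValueError as e:
        raise InputError(f"non-numeric predictor values: {e}") from None

    return CohortData(X=X, y=y_raw.astype(np.int64), predictor_names=predictor_names,
                      ids=ids, subgroup=subgroup, n_dropped=n_dropped)


def save_cohort(data: CohortData, path, outcome_column: str = "outcome",
                subgroup_column: str = "subgroup") -> None:
    """Write a cohort as CSV; :func:`load_cohort` round-trips it exactly."""
    df = data.to_frame(outcome_column=outcome_column,
                       subgroup_column=subgroup_column)
    # repr is the shortest decimal that round-trips a double bit-exactly
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
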