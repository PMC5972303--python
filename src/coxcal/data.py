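"""Right-censored survival data container.

A :class:`SurvivalDataset` holds one row per subject: a nonnegative
follow-up time ``x_i = min(T_i, C_i)`` in years, an event indicator
``delta_i = I(T_i <= C_i)`` and a fixed covariate matrix. Covariates are
kept in a :class:`pandas.DataFrame` so columns carry names; model-fitting
code extracts numpy arrays via :meth:`SurvivalDataset.design`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "DataValidationError"]


class DataValidationError(ValueError):
    """Raised when survival data violate the container invariants."""


@dataclass
class SurvivalDataset:
    """Right-censored survival data: times, event indicators, covariates.

    Parameters
    ----------
    time:
        Follow-up times, nonnegative, one per subject.
    event:
        Event indicators in {0, 1}; at least one event is required.
    covariates:
        ``n x p`` numeric covariate frame (``p`` may be 0). Column names
        identify covariates throughout the package.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=range(len(self.time)))
        elif not isinstance(self.covariates, pd.DataFrame):
            arr = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if arr.shape[0] != len(self.time) and arr.shape[1] == len(self.time):
                arr = arr.T
            self.covariates = pd.DataFrame(
                arr, columns=[f"z{j + 1}" for j in range(arr.shape[1])]
            )
        self._validate()

    # -- invariants -----------------------------------------------------
    def _validate(self) -> None:
        n = len(self.time)
        if n < 2:
            raise DataValidationError("need at least 2 subjects")
        if self.time.ndim != 1 or len(self.event) != n:
            raise DataValidationError("time and event must be equal-length vectors")
        if not np.all(np.isfinite(self.time)):
            raise DataValidationError("non-finite follow-up time")
        if np.any(self.time < 0):
            bad = int(np.flatnonzero(self.time < 0)[0])
            raise DataValidationError(f"negative follow-up time at row {bad}")
        ev = np.asarray(self.event)
        if not np.all(np.isin(ev, (0, 1))):
            bad = int(np.flatnonzero(~np.isin(ev, (0, 1)))[0])
            raise DataValidationError(
                f"event indicator not in {{0,1}} at row {bad} (column 'event')"
            )
        self.event = ev.astype(np.int8)
        if self.event.sum() == 0:
            raise DataValidationError("dataset contains no events")
        if len(self.covariates) != n:
            raise DataValidationError("covariate frame length mismatch")
        for name in self.covariates.columns:
            col = self.covariates[name]
            if not np.issubdtype(np.asarray(col).dtype, np.number):
                raise DataValidationError(f"non-numeric covariate column '{name}'")
            if col.isna().any():
                bad = int(np.flatnonzero(col.isna().to_numpy())[0])
                raise DataValidationError(f"missing value in column '{name}' row {bad}")

    # -- accessors ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def design(self, columns: Sequence[str] | None = None) -> np.ndarray:
        """Return the covariate matrix (optionally a named subset) as floats."""
        if columns is None:
            return self.covariates.to_numpy(dtype=float)
        missing = [c for c in columns if c not in self.covariates.columns]
        if missing:
            raise KeyError(f"unknown covariate column(s): {missing}")
        return self.covariates.loc[:, list(columns)].to_numpy(dtype=float)

    def subset_covariates(self, columns: Sequence[str]) -> "SurvivalDataset":
        return SurvivalDataset(
            self.time.copy(), self.event.copy(), self.covariates.loc[:, list(columns)].copy()
        )

    # -- frame conversion ----------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.time, "event": self.event.astype(int)})
        for c in self.covariates.columns:
            out[c] = self.covariates[c].to_numpy()
        return out

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        time_col: str = "time",
        event_col: str = "event",
        covariate_cols: Sequence[str] | None = None,
    ) -> "SurvivalDataset":
        for col in (time_col, event_col):
            if col not in frame.columns:
                raise DataValidationError(f"missing required column '{col}'")
        if covariate_cols is None:
            covariate_cols = [c for c in frame.columns if c not in (time_col, event_col)]
        time = pd.to_numeric(frame[time_col], errors="coerce").to_numpy()
        if np.any(~np.isfinite(time)):
            bad = int(np.flatnonzero(~np.isfinite(time))[0])
            raise DataValidationError(f"non-numeric time at row {bad} (column '{time_col}')")
        event = pd.to_numeric(frame[event_col], errors="coerce").to_numpy()
        if np.any(~np.isfinite(event)):
            bad = int(np.flatnonzero(~np.isfinite(event))[0])
            raise DataValidationError(f"non-numeric event at row {bad} (column '{event_col}')")
        cov = frame.loc[:, list(covariate_cols)].apply(pd.to_numeric, errors="coerce")
        cov = cov.reset_index(drop=True)
        return cls(time, event, cov)
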