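"""Longitudinal event-table datasets.

The on-disk format follows NONMEM conventions loosely: one CSV row per dose or
observation with columns ``ID``, ``TIME`` (h), ``DV`` (observed concentration,
IU/dL; observation rows), ``AMT`` (dose amount, IU; dose rows) and optionally
``RATE`` (IU/h) or ``DUR`` (h) for infusions — ``RATE`` takes precedence when
both are present.  Every remaining column is a covariate and must be constant
within a subject.  A row is a dose row iff ``AMT`` is non-missing and an
observation row iff ``DV`` is non-missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .pk import DoseEvent, DoseRegimen

_MANDATORY = ("ID", "TIME")


@dataclass
class Subject:
    """One individual: static covariates, a dose schedule, and observations."""

    id: str
    covariates: dict[str, float]
    regimen: DoseRegimen
    obs_times: np.ndarray
    obs_values: np.ndarray

    def __post_init__(self) -> None:
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.obs_values = np.asarray(self.obs_values, dtype=float)
        if self.obs_times.shape != self.obs_values.shape:
            raise DataError(f"subject {self.id}: observation arrays differ in length")
        if not str(self.id):
            raise DataError("subject IDs must be non-empty")


@dataclass
class Dataset:
    """A collection of subjects plus bookkeeping for categorical covariates.

    ``categorical`` maps a covariate name to its ordered levels; such columns
    are one-hot expanded when a design matrix is built.
    """

    subjects: list[Subject]
    categorical: dict[str, list] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.subjects[0].covariates) if self.subjects else []

    def covariate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [s.covariates for s in self.subjects],
            index=[s.id for s in self.subjects],
        )

    def subset(self, indices) -> "Dataset":
        return Dataset(
            subjects=[self.subjects[i] for i in indices],
            categorical=dict(self.categorical),
        )


def design_columns(names, categorical) -> list[str]:
    """Expand covariate names into design-matrix column names (one-hot for
    categorical covariates, ``name=level`` per level)."""
    cols: list[str] = []
    for name in names:
        if name in categorical:
            cols.extend(f"{name}={lev}" for lev in categorical[name])
        else:
            cols.append(name)
    return cols


def design_matrix(dataset: Dataset, names) -> tuple[np.ndarray, list[str]]:
    """Build the raw (unscaled) design matrix for the given covariates."""
    cols = design_columns(names, dataset.categorical)
    x = np.empty((len(dataset), len(cols)))
    for i, s in enumerate(dataset.subjects):
        j = 0
        for name in names:
            if name not in s.covariates:
                raise DataError(
                    f"covariate {name!r} missing for subject {s.id}; "
                    f"available: {sorted(s.covariates)}"
                )
            if name in dataset.categorical:
                levels = dataset.categorical[name]
                for lev in levels:
                    x[i, j] = 1.0 if s.covariates[name] == lev else 0.0
                    j += 1
            else:
                x[i, j] = s.covariates[name]
                j += 1
    return x, cols


def read_event_table(path, categorical: dict[str, list] | None = None) -> Dataset:
    """Parse a CSV event table into a :class:`Dataset`.

    Raises :class:`DataError` (with row numbers, 1-based counting the header)
    for missing mandatory columns, time-varying covariates, or subjects
    without any dose row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise DataError(f"event table is missing mandatory columns: {missing}")
    if "DV" not in df.columns and "AMT" not in df.columns:
        raise DataError("event table needs at least one of DV/AMT columns")
    special = {"ID", "TIME", "DV", "AMT", "RATE", "DUR"}
    cov_cols = [c for c in df.columns if c not in special]
    if (df["TIME"] < 0).any():
        rows = (df.index[df["TIME"] < 0] + 2).tolist()
        raise DataError(f"negative TIME values at rows {rows}")

    subjects = []
    for sid, g in df.groupby("ID", sort=False):
        for c in cov_cols:
            if g[c].nunique(dropna=False) > 1:
                rows = (g.index + 2).tolist()
                raise DataError(
                    f"covariate {c!r} varies within subject {sid} (rows {rows}); "
                    "time-varying covariates are not supported"
                )
        covs = {c: g[c].iloc[0] for c in cov_cols}
        amt = g["AMT"] if "AMT" in g else pd.Series(np.nan, index=g.index)
        dv = g["DV"] if "DV" in g else pd.Series(np.nan, index=g.index)
        dose_rows = g[amt.notna()].sort_values("TIME")
        if dose_rows.empty:
            raise DataError(f"subject {sid} has no dose (AMT) row")
        events = []
        for _, row in dose_rows.iterrows():
            dur = 0.0
            if "RATE" in row.index and pd.notna(row.get("RATE")) and row["RATE"] > 0:
                dur = row["AMT"] / row["RATE"]
            elif "DUR" in row.index and pd.notna(row.get("DUR")):
                dur = float(row["DUR"])
            events.append(DoseEvent(float(row["TIME"]), float(row["AMT"]), dur))
        obs = g[dv.notna()].sort_values("TIME")
        subjects.append(
            Subject(
                id=str(sid),
                covariates=covs,
                regimen=DoseRegimen(events=tuple(events)),
                obs_times=obs["TIME"].to_numpy(dtype=float),
                obs_values=obs["DV"].to_numpy(dtype=float),
            )
        )
    return Dataset(subjects=subjects, categorical=dict(categorical or {}))


def write_event_table(dataset: Dataset, path) -> None:
    """Write a :class:`Dataset` as a CSV event table (round-trip lossless for
    finite values)."""
    rows = []
    has_inf = any(
        e.duration > 0 for s in dataset.subjects for e in s.regimen.events
    )
    for s in dataset.subjects:
        for e in s.regimen.events:
            row = {"ID": s.id, "TIME": e.time, "DV": np.nan, "AMT": e.amount}
            if has_inf:
                row["DUR"] = e.duration
            rows.append({**row, **s.covariates})
        for t, y in zip(s.obs_times, s.obs_values):
            row = {"ID": s.id, "TIME": t, "DV": y, "AMT": np.nan}
            if has_inf:
                row["DUR"] = np.nan
            rows.append({**row, **s.covariates})
    pd.DataFrame(rows).to_csv(path, index=False)
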