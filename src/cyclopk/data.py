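"""Longitudinal TDM dataset container and CSV reader/writer.

The on-disk dialect follows NONMEM conventions: one row per event, dose
rows (EVID=1) carry AMT, observation rows (EVID=0) carry DV; OCC is the
occasion index (one occasion per sampling day), DAY/PDAY the sampling and
post-transplant day, and the remaining columns are covariates.  All doses
are steady-state maintenance doses repeated every ``tau_h`` hours (12 h
BID by default), so an observation's within-interval time is
``(TIME - time of last dose) mod tau``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TdmDataset", "read_dataset", "write_dataset", "DatasetError"]

COLUMNS = [
    "ID", "TIME", "EVID", "MDV", "AMT", "DV", "STYP", "OCC", "DAY", "PDAY",
    "WT", "HGB", "HT", "CREAT", "CLCR", "AGE", "GEND", "TRANS",
]

_COVARIATES = ["WT", "HGB", "HT", "CREAT", "CLCR", "AGE", "GEND", "TRANS"]


class DatasetError(ValueError):
    """Raised when a dataset violates the dialect's invariants."""


@dataclass
class TdmDataset:
    """Ordered event records for a TDM cohort.

    ``df`` holds one row per event with the columns of :data:`COLUMNS`;
    ``tau_h`` is the maintenance inter-dose interval shared by the cohort.
    """

    df: pd.DataFrame
    tau_h: float = 12.0
    name: str = field(default="cohort", compare=False)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def subjects(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def subject(self, subject_id) -> "TdmDataset":
        sub = self.df[self.df["ID"] == subject_id]
        if sub.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        return TdmDataset(sub.copy(), tau_h=self.tau_h, name=f"{self.name}:{subject_id}")

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing required columns: {missing}")
        if df.empty:
            raise DatasetError("dataset has no rows")
        evid = df["EVID"].to_numpy()
        if not np.isin(evid, [0, 1]).all():
            bad = int(np.flatnonzero(~np.isin(evid, [0, 1]))[0])
            raise DatasetError(f"row {bad}: EVID must be 0 or 1")
        dv = df["DV"].to_numpy(dtype=float)
        amt = df["AMT"].to_numpy(dtype=float)
        dose_with_dv = (evid == 1) & ~np.isnan(dv)
        if dose_with_dv.any():
            raise DatasetError(
                f"row {int(np.flatnonzero(dose_with_dv)[0])}: DV present on a dose row"
            )
        obs_without_dv = (evid == 0) & (df["MDV"].to_numpy() == 0) & np.isnan(dv)
        if obs_without_dv.any():
            raise DatasetError(
                f"row {int(np.flatnonzero(obs_without_dv)[0])}: observation row without DV"
            )
        obs_with_amt = (evid == 0) & ~np.isnan(amt)
        if obs_with_amt.any():
            raise DatasetError(
                f"row {int(np.flatnonzero(obs_with_amt)[0])}: AMT present on an observation row"
            )
        dose_without_amt = (evid == 1) & (np.isnan(amt) | (amt < 0))
        if dose_without_amt.any():
            raise DatasetError(
                f"row {int(np.flatnonzero(dose_without_amt)[0])}: dose row without valid AMT"
            )
        if (df["TIME"].to_numpy(dtype=float) < 0).any():
            raise DatasetError("negative TIME")
        for sid, sub in df.groupby("ID", sort=False):
            t = sub["TIME"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                raise DatasetError(f"subject {sid!r}: TIME not non-decreasing")
            if (sub["EVID"] == 0).any() and not (sub["EVID"] == 1).any():
                raise DatasetError(f"subject {sid!r}: observations without any dose event")
            occ = sub.loc[sub["EVID"] == 0, ["DAY", "OCC"]]
            if occ["DAY"].nunique() != occ["OCC"].nunique():
                raise DatasetError(f"subject {sid!r}: OCC not constant within sampling day")
        if (df.loc[evid == 0, "WT"].to_numpy(dtype=float) <= 0).any():
            raise DatasetError("non-positive WT on an observation row")
        if (df.loc[evid == 0, "HGB"].to_numpy(dtype=float) <= 0).any():
            raise DatasetError("non-positive HGB on an observation row")

    # -- derived quantities used by the estimator --------------------------
    def observation_frame(self) -> pd.DataFrame:
        """Observations augmented with the dose in force and interval time.

        Returns a copy of the EVID=0 rows with ``DOSE_MG`` (amount of the
        most recent dose event at or before the observation) and ``TAD``
        (time after dose within the steady-state interval, in [0, tau)).
        """
        out = []
        for sid, sub in self.df.groupby("ID", sort=False):
            sub = sub.reset_index()
            t = sub["TIME"].to_numpy(dtype=float)
            is_dose = (sub["EVID"] == 1).to_numpy()
            dose_t = t[is_dose]
            dose_a = sub["AMT"].to_numpy(dtype=float)[is_dose]
            obs = sub[~is_dose]
            idx = np.searchsorted(dose_t, obs["TIME"].to_numpy(dtype=float), side="right") - 1
            if np.any(idx < 0):
                row = obs.iloc[int(np.flatnonzero(idx < 0)[0])]["index"]
                raise DatasetError(f"row {int(row)}: observation before any dose event")
            obs = obs.copy()
            obs["DOSE_MG"] = dose_a[idx]
            obs["TAD"] = np.mod(
                obs["TIME"].to_numpy(dtype=float) - dose_t[idx], self.tau_h
            )
            out.append(obs)
        return pd.concat(out, ignore_index=True)

    def copy(self) -> "TdmDataset":
        return TdmDataset(self.df.copy(), tau_h=self.tau_h, name=self.name)


def _impute_covariates(df: pd.DataFrame) -> list[str]:
    """Last-observation-carried-forward imputation per subject; returns notes."""
    notes = []
    for col in _COVARIATES:
        if df[col].isna().any():
            df[col] = df.groupby("ID")[col].transform(lambda s: s.ffill().bfill())
            notes.append(f"imputed missing {col} by LOCF within subject")
    return notes


def read_dataset(path, tau_h: float = 12.0) -> TdmDataset:
    """Read and validate a TDM dataset CSV.

    Missing covariate values are tolerated and imputed by last observation
    carried forward within subject (a note is attached to the dataset name).
    """
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing required columns {missing}")
    for col in ["TIME", "AMT", "DV", "WT", "HGB", "HT", "CREAT", "CLCR", "AGE"]:
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ["EVID", "MDV", "OCC", "DAY", "PDAY", "GEND", "TRANS"]:
        df[col] = pd.to_numeric(df[col], downcast="integer", errors="raise")
    _impute_covariates(df)
    return TdmDataset(df[COLUMNS].copy(), tau_h=tau_h, name=str(path))


def write_dataset(ds: TdmDataset, path) -> None:
    """Write a dataset to CSV in the package dialect (blank for NaN)."""
    ds.df[COLUMNS].to_csv(path, index=False, float_format="%.6g")


def dataset_to_csv_string(ds: TdmDataset) -> str:
    buf = io.StringIO()
    write_dataset(ds, buf)
    return buf.getvalue()
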