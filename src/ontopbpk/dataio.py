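"""NONMEM-style dataset I/O and validation.

Datasets are flat CSV tables with one row per dose or observation
event: ID, TIME (h), AMT (mg), EVID (0 observation / 1 dose), MDV,
DV (ng/mL), AGE (years), WT (kg), plus optional SS/II columns for
steady-state dose records and arbitrary extra covariates.  Column names
are case-insensitive and "." marks missing values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PKDataset", "read_dataset", "write_dataset"]

REQUIRED = ("ID", "TIME", "AMT", "EVID", "MDV", "DV", "AGE", "WT")
OPTIONAL = ("SS", "II")


class DatasetError(ValueError):
    """Dataset fails the structural contract."""


@dataclass
class PKDataset:
    """Validated longitudinal PK dataset (wraps a pandas DataFrame)."""

    df: pd.DataFrame

    def __post_init__(self):
        self.df = _validate(self.df)

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def observations(self) -> pd.DataFrame:
        return self.df[(self.df["EVID"] == 0) & (self.df["MDV"] == 0)]

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def subject_summary(self) -> pd.DataFrame:
        obs = self.df["EVID"] == 0
        return self.df.groupby("ID").agg(
            age=("AGE", "first"),
            weight=("WT", "first"),
            n_obs=("EVID", lambda s: int((s == 0).sum())),
            n_dose=("EVID", lambda s: int((s == 1).sum())),
        )


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).upper() for c in df.columns]
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {', '.join(missing)}")
    df = df.replace(".", np.nan)
    numeric = list(REQUIRED) + [c for c in OPTIONAL if c in df.columns]
    for c in numeric:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise DatasetError(f"non-numeric values in column {c}: {exc}") from None
    if df["ID"].isna().any() or df["TIME"].isna().any():
        raise DatasetError("ID and TIME may not be missing")
    obs = df["EVID"] == 0
    bad_dv = obs & (df["MDV"] == 0) & (df["DV"].isna() | (df["DV"] < 0))
    if bad_dv.any():
        raise DatasetError(
            f"{int(bad_dv.sum())} observation row(s) with missing or negative DV"
        )
    for sid, grp in df.groupby("ID"):
        if (grp["EVID"] == 0).any() and not (grp["EVID"] == 1).any():
            raise DatasetError(f"subject {sid} has observations but no dose record")
        t = grp["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise DatasetError(f"TIME not non-decreasing within subject {sid}")
    if df.loc[df["EVID"] == 1, "AMT"].isna().any():
        raise DatasetError("dose records require AMT")
    return df.reset_index(drop=True)


def read_dataset(path: str) -> PKDataset:
    """Read and validate a NONMEM-style CSV dataset."""
    df = pd.read_csv(path, na_values=["."], dtype=str)
    return PKDataset(df)


def write_dataset(data: PKDataset | pd.DataFrame, path: str) -> None:
    """Write a dataset as CSV with "." for missing values."""
    df = data.df if isinstance(data, PKDataset) else data
    df.to_csv(path, index=False, na_rep=".", float_format="%.10g")
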