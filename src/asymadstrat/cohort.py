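"""Cohort exchange objects and CSV round-tripping.

The :class:`CohortTable` is the universal exchange object of the pipeline:
one row per subject carrying demographics, CSF analytes, an optional pair of
PET SUVR ratios and a wide block of peptide abundance columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUP_CONTROL = "Control"
GROUP_ASYMAD = "AsymAD"
GROUP_AD = "AD"
GROUP_UNLABELLED = "Unlabelled"
VALID_GROUPS = (GROUP_CONTROL, GROUP_ASYMAD, GROUP_AD, GROUP_UNLABELLED)

SUBTYPE_CONTROL_LIKE = "ControlLike"
SUBTYPE_AD_LIKE = "ADLike"

#: metadata columns in canonical order; everything after these is peptides
META_COLUMNS = [
    "subject_id",
    "group_label",
    "age",
    "sex",
    "race",
    "education",
    "moca",
    "apoe",
    "abeta42",
    "ttau",
    "ptau",
    "av45_suvr",
    "fdg_suvr",
]


class CohortError(ValueError):
    """Raised on malformed cohort tables or files."""


def peptide_name(i: int) -> str:
    return f"pep_{i + 1:04d}"


@dataclass
class CohortTable:
    """Subjects x (metadata, peptides) table.

    Parameters
    ----------
    data:
        DataFrame containing at least ``subject_id`` and ``group_label``
        plus any of the other metadata columns and peptide columns.
    peptide_columns:
        Names of the peptide abundance columns, in stable order.
    """

    data: pd.DataFrame
    peptide_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        if "subject_id" not in df.columns:
            raise CohortError("cohort table requires a subject_id column")
        ids = df["subject_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise CohortError(f"duplicate subject_id values: {sorted(set(dup))}")
        if "group_label" in df.columns:
            bad = set(df["group_label"].dropna()) - set(VALID_GROUPS)
            if bad:
                raise CohortError(f"unknown group labels: {sorted(bad)}")
        missing = [c for c in self.peptide_columns if c not in df.columns]
        if missing:
            raise CohortError(f"peptide columns absent from table: {missing}")
        if "moca" in df.columns:
            moca = pd.to_numeric(df["moca"], errors="coerce").dropna()
            if len(moca) and ((moca < 0) | (moca > 30)).any():
                raise CohortError("moca values outside [0, 30]")
        for col in ("abeta42", "ttau", "ptau"):
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce").dropna()
                if len(vals) and (vals <= 0).any():
                    raise CohortError(f"non-positive {col} values present")
        self.data = df.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data["subject_id"].astype(str).to_numpy()

    @property
    def group_labels(self) -> np.ndarray:
        return self.data["group_label"].to_numpy()

    def peptide_matrix(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.peptide_columns
        return self.data[cols].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        return CohortTable(self.data.loc[np.asarray(mask)].reset_index(drop=True),
                           list(self.peptide_columns))

    def by_group(self, *groups: str) -> "CohortTable":
        return self.subset(self.data["group_label"].isin(groups).to_numpy())

    def ratio(self, num: str = "ttau", den: str = "abeta42") -> np.ndarray:
        return (self.data[num] / self.data[den]).to_numpy(dtype=float)


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests.

    ``true_event_ordering`` / ``true_stage`` are populated only in
    event-cascade mode; ``true_asymad_subtype`` only for AsymAD subjects.
    """

    data: pd.DataFrame
    true_event_ordering: list[int] | None = None

    def __post_init__(self) -> None:
        df = self.data
        if "subject_id" not in df.columns:
            raise CohortError("ground truth requires a subject_id column")
        if "true_asymad_subtype" in df.columns and "group_label" in df.columns:
            sub = df["true_asymad_subtype"].notna()
            asym = df["group_label"] == GROUP_ASYMAD
            if (sub != asym).any():
                raise CohortError(
                    "true_asymad_subtype must be defined exactly for AsymAD subjects")


def _infer_peptide_columns(columns: Iterable[str]) -> list[str]:
    return [c for c in columns if c not in META_COLUMNS]


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort table as wide CSV (UTF-8, empty cell = missing)."""
    meta = [c for c in META_COLUMNS if c in table.data.columns]
    cols = meta + table.peptide_columns
    table.data[cols].to_csv(path, index=False)


def read_cohort(path: str | Path) -> CohortTable:
    """Read a wide cohort CSV written by :func:`write_cohort`.

    Column mapping is header-driven: known metadata columns are picked up by
    name, every remaining column is treated as a peptide. Empty cells are
    preserved as missing values.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    peptides = _infer_peptide_columns(df.columns)
    for col in peptides:
        empty = df[col].isna().all()
        if empty:
            raise CohortError(f"peptide column {col!r} is entirely empty")
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()
                     & df[col].notna()].index
            row = int(bad[0]) if len(bad) else -1
            raise CohortError(
                f"non-numeric value in peptide column {col!r} at row {row}"
            ) from exc
    return CohortTable(df, peptides)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    df = truth.data.copy()
    if truth.true_event_ordering is not None:
        df.attrs["true_event_ordering"] = truth.true_event_ordering
    df.to_csv(path, index=False)
    if truth.true_event_ordering is not None:
        order_path = Path(path).with_suffix(".ordering.csv")
        pd.DataFrame({"position": range(len(truth.true_event_ordering)),
                      "cluster": truth.true_event_ordering}).to_csv(
            order_path, index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, dtype={"subject_id": str})
    ordering = None
    order_path = Path(path).with_suffix(".ordering.csv")
    if order_path.exists():
        ordering = pd.read_csv(order_path)["cluster"].tolist()
    return GroundTruth(df, true_event_ordering=ordering)
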