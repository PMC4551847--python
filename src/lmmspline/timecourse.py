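"""Tabular data model for time-course expression experiments.

The universal input is a molecules x samples matrix of log-scale
intensities together with a sample sheet mapping every sample (column) to a
subject, a measurement time and an optional treatment group.  Technical or
biological replicates are represented as distinct subjects.  Missing values
are first-class (NaN in the matrix, "NA" or empty cells on disk) and are
skipped, never imputed, by every downstream computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SHEET_COLUMNS = ("sample", "subject", "time")


class ValidationError(ValueError):
    """Raised when a matrix/sample-sheet pair violates the data contract."""


@dataclass
class TimeCourseExperiment:
    """A molecules x samples expression matrix with sample annotations.

    Attributes
    ----------
    values : DataFrame, molecules (rows, unique ids) x samples (columns,
        unique ids); log-scale intensities, NaN for missing.
    samples : DataFrame indexed by sample id with columns ``subject``
        (str), ``time`` (float) and optionally ``group`` (str, constant
        within subject).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.samples = self.samples.copy()
        self.samples["subject"] = self.samples["subject"].astype(str)
        self.samples["time"] = pd.to_numeric(self.samples["time"],
                                             errors="coerce")
        if "group" in self.samples.columns and self.samples["group"].isna().all():
            self.samples = self.samples.drop(columns="group")
        if "group" in self.samples.columns:
            self.samples["group"] = self.samples["group"].astype(str)
        self.validate()

    # -- contract ----------------------------------------------------------

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate molecule ids: {list(dup)[:5]}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dup)[:5]}")
        matrix_ids = set(self.values.columns)
        sheet_ids = set(self.samples.index)
        if matrix_ids != sheet_ids:
            only_m = sorted(matrix_ids - sheet_ids)
            only_s = sorted(sheet_ids - matrix_ids)
            raise ValidationError(
                "matrix columns and sample sheet disagree: "
                f"only in matrix {only_m}; only in sheet {only_s}")
        if not np.isfinite(self.samples["time"]).all():
            bad = self.samples.index[~np.isfinite(self.samples["time"])]
            raise ValidationError(f"non-numeric/non-finite time for samples "
                                  f"{list(bad)[:5]}")
        if self.samples["time"].nunique() < 2:
            raise ValidationError("need at least 2 distinct time values")
        if self.has_groups:
            per_subj = self.samples.groupby("subject")["group"].nunique()
            bad = per_subj[per_subj > 1]
            if len(bad):
                raise ValidationError(
                    f"group label not constant within subject(s): "
                    f"{list(bad.index)[:5]}")
        # harmonize column order to the sheet
        self.values = self.values[self.samples.index]

    # -- convenience -------------------------------------------------------

    @property
    def molecule_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.samples["subject"].nunique()

    @property
    def times(self) -> np.ndarray:
        """Per-sample time values, aligned with the matrix columns."""
        return self.samples["time"].to_numpy(float)

    @property
    def distinct_times(self) -> np.ndarray:
        return np.unique(self.times)

    @property
    def n_timepoints(self) -> int:
        """T: number of distinct observed time points."""
        return self.distinct_times.size

    @property
    def has_groups(self) -> bool:
        return "group" in self.samples.columns

    @property
    def group_levels(self) -> list[str]:
        if not self.has_groups:
            return []
        return sorted(self.samples["group"].unique())

    def subset_molecules(self, ids) -> "TimeCourseExperiment":
        return TimeCourseExperiment(self.values.loc[list(ids)], self.samples)

    def subset_samples(self, ids) -> "TimeCourseExperiment":
        ids = list(ids)
        return TimeCourseExperiment(self.values[ids], self.samples.loc[ids])

    # -- I/O ----------------------------------------------------------------

    def write(self, matrix_path, sheet_path) -> None:
        """Write matrix + sheet as delimited text (dialect from extension)."""
        sep_m = _sep_for(matrix_path)
        sep_s = _sep_for(sheet_path)
        out = self.values.copy()
        out.index.name = "molecule"
        out.to_csv(matrix_path, sep=sep_m, na_rep="NA")
        sheet = self.samples.reset_index()
        sheet = sheet.rename(columns={sheet.columns[0]: "sample"})
        sheet.to_csv(sheet_path, sep=sep_s, index=False)


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_experiment(matrix_path, sheet_path) -> TimeCourseExperiment:
    """Read a matrix (molecule rows, sample columns) and a sample sheet.

    Empty cells or "NA" denote missing values; their count is reported in
    the log.  Fatal on any mismatch between matrix columns and sheet
    sample ids, and on non-numeric times.
    """
    values = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0,
                         na_values=["NA"])
    sheet = pd.read_csv(sheet_path, sep=_sep_for(sheet_path),
                        na_values=["NA"], dtype={"sample": str})
    cols = {c.lower(): c for c in sheet.columns}
    missing_cols = [c for c in SHEET_COLUMNS if c not in cols]
    if missing_cols:
        raise ValidationError(
            f"sample sheet lacks required column(s) {missing_cols}")
    sheet = sheet.rename(columns={cols[k]: k for k in cols})
    sheet = sheet.set_index("sample")
    keep = [c for c in ("subject", "time", "group") if c in sheet.columns]
    exp = TimeCourseExperiment(values, sheet[keep])
    n_missing = int(exp.values.isna().sum().sum())
    logger.info("read %d molecules x %d samples (%d missing cells)",
                exp.n_molecules, len(exp.sample_ids), n_missing)
    return exp


def split_by_group(exp: TimeCourseExperiment) -> dict[str, TimeCourseExperiment]:
    """Partition samples by group level; the molecule set is unchanged."""
    if not exp.has_groups:
        raise ValidationError("experiment has no group annotation")
    out = {}
    for level in exp.group_levels:
        ids = exp.samples.index[exp.samples["group"] == level]
        out[level] = exp.subset_samples(ids)
    return out


def to_long(exp: TimeCourseExperiment) -> pd.DataFrame:
    """Long-format view: one row per (molecule, sample) present cell."""
    long = (exp.values.rename_axis("molecule")
            .reset_index()
            .melt(id_vars="molecule", var_name="sample", value_name="value"))
    long = long.merge(exp.samples.rename_axis("sample").reset_index(),
                      on="sample")
    return long.dropna(subset=["value"])
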