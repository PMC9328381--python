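"""Core data containers and tabular I/O for the paired-timepoint expression pipeline.

The pipeline operates on probe-by-sample log2 intensity matrices measured at two
timepoints (pretreatment and week 4 of methotrexate therapy), a per-sample
clinical metadata table, and a derived probe-by-patient matrix of longitudinal
log2 differences.  All interchange is plain TSV (tab-separated, UTF-8, ``.``
decimal, ``NA`` for missing values in raw-scale inputs only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_TAGS = ("raw", "log2", "normalized_log2")
TIMEPOINTS = ("pretreatment", "week4")
RESPONSES = ("good", "nonresponder")
SMOKING = ("never", "past", "current")

#: columns a sample table must carry, in canonical order
SAMPLE_COLUMNS = [
    "sample_id",
    "patient_id",
    "timepoint",
    "response",
    "sex",
    "age_at_onset",
    "haq",
    "smoking",
    "acpa_positive",
    "swollen28",
    "tender28",
    "crp",
    "vas_global",
]

#: optional month-3 re-measurements of the time-varying covariates
MONTH3_COLUMNS = ["haq_3mo", "swollen28_3mo", "tender28_3mo", "crp_3mo", "vas_global_3mo"]


class PipelineError(ValueError):
    """Base class for domain errors raised by this package."""


class FormatError(PipelineError):
    """Malformed input file (duplicates, bad header, non-numeric body)."""


class VocabularyError(PipelineError):
    """Categorical value outside the declared vocabulary."""


class PairingError(PipelineError):
    """Paired pre/week-4 design violated (duplicate or missing timepoints)."""


class AlignmentError(PipelineError):
    """Probe universes of the two timepoint matrices disagree."""


class ConfigError(PipelineError):
    """Invalid configuration value."""


@dataclass
class ExpressionMatrix:
    """Probe-by-sample matrix of expression intensities.

    Parameters
    ----------
    frame
        DataFrame with probe identifiers as the index and sample identifiers
        as columns.
    scale_tag
        One of ``raw`` (linear intensities, may contain NA), ``log2``
        (log2-transformed, unnormalized) or ``normalized_log2`` (quantile
        normalized log2 intensities, the analysis-ready scale).
    """

    frame: pd.DataFrame
    scale_tag: str

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise VocabularyError(f"unknown scale_tag {self.scale_tag!r}; expected one of {SCALE_TAGS}")
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe IDs: {dups[:5]}")
        if self.frame.columns.has_duplicates:
            dups = self.frame.columns[self.frame.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups[:5]}")
        if self.scale_tag != "raw" and self.frame.isna().any().any():
            raise FormatError(f"missing values not permitted at scale {self.scale_tag!r}")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def probe_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape


@dataclass
class SampleTable:
    """Validated per-sample clinical metadata.

    One row per array sample; each patient contributes at most one sample per
    timepoint and carries a single EULAR response label (good / nonresponder)
    across both of its samples.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in sample table")
        for col, vocab in [("timepoint", TIMEPOINTS), ("response", RESPONSES),
                           ("sex", ("male", "female")), ("smoking", SMOKING)]:
            bad = set(df[col].unique()) - set(vocab)
            if bad:
                raise VocabularyError(f"unknown {col} value(s) {sorted(bad)}; expected {vocab}")
        dup = df.duplicated(subset=["patient_id", "timepoint"])
        if dup.any():
            offenders = df.loc[dup, "patient_id"].unique().tolist()
            raise PairingError(f"patient(s) with more than one sample at a timepoint: {offenders[:5]}")
        if (df.groupby("patient_id")["response"].nunique() > 1).any():
            raise PairingError("response label differs between a patient's samples")
        for col, lo, hi in [("swollen28", 0, 28), ("tender28", 0, 28), ("vas_global", 0, 100)]:
            vals = df[col].astype(float)
            if (vals < lo).any() or (vals > hi).any():
                raise FormatError(f"{col} outside [{lo}, {hi}]")
        if (df["crp"].astype(float) < 0).any():
            raise FormatError("negative CRP")

    @property
    def patients(self) -> list[str]:
        """Unique patient identifiers in lexicographic order."""
        return sorted(self.frame["patient_id"].unique())

    def response_by_patient(self) -> pd.Series:
        """EULAR response label per patient, indexed lexicographically."""
        s = self.frame.drop_duplicates("patient_id").set_index("patient_id")["response"]
        return s.loc[self.patients]

    def rows_at(self, timepoint: str) -> pd.DataFrame:
        if timepoint not in TIMEPOINTS:
            raise VocabularyError(f"unknown timepoint {timepoint!r}")
        sub = self.frame[self.frame["timepoint"] == timepoint]
        return sub.sort_values("patient_id").reset_index(drop=True)


@dataclass
class DeltaMatrix:
    """Probe-by-patient matrix of week-4 minus pretreatment log2 differences."""

    frame: pd.DataFrame  # index: probe_ids, columns: patient_ids

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def probe_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def patient_ids(self) -> list[str]:
        return self.frame.columns.tolist()


@dataclass
class PairedDesign:
    """Patient → (pretreatment sample, week-4 sample) mapping.

    Patients are kept in lexicographic order so downstream fold assignment and
    output files are deterministic.
    """

    pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def patients(self) -> list[str]:
        return list(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def read_expression_matrix(path: str | Path, scale_tag: str) -> ExpressionMatrix:
    """Read a probe-by-sample TSV into an :class:`ExpressionMatrix`.

    The file must have a header row of sample IDs whose first cell is
    ``probe_id``, a first column of probe IDs, and a numeric body (``NA``
    allowed only for ``scale_tag='raw'``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=["NA"], keep_default_na=False)
    body = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        # pd.to_numeric only to locate bad cells; numpy parsing is
        # correctly rounded, which keeps write/read round-trips bit-exact
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-numeric cell at probe {df.index[i]!r} (row {i + 2}), sample {col!r} (column {j + 2}): "
                f"{df[col].iloc[i]!r}"
            )
        body[col] = df[col].astype(np.float64)
    body.index.name = "probe_id"
    return ExpressionMatrix(body, scale_tag)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV with full float precision (round-trip safe)."""
    frame = matrix.frame.copy()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_sample_table(path: str | Path) -> SampleTable:
    """Read and validate a sample metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    if "acpa_positive" in df.columns:
        df["acpa_positive"] = df["acpa_positive"].astype(bool)
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def align_paired_design(
    expr_pre: ExpressionMatrix,
    expr_wk4: ExpressionMatrix,
    samples: SampleTable,
) -> PairedDesign:
    """Map each patient to its (pretreatment, week-4) sample columns.

    Only patients with both timepoints present in the respective matrices are
    included; incomplete patients are dropped with a logged warning.  The probe
    universes of the two matrices must agree as sets (row order may differ —
    value extraction realigns by probe ID downstream).
    """
    if set(expr_pre.probe_ids) != set(expr_wk4.probe_ids):
        only_pre = set(expr_pre.probe_ids) - set(expr_wk4.probe_ids)
        only_wk4 = set(expr_wk4.probe_ids) - set(expr_pre.probe_ids)
        raise AlignmentError(
            f"probe sets differ between timepoints: {len(only_pre)} only in pre, {len(only_wk4)} only in week4"
        )
    df = samples.frame
    known = set(df["sample_id"])
    for m, tag in [(expr_pre, "pretreatment"), (expr_wk4, "week4")]:
        unknown = set(m.sample_ids) - known
        if unknown:
            raise PairingError(f"{tag} matrix sample(s) missing from sample table: {sorted(unknown)[:5]}")

    sample_of: Mapping[tuple[str, str], str] = {
        (r.patient_id, r.timepoint): r.sample_id for r in df.itertuples()
    }
    pre_cols = set(expr_pre.sample_ids)
    wk4_cols = set(expr_wk4.sample_ids)
    pairs: dict[str, tuple[str, str]] = {}
    for patient in sorted(df["patient_id"].unique()):
        pre = sample_of.get((patient, "pretreatment"))
        wk4 = sample_of.get((patient, "week4"))
        if pre in pre_cols and wk4 in wk4_cols:
            pairs[patient] = (pre, wk4)
        else:
            logger.warning("patient %s lacks a complete pre/week4 pair; excluded from paired design", patient)
    return PairedDesign(pairs)
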