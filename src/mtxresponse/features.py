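"""Feature construction for the response classifiers.

Three expression feature sets (pretreatment, week 4, and their log2 "ratio",
i.e. the per-patient week4 minus pretreatment difference) and two clinical
covariate sets (baseline, month 3), plus leakage-safe standardization whose
parameters are estimated on training patients only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    ConfigError,
    DeltaMatrix,
    ExpressionMatrix,
    FormatError,
    PairedDesign,
    PairingError,
    SampleTable,
)

logger = logging.getLogger(__name__)

CONTRAST_TAGS = ("expr_pre", "expr_wk4", "expr_ratio", "clinical_baseline", "clinical_3mo")

#: 9 source covariates expand to 10 model features (smoking -> 2 indicators)
CLINICAL_FEATURES = [
    "sex_female",
    "age_at_onset",
    "haq",
    "smoking_past",
    "smoking_current",
    "acpa_positive",
    "swollen28",
    "tender28",
    "crp",
    "vas_global",
]

_MONTH3_SOURCE = {
    "haq": "haq_3mo",
    "swollen28": "swollen28_3mo",
    "tender28": "tender28_3mo",
    "crp": "crp_3mo",
    "vas_global": "vas_global_3mo",
}


@dataclass
class FeatureMatrix:
    """Feature-by-patient matrix with a contrast tag."""

    frame: pd.DataFrame  # index: feature_ids, columns: patient_ids
    contrast_tag: str

    def __post_init__(self) -> None:
        if self.contrast_tag not in CONTRAST_TAGS:
            raise ConfigError(f"unknown contrast_tag {self.contrast_tag!r}; expected one of {CONTRAST_TAGS}")
        if self.frame.index.has_duplicates:
            raise FormatError("duplicate feature IDs")
        if self.frame.isna().any().any():
            raise FormatError("missing values in feature matrix")

    @property
    def feature_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def patient_ids(self) -> list[str]:
        return self.frame.columns.tolist()


@dataclass
class StandardizationParams:
    """Per-feature location/scale estimated on a training subset.

    Zero-variance training features are dropped (recorded in
    ``dropped_features``) rather than divided by zero.
    """

    mean: pd.Series
    sd: pd.Series
    dropped_features: list[str]
    training_patients: list[str]


def delta_expression(
    pre: ExpressionMatrix,
    wk4: ExpressionMatrix,
    pairing: PairedDesign,
) -> DeltaMatrix:
    """Per-patient week-4 minus pretreatment log2 difference.

    On the log2 scale this equals the log of the intensity ratio, the
    longitudinal "ratio" contrast.  Rows of the week-4 matrix are realigned to
    the pretreatment probe order by probe ID.
    """
    if set(pre.probe_ids) != set(wk4.probe_ids):
        raise PairingError("probe sets differ between timepoints")
    missing_pre = [p for p, (s_pre, _) in pairing.pairs.items() if s_pre not in pre.frame.columns]
    missing_wk4 = [p for p, (_, s_wk4) in pairing.pairs.items() if s_wk4 not in wk4.frame.columns]
    if missing_pre or missing_wk4:
        raise PairingError(f"paired samples absent from matrices for patients {missing_pre + missing_wk4}")
    wk4_aligned = wk4.frame.reindex(index=pre.frame.index)
    patients = pairing.patients
    pre_cols = [pairing.pairs[p][0] for p in patients]
    wk4_cols = [pairing.pairs[p][1] for p in patients]
    delta = wk4_aligned[wk4_cols].to_numpy() - pre.frame[pre_cols].to_numpy()
    return DeltaMatrix(pd.DataFrame(delta, index=pre.frame.index, columns=patients))


def expression_features(matrix: ExpressionMatrix | DeltaMatrix,
                        pairing: PairedDesign | None = None,
                        contrast_tag: str = "expr_ratio") -> FeatureMatrix:
    """Wrap an expression or delta matrix as a probe-by-patient feature matrix."""
    if isinstance(matrix, DeltaMatrix):
        return FeatureMatrix(matrix.frame.copy(), "expr_ratio")
    if pairing is None:
        raise ConfigError("a PairedDesign is required to map samples to patients")
    col_idx = 0 if contrast_tag == "expr_pre" else 1
    cols = [pairing.pairs[p][col_idx] for p in pairing.patients]
    frame = matrix.frame[cols].copy()
    frame.columns = pairing.patients
    return FeatureMatrix(frame, contrast_tag)


def encode_clinical(samples: SampleTable, timepoint_tag: str = "clinical_baseline") -> FeatureMatrix:
    """Encode the nine clinical covariates as ten numeric model features.

    Binary covariates (sex, ACPA) map to {0, 1}; smoking maps to past/current
    indicators with never-smokers as the reference; numeric covariates pass
    through.  ``clinical_3mo`` swaps in the month-3 re-measurements of the
    time-varying covariates (HAQ, joint counts, CRP, VAS).
    """
    if timepoint_tag not in ("clinical_baseline", "clinical_3mo"):
        raise ConfigError(f"timepoint_tag must be clinical_baseline or clinical_3mo, got {timepoint_tag!r}")
    df = samples.frame.drop_duplicates("patient_id").sort_values("patient_id").set_index("patient_id")
    if timepoint_tag == "clinical_3mo":
        missing = [c for c in _MONTH3_SOURCE.values() if c not in df.columns]
        if missing:
            raise FormatError(f"month-3 covariates missing from sample table: {missing}")
        df = df.drop(columns=list(_MONTH3_SOURCE)).rename(columns={v: k for k, v in _MONTH3_SOURCE.items()})
    na_cols = df[["sex", "age_at_onset", "haq", "smoking", "acpa_positive",
                  "swollen28", "tender28", "crp", "vas_global"]].isna()
    if na_cols.any().any():
        bad = df.index[na_cols.any(axis=1)].tolist()
        raise FormatError(f"missing clinical covariate(s) for patients {bad[:5]}")
    feats = pd.DataFrame(index=df.index)
    feats["sex_female"] = (df["sex"] == "female").astype(float)
    feats["age_at_onset"] = df["age_at_onset"].astype(float)
    feats["haq"] = df["haq"].astype(float)
    feats["smoking_past"] = (df["smoking"] == "past").astype(float)
    feats["smoking_current"] = (df["smoking"] == "current").astype(float)
    feats["acpa_positive"] = df["acpa_positive"].astype(float)
    for col in ["swollen28", "tender28", "crp", "vas_global"]:
        feats[col] = df[col].astype(float)
    return FeatureMatrix(feats[CLINICAL_FEATURES].T, timepoint_tag)


def fit_standardizer(features: FeatureMatrix, training_patients: list[str]) -> StandardizationParams:
    """Estimate per-feature mean/SD from the training patients only."""
    if len(training_patients) == 0:
        raise ConfigError("training set is empty")
    missing = set(training_patients) - set(features.patient_ids)
    if missing:
        raise ConfigError(f"training patients absent from features: {sorted(missing)[:5]}")
    # contiguous copy so the summation order (hence the last bit of the
    # estimates) does not depend on the frame's internal block layout
    train = np.ascontiguousarray(features.frame[list(training_patients)].to_numpy())
    mean = pd.Series(train.mean(axis=1), index=features.frame.index)
    sd = pd.Series(np.std(train, axis=1, ddof=1), index=features.frame.index)
    dropped = sd.index[(sd == 0) | sd.isna()].tolist()
    if dropped:
        logger.warning("dropping %d zero-variance feature(s), e.g. %s", len(dropped), dropped[:3])
    keep = sd.index.difference(dropped, sort=False)
    return StandardizationParams(
        mean=mean.loc[keep],
        sd=sd.loc[keep],
        dropped_features=dropped,
        training_patients=list(training_patients),
    )


def apply_standardizer(params: StandardizationParams, features: FeatureMatrix) -> FeatureMatrix:
    """Center/scale features with training-set parameters (never the target's own)."""
    frame = features.frame.loc[params.mean.index]
    z = frame.sub(params.mean, axis=0).div(params.sd, axis=0)
    return FeatureMatrix(z, features.contrast_tag)
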