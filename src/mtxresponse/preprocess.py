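"""Expression quality control: probe filtering, quantile normalization, log2
transform, and PCA/dendrogram-based sample-outlier detection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .data import ConfigError, ExpressionMatrix, FormatError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Bookkeeping for the probe-filtering / outlier stage."""

    n_probes_in: int
    n_probes_removed_unexpressed: int
    n_probes_removed_blacklist: int
    n_probes_out: int
    outlier_samples: list[str] = field(default_factory=list)
    per_sample_stats: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        expected = self.n_probes_in - self.n_probes_removed_unexpressed - self.n_probes_removed_blacklist
        if self.n_probes_out != expected:
            raise PipelineError("QCReport counts are inconsistent")

    def to_dict(self) -> dict:
        d = {
            "n_probes_in": self.n_probes_in,
            "n_probes_removed_unexpressed": self.n_probes_removed_unexpressed,
            "n_probes_removed_blacklist": self.n_probes_removed_blacklist,
            "n_probes_out": self.n_probes_out,
            "outlier_samples": list(self.outlier_samples),
        }
        if self.per_sample_stats is not None:
            d["per_sample_stats"] = self.per_sample_stats.to_dict(orient="index")
        return d


def expressed_flags_from_floor(matrix: ExpressionMatrix, floor: float) -> pd.DataFrame:
    """Boolean probe-by-sample detection flags: intensity above ``floor``.

    Synthetic stand-in for array detection calls; real bead-level detection
    p-values are out of scope.
    """
    return matrix.frame > floor


def filter_probes(
    raw: ExpressionMatrix,
    expressed_flags: pd.DataFrame,
    blacklist: set[str] | None = None,
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove probes not expressed on any array, plus an explicit blacklist.

    A probe is retained when it is flagged expressed in at least one sample and
    is not blacklisted.  Retained values are passed through untouched.
    """
    if expressed_flags.shape != raw.frame.shape:
        raise FormatError(
            f"expressed_flags shape {expressed_flags.shape} does not match matrix {raw.frame.shape}"
        )
    flags = expressed_flags.reindex(index=raw.frame.index, columns=raw.frame.columns)
    if flags.isna().any().any():
        raise FormatError("expressed_flags index/columns do not match the matrix")
    blacklist = blacklist or set()
    expressed_any = flags.any(axis=1)
    blacklisted = raw.frame.index.isin(blacklist)
    keep = expressed_any.to_numpy() & ~blacklisted
    n_unexpr = int((~expressed_any).sum())
    # blacklist removals counted among probes that would otherwise survive
    n_black = int((blacklisted & expressed_any.to_numpy()).sum())
    out = ExpressionMatrix(raw.frame.loc[keep], raw.scale_tag)
    report = QCReport(
        n_probes_in=raw.frame.shape[0],
        n_probes_removed_unexpressed=n_unexpr,
        n_probes_removed_blacklist=n_black,
        n_probes_out=int(keep.sum()),
    )
    return out, report


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns so every sample shares one distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; within-column ranks are preserved.  Ties are resolved by
    averaging the reference values over the tied ranks.  The operation is
    idempotent (exactly so on tie-free data).
    """
    if matrix.frame.isna().any().any():
        raise FormatError("missing values present; run probe filtering first")
    x = matrix.values
    n_rows = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")  # 1-based, ties averaged
        # fractional ranks (from ties) interpolate between reference values
        out[:, j] = np.interp(ranks, np.arange(1, n_rows + 1), reference)
    frame = pd.DataFrame(out, index=matrix.frame.index, columns=matrix.frame.columns)
    tag = "normalized_log2" if matrix.scale_tag in ("log2", "normalized_log2") else matrix.scale_tag
    return ExpressionMatrix(frame, tag)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2 of a raw-scale matrix."""
    if matrix.scale_tag != "raw":
        raise ConfigError(f"matrix is already on scale {matrix.scale_tag!r}; refusing to log2-transform")
    vals = matrix.values
    bad = ~(vals > 0)
    if bad.any():
        offenders = matrix.frame.index[bad.any(axis=1)].tolist()
        raise PipelineError(f"non-positive intensities for probe(s) {offenders[:5]}")
    frame = pd.DataFrame(np.log2(vals), index=matrix.frame.index, columns=matrix.frame.columns)
    return ExpressionMatrix(frame, "log2")


def detect_outlier_samples(
    matrix: ExpressionMatrix,
    z_cutoff: float = 4.0,
) -> tuple[list[str], np.ndarray]:
    """Flag samples extreme on PC1/PC2 and return a sample dendrogram.

    A sample is an outlier when its score on either of the first two principal
    components of the sample-by-probe matrix exceeds ``z_cutoff`` standard
    deviations of that component's scores.  Also returns the average-linkage
    dendrogram (scipy linkage matrix) of samples under 1 - Pearson distance,
    for visual inspection.
    """
    x = matrix.values.T  # samples x probes
    n = x.shape[0]
    if n < 3:
        raise ConfigError("outlier detection needs at least 3 samples")
    centered = x - x.mean(axis=0)
    if not np.any(centered):
        raise PipelineError("constant expression matrix; PCA undefined")
    # scores on the first two PCs via thin SVD of the centered sample matrix
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    n_pc = min(2, s.size)
    scores = u[:, :n_pc] * s[:n_pc]
    sds = scores.std(axis=0, ddof=1)
    sds[sds == 0] = np.inf
    z = np.abs(scores / sds)
    flagged = np.flatnonzero((z > z_cutoff).any(axis=1))
    outliers = [matrix.sample_ids[i] for i in flagged]

    corr = np.corrcoef(x)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dendrogram = linkage(squareform(dist, checks=False), method="average")
    if outliers:
        logger.warning("flagged %d outlier sample(s): %s", len(outliers), outliers)
    return outliers, dendrogram


def run_qc(
    raw: ExpressionMatrix,
    floor: float = 5.0,
    blacklist: set[str] | None = None,
    z_cutoff: float = 4.0,
) -> tuple[ExpressionMatrix, QCReport]:
    """Full QC chain: detection-floor filtering, quantile normalization,
    outlier flagging.  Flagged outliers are reported, not dropped (the study
    design keeps paired samples; exclusion is the analyst's call)."""
    flags = expressed_flags_from_floor(raw, floor)
    filtered, report = filter_probes(raw, flags, blacklist)
    if raw.scale_tag == "raw":
        filtered = log2_transform(filtered)
    normalized = quantile_normalize(filtered)
    outliers, _ = detect_outlier_samples(normalized, z_cutoff)
    report.outlier_samples = outliers
    stats = pd.DataFrame({
        "mean": normalized.frame.mean(axis=0),
        "sd": normalized.frame.std(axis=0, ddof=1),
        "median": normalized.frame.median(axis=0),
    })
    report.per_sample_stats = stats
    return normalized, report
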