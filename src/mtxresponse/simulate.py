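"""Synthetic paired-timepoint cohort generator.

Emulates the structure of a whole-blood methotrexate-response study: ~85 RA
patients (two EULAR response groups of 42 good responders and 43
nonresponders), probe-level log2 expression at pretreatment and week 4,
clinical covariates with group-specific distributions, planted coexpression
modules (optionally active only in nonresponders), and a planted
response-associated shift in the week-4 minus pretreatment difference.

Clinical covariates are generated top-down: a patient-level DAS28-CRP target is
drawn per response group, then decomposed into tender/swollen joint counts,
CRP and patient-global VAS via Dirichlet-distributed contribution shares, so
that the score recomputed from the components recovers the group means.
EULAR response labels follow from simulated baseline and month-6 DAS28-CRP
trajectories; patients whose realized category is "moderate" are redrawn, so
the emitted cohort contains only good responders and nonresponders, mirroring
the two-group study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import (
    ConfigError,
    ExpressionMatrix,
    SampleTable,
)

__all__ = [
    "GroupClinicalParams",
    "ModuleSpec",
    "SimulationConfig",
    "DiseaseActivityRecord",
    "GroundTruth",
    "SimulatedCohort",
    "compute_das28_crp",
    "eular_category",
    "simulate_clinical",
    "simulate_cohort",
    "default_clinical_params",
]

# DAS28-CRP = 0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.36*ln(CRP+1) + 0.014*VAS + 0.96
_DAS28_INTERCEPT = 0.96


def compute_das28_crp(tender28, swollen28, crp, vas_global):
    """Disease Activity Score over 28 joints using CRP (mg/liter) and 100-mm VAS.

    Accepts scalars or arrays; raises on negative CRP (the log term is
    undefined below -1 and CRP is a concentration).
    """
    crp = np.asarray(crp, dtype=float)
    if np.any(crp < 0):
        raise ConfigError("CRP must be non-negative")
    score = (
        0.56 * np.sqrt(np.asarray(tender28, dtype=float))
        + 0.28 * np.sqrt(np.asarray(swollen28, dtype=float))
        + 0.36 * np.log(crp + 1.0)
        + 0.014 * np.asarray(vas_global, dtype=float)
        + _DAS28_INTERCEPT
    )
    return float(score) if score.ndim == 0 else score


def eular_category(das28_baseline: float, das28_month6: float) -> str:
    """EULAR response category from baseline and month-6 DAS28.

    Classic grid: good requires improvement > 1.2 with a month-6 score <= 3.2;
    none is improvement <= 0.6, or improvement <= 1.2 with month-6 score > 5.1;
    everything else is moderate.
    """
    if not (math.isfinite(das28_baseline) and math.isfinite(das28_month6)):
        raise ConfigError("DAS28 scores must be finite")
    improvement = das28_baseline - das28_month6
    if improvement > 1.2 and das28_month6 <= 3.2:
        return "good"
    if improvement <= 0.6 or (improvement <= 1.2 and das28_month6 > 5.1):
        return "none"
    return "moderate"


@dataclass(frozen=True)
class GroupClinicalParams:
    """Per-response-group clinical covariate distribution parameters.

    Defaults (see :func:`default_clinical_params`) follow the pretreatment
    characteristics of the two EULAR groups in the emulated study: proportions
    for sex/ACPA/smoking, normal age-at-onset, normal HAQ around the printed
    median with an IQR-matched SD, and group DAS28 mean +/- SD.  ``crp`` is
    log-normal on the natural-log scale (exp(2.2) ~ 9 mg/liter for good
    responders, a typical active-RA value).  ``share_weights`` are the mean
    Dirichlet shares of the four variable DAS28 terms (tender, swollen, CRP,
    VAS), centered on the group's printed component medians.
    """

    p_female: float
    age_mean: float
    age_sd: float
    haq_median: float
    haq_sd: float
    smoking_probs: tuple[float, float, float]  # never, past, current
    p_acpa: float
    das28_mean: float
    das28_sd: float
    share_weights: tuple[float, float, float, float]
    share_concentration: float
    improvement_mean: float
    improvement_sd: float

    def validate(self) -> None:
        for name, p in [("p_female", self.p_female), ("p_acpa", self.p_acpa)]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a proportion in [0, 1], got {p}")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-9 or min(self.smoking_probs) < 0:
            raise ConfigError("smoking_probs must be non-negative and sum to 1")
        if min(self.share_weights) <= 0:
            raise ConfigError("share_weights must be positive")
        if self.das28_sd <= 0 or self.age_sd <= 0:
            raise ConfigError("scale parameters must be positive")


def _shares_from_medians(tender: float, swollen: float, ln_crp: float, vas: float) -> tuple:
    """Mean Dirichlet shares implied by group component medians."""
    contribs = np.array([
        0.56 * math.sqrt(tender),
        0.28 * math.sqrt(swollen),
        0.36 * math.log(math.exp(ln_crp) + 1.0),
        0.014 * vas,
    ])
    return tuple(contribs / contribs.sum())


def default_clinical_params() -> dict[str, GroupClinicalParams]:
    """Study-default clinical parameters for the two EULAR response groups."""
    return {
        "good": GroupClinicalParams(
            p_female=0.76,
            age_mean=59.0, age_sd=15.0,
            haq_median=1.18, haq_sd=(1.7 - 0.9) / 1.349,
            smoking_probs=(23 / 42, 11 / 42, 8 / 42),
            p_acpa=0.64,
            das28_mean=4.8, das28_sd=1.0,
            share_weights=_shares_from_medians(8, 5, 2.2, 44),
            share_concentration=60.0,
            improvement_mean=2.3, improvement_sd=0.7,
        ),
        "nonresponder": GroupClinicalParams(
            p_female=0.77,
            age_mean=55.0, age_sd=14.0,
            haq_median=1.0, haq_sd=(1.6 - 0.3) / 1.349,
            smoking_probs=(16 / 43, 17 / 43, 10 / 43),
            p_acpa=0.58,
            das28_mean=4.0, das28_sd=1.3,
            share_weights=_shares_from_medians(6, 3, 1.7, 32),
            share_concentration=60.0,
            improvement_mean=0.1, improvement_sd=0.5,
        ),
    }


@dataclass(frozen=True)
class ModuleSpec:
    """One planted coexpression module: size, within-module correlation target,
    and whether its latent factor is active in both groups or only in
    nonresponder samples."""

    size: int
    correlation: float
    restriction: str = "both"  # "both" | "nonresponder_only"

    def validate(self) -> None:
        if self.size <= 0:
            raise ConfigError("module size must be positive")
        if not 0.0 < self.correlation < 1.0:
            raise ConfigError("within-module correlation target must lie in (0, 1)")
        if self.restriction not in ("both", "nonresponder_only"):
            raise ConfigError(f"unknown module restriction {self.restriction!r}")


def _default_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec(200, 0.6, "both"),
        ModuleSpec(150, 0.6, "both"),
        ModuleSpec(100, 0.6, "both"),
        ModuleSpec(80, 0.6, "nonresponder_only"),
        ModuleSpec(60, 0.6, "nonresponder_only"),
    ]


@dataclass
class SimulationConfig:
    """Full synthetic-cohort configuration.

    Defaults reproduce the emulated study conditions: 42 good responders vs 43
    nonresponders, ~22,771 analysis-ready probes, planted modules at
    within-module correlation 0.6 (two of them nonresponder-specific), 50
    longitudinal signal genes at a standardized effect of 1.0 noise-SD in the
    week4-minus-pretreatment difference, and group-conditional clinical
    covariate distributions typical of an early-RA methotrexate cohort.
    """

    n_good: int = 42
    n_nonresponder: int = 43
    n_genes: int = 22771
    module_spec: list[ModuleSpec] = field(default_factory=_default_modules)
    n_signal_genes: int = 50
    signal_effect: float = 1.0
    noise_sd: float = 0.5
    frac_unexpressed: float = 0.01
    sample_offset_sd: float = 0.15
    baseline_mean: float = 7.5
    baseline_sd: float = 1.5
    clinical_params: dict[str, GroupClinicalParams] = field(default_factory=default_clinical_params)
    seed: int = 0

    def validate(self) -> None:
        for name, n in [("n_good", self.n_good), ("n_nonresponder", self.n_nonresponder),
                        ("n_genes", self.n_genes)]:
            if n <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_signal_genes < 0 or self.noise_sd <= 0:
            raise ConfigError("n_signal_genes must be >= 0 and noise_sd > 0")
        for spec in self.module_spec:
            spec.validate()
        n_module_genes = sum(m.size for m in self.module_spec)
        n_unexpressed = int(round(self.frac_unexpressed * self.n_genes))
        if n_module_genes + self.n_signal_genes + n_unexpressed > self.n_genes:
            raise ConfigError(
                f"module genes ({n_module_genes}) + signal genes ({self.n_signal_genes}) + "
                f"unexpressed genes ({n_unexpressed}) exceed n_genes ({self.n_genes}); "
                "planted modules are disjoint"
            )
        for group in ("good", "nonresponder"):
            if group not in self.clinical_params:
                raise ConfigError(f"clinical_params missing group {group!r}")
            self.clinical_params[group].validate()


@dataclass(frozen=True)
class DiseaseActivityRecord:
    """Component-level disease activity at one assessment."""

    tender28: int
    swollen28: int
    crp: float
    vas_global: float
    das28: float
    timepoint: str  # "baseline" | "month6"


@dataclass
class GroundTruth:
    """Planted structure returned alongside the simulated matrices."""

    module_labels: pd.Series  # gene -> planted module name or "grey"
    module_restrictions: dict[str, str]  # module name -> "both" | "nonresponder_only"
    signal_genes: list[str]
    unexpressed_genes: list[str]


@dataclass
class SimulatedCohort:
    expr_pre: ExpressionMatrix
    expr_wk4: ExpressionMatrix
    samples: SampleTable
    ground_truth: GroundTruth


def _calibrated_truncnorm_mean(target_mean: float, sd: float, lower: float) -> float:
    """Location parameter such that a normal truncated below at ``lower`` has
    the requested mean (compensates the upward truncation bias)."""
    def gap(mu: float) -> float:
        a = (lower - mu) / sd
        return stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd) - target_mean

    return float(optimize.brentq(gap, target_mean - 4 * sd, target_mean + sd))


# a DAS28 decomposition needs a strictly positive variable part
_DAS28_FLOOR = _DAS28_INTERCEPT + 0.02


def _decompose_das28(das28: np.ndarray, params: GroupClinicalParams, rng: np.random.Generator):
    """Split DAS28 scores into (tender, swollen, crp, vas) components.

    Each patient's variable part (score minus intercept) is allocated across
    the four terms with Dirichlet shares centered on the group's component
    medians, then inverted through the formula.  Joint counts are rounded and
    clipped to [0, 28]; the continuous components (VAS, then CRP) absorb the
    rounding residual, so the recomputed score equals the target except in the
    rare case where rounding overshoots a near-floor score.
    """
    n = das28.shape[0]
    amount = das28 - _DAS28_INTERCEPT
    shares = rng.dirichlet(params.share_concentration * np.asarray(params.share_weights), size=n)
    contrib = shares * amount[:, None]
    tender = np.clip(np.round((contrib[:, 0] / 0.56) ** 2), 0, 28).astype(int)
    swollen = np.clip(np.round((contrib[:, 1] / 0.28) ** 2), 0, 28).astype(int)
    remainder = amount - 0.56 * np.sqrt(tender) - 0.28 * np.sqrt(swollen)
    # CRP keeps its drawn share; VAS takes up the joint-count rounding error,
    # and CRP finally absorbs the VAS integer rounding
    vas = np.clip(np.round((remainder - contrib[:, 2]) / 0.014), 0, 100).astype(int)
    crp = np.maximum(np.expm1((remainder - 0.014 * vas) / 0.36), 0.0)
    return tender, swollen, crp, vas


def _truncnorm_sample(
    rng: np.random.Generator,
    loc: float,
    scale: float,
    lower,
    upper,
    size: int,
) -> np.ndarray:
    """Vectorized truncated-normal draws by inverse-CDF (bounds may be arrays)."""
    a = stats.norm.cdf((np.asarray(lower, dtype=float) - loc) / scale)
    b = stats.norm.cdf((np.asarray(upper, dtype=float) - loc) / scale)
    u = rng.uniform(np.broadcast_to(a, (size,)), np.broadcast_to(b, (size,)))
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return loc + scale * stats.norm.ppf(u)


def simulate_clinical(
    n_good: int,
    n_nonresponder: int,
    clinical_params: dict[str, GroupClinicalParams] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate per-patient baseline (and follow-up) clinical covariates.

    Returns one row per patient with response group, demographic covariates,
    baseline DAS28-CRP components, month-3 re-measurements of the time-varying
    covariates, and the month-6 DAS28 used for EULAR labeling.  The month-6
    improvement is drawn from its conditional distribution given the target
    EULAR category (good, or none for nonresponders), so baseline covariates
    stay unbiased and no moderate responders enter the emitted cohort,
    mirroring the two-group study design.
    """
    params_by_group = clinical_params or default_clinical_params()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if n_good <= 0 or n_nonresponder <= 0:
        raise ConfigError("group sizes must be positive")
    for group_params in params_by_group.values():
        group_params.validate()
    n_total = n_good + n_nonresponder
    # interleave group membership over lexicographic patient ids
    membership = np.array(["good"] * n_good + ["nonresponder"] * n_nonresponder)
    rng.shuffle(membership)
    width = max(3, len(str(n_total)))
    pids = np.array([f"P{i + 1:0{width}d}" for i in range(n_total)])

    frames = []
    for group in ("good", "nonresponder"):
        mask = membership == group
        n = int(mask.sum())
        p = params_by_group[group]

        # baseline DAS28 from the group's truncated, mean-calibrated normal;
        # a good responder needs room for >1.2 improvement above the score
        # floor even after component rounding shifts the recomputed score
        lower = _DAS28_FLOOR + 1.65 if group == "good" else _DAS28_FLOOR
        mu0 = _calibrated_truncnorm_mean(p.das28_mean, p.das28_sd, lower)
        das0 = _truncnorm_sample(rng, mu0, p.das28_sd, lower, np.inf, n)
        tender, swollen, crp, vas = _decompose_das28(das0, p, rng)
        # the component-consistent score is the patient's measured baseline
        das_rec = compute_das28_crp(tender, swollen, crp, vas)
        # month-6 improvement from its conditional given the target category:
        # good requires improvement > 1.2 with month-6 score <= 3.2;
        # nonresponse is realized as improvement <= 0.6 (EULAR "none")
        if group == "good":
            imp_lo = np.maximum(1.2, das_rec - 3.2) + 1e-9
            imp_hi = das_rec - _DAS28_FLOOR
        else:
            imp_lo = np.full(n, -np.inf)
            imp_hi = np.minimum(0.6, das_rec - _DAS28_FLOOR)
        improvement = _truncnorm_sample(rng, p.improvement_mean, p.improvement_sd,
                                        imp_lo, imp_hi, n)
        das6 = das_rec - improvement
        das3 = np.maximum(das_rec - 0.5 * improvement + rng.normal(0.0, 0.25, n), _DAS28_FLOOR)
        t3, s3, c3, v3 = _decompose_das28(das3, p, rng)
        haq = np.clip(rng.normal(p.haq_median, p.haq_sd, n), 0.0, 3.0)

        frames.append(pd.DataFrame({
            "patient_id": pids[mask],
            "response": group,
            "sex": np.where(rng.random(n) < p.p_female, "female", "male"),
            "age_at_onset": np.clip(rng.normal(p.age_mean, p.age_sd, n), 18.0, 95.0),
            "haq": haq,
            "smoking": np.array(("never", "past", "current"))[
                rng.choice(3, size=n, p=p.smoking_probs)],
            "acpa_positive": rng.random(n) < p.p_acpa,
            "tender28": tender,
            "swollen28": swollen,
            "crp": crp,
            "vas_global": vas.astype(float),
            "das28_baseline": das_rec,
            "das28_month6": das6,
            "haq_3mo": np.clip(haq - 0.15 * improvement + rng.normal(0.0, 0.15, n), 0.0, 3.0),
            "tender28_3mo": t3,
            "swollen28_3mo": s3,
            "crp_3mo": c3,
            "vas_global_3mo": v3.astype(float),
        }))
    out = pd.concat(frames, ignore_index=True).sort_values("patient_id").reset_index(drop=True)
    categories = [eular_category(b, m) for b, m in zip(out["das28_baseline"], out["das28_month6"])]
    expected = ["good" if r == "good" else "none" for r in out["response"]]
    if categories != expected:  # pragma: no cover - decomposition rounding guard
        bad = [i for i, (c, e) in enumerate(zip(categories, expected)) if c != e]
        raise ConfigError(f"EULAR category not realized for {len(bad)} patient(s)")
    return out


def _patient_frame_to_sample_table(patients: pd.DataFrame) -> SampleTable:
    """Expand the per-patient frame to two sample rows (pre, week 4) each."""
    rows = []
    for r in patients.itertuples():
        for tp, suffix in [("pretreatment", "pre"), ("week4", "wk4")]:
            rows.append({
                "sample_id": f"{r.patient_id}-{suffix}",
                "patient_id": r.patient_id,
                "timepoint": tp,
                "response": r.response,
                "sex": r.sex,
                "age_at_onset": r.age_at_onset,
                "haq": r.haq,
                "smoking": r.smoking,
                "acpa_positive": r.acpa_positive,
                "swollen28": r.swollen28,
                "tender28": r.tender28,
                "crp": r.crp,
                "vas_global": r.vas_global,
                "das28_baseline": r.das28_baseline,
                "das28_month6": r.das28_month6,
                "haq_3mo": r.haq_3mo,
                "swollen28_3mo": r.swollen28_3mo,
                "tender28_3mo": r.tender28_3mo,
                "crp_3mo": r.crp_3mo,
                "vas_global_3mo": r.vas_global_3mo,
            })
    return SampleTable(pd.DataFrame(rows))


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate paired pretreatment / week-4 expression matrices plus metadata.

    Expression model (log2 scale): per-gene baseline mean + planted latent
    factors + per-sample array offset + i.i.d. Gaussian noise.  Genes of a
    planted module load on a shared standard-normal factor with loading
    ``noise_sd * sqrt(rho / (1 - rho))``, which calibrates the expected
    within-module Pearson correlation to the target ``rho``.  Factors of
    nonresponder-restricted modules are active only in nonresponder samples.
    Signal genes receive a mean shift in the week-4 minus pretreatment
    difference for nonresponders equal to ``signal_effect`` standard deviations
    of that difference (a standardized effect size).  A small fraction
    of probes is simulated as unexpressed (low intensity everywhere) to give
    the QC stage something to remove.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_clin, rng_expr = (np.random.default_rng(s) for s in ss.spawn(2))

    patients = simulate_clinical(config.n_good, config.n_nonresponder,
                                 config.clinical_params, rng_clin)
    patients = patients.sort_values("patient_id").reset_index(drop=True)
    samples = _patient_frame_to_sample_table(patients)
    is_nonresponder = (patients["response"] == "nonresponder").to_numpy()
    n_patients = len(patients)

    n_genes = config.n_genes
    width = max(5, len(str(n_genes)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    n_unexpressed = int(round(config.frac_unexpressed * n_genes))

    # gene layout: [module blocks][signal genes][background][unexpressed]
    module_labels = pd.Series("grey", index=gene_ids, name="module")
    restrictions: dict[str, str] = {}
    cursor = 0
    module_slices: list[tuple[str, slice, ModuleSpec]] = []
    for i, spec in enumerate(config.module_spec):
        name = f"planted{i + 1}"
        sl = slice(cursor, cursor + spec.size)
        module_labels.iloc[sl] = name
        restrictions[name] = spec.restriction
        module_slices.append((name, sl, spec))
        cursor += spec.size
    signal_genes = gene_ids[cursor:cursor + config.n_signal_genes]
    signal_slice = slice(cursor, cursor + config.n_signal_genes)
    unexpressed_genes = gene_ids[n_genes - n_unexpressed:] if n_unexpressed else []

    mu = rng_expr.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    mu = np.maximum(mu, 6.0)
    if n_unexpressed:
        mu[n_genes - n_unexpressed:] = rng_expr.normal(3.0, 0.2, size=n_unexpressed)

    sd = config.noise_sd
    matrices = {}
    for tp in ("pre", "wk4"):
        x = mu[:, None] + rng_expr.normal(0.0, sd, size=(n_genes, n_patients))
        x += rng_expr.normal(0.0, config.sample_offset_sd, size=n_patients)[None, :]
        for name, sl, spec in module_slices:
            loading = sd * math.sqrt(spec.correlation / (1.0 - spec.correlation))
            factor = rng_expr.normal(0.0, 1.0, size=n_patients)
            if spec.restriction == "nonresponder_only":
                factor = np.where(is_nonresponder, factor, 0.0)
            x[sl, :] += loading * factor[None, :]
        if tp == "wk4" and config.n_signal_genes:
            # signal_effect is the standardized mean difference of the week4
            # minus pretreatment delta between groups; the delta of a
            # background gene has variance 2*(noise_sd^2 + sample_offset_sd^2)
            delta_sd = math.sqrt(2.0 * (sd**2 + config.sample_offset_sd**2))
            x[signal_slice, :] += (config.signal_effect * delta_sd) * is_nonresponder[None, :]
        matrices[tp] = x

    pre_cols = [f"{pid}-pre" for pid in patients["patient_id"]]
    wk4_cols = [f"{pid}-wk4" for pid in patients["patient_id"]]
    expr_pre = ExpressionMatrix(
        pd.DataFrame(matrices["pre"], index=gene_ids, columns=pre_cols), "log2")
    expr_wk4 = ExpressionMatrix(
        pd.DataFrame(matrices["wk4"], index=gene_ids, columns=wk4_cols), "log2")

    truth = GroundTruth(
        module_labels=module_labels,
        module_restrictions=restrictions,
        signal_genes=signal_genes,
        unexpressed_genes=unexpressed_genes,
    )
    return SimulatedCohort(expr_pre, expr_wk4, samples, truth)
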