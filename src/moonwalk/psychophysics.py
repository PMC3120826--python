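"""Simulated depth-order psychophysics and the accompanying statistics.

Human observers reported whether the moving center appeared far or near as
the surround's temporal coherence varied.  This module replaces the human
subjects with a simulated population: each simulated subject reports
"center far" with probability given by a logistic psychometric function of
temporal coherence (plus a per-subject random intercept), optionally gated
by an extraneous center/surround segmentation cue (a contrast difference).

Analyses mirror the study's statistics: a maximum-likelihood logistic
regression (IRLS) with an r-squared defined as the squared Pearson
correlation between per-condition observed proportions and fitted
probabilities, an exact two-sided binomial proportions test, and a Pearson
chi-square goodness-of-fit check of residual normality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .stimgen import StimulusSpec, generate_sequence, set_region_contrast
from . import ideal_observer as io_mod

__all__ = [
    "PsychometricModel",
    "GatingPsychometricModel",
    "ExperimentDesign",
    "FitResult",
    "SeparationError",
    "simulate_responses",
    "fit_logistic",
    "binomial_proportions_test",
    "residual_normality_chisq",
    "run_experiment_2",
    "EXPERIMENT2_CONDITIONS",
]

#: Segmentation-cue arms of the contrast-gating experiment.
EXPERIMENT2_CONDITIONS = ("none", "low-surround", "low-center")


class SeparationError(ValueError):
    """Raised when logistic data are degenerate (single level or separated)."""


@dataclass(frozen=True)
class PsychometricModel:
    """Logistic psychometric function of temporal coherence (in percent).

    P(report far | coherence c) = lapse/2 + (1 - lapse) * logistic(b0 + b1*c).
    """

    beta0: float = -20.0
    beta1: float = 0.25  # per percentage point of coherence
    lapse_rate: float = 0.02

    def __post_init__(self):
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must be in [0, 0.1]")

    def p_far(self, coherence_pct, extra_intercept=0.0) -> np.ndarray:
        eta = self.beta0 + self.beta1 * np.asarray(coherence_pct, dtype=float)
        p = expit(eta + extra_intercept)
        return self.lapse_rate / 2.0 + (1.0 - self.lapse_rate) * p


@dataclass(frozen=True)
class GatingPsychometricModel(PsychometricModel):
    """Psychometric model with a segmentation-cue ('gating') boost.

    When an extraneous segmentation cue delineates the occluder (a contrast
    difference between center and surround), the far interpretation is
    restored regardless of flicker; ``segmentation_boost`` is added to the
    linear predictor whenever such a cue is present.
    """

    segmentation_boost: float = 15.0

    def p_far(self, coherence_pct, extra_intercept=0.0, segmented=False):
        boost = self.segmentation_boost if segmented else 0.0
        return super().p_far(coherence_pct, extra_intercept + boost)


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial-table layout for a simulated psychophysics session.

    Coherence levels, trial counts and the subject count are the package's
    defaults for a session emulating an 11-subject study; trial order is a
    seeded random permutation (all trials randomly interleaved).
    """

    coherences_pct: tuple = (50.0, 60.0, 70.0, 80.0, 90.0, 100.0)
    contrast_conditions: tuple = ("none",)
    directions_deg: tuple = (0.0, 90.0, 180.0, 270.0)
    n_subjects: int = 11
    n_trials_per_condition: int = 20
    subject_intercept_sd: float = 0.5


@dataclass
class FitResult:
    """Outcome of a logistic psychometric fit."""

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    r_squared: float
    residuals: np.ndarray  # per-condition Pearson residuals
    fitted: pd.DataFrame  # coherence_pct, n, k_far, p_obs, p_fit
    converged: bool
    r_squared_definition: str = (
        "squared Pearson correlation between per-condition observed "
        "proportions and fitted probabilities"
    )

    def wald_interval(self, which: int = 1, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        b, se = ((self.beta0, self.se_beta0), (self.beta1, self.se_beta1))[which]
        return (b - z * se, b + z * se)


# ---------------------------------------------------------------------------
# simulation


def simulate_responses(
    model: PsychometricModel, design: ExperimentDesign, seed: int = 0
) -> pd.DataFrame:
    """Draw one Bernoulli trial table from the psychometric model.

    Returns a DataFrame with columns subject_id, coherence_pct, condition,
    direction_deg, report ('far'/'near'), in seeded randomly interleaved
    order.  Per-subject intercepts are Normal(0, subject_intercept_sd).
    """
    rng = np.random.default_rng(seed)
    intercepts = rng.normal(0.0, design.subject_intercept_sd, design.n_subjects)
    rows = []
    for subj in range(design.n_subjects):
        for cond in design.contrast_conditions:
            for coh in design.coherences_pct:
                n = design.n_trials_per_condition
                segmented = cond != "none"
                if isinstance(model, GatingPsychometricModel):
                    p = model.p_far(coh, intercepts[subj], segmented=segmented)
                else:
                    p = model.p_far(coh, intercepts[subj])
                reports = rng.random(n) < p
                directions = rng.choice(design.directions_deg, size=n)
                for rep, direc in zip(reports, directions):
                    rows.append((subj, float(coh), cond, float(direc), "far" if rep else "near"))
    df = pd.DataFrame(
        rows, columns=["subject_id", "coherence_pct", "condition", "direction_deg", "report"]
    )
    order = rng.permutation(len(df))
    return df.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# fitting and tests


def _condition_table(dataset: pd.DataFrame) -> pd.DataFrame:
    g = dataset.assign(far=(dataset["report"] == "far").astype(int)).groupby(
        "coherence_pct", as_index=False
    )["far"]
    tab = g.agg(k_far="sum", n="count")
    tab["p_obs"] = tab["k_far"] / tab["n"]
    return tab


def fit_logistic(dataset: pd.DataFrame) -> FitResult:
    """Maximum-likelihood logistic regression of 'far' reports on coherence.

    Fits by iteratively reweighted least squares on the per-condition
    binomial counts.  Degenerate inputs — fewer than two coherence levels,
    or only one response category overall (complete separation) — raise
    :class:`SeparationError` instead of returning a silent fit.
    """
    tab = _condition_table(dataset)
    if len(tab) < 2:
        raise SeparationError("need at least two distinct coherence levels")
    total_far = tab["k_far"].sum()
    total = tab["n"].sum()
    if total_far == 0 or total_far == total:
        raise SeparationError("all responses identical: logistic fit is separated")
    endog = np.column_stack([tab["k_far"], tab["n"] - tab["k_far"]])
    exog = sm.add_constant(tab["coherence_pct"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    converged = bool(res.converged) and bool(np.all(np.isfinite(bse)))
    p_fit = np.asarray(res.predict(exog), dtype=float)
    tab = tab.assign(p_fit=p_fit)
    if np.std(tab["p_obs"]) == 0 or np.std(p_fit) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(tab["p_obs"], p_fit)[0, 1] ** 2)
    pearson_resid = (tab["k_far"] - tab["n"] * p_fit) / np.sqrt(
        tab["n"] * p_fit * (1.0 - p_fit)
    )
    return FitResult(
        beta0=params[0],
        beta1=params[1],
        se_beta0=bse[0],
        se_beta1=bse[1],
        r_squared=r2,
        residuals=pearson_resid.to_numpy(),
        fitted=tab,
        converged=converged,
    )


def binomial_proportions_test(k_far: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test (minimum-likelihood method).

    Two-sided p-value: the sum of probabilities of all outcomes no more
    likely than the observed count under Binomial(n, p0).
    """
    if not (0 <= k_far <= n):
        raise ValueError("k_far must lie in [0, n]")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    return float(stats.binomtest(k_far, n, p0).pvalue)


def residual_normality_chisq(residuals: np.ndarray, n_bins: int = 10) -> float:
    """Pearson chi-square test of standardized residuals against N(0, 1).

    Residuals are standardized by their sample mean and SD and binned into
    equal-probability normal bins; bins are reduced until every expected
    count reaches 5.  Degrees of freedom are bins - 3 (two estimated
    parameters).  Raises if too few residuals remain for at least 4 bins.
    """
    x = np.asarray(residuals, dtype=float)
    n = x.size
    k = min(int(n_bins), n // 5)  # expected count n/k >= 5
    if k < 4:
        raise ValueError(
            f"{n} residuals are too few for a chi-square normality test "
            "(need at least 20 for 4 bins with expected counts of 5)"
        )
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("residuals are constant")
    z = (x - x.mean()) / sd
    edges = stats.norm.ppf(np.linspace(0.0, 1.0, k + 1))
    observed, _ = np.histogram(z, bins=edges)
    expected = n / k
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = k - 3
    return float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# contrast-gating experiment


def run_experiment_2(
    seed: int = 0,
    base_spec: StimulusSpec | None = None,
    model: GatingPsychometricModel | None = None,
    design: ExperimentDesign | None = None,
    low_contrast: float = 0.25,
    run_ideal_observer: bool = True,
) -> pd.DataFrame:
    """Simulate the contrast-gating experiment on six stimulus conditions.

    Conditions are {no manipulation, low-contrast surround, low-contrast
    center} x {static (100%), flickery (50%)} surrounds.  Each stimulus is
    synthesized, optionally passed through the Ideal Observer (whose
    evidence region excludes the surround, so its decision is F, center
    far, throughout), and observer reports are simulated from a
    gating-aware psychometric model.  Returns one row per condition with
    the proportion of 'far' reports.
    """
    base_spec = base_spec if base_spec is not None else StimulusSpec()
    model = model if model is not None else GatingPsychometricModel()
    design = design if design is not None else ExperimentDesign(
        coherences_pct=(50.0, 100.0), contrast_conditions=EXPERIMENT2_CONDITIONS
    )
    rng = np.random.default_rng(seed)
    intercepts = rng.normal(0.0, design.subject_intercept_sd, design.n_subjects)

    rows = []
    for cond in design.contrast_conditions:
        if cond not in EXPERIMENT2_CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
        for coh in design.coherences_pct:
            decision = None
            if run_ideal_observer:
                spec = dc_replace(
                    base_spec,
                    surround_temporal_coherence=float(coh) / 100.0,
                    rng_seed=int(rng.integers(0, 2**31 - 1)),
                )
                seq = generate_sequence(spec)
                if cond == "low-surround":
                    seq = set_region_contrast(seq, "surround", low_contrast)
                elif cond == "low-center":
                    seq = set_region_contrast(seq, "center", low_contrast)
                decision, _ = io_mod.decide(seq)
            segmented = cond != "none"
            n_total = 0
            k_far = 0
            for subj in range(design.n_subjects):
                p = model.p_far(coh, intercepts[subj], segmented=segmented)
                n = design.n_trials_per_condition
                k_far += int((rng.random(n) < p).sum())
                n_total += n
            rows.append(
                {
                    "condition": cond,
                    "coherence_pct": float(coh),
                    "k_far": k_far,
                    "n_trials": n_total,
                    "p_far": k_far / n_total,
                    "ideal_observer": decision,
                }
            )
    return pd.DataFrame(rows)
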