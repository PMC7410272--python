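"""Peak extraction, trial aggregation and statistical comparison of loads.

The aggregation contract is mean-of-peaks: peaks are extracted per trial and
then averaged over the (nominally three) trials of a subject x activity x
model x level condition, never the other way round.  Group comparisons run on
log-transformed peaks with a per-modality linear mixed model (subject random
intercept); contrasts are exponentiated to percent-of-intact.  A one-sided
one-sample Wilcoxon signed-rank test compares observed medians to published
thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from oiload.errors import DegenerateDataError, InvalidInputError
from oiload.inverse_dynamics import LoadSeries

MODALITIES = ("bending", "torsion", "axial")
TRIALS_PER_CONDITION = 3


@dataclass(frozen=True)
class PeakLoads:
    """Per-trial (or trial-averaged) peak loads for one condition."""

    subject_id: str
    activity: str
    model_variant: str  # "intact" or a prosthesis category
    level: float
    bending_peak: float  # N.m
    torsion_peak: float  # N.m
    axial_peak: float  # N
    trial_index: int = 0

    def __post_init__(self) -> None:
        for name in ("bending_peak", "torsion_peak", "axial_peak"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidInputError(f"{name} must be finite")
        if self.bending_peak < 0 or self.torsion_peak < 0:
            raise InvalidInputError("moment peaks must be >= 0")

    def value(self, modality: str) -> float:
        return {"bending": self.bending_peak, "torsion": self.torsion_peak,
                "axial": self.axial_peak}[modality]

    @property
    def condition_key(self) -> tuple:
        return (self.subject_id, self.activity, self.model_variant, self.level)


@dataclass(frozen=True)
class ComparisonResult:
    """One exponentiated mixed-model contrast, in percent of the reference."""

    label: str
    modality: str
    percent_estimate: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.percent_estimate > 0:
            raise InvalidInputError("percent_estimate must be > 0")
        if not (self.ci_low <= self.percent_estimate <= self.ci_high):
            raise InvalidInputError("confidence bounds must bracket estimate")


def extract_peaks(loads: LoadSeries, subject_id: str = "", activity: str = "",
                  model_variant: str = "intact", level: float = 0.0,
                  trial_index: int = 0,
                  axial_convention: str = "tensile") -> PeakLoads:
    """Per-modality maxima of a load series.

    Bending/torsion use the series maximum; axial uses the tensile maximum
    under the default convention, or the absolute maximum with
    ``axial_convention='absolute'``.
    """
    if loads.n_samples == 0:
        raise InvalidInputError("empty load series")
    if axial_convention == "tensile":
        axial = float(np.max(loads.axial))
    elif axial_convention == "absolute":
        axial = float(np.max(np.abs(loads.axial)))
    else:
        raise InvalidInputError(
            f"unknown axial convention {axial_convention!r}")
    return PeakLoads(subject_id=subject_id, activity=activity,
                     model_variant=model_variant, level=level,
                     bending_peak=float(np.max(loads.bending)),
                     torsion_peak=float(np.max(loads.torsion)),
                     axial_peak=axial, trial_index=trial_index)


def aggregate_trials(peaks: list[PeakLoads],
                     allow_partial: bool = False) -> PeakLoads:
    """Arithmetic mean of per-trial peaks for one condition (mean-of-peaks)."""
    if not peaks:
        raise InvalidInputError("no peaks to aggregate")
    keys = {p.condition_key for p in peaks}
    if len(keys) != 1:
        raise InvalidInputError(
            f"cannot aggregate across conditions: {sorted(keys)}")
    if len(peaks) != TRIALS_PER_CONDITION and not allow_partial:
        raise InvalidInputError(
            f"expected {TRIALS_PER_CONDITION} trials, got {len(peaks)}; "
            "pass allow_partial=True to aggregate anyway")
    return replace(
        peaks[0],
        bending_peak=float(np.mean([p.bending_peak for p in peaks])),
        torsion_peak=float(np.mean([p.torsion_peak for p in peaks])),
        axial_peak=float(np.mean([p.axial_peak for p in peaks])),
        trial_index=-1)


def percent_vs_intact(prosthetic_mean: float, intact_mean: float) -> float:
    """Prosthetic load as a percentage of the intact reference (100 %)."""
    if not intact_mean > 0:
        raise InvalidInputError(
            "intact reference must be > 0 for a percent ratio")
    return 100.0 * prosthetic_mean / intact_mean


def peaks_to_dataframe(peaks: list[PeakLoads]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": p.subject_id, "activity": p.activity,
        "model_variant": p.model_variant, "level": p.level,
        "trial_index": p.trial_index, "bending_peak": p.bending_peak,
        "torsion_peak": p.torsion_peak, "axial_peak": p.axial_peak,
    } for p in peaks])


def fit_log_mixed_model(peak_table: pd.DataFrame,
                        reference: str = "intact") -> list[ComparisonResult]:
    """Per-modality mixed model on log(peak) with subject random intercept.

    Fixed effects: model_variant (treatment-coded against ``reference``) plus
    level and activity when they vary.  Each prosthetic-variant coefficient is
    exponentiated into a percent-of-reference estimate with 95 % CI and
    p-value.  A singular or failed mixed fit falls back (with a warning) to a
    fixed-effects-only OLS fit.
    """
    import statsmodels.formula.api as smf

    df = peak_table.copy()
    if df["subject_id"].nunique() < 2:
        raise InvalidInputError("need >= 2 subjects for a mixed model")
    variants = [v for v in df["model_variant"].unique() if v != reference]
    if not variants:
        return []
    if reference not in set(df["model_variant"]):
        raise InvalidInputError(f"reference variant {reference!r} missing")

    terms = [f"C(model_variant, Treatment('{reference}'))"]
    if df["level"].nunique() > 1:
        terms.append("C(level)")
    if df["activity"].nunique() > 1:
        terms.append("C(activity)")
    rhs = " + ".join(terms)

    results: list[ComparisonResult] = []
    for modality in MODALITIES:
        col = f"{modality}_peak"
        sub = df[df[col] > 0].copy()
        sub["log_peak"] = np.log(sub[col])
        fit = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = smf.mixedlm(f"log_peak ~ {rhs}", sub,
                                 groups=sub["subject_id"])
                fit = md.fit(reml=True, method="lbfgs")
                if np.any(np.isnan(fit.bse.values)):
                    fit = None
            except Exception:
                fit = None
        if fit is None:
            warnings.warn(
                f"{modality}: singular mixed fit, falling back to "
                "fixed-effects-only OLS", RuntimeWarning, stacklevel=2)
            fit = smf.ols(f"log_peak ~ {rhs}", sub).fit()
        ci = fit.conf_int()
        for variant in variants:
            name = (f"C(model_variant, Treatment('{reference}'))"
                    f"[T.{variant}]")
            if name not in fit.params.index:
                continue
            beta = fit.params[name]
            lo, hi = ci.loc[name]
            results.append(ComparisonResult(
                label=f"{variant}_vs_{reference}", modality=modality,
                percent_estimate=100.0 * float(np.exp(beta)),
                ci_low=100.0 * float(np.exp(lo)),
                ci_high=100.0 * float(np.exp(hi)),
                p_value=float(fit.pvalues[name])))
    return results


def wilcoxon_vs_threshold(values, threshold: float,
                          direction: str = "greater") -> float:
    """One-sided one-sample Wilcoxon signed-rank p-value against a threshold.

    Exact null enumeration for n <= 25 (no ties), normal approximation with
    continuity correction beyond.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 5:
        raise InvalidInputError("need at least 5 values")
    if direction not in ("greater", "less"):
        raise InvalidInputError("direction must be 'greater' or 'less'")
    diffs = values - threshold
    nonzero = diffs[diffs != 0.0]
    if len(nonzero) == 0:
        raise DegenerateDataError("all values equal the threshold")
    ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(nonzero, alternative=direction, method=method,
                         correction=(method == "approx"))
    return float(res.pvalue)
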