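"""Full-vs-subset model comparison and population statistics.

Model accuracy is the Pearson correlation R between the out-of-fold
predicted spike probability and the Gaussian-smoothed observed rate,
computed over contact bins only: contact-driven primary afferents are
silent between contacts, and including the trivially predictable silent
bins would inflate R.  Subset models (mechanical-only, kinematic-only) are
compared to the full six-predictor model two ways: the coefficient of
determination R^2 between the two predicted probability series (how much of
the full model's information the subset retains — not accuracy), and the
percent difference 100*(R_full - R_subset)/R_full.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ComparisonResult",
    "CouplingProfile",
    "UndefinedCorrelation",
    "pearson_contact",
    "subset_full_r2",
    "percent_error",
    "aggregate_betas",
    "coupling_profile",
    "population_stats",
]


class UndefinedCorrelation(ValueError):
    """A correlation was requested for a constant series on the mask."""


@dataclass
class ComparisonResult:
    """Per-neuron accuracy metrics for the full and subset models."""

    neuron_id: int
    r_full: float
    r_mech: float
    r_kin: float
    r2_mech_vs_full: float
    r2_kin_vs_full: float
    preparation: str = "anesthetized"  # "anesthetized" (passive) | "awake" (active)
    excluded: bool = False

    @property
    def pct_err_mech(self) -> float:
        return percent_error(self.r_full, self.r_mech)

    @property
    def pct_err_kin(self) -> float:
        return percent_error(self.r_full, self.r_kin)


@dataclass
class CouplingProfile:
    """Pairwise |Pearson r| among contact-bin predictors plus input ranges."""

    names: tuple
    abs_corr: np.ndarray           # (6, 6), symmetric, diag 1; NaN = undefined
    theta_range_deg: float
    r_range_mm: float
    n_contact_bins: int

    def pair(self, a: str, b: str) -> float:
        return float(self.abs_corr[self.names.index(a), self.names.index(b)])


def _masked_pair(x, y, mask):
    x = np.asarray(x, dtype=float)[mask]
    y = np.asarray(y, dtype=float)[mask]
    if x.size == 0:
        raise UndefinedCorrelation("empty contact mask")
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        raise UndefinedCorrelation("constant series on the contact mask")
    return x, y


def pearson_contact(predicted, rate, mask) -> float:
    """Pearson R between predicted probability and observed rate, contact only."""
    x, y = _masked_pair(predicted, rate, np.asarray(mask, dtype=bool))
    return float(stats.pearsonr(x, y).statistic)


def subset_full_r2(subset_pred, full_pred, mask) -> float:
    """Squared Pearson correlation between subset and full model predictions.

    Measures how much of the full model's predicted structure the subset
    carries — not how well either predicts the neuron.
    """
    return pearson_contact(subset_pred, full_pred, mask) ** 2


def percent_error(r_full: float, r_subset: float) -> float:
    """100 * (R_full - R_subset) / R_full; negative when the subset wins."""
    if r_full == 0:
        raise UndefinedCorrelation("percent error undefined for R_full = 0")
    return 100.0 * (r_full - r_subset) / r_full


def aggregate_betas(fits, outlier_threshold: float = 1e3):
    """Elementwise mean |beta_lj| across neurons, dropping pathological fits.

    Fits whose largest |beta| exceeds ``outlier_threshold`` (runaway
    coefficients from separation) are excluded.  Returns (mean_abs (L, K),
    n_retained).
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    shape = fits[0].beta.shape
    names = fits[0].predictor_names
    kept = []
    for f in fits:
        if f.beta.shape != shape or f.predictor_names != names:
            raise ValueError("fits disagree on basis or predictor order")
        if np.max(np.abs(f.coef)) <= outlier_threshold:
            kept.append(np.abs(f.beta))
    if not kept:
        raise ValueError("all fits excluded by the outlier rule")
    return np.mean(kept, axis=0), len(kept)


def coupling_profile(predictors) -> CouplingProfile:
    """Absolute pairwise correlations among the six predictors on contact bins.

    Large decoupled stimulation regimes show low |corr| between angle and
    moment; narrow small-angle regimes show |corr| near 1 (the collinearity
    that prevents discriminating mechanical from kinematic coding).
    """
    mask = np.asarray(predictors.contact, dtype=bool)
    if mask.sum() < 100:
        raise ValueError("need at least 100 contact bins")
    vals = predictors.values[mask]
    k = vals.shape[1]
    corr = np.full((k, k), np.nan)
    sds = vals.std(axis=0)
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(vals.T)
    for i in range(k):
        for j in range(k):
            if sds[i] > 1e-15 and sds[j] > 1e-15:
                corr[i, j] = abs(c[i, j])
    from .predictors import PREDICTOR_NAMES

    names = PREDICTOR_NAMES
    theta = vals[:, 4]
    r_mm = vals[:, 3]
    return CouplingProfile(
        names=names, abs_corr=corr,
        theta_range_deg=float(theta.max() - theta.min()),
        r_range_mm=float(r_mm.max() - r_mm.min()),
        n_contact_bins=int(mask.sum()),
    )


@dataclass
class PopulationReport:
    n_input: int
    n_retained: int
    excluded_ids: list = field(default_factory=list)
    median_r_full: float = np.nan
    ranksum_p_awake_vs_anesthetized: float | None = None
    signed_rank_p_pct_err: dict = field(default_factory=dict)
    paired_t_p_mech_vs_kin: float | None = None
    below_diagonal_fraction: float = np.nan
    slope: float = np.nan
    slope_ci: tuple = (np.nan, np.nan)


def population_stats(results, min_group: int = 5) -> PopulationReport:
    """Population-level tests of the mechanics-vs-kinematics comparison.

    Applies the exclusion rule (drop neurons whose full model does worse
    than both subset models), then computes: a rank-sum test between
    preparations on R_full; a signed-rank test between mechanical and
    kinematic percent errors within each preparation; a paired t-test and
    below-diagonal fraction for R_mech vs R_kin; the median R_full; and an
    OLS slope of R_kin on R_mech with a normal-theory 95% CI.  Tests whose
    group is smaller than ``min_group`` are reported as None.
    """
    import statsmodels.api as sm

    excluded = [r.neuron_id for r in results
                if r.r_full < r.r_mech and r.r_full < r.r_kin]
    kept = [r for r in results if r.neuron_id not in excluded]
    rep = PopulationReport(n_input=len(results), n_retained=len(kept),
                           excluded_ids=excluded)
    if not kept:
        return rep
    r_full = np.array([r.r_full for r in kept])
    r_mech = np.array([r.r_mech for r in kept])
    r_kin = np.array([r.r_kin for r in kept])
    rep.median_r_full = float(np.median(r_full))

    awake = [r for r in kept if r.preparation == "awake"]
    anesth = [r for r in kept if r.preparation == "anesthetized"]
    if len(awake) >= min_group and len(anesth) >= min_group:
        rep.ranksum_p_awake_vs_anesthetized = float(
            stats.ranksums([r.r_full for r in awake],
                           [r.r_full for r in anesth]).pvalue)

    for prep, group in (("awake", awake), ("anesthetized", anesth)):
        if len(group) >= min_group:
            pe_m = [r.pct_err_mech for r in group]
            pe_k = [r.pct_err_kin for r in group]
            diffs = np.asarray(pe_m) - np.asarray(pe_k)
            if np.all(diffs == 0):
                rep.signed_rank_p_pct_err[prep] = 1.0
            else:
                rep.signed_rank_p_pct_err[prep] = float(
                    stats.wilcoxon(pe_m, pe_k).pvalue)

    if len(kept) >= min_group:
        if np.any(r_mech != r_kin):
            rep.paired_t_p_mech_vs_kin = float(stats.ttest_rel(r_mech, r_kin).pvalue)
        non_tied = r_mech != r_kin
        if non_tied.any():
            rep.below_diagonal_fraction = float(
                np.mean(r_kin[non_tied] < r_mech[non_tied]))
        if np.std(r_mech) > 1e-12:
            ols = sm.OLS(r_kin, sm.add_constant(r_mech)).fit()
            rep.slope = float(ols.params[1])
            ci = ols.conf_int(alpha=0.05)
            rep.slope_ci = (float(ci[1][0]), float(ci[1][1]))
    return rep
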