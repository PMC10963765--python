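"""Two-sample MR estimators, sensitivity diagnostics and power.

Notation follows the summary-data MR literature: instrument j has exposure
association b_Xj (SE s_Xj) and outcome association b_Yj (SE s_Yj), all aligned
to a common effect allele. The causal effect of a 1-SD exposure change is
estimated by:

* the Wald ratio b_Yj / b_Xj for a single instrument,
* inverse-variance-weighted regression through the origin with multiplicative
  random effects (IVW-RE) as the primary multi-instrument model,
* the weighted median (consistent when >=50% of weight is valid),
* the mode-based estimate (consistent when the largest homogeneous cluster of
  ratio estimates is valid), and
* MR-Egger regression, whose intercept tests directional pleiotropy.

Random-effects dialect: the fixed-effect SE is multiplied by the residual
standard deviation max(1, sqrt(Q / df)) — standard errors are inflated under
over-dispersion, never shrunk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_summary import ConfigurationError, HarmonisedSet, InputError

Z95 = float(stats.norm.ppf(0.975))


class InsufficientInstrumentsError(InputError):
    """Fewer instruments than the estimator requires."""


@dataclass
class MREstimate:
    method: str  # wald | ivw_re | wme | mbe | egger_slope
    beta: float
    se: float
    pvalue: float
    n_snp: int
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if np.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se

    @property
    def or_sd(self) -> float:
        """exp(beta): odds ratio per SD for binary outcomes."""
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_true: bool
    pvalue: float


@dataclass
class InstrumentStrength:
    f: np.ndarray          # per-variant F = (b_X / s_X)^2
    pve: np.ndarray        # per-variant variance explained 2p(1-p)b^2
    mean_f: float
    total_pve: float


@dataclass
class PowerEstimate:
    power: float
    alpha: float
    beta: float
    pve: float
    n: int
    case_fraction: float


def _norm_p(z) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def wald_ratio(b_x: float, s_x: float, b_y: float, s_y: float) -> MREstimate:
    """Single-instrument causal estimate b_Y / b_X.

    The SE uses the first-order delta method, s_Y / |b_X|, ignoring
    exposure-side uncertainty.
    """
    if b_x == 0:
        raise InputError("Wald ratio undefined: exposure effect is zero")
    beta = b_y / b_x
    se = s_y / abs(b_x)
    return MREstimate("wald", beta, se, _norm_p(beta / se), n_snp=1)


def _ivw_core(b_x, b_y, s_y):
    w = 1.0 / s_y**2
    denom = float(np.sum(w * b_x**2))
    beta = float(np.sum(w * b_x * b_y)) / denom
    se_fixed = 1.0 / np.sqrt(denom)
    q = float(np.sum(w * (b_y - beta * b_x) ** 2))
    return beta, se_fixed, q, w


def ivw_random_effects(h: HarmonisedSet) -> MREstimate:
    """IVW with multiplicative random effects.

    Weighted regression of b_Y on b_X through the origin with weights
    1/s_Y^2; the fixed-effect SE is inflated by sqrt(Q/(J-1)) when the
    heterogeneity statistic exceeds its degrees of freedom.
    """
    b_x, _, b_y, s_y = h.arrays()
    j = len(b_x)
    if j < 2:
        raise InsufficientInstrumentsError("IVW requires >= 2 instruments")
    beta, se_fixed, q, _ = _ivw_core(b_x, b_y, s_y)
    sigma = max(1.0, np.sqrt(q / (j - 1)))
    se = se_fixed * sigma
    return MREstimate("ivw_re", beta, se, _norm_p(beta / se), n_snp=j)


def cochran_q(h: HarmonisedSet, beta: float) -> tuple[float, int, float]:
    """Heterogeneity of ratio estimates about ``beta``: (Q, df, p)."""
    b_x, _, b_y, s_y = h.arrays()
    j = len(b_x)
    if j < 2:
        raise InsufficientInstrumentsError("Cochran Q requires >= 2 instruments")
    w = 1.0 / s_y**2
    q = float(np.sum(w * (b_y - beta * b_x) ** 2))
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


def _ratio_weights(b_x, b_y, s_y):
    """Ratio estimates and first-order inverse-variance weights."""
    ratio = b_y / b_x
    w = b_x**2 / s_y**2  # 1 / Var(ratio), Var ~= s_y^2 / b_x^2
    return ratio, w


def _weighted_median(ratio, w):
    order = np.argsort(ratio)
    r, wt = ratio[order], w[order]
    s = (np.cumsum(wt) - 0.5 * wt) / np.sum(wt)
    return float(np.interp(0.5, s, r))


def _bootstrap_se(b_x, s_x, b_y, s_y, estimator, n_boot, seed):
    rng = np.random.default_rng(seed)
    j = len(b_x)
    est = np.empty(n_boot)
    for i in range(n_boot):
        bx = rng.normal(b_x, s_x)
        by = rng.normal(b_y, s_y)
        est[i] = estimator(bx, by)
    return float(np.std(est, ddof=1)), est


def weighted_median(
    h: HarmonisedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted median of the per-instrument ratio estimates.

    Cumulative standardised weights s_j = (sum_{k<=j} w_k - w_j/2) / sum(w)
    are linearly interpolated at 0.5. The SE comes from a parametric
    bootstrap (instrument effects resampled from normals at their SEs).
    """
    b_x, s_x, b_y, s_y = h.arrays()
    j = len(b_x)
    if j < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 instruments")
    if seed is None:
        raise ConfigurationError("weighted_median requires an explicit seed")
    ratio, w = _ratio_weights(b_x, b_y, s_y)
    beta = _weighted_median(ratio, w)

    def est(bx, by):
        r, wt = _ratio_weights(bx, by, s_y)
        return _weighted_median(r, wt)

    se, _ = _bootstrap_se(b_x, s_x, b_y, s_y, est, n_boot, seed)
    se = max(se, 1e-12)
    return MREstimate("wme", beta, se, _norm_p(beta / se), n_snp=j)


def _mbe_bandwidth(ratio, w, phi):
    """Modified Silverman rule: 0.9 min(sd, MAD/0.6745-scaled) n^{-1/5} phi."""
    n = len(ratio)
    s = np.std(ratio, ddof=1)
    mad = stats.median_abs_deviation(ratio, scale="normal")
    scale = min(s, mad) if mad > 0 else s
    if scale == 0:
        return 0.0
    return float(phi * 0.9 * scale * n ** (-1 / 5))


def _mbe_point(ratio, w, phi, n_grid=2048):
    h_bw = _mbe_bandwidth(ratio, w, phi)
    if h_bw == 0:  # degenerate: all ratios identical
        return float(ratio[0])
    lo, hi = ratio.min() - 3 * h_bw, ratio.max() + 3 * h_bw
    grid = np.linspace(lo, hi, n_grid)
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h_bw) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def mode_based(
    h: HarmonisedSet,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode of the inverse-variance-weighted kernel density of ratio estimates.

    Normal kernel; bandwidth is ``phi`` times a modified Silverman scale.
    SE from the parametric bootstrap, as for the weighted median.
    """
    b_x, s_x, b_y, s_y = h.arrays()
    j = len(b_x)
    if j < 3:
        raise InsufficientInstrumentsError("mode-based estimate requires >= 3 instruments")
    if seed is None:
        raise ConfigurationError("mode_based requires an explicit seed")
    ratio, w = _ratio_weights(b_x, b_y, s_y)
    beta = _mbe_point(ratio, w, phi)

    def est(bx, by):
        r, wt = _ratio_weights(bx, by, s_y)
        return _mbe_point(r, wt, phi, n_grid=512)

    se, _ = _bootstrap_se(b_x, s_x, b_y, s_y, est, n_boot, seed)
    se = max(se, 1e-12)
    return MREstimate("mbe", beta, se, _norm_p(beta / se), n_snp=j)


def egger_regression(h: HarmonisedSet) -> EggerResult:
    """MR-Egger: weighted regression of b_Y on b_X with an intercept.

    Instruments are oriented so every b_X is positive (sign flips applied to
    both sides). Weights are 1/s_Y^2; SEs carry the same multiplicative
    random-effects floor as IVW; inference uses a t distribution on J-2 df.
    """
    b_x, _, b_y, s_y = h.arrays()
    j = len(b_x)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 instruments")
    sign = np.where(b_x < 0, -1.0, 1.0)
    x, y = b_x * sign, b_y * sign
    w = 1.0 / s_y**2
    X = np.column_stack([np.ones(j), x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    sigma = max(1.0, np.sqrt(q / (j - 2)))
    cov = np.linalg.inv(xtwx) * sigma**2
    se = np.sqrt(np.diag(cov))
    t = stats.t(df=j - 2)
    p = 2 * t.sf(np.abs(coef / se))
    tcrit = float(t.ppf(0.975))
    slope = MREstimate(
        "egger_slope", float(coef[1]), float(se[1]), float(p[1]), n_snp=j,
        ci_low=float(coef[1] - tcrit * se[1]),
        ci_high=float(coef[1] + tcrit * se[1]),
    )
    return EggerResult(slope, float(coef[0]), float(se[0]), float(p[0]))


def _per_variant_r2(beta, eaf, trait_type, lifetime_risk=None):
    r2 = 2 * eaf * (1 - eaf) * beta**2
    if trait_type == "binary":
        if lifetime_risk is None or not (0 < lifetime_risk < 1):
            raise ConfigurationError(
                "binary trait r^2 requires lifetime_risk in (0, 1)"
            )
        r2 = r2 * lifetime_risk * (1 - lifetime_risk)
    return r2


def steiger_direction(
    h: HarmonisedSet,
    n_exp: int,
    n_out: int,
    lifetime_risk: float | None = None,
    exposure_lifetime_risk: float | None = None,
) -> SteigerResult:
    """Directionality test: does the instrument set explain more exposure
    variance than outcome variance?

    Per-variant r^2 is 2p(1-p)b^2 for continuous traits; for a binary trait
    the observed-scale linear-probability approximation multiplies by
    K(1-K) where K is the lifetime risk. The p-value compares the implied
    correlations via Fisher's z transform with the two sample sizes.
    """
    eaf = h.data["eaf"].to_numpy(float)
    if np.isnan(eaf).any():
        raise InputError("Steiger test requires eaf for every instrument")
    b_x, _, b_y, _ = h.arrays()
    r2_x = float(np.sum(_per_variant_r2(
        b_x, eaf, h.exposure_type, exposure_lifetime_risk)))
    r2_y = float(np.sum(_per_variant_r2(
        b_y, eaf, h.outcome_type, lifetime_risk)))
    r2_x, r2_y = min(r2_x, 1.0), min(r2_y, 1.0)
    zx = np.arctanh(np.sqrt(r2_x))
    zy = np.arctanh(np.sqrt(r2_y))
    denom = np.sqrt(1 / (n_exp - 3) + 1 / (n_out - 3))
    p = _norm_p((zx - zy) / denom)
    return SteigerResult(r2_x, r2_y, direction_true=r2_x > r2_y, pvalue=p)


def per_snp_diagnostics(h: HarmonisedSet):
    """Leave-one-out IVW estimates and per-variant Wald ratios.

    Returns a DataFrame with one leave-one-out row per omitted variant
    (analysis='loo') and one single-variant row per instrument
    (analysis='single').
    """
    import pandas as pd

    if h.n_snp < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 instruments")
    rows = []
    ids = h.data["variant_id"].tolist()
    for i, v in enumerate(ids):
        sub = HarmonisedSet(
            h.exposure_id, h.outcome_id,
            h.data.drop(index=h.data.index[i]).reset_index(drop=True),
            exposure_type=h.exposure_type, outcome_type=h.outcome_type,
        )
        est = ivw_random_effects(sub)
        rows.append({"analysis": "loo", "variant_id": v,
                     "beta": est.beta, "se": est.se, "pvalue": est.pvalue})
    for i, v in enumerate(ids):
        r = h.data.iloc[i]
        est = wald_ratio(r["beta_x"], r["se_x"], r["beta_y"], r["se_y"])
        rows.append({"analysis": "single", "variant_id": v,
                     "beta": est.beta, "se": est.se, "pvalue": est.pvalue})
    return pd.DataFrame(rows)


def instrument_strength(h: HarmonisedSet) -> InstrumentStrength:
    """Per-variant F statistics and variance explained on the exposure."""
    b_x, s_x, _, _ = h.arrays()
    eaf = h.data["eaf"].to_numpy(float)
    f = (b_x / s_x) ** 2
    pve = 2 * eaf * (1 - eaf) * b_x**2
    return InstrumentStrength(f, pve, float(np.mean(f)), float(min(np.sum(pve), 1.0)))


def filter_weak_instruments(h: HarmonisedSet, f_min: float = 10.0) -> HarmonisedSet:
    """Drop instruments with F below ``f_min`` (weak-instrument exclusion)."""
    b_x, s_x, _, _ = h.arrays()
    keep = (b_x / s_x) ** 2 >= f_min
    return HarmonisedSet(
        h.exposure_id, h.outcome_id,
        h.data.loc[keep].reset_index(drop=True),
        flipped=h.flipped,
        palindromic_dropped=h.palindromic_dropped,
        incompatible_dropped=h.incompatible_dropped,
        exposure_type=h.exposure_type, outcome_type=h.outcome_type,
    )


def mr_power(
    n_case: int,
    n_control: int,
    pve: float,
    beta: float,
    alpha: float = 0.05,
) -> PowerEstimate:
    """Two-sided power of an MR test against a binary outcome.

    Normal approximation in the style of the standard MR power calculators:
    the MR estimate's SE against a case-control outcome is about
    1 / sqrt(N phi (1-phi) R^2), with N the total sample, phi the case
    fraction and R^2 the variance the instruments explain in the exposure,
    so the non-centrality is |beta| sqrt(N phi (1-phi) R^2).
    """
    if not 0 <= pve <= 1:
        raise ConfigurationError("pve must lie in [0, 1]")
    if n_case <= 0 or n_control <= 0:
        raise ConfigurationError("case/control counts must be positive")
    n = n_case + n_control
    phi = n_case / n
    lam = abs(beta) * np.sqrt(n * phi * (1 - phi) * pve)
    zc = stats.norm.ppf(1 - alpha / 2)
    power = float(stats.norm.sf(zc - lam) + stats.norm.cdf(-zc - lam))
    return PowerEstimate(power, alpha, beta, pve, n, phi)


def dispatch_estimators(
    h: HarmonisedSet,
    n_boot: int = 1000,
    seed: int | None = None,
    phi: float = 1.0,
) -> dict:
    """Run the estimator battery appropriate to the instrument count.

    1 instrument -> Wald ratio only; >= 2 -> IVW-RE primary (+ Cochran Q);
    >= 3 additionally the weighted median, mode-based estimate and MR-Egger.
    """
    out: dict = {"n_snp": h.n_snp}
    if h.n_snp == 0:
        return out
    if h.n_snp == 1:
        r = h.data.iloc[0]
        out["primary"] = wald_ratio(r["beta_x"], r["se_x"], r["beta_y"], r["se_y"])
        return out
    out["primary"] = ivw_random_effects(h)
    q, df, p_q = cochran_q(h, out["primary"].beta)
    out["q"] = {"q": q, "df": df, "pvalue": p_q}
    if h.n_snp >= 3:
        out["wme"] = weighted_median(h, n_boot=n_boot, seed=seed)
        out["mbe"] = mode_based(h, phi=phi, n_boot=n_boot, seed=seed)
        out["egger"] = egger_regression(h)
        out["loo"] = per_snp_diagnostics(h)
    return out
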