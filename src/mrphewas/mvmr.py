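"""Multivariable MR: joint direct effects and conditional instrument strength.

The multivariable IVW model regresses the outcome associations b_Y on the
J x K matrix of exposure associations B_X without an intercept, weighting by
1/s_Y^2. Each coefficient is the direct effect of its exposure holding the
others fixed. Conditional F statistics measure how much instrument signal an
exposure retains once the other exposures' associations are partialled out —
the multivariable analogue of the marginal F > 10 rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_summary import InputError

WEAK_CONDITIONAL_F = 3.0  # report-level flag, not a hard error


class CollinearityError(InputError):
    """The exposure-association design matrix is rank deficient."""


@dataclass
class MVMRDataset:
    """Harmonised instrument effects for K exposures and one outcome.

    ``b_x`` and ``s_x`` are J x K; ``b_y`` and ``s_y`` length J. All effects
    must reference a common effect allele per instrument.
    """

    exposure_ids: list
    b_x: np.ndarray
    s_x: np.ndarray
    b_y: np.ndarray
    s_y: np.ndarray
    variant_ids: list | None = None
    rho: np.ndarray | None = None  # instrument correlation (identity if None)

    def __post_init__(self) -> None:
        self.b_x = np.atleast_2d(np.asarray(self.b_x, float))
        self.s_x = np.atleast_2d(np.asarray(self.s_x, float))
        self.b_y = np.asarray(self.b_y, float)
        self.s_y = np.asarray(self.s_y, float)
        j, k = self.b_x.shape
        if k != len(self.exposure_ids):
            raise InputError("b_x columns must match exposure_ids")
        if k >= 2 and j <= k:
            raise InputError(
                f"MVMR needs more instruments than exposures (J={j}, K={k})"
            )
        if self.s_x.shape != (j, k) or len(self.b_y) != j or len(self.s_y) != j:
            raise InputError("MVMR arrays have inconsistent shapes")

    @property
    def n_instruments(self) -> int:
        return self.b_x.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.b_x.shape[1]


@dataclass
class MVMRResult:
    estimates: pd.DataFrame  # exposure, beta, se, pvalue, ci_low, ci_high, or_mvmr
    residual_q: float
    residual_df: int
    extra: dict = field(default_factory=dict)


def _dependent_columns(X: np.ndarray, ids: list) -> list:
    """Name columns that are linear combinations of earlier ones (via QR)."""
    dependent = []
    for k in range(1, X.shape[1]):
        sub = X[:, : k + 1]
        if np.linalg.matrix_rank(sub, tol=1e-8 * np.linalg.norm(sub)) <= k:
            dependent.append(ids[k])
    return dependent


def mv_ivw(data: MVMRDataset) -> MVMRResult:
    """Multivariable IVW: weighted multiple regression of b_Y on B_X.

    No intercept; weights 1/s_Y^2; per-exposure SEs from the weighted normal
    equations with the multiplicative random-effects floor max(1, sqrt(Q/df)).
    """
    X, y, s_y = data.b_x, data.b_y, data.s_y
    j, k = X.shape
    if np.linalg.matrix_rank(X, tol=1e-8 * np.linalg.norm(X)) < k:
        dep = _dependent_columns(X, data.exposure_ids) or data.exposure_ids
        raise CollinearityError(
            f"collinear exposure associations: {dep}"
        )
    w = 1.0 / s_y**2
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    df = j - k
    sigma = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
    cov = np.linalg.inv(xtwx) * sigma**2
    se = np.sqrt(np.diag(cov))
    z = coef / se
    p = 2 * stats.norm.sf(np.abs(z))
    zc = stats.norm.ppf(0.975)
    est = pd.DataFrame({
        "exposure": data.exposure_ids,
        "beta": coef, "se": se, "pvalue": p,
        "ci_low": coef - zc * se, "ci_high": coef + zc * se,
        "or_mvmr": np.exp(coef),
    })
    return MVMRResult(est, residual_q=q, residual_df=df)


def conditional_f(data: MVMRDataset) -> pd.DataFrame:
    """Conditional F statistic per exposure.

    For exposure k, regress its instrument-exposure associations on those of
    the remaining exposures (weighted by 1/s_Xk^2, whitened by the instrument
    correlation when supplied); the conditional F is the weighted residual sum
    of squares divided by J - K + 1. An exposure whose associations are a
    linear combination of the others scores ~0; with a single exposure this
    reduces to the mean marginal F scaled by J/(J - K + 1) = 1.
    """
    X = data.b_x
    j, k = X.shape
    if data.rho is not None:
        L = np.linalg.cholesky(np.asarray(data.rho, float))
        Linv = np.linalg.inv(L)
    else:
        Linv = None
    rows = []
    for idx, exp_id in enumerate(data.exposure_ids):
        target = X[:, idx]
        others = np.delete(X, idx, axis=1)
        s = data.s_x[:, idx]
        t_w = target / s
        if Linv is not None:
            t_w = Linv @ t_w
        if others.shape[1] == 0:
            rss = float(np.sum(t_w**2))
        else:
            o_w = others / s[:, None]
            if Linv is not None:
                o_w = Linv @ o_w
            coef, *_ = np.linalg.lstsq(o_w, t_w, rcond=None)
            rss = float(np.sum((t_w - o_w @ coef) ** 2))
        df = j - k + 1
        f = rss / df
        rows.append({
            "exposure": exp_id,
            "conditional_f": f,
            "weak": f < WEAK_CONDITIONAL_F,
            "note": ("weak, excluded from MVMR" if f < WEAK_CONDITIONAL_F else ""),
        })
    return pd.DataFrame(rows)


def build_mvmr_dataset(harmonised_sets: list) -> MVMRDataset:
    """Assemble an MVMRDataset from per-exposure harmonised sets.

    Takes the intersection of variants with complete data across all
    exposures and the (shared) outcome; outcome effects are taken from the
    first set.
    """
    if len(harmonised_sets) < 2:
        raise InputError("MVMR requires >= 2 exposures")
    common = None
    for h in harmonised_sets:
        ids = set(h.data["variant_id"])
        common = ids if common is None else common & ids
    common = sorted(common)
    if not common:
        raise InputError("no shared instruments across exposures")
    b_x, s_x = [], []
    for h in harmonised_sets:
        d = h.data.set_index("variant_id").loc[common]
        b_x.append(d["beta_x"].to_numpy(float))
        s_x.append(d["se_x"].to_numpy(float))
    d0 = harmonised_sets[0].data.set_index("variant_id").loc[common]
    return MVMRDataset(
        exposure_ids=[h.exposure_id for h in harmonised_sets],
        b_x=np.column_stack(b_x), s_x=np.column_stack(s_x),
        b_y=d0["beta_y"].to_numpy(float), s_y=d0["se_y"].to_numpy(float),
        variant_ids=common,
    )
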