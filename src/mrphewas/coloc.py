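"""Bayesian colocalisation of two traits in a cis region.

Under a single-causal-variant assumption per trait, five hypotheses are
enumerated for a region: H0 no association with either trait, H1/H2
association with one trait only, H3 both traits associated through distinct
variants, H4 a shared causal variant. Per-variant evidence is the Wakefield
approximate Bayes factor

    log ABF = 0.5 * (log(1 - r) + r z^2),   r = W / (V + W),

with V the squared SE and W the squared prior effect SD. Hypothesis support
sums ABFs over variants (pairs of distinct variants for H3), weighted by the
priors p1, p2, p12; everything is accumulated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io_summary import ConfigurationError, InputError

PRIOR_SD_QUANTITATIVE = 0.20
PRIOR_SD_BINARY = 0.15

HYPOTHESES = ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")


@dataclass
class RegionStats:
    """Per-variant statistics for one trait across a cis region."""

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    variant_ids: list
    beta: np.ndarray
    se: np.ndarray
    n: int | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.se = np.asarray(self.se, float)
        if len(self.variant_ids) == 0:
            raise InputError("region has no variants")
        if np.any(self.se <= 0):
            raise InputError("all region SEs must be positive")

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    def default_prior_sd(self) -> float:
        return PRIOR_SD_BINARY if self.trait_type == "binary" else PRIOR_SD_QUANTITATIVE


@dataclass
class ColocResult:
    pp: dict
    priors: dict
    n_variants: int
    classification: str = field(default="indeterminate")

    def __post_init__(self) -> None:
        total = sum(self.pp.values())
        assert abs(total - 1.0) < 1e-9, "posteriors must sum to 1"


def log_abf(beta, se, prior_sd: float) -> np.ndarray:
    """Per-variant log approximate Bayes factor against the null."""
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise InputError("se must be positive")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log1p(-r) + r * z2)


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a > b, stable."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def cis_window(gene_start: int, gene_end: int, flank: int = 1_000_000) -> tuple[int, int]:
    """Gene body +/- ``flank`` bp, 1-based inclusive, floored at 1."""
    return max(1, gene_start - flank), gene_end + flank


def intersect_regions(t1: RegionStats, t2: RegionStats) -> tuple[RegionStats, RegionStats]:
    """Restrict both traits to their shared variants, in t1's order."""
    common = [v for v in t1.variant_ids if v in set(t2.variant_ids)]
    if not common:
        raise InputError("no shared variants between the two traits")

    def take(t: RegionStats) -> RegionStats:
        idx = [t.variant_ids.index(v) for v in common]
        return RegionStats(t.trait_id, t.trait_type, common,
                           t.beta[idx], t.se[idx], t.n)

    return take(t1), take(t2)


def coloc_posteriors(
    t1: RegionStats,
    t2: RegionStats,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
    threshold: float = 0.80,
) -> ColocResult:
    """Posterior probabilities of the five colocalisation hypotheses.

    Variant sets are intersected first. Un-normalised log evidence:
    H0 = 0; H1 = log p1 + logsum(B1); H2 = log p2 + logsum(B2);
    H3 = log p1 + log p2 + log(sum(B1) sum(B2) - sum(B1*B2));
    H4 = log p12 + logsum(B1*B2).
    """
    t1, t2 = intersect_regions(t1, t2)
    l1 = log_abf(t1.beta, t1.se, prior_sd1 or t1.default_prior_sd())
    l2 = log_abf(t2.beta, t2.se, prior_sd2 or t2.default_prior_sd())

    ls1 = float(logsumexp(l1))
    ls2 = float(logsumexp(l2))
    ls12 = float(logsumexp(l1 + l2))

    lh = np.array([
        0.0,
        np.log(p1) + ls1,
        np.log(p2) + ls2,
        np.log(p1) + np.log(p2) + _logdiff(ls1 + ls2, ls12),
        np.log(p12) + ls12,
    ])
    pp_arr = np.exp(lh - logsumexp(lh))
    pp_arr /= pp_arr.sum()
    pp = dict(zip(HYPOTHESES, (float(x) for x in pp_arr)))
    result = ColocResult(
        pp, {"p1": p1, "p2": p2, "p12": p12}, n_variants=len(t1.variant_ids)
    )
    result.classification = classify_coloc(result, threshold)
    return result


def classify_coloc(result: ColocResult, threshold: float = 0.80) -> str:
    """'shared' if PP_H4 >= threshold, 'distinct' if PP_H3 >= threshold,
    else 'indeterminate'."""
    if result.pp["pp_h4"] >= threshold:
        return "shared"
    if result.pp["pp_h3"] >= threshold:
        return "distinct"
    return "indeterminate"


def coloc_eligible(outcome_pvalue: float, p_threshold: float = 1e-6) -> bool:
    """Eligibility gate: run colocalisation only when the cis instrument's
    outcome association has p below ``p_threshold``."""
    if not 0 < p_threshold <= 1:
        raise ConfigurationError("p_threshold must lie in (0, 1]")
    return outcome_pvalue < p_threshold


def region_from_table(records: pd.DataFrame, trait_id: str, trait_type: str,
                      n: int | None = None) -> RegionStats:
    """Build RegionStats from a summary-stat DataFrame slice."""
    return RegionStats(
        trait_id, trait_type,
        records["variant_id"].tolist(),
        records["beta"].to_numpy(float),
        records["se"].to_numpy(float),
        n,
    )
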