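"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works directly at the summary level — no individual genotypes.
For instrument j with effect-allele frequency p_j:

* true exposure effect  gamma_j ~ N(0, gamma_sd^2),
* true outcome effect   Gamma_j = beta_causal * gamma_j + sign(gamma_j) * a_j,
  with the pleiotropic term a_j ~ N(pleiotropy_mean, pleiotropy_sd^2)
  (balanced pleiotropy: mean 0; directional: mean != 0). Directional
  pleiotropy is defined in the exposure-increasing-allele frame — the frame
  MR-Egger regresses in — so a non-zero mean acts coherently instead of
  cancelling across arbitrarily labelled alleles,
* observed effects are drawn independently in the two samples,
  b_Xj ~ N(gamma_j, s_Xj^2) and b_Yj ~ N(Gamma_j, s_Yj^2), where
  s_Xj = 1/sqrt(2 p_j (1-p_j) n_exposure) for a standardised continuous
  exposure and s_Yj = 1/sqrt(2 p_j (1-p_j) n phi (1-phi)) for a binary
  outcome with case fraction phi (logistic approximation).

Independence of the two draws reproduces the two-sample design (no sample
overlap). Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io_summary import InputError, LDMatrix, SummaryStatTable
from .coloc import RegionStats

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class ScenarioTruth:
    """Generative parameters for one two-sample scenario."""

    beta_causal: float = 0.0
    n_instruments: int = 50
    gamma_sd: float = 0.05
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exposure: int = 300_000
    n_case: int = 60_000
    n_control: int = 60_000
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.0
    correlated_pleiotropy: float = 0.0  # couples alpha_j to gamma_j (breaks InSIDE)
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("ScenarioTruth requires an explicit seed")
        if self.gamma_sd < 0 or self.pleiotropy_sd < 0:
            raise InputError("SDs must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InputError("maf_range must lie within (0, 0.5]")

    def to_dict(self) -> dict:
        return asdict(self)


def generate_ld_matrix(j: int, rho: float, seed: int | None = None) -> LDMatrix:
    """AR(1) LD: r_ik = rho^|i-k|; positive definite for |rho| < 1."""
    if not abs(rho) < 1:
        raise InputError("|rho| must be < 1")
    idx = np.arange(j)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    ids = [f"rs{i + 1}" for i in range(j)]
    return LDMatrix(ids, r)


def _p_from_z(z):
    return np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)


def generate_two_sample(truth: ScenarioTruth):
    """Draw exposure and outcome summary-stat tables for one scenario.

    Returns ``(exposure_table, outcome_table, ld, truth_record)`` where the
    truth record also carries the realised per-variant gamma_j and alpha_j.
    """
    rng = np.random.default_rng(truth.seed)
    j = truth.n_instruments
    p = rng.uniform(*truth.maf_range, size=j)
    gamma = rng.normal(0.0, truth.gamma_sd, size=j)
    # pleiotropy acts in the exposure-increasing-allele frame
    alpha = np.sign(gamma) * rng.normal(
        truth.pleiotropy_mean, truth.pleiotropy_sd, size=j)
    if truth.correlated_pleiotropy:
        alpha = alpha + truth.correlated_pleiotropy * gamma
    big_gamma = truth.beta_causal * gamma + alpha

    s_x = 1.0 / np.sqrt(2 * p * (1 - p) * truth.n_exposure)
    n_out = truth.n_case + truth.n_control
    phi = truth.n_case / n_out
    s_y = 1.0 / np.sqrt(2 * p * (1 - p) * n_out * phi * (1 - phi))

    b_x = rng.normal(gamma, s_x)
    b_y = rng.normal(big_gamma, s_y)

    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(j)]
    ids = [f"rs{i + 1}" for i in range(j)]
    base = {
        "variant_id": ids,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "eaf": p,
        "chrom": 1,
        "pos": 1_000_000 + 10_000 * np.arange(j),
    }
    exposure = SummaryStatTable(
        f"exposure_seed{truth.seed}", "continuous",
        pd.DataFrame({**base, "beta": b_x, "se": s_x,
                      "pvalue": _p_from_z(b_x / s_x),
                      "n": truth.n_exposure}),
    )
    outcome = SummaryStatTable(
        f"outcome_seed{truth.seed}", "binary",
        pd.DataFrame({**base, "beta": b_y, "se": s_y,
                      "pvalue": _p_from_z(b_y / s_y),
                      "n": n_out, "n_case": truth.n_case,
                      "n_control": truth.n_control}),
    )
    ld = generate_ld_matrix(j, truth.ld_rho)
    record = truth.to_dict()
    record.update({"gamma": gamma.tolist(), "alpha": alpha.tolist()})
    return exposure, outcome, ld, record


def generate_coloc_region(
    j: int,
    shared: bool | None,
    seed: int,
    z_causal_1: float = 8.0,
    z_causal_2: float = 8.0,
    rho: float = 0.5,
    n1: int = 10_000,
    n2: int = 100_000,
    maf: float = 0.3,
) -> tuple[RegionStats, RegionStats, dict]:
    """Simulate a two-trait region with a known causal configuration.

    ``shared=True`` plants one causal variant common to both traits,
    ``shared=False`` plants distinct causal variants, ``shared=None`` plants
    none (null region). Marginal z-scores are the causal z propagated through
    AR(1) LD, observed z ~ MVN(R z_true, R).
    """
    if j < 2:
        raise InputError("coloc region needs >= 2 variants")
    rng = np.random.default_rng(seed)
    r = generate_ld_matrix(j, rho).r
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(j))

    z_true1 = np.zeros(j)
    z_true2 = np.zeros(j)
    if shared is True:
        c1 = c2 = int(rng.integers(j))
        z_true1[c1] = z_causal_1
        z_true2[c2] = z_causal_2
    elif shared is False:
        c1 = int(rng.integers(j))
        # distinct causal variant, well separated so LD does not alias them
        offset = j // 2
        c2 = (c1 + offset) % j
        z_true1[c1] = z_causal_1
        z_true2[c2] = z_causal_2
    else:
        c1 = c2 = None

    z1 = r @ z_true1 + chol @ rng.standard_normal(j)
    z2 = r @ z_true2 + chol @ rng.standard_normal(j)

    ids = [f"rs{i + 1}" for i in range(j)]
    se1 = np.full(j, 1.0 / np.sqrt(2 * maf * (1 - maf) * n1))
    se2 = np.full(j, 1.0 / np.sqrt(2 * maf * (1 - maf) * n2))
    t1 = RegionStats("protein", "quantitative", ids, z1 * se1, se1, n1)
    t2 = RegionStats("cancer", "binary", ids, z2 * se2, se2, n2)
    return t1, t2, {"shared": shared, "causal_1": c1, "causal_2": c2, "seed": seed}


def write_scenario(exposure, outcome, ld, record, directory) -> dict:
    """Write a scenario as the TSV dialect the IO module reads + JSON truth."""
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": d / "exposure.tsv",
        "outcome": d / "outcome.tsv",
        "ld": d / "ld.tsv",
        "truth": d / "truth.json",
    }
    exposure.records.to_csv(paths["exposure"], sep="\t", index=False)
    outcome.records.to_csv(paths["outcome"], sep="\t", index=False)
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        paths["ld"], sep="\t")
    paths["truth"].write_text(json.dumps(record, indent=1))
    return {k: str(v) for k, v in paths.items()}
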