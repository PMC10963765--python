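"""Replicate-study harnesses: calibration experiments over the synthetic
generator.

Each function runs many independently seeded scenarios through the same code
path the pipeline uses (instrument selection -> harmonisation -> estimation)
and summarises operating characteristics: bias, CI coverage, type-I error,
pleiotropy-intercept recovery, colocalisation classification recovery, and
the behaviour of the grading tiers under a fully null phenome-wide sweep.

Seeds for individual replicates are derived from the top-level seed via
numpy's SeedSequence spawning, so every summary is reproducible from one
integer.
"""

from __future__ import annotations

import numpy as np

from .coloc import coloc_posteriors
from .estimators import egger_regression, ivw_random_effects
from .grading import PipelineConfig, run_phewas
from .io_summary import harmonise, select_instruments
from .synthetic import ScenarioTruth, generate_coloc_region, generate_two_sample


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _selected_hset(truth: ScenarioTruth):
    exposure, outcome, _, _ = generate_two_sample(truth)
    return harmonise(select_instruments(exposure), outcome)


def ivw_recovery(
    n_reps: int = 500,
    beta_causal: float = 0.3,
    seed: int = 0,
    **scenario_kwargs,
) -> dict:
    """Bias and 95% CI coverage of IVW-RE under a known causal effect."""
    est, covered = [], 0
    for s in _child_seeds(seed, n_reps):
        h = _selected_hset(ScenarioTruth(
            beta_causal=beta_causal, seed=s, **scenario_kwargs))
        iv = ivw_random_effects(h)
        est.append(iv.beta)
        covered += iv.ci_low <= beta_causal <= iv.ci_high
    est = np.asarray(est)
    return {
        "beta_causal": beta_causal,
        "n_reps": n_reps,
        "mean_beta": float(est.mean()),
        "mc_se": float(est.std(ddof=1) / np.sqrt(n_reps)),
        "coverage": covered / n_reps,
    }


def null_rejection_rate(n_reps: int = 2000, seed: int = 0,
                        alpha: float = 0.05, **scenario_kwargs) -> dict:
    """Type-I error of the IVW test when the true causal effect is zero."""
    rej = 0
    for s in _child_seeds(seed, n_reps):
        h = _selected_hset(ScenarioTruth(beta_causal=0.0, seed=s,
                                         **scenario_kwargs))
        rej += ivw_random_effects(h).pvalue < alpha
    return {"n_reps": n_reps, "alpha": alpha, "rejection_rate": rej / n_reps}


def egger_intercept_recovery(
    n_reps: int = 500,
    pleiotropy_mean: float = 0.05,
    seed: int = 0,
    **scenario_kwargs,
) -> dict:
    """Mean MR-Egger intercept under directional pleiotropy."""
    scenario_kwargs.setdefault("beta_causal", 0.3)
    scenario_kwargs.setdefault("pleiotropy_sd", 0.02)
    ints = []
    for s in _child_seeds(seed, n_reps):
        h = _selected_hset(ScenarioTruth(
            pleiotropy_mean=pleiotropy_mean, seed=s, **scenario_kwargs))
        ints.append(egger_regression(h).intercept)
    ints = np.asarray(ints)
    return {
        "pleiotropy_mean": pleiotropy_mean,
        "n_reps": n_reps,
        "mean_intercept": float(ints.mean()),
        "mc_se": float(ints.std(ddof=1) / np.sqrt(n_reps)),
    }


def coloc_recovery(
    n_seeds: int = 100,
    shared: bool | None = True,
    seed: int = 0,
    j: int = 200,
    rho: float = 0.5,
    pp_threshold: float = 0.8,
) -> dict:
    """Fraction of simulated regions whose dominant posterior matches truth."""
    hits = 0
    target = "pp_h4" if shared else ("pp_h3" if shared is False else "pp_h0")
    for s in _child_seeds(seed, n_seeds):
        t1, t2, _ = generate_coloc_region(j, shared, seed=s, rho=rho)
        res = coloc_posteriors(t1, t2)
        if shared is None:
            hits += max(res.pp, key=res.pp.get) == "pp_h0"
        else:
            hits += res.pp[target] > pp_threshold
    return {"n_seeds": n_seeds, "shared": shared, "target": target,
            "recovery_rate": hits / n_seeds}


def null_phewas_sweep(
    n_traits: int = 100,
    seed: int = 0,
    n_boot: int = 200,
) -> dict:
    """Grade distribution over a sweep where every trait is truly null."""
    seeds = _child_seeds(seed, n_traits + 1)
    manifest = []
    outcome = None
    for i, s in enumerate(seeds[:-1]):
        exposure, out, ld, _ = generate_two_sample(
            ScenarioTruth(beta_causal=0.0, seed=s))
        exposure.trait_id = f"null_trait_{i:03d}"
        if outcome is None:
            outcome = out
            outcome.trait_id = "outcome"
        manifest.append((exposure, ld))
    cfg = PipelineConfig(seed=seeds[-1], n_boot=n_boot)
    table, _, counts = run_phewas(manifest, outcome, cfg)
    return {
        "n_traits": n_traits,
        "counts": {k: int(v) for k, v in counts.items()},
        "robust": int(counts.get("robust", 0)),
        "suggestive": int(counts.get("suggestive", 0)),
    }
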