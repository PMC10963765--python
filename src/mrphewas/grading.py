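"""Per-pair MR analysis orchestration and four-tier evidence grading.

Continuous exposures are graded on a hierarchy agreed a priori:

* robust        — P_IVW-RE below the Bonferroni cutoff alpha/n_tests
                  (0.05/3,500 = 1.4e-5 by default), the weighted median or
                  mode-based estimate significant at 0.05, the directionality
                  test pointing from exposure to outcome, and >1 instruments;
* probable      — as robust but only P_IVW-RE < 0.05;
* suggestive    — P_IVW-RE < 0.05 or P_Wald < 0.05 (all significant
                  single-instrument results land here);
* non_significant — everything else.

Binary exposures are simply supported (P < 0.05) or not_supported; effect
sizes for binary-on-binary MR are reported on the beta/SE scale, ORs only
for consistency. All p-value comparisons are strict.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import estimators as est
from .io_summary import (
    HarmonisedSet, InputError, SummaryStatTable,
    clump_greedy, harmonise, read_summary_stats, read_ld_matrix,
    select_instruments,
)

logger = logging.getLogger(__name__)

DEFAULT_N_TESTS = 3500
DEFAULT_ALPHA = 0.05

CONTINUOUS_LEVELS = ("robust", "probable", "suggestive", "non_significant")
BINARY_LEVELS = ("supported", "not_supported")


@dataclass
class PipelineConfig:
    """Thresholds and knobs for the per-pair pipeline."""

    p_max: float = 5e-8
    maf_min: float = 0.01
    r2_max: float = 0.01
    f_min: float = 10.0
    palindrome_maf_max: float = 0.42
    n_tests: int = DEFAULT_N_TESTS
    alpha: float = DEFAULT_ALPHA
    n_boot: int = 1000
    mbe_phi: float = 1.0
    lifetime_risk: float | None = 0.05
    seed: int = 0


@dataclass
class AssociationBundle:
    exposure_id: str
    outcome_id: str
    n_snp: int
    primary: est.MREstimate | None
    wme: est.MREstimate | None = None
    mbe: est.MREstimate | None = None
    egger: est.EggerResult | None = None
    steiger: est.SteigerResult | None = None
    q: dict | None = None
    strength: est.InstrumentStrength | None = None
    loo: pd.DataFrame | None = None
    notes: list = field(default_factory=list)


@dataclass
class EvidenceGrade:
    level: str
    reasons: list

    def __post_init__(self) -> None:
        assert self.reasons, "rule trace must be non-empty"


def bonferroni_threshold(alpha: float = DEFAULT_ALPHA,
                         n_tests: int = DEFAULT_N_TESTS) -> float:
    """The robust-tier IVW p-value cutoff, alpha / n_tests."""
    return alpha / n_tests


def grade_continuous(
    b: AssociationBundle,
    n_tests: int = DEFAULT_N_TESTS,
    alpha: float = DEFAULT_ALPHA,
) -> EvidenceGrade:
    """Apply the four-tier rule to a continuous-exposure bundle."""
    if b.primary is None:
        return EvidenceGrade("non_significant", ["no instruments survived QC"])
    p = b.primary.pvalue
    trace = [f"P_{b.primary.method}={p:.3e}"]

    if b.n_snp > 1:
        if b.steiger is None:
            raise InputError(
                "incomplete bundle: Steiger result required when n_snp > 1"
            )
        aux_p = [x.pvalue for x in (b.wme, b.mbe) if x is not None]
        aux_ok = any(x < 0.05 for x in aux_p)
        direction_ok = b.steiger.direction_true
        trace.append(
            f"WME/MBE significant: {aux_ok}; Steiger direction true: {direction_ok}"
        )
        cutoff = bonferroni_threshold(alpha, n_tests)
        if p < cutoff and aux_ok and direction_ok:
            trace.append(f"P < {cutoff:.2e} (alpha/n_tests) with auxiliary support")
            return EvidenceGrade("robust", trace)
        if p < 0.05 and aux_ok and direction_ok:
            trace.append("P < 0.05 with auxiliary support")
            return EvidenceGrade("probable", trace)
    if p < 0.05:
        trace.append("P < 0.05 without full auxiliary support -> suggestive")
        return EvidenceGrade("suggestive", trace)
    trace.append("P >= 0.05")
    return EvidenceGrade("non_significant", trace)


def grade_binary(estimate: est.MREstimate) -> EvidenceGrade:
    """Binary exposures: supported iff P < 0.05 (strict)."""
    p = estimate.pvalue
    if p < 0.05:
        return EvidenceGrade("supported", [f"P={p:.3e} < 0.05"])
    return EvidenceGrade("not_supported", [f"P={p:.3e} >= 0.05"])


def analyse_pair(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    ld=None,
    config: PipelineConfig | None = None,
) -> tuple[AssociationBundle, EvidenceGrade]:
    """Full single-pair pipeline.

    instrument selection -> LD clumping -> weak-instrument (F < f_min)
    exclusion -> harmonisation -> estimator dispatch -> Steiger -> grading.
    Zero surviving instruments yields a graded 'no-instrument' bundle, not an
    exception. Deterministic given ``config.seed``.
    """
    cfg = config or PipelineConfig()
    notes = []
    inst = select_instruments(exposure, cfg.p_max, cfg.maf_min)
    notes.append(f"instruments after p/MAF filter: {inst.n_variants}")
    if inst.n_variants and ld is not None:
        inst = clump_greedy(inst, ld, cfg.r2_max)
        notes.append(f"after clumping: {inst.n_variants}")
    if inst.n_variants == 0:
        bundle = AssociationBundle(exposure.trait_id, outcome.trait_id, 0,
                                   None, notes=notes + ["no instruments"])
        return bundle, EvidenceGrade("non_significant", ["no instruments survived QC"])

    h = harmonise(inst, outcome, cfg.palindrome_maf_max)
    h = est.filter_weak_instruments(h, cfg.f_min)
    notes.append(f"after harmonisation and F>={cfg.f_min:g} filter: {h.n_snp}")
    if h.n_snp == 0:
        bundle = AssociationBundle(exposure.trait_id, outcome.trait_id, 0,
                                   None, notes=notes + ["no instruments"])
        return bundle, EvidenceGrade("non_significant", ["no instruments survived QC"])

    results = est.dispatch_estimators(
        h, n_boot=cfg.n_boot, seed=cfg.seed, phi=cfg.mbe_phi
    )
    steiger = None
    if h.n_snp > 1:
        n_exp = int(np.nanmedian(exposure.records["n"]))
        n_out = int(np.nanmedian(outcome.records["n"]))
        steiger = est.steiger_direction(
            h, n_exp=n_exp, n_out=n_out,
            lifetime_risk=(cfg.lifetime_risk if outcome.trait_type == "binary"
                           else None),
        )
    bundle = AssociationBundle(
        exposure.trait_id, outcome.trait_id, h.n_snp,
        primary=results.get("primary"),
        wme=results.get("wme"), mbe=results.get("mbe"),
        egger=results.get("egger"), steiger=steiger,
        q=results.get("q"), strength=est.instrument_strength(h),
        loo=results.get("loo"), notes=notes,
    )
    if exposure.trait_type == "binary":
        grade = grade_binary(bundle.primary)
    else:
        grade = grade_continuous(bundle, cfg.n_tests, cfg.alpha)
    return bundle, grade


def bundle_row(bundle: AssociationBundle, grade: EvidenceGrade) -> dict:
    """Flatten a bundle to one results-table row."""
    row = {
        "exposure": bundle.exposure_id,
        "outcome": bundle.outcome_id,
        "n_snp": bundle.n_snp,
        "grade": grade.level,
        "rule_trace": " | ".join(grade.reasons),
    }
    if bundle.primary is not None:
        e = bundle.primary
        row.update({
            "method": e.method, "beta": e.beta, "se": e.se, "pvalue": e.pvalue,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "or_sd": e.or_sd,
            "or_ci_low": e.or_ci[0], "or_ci_high": e.or_ci[1],
            "z": e.beta / e.se,
        })
    else:
        row.update({"method": "none", "beta": np.nan, "se": np.nan,
                    "pvalue": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "or_sd": np.nan, "or_ci_low": np.nan, "or_ci_high": np.nan,
                    "z": np.nan})
    for name in ("wme", "mbe"):
        e = getattr(bundle, name)
        row[f"{name}_pvalue"] = e.pvalue if e is not None else np.nan
    if bundle.egger is not None:
        row["egger_intercept"] = bundle.egger.intercept
        row["egger_intercept_pvalue"] = bundle.egger.intercept_pvalue
    if bundle.steiger is not None:
        row["steiger_direction_true"] = bundle.steiger.direction_true
    return row


def run_phewas(
    manifest: list,
    outcome: SummaryStatTable,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Sweep many exposures against one outcome.

    ``manifest`` holds either loaded exposure tables or
    ``(exposure_table, ld_matrix)`` pairs. Returns the graded results table,
    a Z-statistic (beta/se) matrix for external clustering, and summary
    counts per grade (plus a count of skipped entries).
    """
    if not manifest:
        raise InputError("empty manifest")
    cfg = config or PipelineConfig()
    rows = []
    skipped = 0
    for entry in manifest:
        exposure, ld = entry if isinstance(entry, tuple) else (entry, None)
        try:
            bundle, grade = analyse_pair(exposure, outcome, ld, cfg)
        except Exception:  # noqa: BLE001 — a bad pair must not kill the sweep
            logger.exception("pair %s failed; skipping", getattr(
                exposure, "trait_id", entry))
            skipped += 1
            continue
        rows.append(bundle_row(bundle, grade))
    table = pd.DataFrame(rows)
    z = table.pivot_table(index="exposure", columns="outcome", values="z")
    counts = table["grade"].value_counts().to_dict()
    counts["skipped"] = skipped
    return table, z, counts


def run_phewas_from_files(
    exposure_paths: list,
    outcome_path,
    config: PipelineConfig | None = None,
    ld_paths: dict | None = None,
    outcome_trait_type: str = "binary",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """File-based wrapper around :func:`run_phewas`."""
    outcome = read_summary_stats(outcome_path, trait_type=outcome_trait_type)
    manifest = []
    skipped = 0
    for path in exposure_paths:
        try:
            table = read_summary_stats(path, trait_type="continuous")
        except Exception:  # noqa: BLE001
            logger.exception("unreadable manifest entry %s; skipped", path)
            skipped += 1
            continue
        ld = read_ld_matrix(ld_paths[path]) if ld_paths and path in ld_paths else None
        manifest.append((table, ld))
    table, z, counts = run_phewas(manifest, outcome, config)
    counts["skipped"] += skipped
    return table, z, counts


def export_results(table: pd.DataFrame, z: pd.DataFrame, counts: dict,
                   directory) -> dict:
    """Write the results TSV, the Z matrix, and a JSON mirror."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": d / "mr_results.tsv",
        "z_matrix": d / "z_matrix.tsv",
        "summary": d / "summary.json",
    }
    table.to_csv(paths["results"], sep="\t", index=False)
    z.to_csv(paths["z_matrix"], sep="\t")
    paths["summary"].write_text(json.dumps(counts, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
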