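"""Reading, filtering, clumping and harmonising GWAS summary statistics.

Summary statistics are held as pandas DataFrames wrapped in light dataclasses.
The canonical column set is ``variant_id, effect_allele, other_allele, eaf,
beta, se, pvalue, n`` with optional ``n_case, n_control, chrom, pos``. Effects
are per-SD for continuous traits and log-odds-ratios for binary traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "variant_id", "effect_allele", "other_allele", "eaf",
    "beta", "se", "pvalue", "n",
]
OPTIONAL_COLUMNS = ["n_case", "n_control", "chrom", "pos"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)


class ConfigurationError(ValueError):
    """A user-supplied configuration (column map, constant) is unusable."""


class InputError(ValueError):
    """Input data are structurally invalid for the requested operation."""


@dataclass
class SummaryStatTable:
    """One trait's per-variant association records, unique by variant_id."""

    trait_id: str
    trait_type: str  # "continuous" | "binary"
    records: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}"
            )
        if self.records["variant_id"].duplicated().any():
            dups = self.records.loc[
                self.records["variant_id"].duplicated(), "variant_id"
            ].tolist()
            raise InputError(f"duplicate variant_id(s): {dups[:5]}")
        if self.trait_type == "binary":
            if "n_case" not in self.records.columns or (
                self.records["n_case"].isna().any()
            ):
                raise InputError(
                    f"binary trait {self.trait_id!r} requires n_case/n_control on all records"
                )

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def subset(self, mask) -> "SummaryStatTable":
        return SummaryStatTable(
            self.trait_id, self.trait_type,
            self.records.loc[mask].reset_index(drop=True),
        )


@dataclass
class LDMatrix:
    """Pairwise variant correlations (r, not r^2) with row/column IDs."""

    variant_ids: list
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise InputError("LD matrix shape does not match variant_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise InputError("LD matrix diagonal is not unity")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise InputError("LD entries outside [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r2(self, a: str, b: str) -> float:
        try:
            return float(self.r[self._index[a], self._index[b]] ** 2)
        except KeyError as exc:
            raise InputError(f"variant {exc.args[0]!r} absent from LD matrix") from None


@dataclass
class HarmonisedSet:
    """Exposure and outcome effects aligned to a common effect allele.

    Columns: variant_id, beta_x, se_x, beta_y, se_y, eaf (exposure side).
    """

    exposure_id: str
    outcome_id: str
    data: pd.DataFrame
    flipped: int = 0
    palindromic_dropped: int = 0
    incompatible_dropped: int = 0
    exposure_type: str = "continuous"
    outcome_type: str = "binary"
    extra: dict = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return len(self.data)

    def arrays(self):
        d = self.data
        return (
            d["beta_x"].to_numpy(float), d["se_x"].to_numpy(float),
            d["beta_y"].to_numpy(float), d["se_y"].to_numpy(float),
        )


def _validate_records(df: pd.DataFrame, trait_type: str) -> tuple[pd.DataFrame, int]:
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    ok = (
        df["se"].gt(0)
        & df["eaf"].gt(0) & df["eaf"].lt(1)
        & df["pvalue"].gt(0) & df["pvalue"].le(1)
        & df["effect_allele"].ne(df["other_allele"])
        & df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & df["beta"].notna()
    )
    if trait_type == "binary" and "n_case" in df.columns:
        ok &= (df["n_case"] + df["n_control"]).eq(df["n"])
    n_dropped = int((~ok).sum())
    return df.loc[ok].reset_index(drop=True), n_dropped


def read_summary_stats(
    path,
    column_map: dict | None = None,
    trait_type: str = "continuous",
    trait_id: str | None = None,
    sep: str = "\t",
) -> SummaryStatTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical names to the file's headers. Rows violating
    record invariants (se <= 0, eaf outside (0,1), bad alleles, p outside
    (0,1]) are dropped and counted, not fatal.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise ConfigurationError(f"mapped column(s) not in file: {missing}")
        df = df.rename(columns=rename)
    needed = [c for c in CANONICAL_COLUMNS]
    if trait_type == "binary":
        needed += ["n_case", "n_control"]
    absent = [c for c in needed if c not in df.columns]
    if absent:
        raise ConfigurationError(f"missing mandatory column(s): {absent}")
    df, n_dropped = _validate_records(df, trait_type)
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s)", path, n_dropped)
    if df.empty:
        raise InputError(f"{path}: no valid records after validation")
    return SummaryStatTable(
        trait_id or str(path), trait_type, df, n_dropped=n_dropped
    )


def read_ld_matrix(path, sep: str = "\t") -> LDMatrix:
    """Read a square LD correlation matrix with variant IDs on both margins."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return LDMatrix(list(df.index), df.to_numpy(float))


def select_instruments(
    table: SummaryStatTable,
    p_max: float = 5e-8,
    maf_min: float = 0.01,
) -> SummaryStatTable:
    """Keep genome-wide-significant common variants.

    Retains records with p < ``p_max`` (strict) and minor-allele frequency
    strictly above ``maf_min``.
    """
    maf = np.minimum(table.records["eaf"], 1 - table.records["eaf"])
    mask = table.records["pvalue"].lt(p_max) & maf.gt(maf_min)
    out = table.subset(mask.to_numpy())
    if out.n_variants == 0:
        logger.info("%s: no instruments survive p<%g, MAF>%g",
                    table.trait_id, p_max, maf_min)
    return out


def clump_greedy(
    table: SummaryStatTable,
    ld: LDMatrix,
    r2_max: float = 0.01,
) -> SummaryStatTable:
    """Greedy LD clumping: strongest association first, prune r^2 > ``r2_max``.

    Variants are visited by ascending p-value (ties broken by variant_id for
    determinism); a variant is kept iff its squared correlation with every
    previously kept variant is <= ``r2_max``.
    """
    df = table.records
    missing = [v for v in df["variant_id"] if v not in ld._index]
    if missing:
        raise InputError(f"variant(s) absent from LD matrix: {missing[:5]}")
    order = df.sort_values(
        ["pvalue", "variant_id"], kind="mergesort"
    )["variant_id"].tolist()
    kept: list[str] = []
    for v in order:
        if all(ld.r2(v, k) <= r2_max for k in kept):
            kept.append(v)
    keep_set = set(kept)
    mask = df["variant_id"].isin(keep_set).to_numpy()
    out = table.subset(mask)
    # restore kept (p-value) order
    pos = {v: i for i, v in enumerate(kept)}
    out.records = out.records.sort_values(
        "variant_id", key=lambda s: s.map(pos), kind="mergesort"
    ).reset_index(drop=True)
    return out


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonise(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    palindrome_maf_max: float = 0.42,
) -> HarmonisedSet:
    """Align exposure and outcome effects to the exposure's effect allele.

    Variants are intersected on ID. If the outcome's allele labels are swapped
    relative to the exposure, the outcome beta is negated and its frequency
    complemented. Strand flips (both alleles complemented) are resolved by
    complementing before matching. Palindromic variants (A/T or C/G) are kept
    only when the minor-allele frequency is below ``palindrome_maf_max`` on
    both sides and the frequencies agree on orientation; otherwise they are
    dropped and counted. Unresolvable allele pairs are dropped and counted,
    never silently kept.
    """
    exp = exposure.records.set_index("variant_id")
    out = outcome.records.set_index("variant_id")
    common = [v for v in exposure.records["variant_id"] if v in out.index]

    rows = []
    flipped = palindromic_dropped = incompatible = 0
    for v in common:
        e, o = exp.loc[v], out.loc[v]
        ea, oa = e["effect_allele"], e["other_allele"]
        b_y, eaf_y = float(o["beta"]), float(o["eaf"])
        oea, ooa = o["effect_allele"], o["other_allele"]

        if _is_palindromic(ea, oa):
            # alignable only by frequency: ambiguous-MAF variants dropped
            if {oea, ooa} != {ea, oa}:
                incompatible += 1
                continue
            maf_e = min(e["eaf"], 1 - e["eaf"])
            maf_o = min(eaf_y, 1 - eaf_y)
            if maf_e >= palindrome_maf_max or maf_o >= palindrome_maf_max:
                palindromic_dropped += 1
                continue
            same_orientation = (e["eaf"] < 0.5) == (
                (eaf_y if oea == ea else 1 - eaf_y) < 0.5
            )
            if oea == ea:
                if not same_orientation:
                    b_y, eaf_y = -b_y, 1 - eaf_y
                    flipped += 1
            else:
                if same_orientation:
                    b_y, eaf_y = -b_y, 1 - eaf_y
                    flipped += 1
        elif (oea, ooa) == (ea, oa):
            pass
        elif (oea, ooa) == (oa, ea):
            b_y, eaf_y = -b_y, 1 - eaf_y
            flipped += 1
        elif (oea, ooa) == (_COMPLEMENT[ea], _COMPLEMENT[oa]):
            pass  # strand flip, same orientation
        elif (oea, ooa) == (_COMPLEMENT[oa], _COMPLEMENT[ea]):
            b_y, eaf_y = -b_y, 1 - eaf_y
            flipped += 1
        else:
            incompatible += 1
            continue

        rows.append({
            "variant_id": v,
            "beta_x": float(e["beta"]), "se_x": float(e["se"]),
            "beta_y": b_y, "se_y": float(o["se"]),
            "eaf": float(e["eaf"]), "eaf_outcome": eaf_y,
            "effect_allele": ea, "other_allele": oa,
        })

    if incompatible:
        logger.debug("%s/%s: %d unresolvable variant(s)",
                     exposure.trait_id, outcome.trait_id, incompatible)
    data = pd.DataFrame(
        rows,
        columns=["variant_id", "beta_x", "se_x", "beta_y", "se_y",
                 "eaf", "eaf_outcome", "effect_allele", "other_allele"],
    )
    return HarmonisedSet(
        exposure.trait_id, outcome.trait_id, data,
        flipped=flipped,
        palindromic_dropped=palindromic_dropped,
        incompatible_dropped=incompatible,
        exposure_type=exposure.trait_type,
        outcome_type=outcome.trait_type,
    )


def harmonised_to_tables(h: HarmonisedSet) -> tuple[SummaryStatTable, SummaryStatTable]:
    """Re-express a HarmonisedSet as two aligned summary-stat tables.

    Useful for idempotence checks and for feeding downstream single-trait
    operations; p-values are recomputed from z-scores. Trait typing is not
    preserved (case/control counts are gone), so both come back continuous.
    """
    from scipy import stats

    def table(beta, se, eaf, trait_id, trait_type="continuous"):
        z = beta / se
        df = pd.DataFrame({
            "variant_id": h.data["variant_id"],
            "effect_allele": h.data["effect_allele"],
            "other_allele": h.data["other_allele"],
            "eaf": eaf,
            "beta": beta, "se": se,
            "pvalue": np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
            "n": np.nan,
        })
        return SummaryStatTable(trait_id, trait_type, df)

    return (
        table(h.data["beta_x"], h.data["se_x"], h.data["eaf"], h.exposure_id),
        table(h.data["beta_y"], h.data["se_y"], h.data["eaf_outcome"],
              h.outcome_id),
    )
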