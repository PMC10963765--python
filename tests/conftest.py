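import numpy as np
import pandas as pd
import pytest

from mrphewas.io_summary import HarmonisedSet, LDMatrix, SummaryStatTable


def make_table(
    variant_ids,
    beta,
    se,
    eaf=None,
    pvalue=None,
    alleles=None,
    n=100_000,
    trait_id="trait",
    trait_type="continuous",
    **extra,
):
    """Assemble a SummaryStatTable from arrays, filling sensible defaults."""
    j = len(variant_ids)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if eaf is None:
        eaf = np.full(j, 0.3)
    if pvalue is None:
        from scipy import stats

        pvalue = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    if alleles is None:
        alleles = [("A", "G")] * j
    df = pd.DataFrame({
        "variant_id": variant_ids,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "pvalue": pvalue,
        "n": n,
        **extra,
    })
    return SummaryStatTable(trait_id, trait_type, df)


def make_hset(b_x, s_x, b_y, s_y, eaf=None, outcome_type="binary"):
    """Assemble a HarmonisedSet directly from effect arrays."""
    j = len(b_x)
    if eaf is None:
        eaf = np.full(j, 0.3)
    data = pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(j)],
        "beta_x": np.asarray(b_x, float),
        "se_x": np.asarray(s_x, float),
        "beta_y": np.asarray(b_y, float),
        "se_y": np.asarray(s_y, float),
        "eaf": np.asarray(eaf, float),
        "eaf_outcome": np.asarray(eaf, float),
        "effect_allele": "A",
        "other_allele": "G",
    })
    return HarmonisedSet("exp", "out", data, outcome_type=outcome_type)


@pytest.fixture
def spec_triple_hset():
    """Three-instrument set with a closed-form IVW solution (beta = 79/141)."""
    return make_hset(
        b_x=[0.5, 0.8, 1.0], s_x=[0.02, 0.02, 0.02],
        b_y=[0.3, 0.2, 0.6], s_y=[0.1, 0.2, 0.1],
    )


@pytest.fixture
def random_hset():
    rng = np.random.default_rng(42)
    j = 20
    b_x = rng.normal(0.1, 0.03, j)
    return make_hset(
        b_x=b_x, s_x=np.full(j, 0.005),
        b_y=0.4 * b_x + rng.normal(0, 0.02, j),
        s_y=rng.uniform(0.01, 0.05, j),
    )


@pytest.fixture
def identity_ld():
    def _make(ids):
        return LDMatrix(list(ids), np.eye(len(ids)))

    return _make
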