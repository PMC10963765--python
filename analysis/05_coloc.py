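#!/usr/bin/env python
"""Colocalisation: a worked region plus classification recovery.

Shows the posterior breakdown for one shared-variant region, then measures
how often 100 simulated shared / distinct / null regions are classified
correctly at PP > 0.8. Writes results/coloc.tsv.
"""

from pathlib import Path

import pandas as pd

from mrphewas.coloc import coloc_posteriors
from mrphewas.experiments import coloc_recovery
from mrphewas.synthetic import generate_coloc_region

OUT = Path(__file__).resolve().parents[1] / "results" / "coloc.tsv"


def main() -> None:
    t1, t2, truth = generate_coloc_region(200, shared=True, seed=31)
    res = coloc_posteriors(t1, t2)
    print("worked shared-variant region (J=200, AR(1) rho=0.5):")
    for h, v in res.pp.items():
        print(f"  {h.upper()}: {v:.3f}")
    print(f"  classification: {res.classification} "
          f"(causal variant index {truth['causal_1']})\n")

    rows = []
    for shared, label in ((True, "shared"), (False, "distinct"), (None, "null")):
        r = coloc_recovery(n_seeds=100, shared=shared, seed=32)
        rows.append({"scenario": label, "target": r["target"],
                     "recovery_rate": r["recovery_rate"],
                     "n_seeds": r["n_seeds"]})
        print(f"{label}: dominant hypothesis recovered in "
              f"{100 * r['recovery_rate']:.0f}% of {r['n_seeds']} regions")

    OUT.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT, sep="\t", index=False)
    print(f"table -> {OUT}")


if __name__ == "__main__":
    main()
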