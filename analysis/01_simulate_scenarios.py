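#!/usr/bin/env python
"""Generate the study's synthetic scenarios and write them to disk.

Three two-sample scenarios (a strong causal effect, a null, and one with
directional pleiotropy) are written as summary-stat/LD TSVs with JSON truth
sidecars under results/scenarios/, ready for the downstream drivers and for
inspection.
"""

from pathlib import Path

from mrphewas.synthetic import ScenarioTruth, generate_two_sample, write_scenario

OUT = Path(__file__).resolve().parents[1] / "results" / "scenarios"

SCENARIOS = {
    "causal": ScenarioTruth(beta_causal=0.3, seed=101),
    "null": ScenarioTruth(beta_causal=0.0, seed=102),
    "pleiotropic": ScenarioTruth(beta_causal=0.3, pleiotropy_mean=0.05,
                                 pleiotropy_sd=0.02, seed=103),
}


def main() -> None:
    for name, truth in SCENARIOS.items():
        paths = write_scenario(*generate_two_sample(truth), OUT / name)
        print(f"{name}: beta={truth.beta_causal}, "
              f"pleiotropy mean={truth.pleiotropy_mean} -> {paths['exposure']}")
    print(f"\n{len(SCENARIOS)} scenarios under {OUT}")


if __name__ == "__main__":
    main()
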