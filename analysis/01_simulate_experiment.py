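#!/usr/bin/env python
"""Simulate the phenomic plate experiment.

World: 96 replicate reference cultures and 80 knockout strains — 8 planted
deletion enhancers (drug slows them more than the reference), 8 planted
suppressors, 4 shift-only strains (altered baseline growth, no drug
interaction) — imaged on a 0-48 h grid under the gemcitabine and cytarabine
dose series. Writes the long-format time series and the ground-truth table.
"""

import argparse
from pathlib import Path

from phenomiq import SimulationConfig, StrainEffects, generate_plate_experiment, io

GEM, CYT = "gemcitabine", "cytarabine"


def build_config(seed: int) -> SimulationConfig:
    effects = {}
    for i in range(1, 9):
        effects[f"YKO_{i:04d}"] = StrainEffects(
            slopes={GEM: {"L": 0.30, "K": -3.0}, CYT: {"L": 0.09, "K": -0.9}}
        )
    for i in range(9, 17):
        effects[f"YKO_{i:04d}"] = StrainEffects(
            slopes={GEM: {"L": -0.30, "K": 3.0}, CYT: {"L": -0.09, "K": 0.9}}
        )
    for i in range(17, 21):
        effects[f"YKO_{i:04d}"] = StrainEffects(shift={"K": 25.0, "L": 4.0})
    return SimulationConfig(
        seed=seed, n_mutant_strains=80, n_reference_cultures=96,
        planted_effects=effects,
    )


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    config = build_config(args.seed)
    ts, truth = generate_plate_experiment(config)
    io.write_tsv(ts, args.outdir / "timeseries.tsv")
    io.write_tsv(truth, args.outdir / "ground_truth.tsv")

    n_cultures = ts.groupby(["plate", "row", "col"]).ngroups
    print(f"simulated {n_cultures} cultures "
          f"({config.n_reference_cultures} reference replicates, "
          f"{config.n_mutant_strains} mutants) x 2 drugs x 5 doses")
    for drug in (GEM, CYT):
        counts = truth[f"class_{drug}"].value_counts().to_dict()
        print(f"  planted classes ({drug}): {counts}")


if __name__ == "__main__":
    main()
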