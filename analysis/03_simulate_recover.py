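#!/usr/bin/env python
"""Simulated dose-response experiment: generate a ground-truth MSAP dataset
(0/15/50/100 μM, three replicates, band-call noise), score methylation
levels per dose after replicate consensus, and recover the demethylation
rate constant kappa from the 50 μM arm's true states.

Writes results/simulated_levels.tsv.
"""

from pathlib import Path

import pandas as pd

from msapkit.scoring import aggregate_replicates, levels_table
from msapkit.simulate import SimulationConfig, estimate_kappa, simulate_experiment

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240601


def main() -> None:
    config = SimulationConfig(n_loci=2000, seed=SEED)
    exp = simulate_experiment(config)

    frames = []
    for dose in config.doses:
        consensus = aggregate_replicates(exp.matrix(float(dose)))
        frames.append(levels_table(consensus, ("tissue", "dose")))
    levels = pd.concat(frames, ignore_index=True).sort_values("dose")
    OUT.mkdir(exist_ok=True)
    levels.to_csv(OUT / "simulated_levels.tsv", sep="\t", index=False)
    print(levels.to_string(index=False))

    kappa_hat = estimate_kappa(
        exp.truth["state_0uM"].to_numpy(),
        exp.truth["state_50uM"].to_numpy(),
        50.0,
    )
    print(
        f"\nkappa: true {config.kappa:.4f} /uM, recovered {kappa_hat:.4f} /uM "
        f"({abs(kappa_hat - config.kappa) / config.kappa * 100:.1f}% off) "
        f"from the 50 uM arm of {config.n_loci} loci."
    )
    print(
        "Total methylation level declines with dose while the hypermethylated "
        "(IV) pool shrinks into detectable II/III states."
    )


if __name__ == "__main__":
    main()
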