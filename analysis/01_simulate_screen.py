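#!/usr/bin/env python
"""Generate the demonstration screen dataset.

Simulates a 20-gene screen (plus 4 control genotypes) under the default
study conditions -- Poisson vacuole counts, binomial stress trials with
control impairment near 26%/19%, noisy ERG traces, and age-declining
climbing speed for both disease models -- and writes one TSV per assay
plus the truth labels under results/screen/.
"""

from pathlib import Path

from adscreen.config import SimulationConfig
from adscreen.simulate import simulate_screen, write_screen_tables

OUT = Path(__file__).resolve().parents[1] / "results" / "screen"
CONFIG = SimulationConfig(seed=2024, n_genes=20, n_control_genotypes=4)


def main() -> None:
    dataset = simulate_screen(CONFIG)
    paths = write_screen_tables(dataset, OUT)
    n_true = {
        label: sum(bool(t.get(label)) for t in dataset.truth.values())
        for label in ("degenerating", "erg_decreased", "stress_sensitive", "modifier")
    }
    print(f"simulated {CONFIG.n_genes} genes + {CONFIG.n_control_genotypes} controls")
    print(f"true positives per assay: {n_true}")
    for name, p in paths.items():
        print(f"  wrote {name}: {p.relative_to(OUT.parent.parent)}")


if __name__ == "__main__":
    main()
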