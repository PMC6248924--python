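#!/usr/bin/env python
"""Quantify pipeline performance across many generator seeds.

A smaller-scale version of the acceptance computation for interactive
use: DE recovery/boundary accuracy over 20 seeds, classifier accuracy on
100 + 100 held-out sequences, and tree congruence over 30 simulations.
Writes benchmarks.json.
"""

import json
from pathlib import Path

from flagellarch import benchmarks as B

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    BASE.mkdir(parents=True, exist_ok=True)
    out = {
        "recovery": B.de_recovery_benchmark(n_seeds=20, base_seed=SEED * 100),
        "classifier": B.classifier_benchmark(n_each=100, seed=SEED),
        "congruence": B.congruence_benchmark(n_seeds=30, base_seed=SEED * 100),
        "convergence": B.convergence_benchmark(seed=SEED),
        "standins": B.standin_benchmark(seed=SEED),
    }
    (BASE / "benchmarks.json").write_text(json.dumps(out, indent=1))
    print(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
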