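#!/usr/bin/env python
"""Generate the full synthetic input set for the downstream analyses.

Emits, under results/synthetic/: coding sequences with three planted
editing sites (whose tryptic contexts match the biological ones), an
editing-site table, a PSM evidence table with planted editing fractions,
two-condition complexome maps with planted complex masses, and a quant
matrix with a planted complex-wide fold change — plus truth.json listing
every planted quantity.

Usage: python analysis/01_simulate_inputs.py [--seed 1] [--out results/synthetic]
"""

import argparse
import json
from pathlib import Path

from editoform.simulate import emit_all


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()

    truth = emit_all(seed=args.seed, out_dir=args.out)
    print(f"synthetic inputs written to {args.out}/ (seed {args.seed})")
    print("planted truths:")
    print(json.dumps(truth, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
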