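#!/usr/bin/env python
"""Sensitivity of the shared temperature-dependent model.

How strong must a Pleistocene speciation slowdown be for the multi-clade
temperature-dependent model to detect it (AICdiff > 2) given six clades
of this size and structure? Simulates datasets whose speciation rate
drops to a grid of fractions of its Tertiary value at 2.6 Ma BP and
reports detection power per drop factor; the drop-factor-1.0 row is the
false-positive rate. Use --nsim to trade runtime for precision.
"""

import argparse
from pathlib import Path

from montane.simulate import sensitivity_power

OUT = Path(__file__).resolve().parents[1] / "results" / "power"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--nsim", type=int, default=20)
    parser.add_argument("--seed", type=int, default=123)
    parser.add_argument("--drops", type=float, nargs="+",
                        default=[1.0, 0.8, 0.63, 0.5, 0.3])
    args = parser.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    table = sensitivity_power(args.drops, args.nsim, seed=args.seed)
    table.to_csv(OUT / "power.csv", index=False)
    print(table.to_string(index=False))
    detectable = table[(table.drop_factor < 1.0) & (table.power > 0.8)]
    if len(detectable):
        print(f"\ndrops to {detectable.drop_factor.max():.2f} of the "
              "Tertiary rate or less are detected with power > 0.8; weaker "
              "slowdowns cannot be excluded by this design.")


if __name__ == "__main__":
    main()
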