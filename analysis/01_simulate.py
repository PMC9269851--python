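#!/usr/bin/env python
"""Simulate the study cohort and write raw traces + design tables.

Traces are large and go under scratch/ (regenerable from the seed); the
participant and trial tables are what downstream scripts consume.
"""

import argparse
from pathlib import Path

from gaitsym.pipeline import simulate_to_dir
from gaitsym.simulate import CohortDesign


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20220701)
    ap.add_argument("--scale", type=int, default=0,
                    help="participants per group (0 = full 137-participant design)")
    ap.add_argument("--out", type=Path, default=Path("scratch/cohort"))
    args = ap.parse_args()

    design = CohortDesign()
    if args.scale:
        design = design.scaled(args.scale)
    out = simulate_to_dir(design, args.seed, args.out, write_ground_truth=False)
    print(f"simulated {design.n_participants} participants "
          f"({design.n_participants * 9} trials) under {out}")


if __name__ == "__main__":
    main()
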