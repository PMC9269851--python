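#!/usr/bin/env python
"""Raw traces -> per-trial Symmetry Index and normalized walking speed."""

import argparse
from pathlib import Path

from gaitsym.config import PipelineConfig
from gaitsym.pipeline import process_directory


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="in_dir", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/processed"))
    ap.add_argument("--config", type=Path, default=None)
    args = ap.parse_args()

    cfg = PipelineConfig.from_yaml(args.config) if args.config else PipelineConfig()
    out = process_directory(args.in_dir, args.out, cfg)
    print(f"si_results.csv and speed_results.csv written under {out}")


if __name__ == "__main__":
    main()
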