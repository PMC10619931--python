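"""Shared bootstrap for the analysis drivers: build the simulated study.

The simulation is fully deterministic in the seed, so every driver can
rebuild the identical dataset instead of passing large intermediates
around; driver 01 additionally materialises the standard-format files
for inspection.
"""

import argparse
import sys
from pathlib import Path

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

from l1locus.synthetic_data import SimConfig, build_toy_genome, simulate_reads  # noqa: E402


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--results", type=Path, default=REPO / "results")
    parser.add_argument("--scratch", type=Path, default=REPO / "scratch")
    args = parser.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)
    return args


def build_study(seed: int):
    genome = build_toy_genome(SimConfig(seed=seed))
    return simulate_reads(genome)
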