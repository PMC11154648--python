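"""Generate the default synthetic national seafood system.

Builds the 31-province world (11 coastal), its contaminant field, species
table and noisy observed trade flows, and writes every input table the
later stages read.  Prints the scale of the system it generated.

Run:  python analysis/01_simulate_world.py [--seed 1] [--out results/run]
"""

import argparse
from pathlib import Path

from seatrade.pipeline import RunConfig, stage_simulate


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    config = RunConfig.from_mapping({"world": {"seed": args.seed}})
    files = stage_simulate(config, args.out)

    from seatrade.io import read_world

    world = read_world(args.out)
    print(f"wrote {len(files)} tables to {args.out}")
    print(f"provinces: {len(world.names)} ({len(world.coastal)} coastal)")
    print(f"national supply {world.supply.values.sum():.1f} kt/yr, "
          f"demand {world.demand.values.sum():.1f} kt/yr "
          f"(surplus {world.supply.values.sum() - world.demand.values.sum():.1f})")
    rates = world.consumption.sum(axis=1)
    coastal = world.provinces.coastal
    print(f"mean per-capita seafood intake: coastal "
          f"{rates[coastal].mean():.1f} g/day, inland {rates[~coastal].mean():.1f} g/day")


if __name__ == "__main__":
    main()
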