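#!/usr/bin/env python
"""Generate the synthetic 8-herd Holstein population used by the analysis.

Writes the raw tables (pedigree, lactations, dated treatment events, 305-d
production/SCS, conformation, ground truth) to scratch/herd/ -- the later
numbered scripts read from there.  The configuration is the package default:
2,214 first-parity cows from 260 AI sires across 8 herds, category incidence
targets near the field frequencies (26.5 / 13.3 / 26.7 / 7.7 / 14.1 percent),
and the documented synthetic cost table.
"""

from pathlib import Path

from herdhealth.simulate import SimulationConfig, simulate_herd
from herdhealth.treatments import default_cost_table

OUTDIR = Path(__file__).resolve().parent.parent / "scratch" / "herd"
SEED = 42


def main() -> None:
    config = SimulationConfig(seed=SEED)
    herd = simulate_herd(config)
    herd.write(OUTDIR)
    default_cost_table().to_yaml(OUTDIR / "cost_table.yaml")
    n1 = (herd.lactations["parity"] == 1).sum()
    print(f"simulated {len(herd.cows)} cows in {config.n_herds} herds (seed {SEED})")
    print(f"  lactations: {len(herd.lactations)} ({n1} first parity)")
    print(f"  raw treatment records: {len(herd.events)}")
    print(f"  sires: {herd.cows['sire_id'].nunique()}, "
          f"MGS: {herd.cows['mgs_id'].nunique()}")
    print(f"wrote tables to {OUTDIR}")


if __name__ == "__main__":
    main()
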