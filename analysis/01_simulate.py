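#!/usr/bin/env python
"""Generate the two reference synthetic communities used by all later steps.

* a neutral community (20 plants x 30 pollinators, 2000 visits) where
  visitation follows relative abundance only — the regime the sharing null
  model assumes, used for calibration;
* a trait-structured community (40 x 60, 4 planted modules, affinity 0.95,
  2000 visits) used for module recovery, roles and influence.

Writes long-format records and ground-truth module tables to results/data/.
"""

import sys
from pathlib import Path

import pandas as pd

import pollinet as pn
from pollinet.network import records_to_csv

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def write_truth(gt: pn.GroundTruth, path: Path) -> None:
    rows = [
        {"species": s, "level": "plant", "module": m}
        for s, m in gt.plant_modules.items()
    ] + [
        {"species": s, "level": "pollinator", "module": m}
        for s, m in gt.pollinator_modules.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    neutral_cfg = pn.SyntheticConfig(
        n_plants=20, n_pollinators=30, n_modules=1, affinity=0.0,
        abundance_sigma=1.0, total_visits=2000, seed=pn.derive_seed(SEED, "neutral"),
    )
    records, gt = pn.generate_neutral(neutral_cfg)
    records_to_csv(records, OUT / "neutral_records.csv")
    write_truth(gt, OUT / "neutral_truth.csv")
    print(
        f"neutral: {sum(r.count for r in records)} events, "
        f"{len(gt.plant_modules)} plants, {len(gt.pollinator_modules)} pollinators "
        f"({len(gt.dropped_plants)} plants, {len(gt.dropped_pollinators)} "
        f"pollinators dropped with zero interactions)"
    )

    modular_cfg = pn.SyntheticConfig(
        n_plants=40, n_pollinators=60, n_modules=4, affinity=0.95,
        abundance_sigma=1.0, total_visits=2000, seed=pn.derive_seed(SEED, "modular"),
    )
    records, gt = pn.generate_modular(modular_cfg)
    records_to_csv(records, OUT / "modular_records.csv")
    write_truth(gt, OUT / "modular_truth.csv")
    print(
        f"modular: {sum(r.count for r in records)} events, "
        f"{len(gt.plant_modules)} plants, {len(gt.pollinator_modules)} pollinators, "
        f"4 planted modules at affinity 0.95"
    )


if __name__ == "__main__":
    main()
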