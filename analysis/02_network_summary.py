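#!/usr/bin/env python
"""Pool the simulated visitation records and report visit-share summaries.

For each reference community: total interactions, species counts, the
most-visited plant and pollinator, and the focal plant's shared/unique
visitor statistics.  Tables go to results/summary/.
"""

from pathlib import Path

import pollinet as pn

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "summary"


def summarize(name: str) -> None:
    records = pn.read_visitation_records(BASE / "data" / f"{name}_records.csv")
    net = pn.pool_records(records)
    pn.write_matrix_tsv(net, OUT / f"{name}_network.tsv")
    rep = pn.network_summary(net)
    rep.plant_shares.to_csv(OUT / f"{name}_plant_shares.csv", index=False)
    rep.pollinator_shares.to_csv(OUT / f"{name}_pollinator_shares.csv", index=False)
    top_plant = rep.plant_shares.iloc[0]
    top_poll = rep.pollinator_shares.iloc[0]
    print(
        f"{name}: {rep.total_interactions} interactions, {rep.n_plants} plants, "
        f"{rep.n_pollinators} pollinators"
    )
    print(
        f"  most visited plant: {top_plant['plant']} ({top_plant['share_pct']}%); "
        f"most active pollinator: {top_poll['pollinator']} "
        f"({top_poll['share_pct']}%, visits {top_poll['plants_visited']} plant species)"
    )
    focal = str(top_plant["plant"])
    sharing = pn.shared_pollinator_stats(net, focal)
    print(
        f"  focal {focal}: {sharing.n_interactions} interactions from "
        f"{sharing.n_visitor_taxa} taxa; {sharing.shared_taxa_pct}% of its visitor "
        f"taxa are shared with other plants; unique visitors contribute "
        f"{sharing.unique_interaction_pct}% of its interactions"
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in ("neutral", "modular"):
        summarize(name)


if __name__ == "__main__":
    main()
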