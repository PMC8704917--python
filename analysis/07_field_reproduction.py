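#!/usr/bin/env python
"""Run the full analysis on an empirical field visitation dataset.

Requires the survey's records exported as a long-format CSV with columns
plant, pollinator[, site, date, count] at data/field/visitation.csv.  Field
data are not redistributed here; without the file this driver explains
what to do and exits.
"""

import sys
from pathlib import Path

import pollinet as pn

FIELD = Path(__file__).resolve().parent.parent / "data" / "field" / "visitation.csv"
OUT = Path(__file__).resolve().parent.parent / "results" / "field"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    if not FIELD.exists():
        print(
            f"field dataset not found at {FIELD}.\n"
            "Obtain the survey's visitation records and export them as a "
            "CSV with columns plant,pollinator[,site,date,count], then rerun."
        )
        raise SystemExit(1)
    OUT.mkdir(parents=True, exist_ok=True)
    net = pn.pool_records(pn.read_visitation_records(FIELD))
    rep = pn.network_summary(net)
    print(
        f"{rep.total_interactions} interactions, {rep.n_plants} plants, "
        f"{rep.n_pollinators} pollinators"
    )
    rep.plant_shares.to_csv(OUT / "plant_shares.csv", index=False)
    top = rep.plant_shares.iloc[0]
    print(f"most visited plant: {top['plant']} ({top['share_pct']}%)")

    focal = "Brassica napus"
    sharing = pn.shared_pollinator_stats(net, focal)
    print(
        f"{focal}: {sharing.n_interactions} interactions from "
        f"{sharing.n_visitor_taxa} taxa, {sharing.shared_taxa_pct}% shared, "
        f"unique visitors {sharing.unique_interaction_pct}% of interactions"
    )

    env = pn.null_sharing_envelope(net, focal, n_rep=1000,
                                   seed=pn.derive_seed(SEED, "field-env"))
    from pollinet.sharing import envelopes_to_frame

    envelopes_to_frame(env).to_csv(OUT / "null_sharing.csv", index=False)

    part = pn.meta_optimize(net, n_restarts=10, seed=pn.derive_seed(SEED, "field-mod"))
    print(f"modularity Q = {part.q:.3f}, {part.n_modules} modules")
    part.to_frame().to_csv(OUT / "modules.csv", index=False)

    thr = pn.role_thresholds(net, n_null=1000, quantile=0.95,
                             seed=pn.derive_seed(SEED, "field-roles"))
    print(
        f"thresholds: plants c = {thr.plant_c:.2f}, z = {thr.plant_z:.2f}; "
        f"pollinators c = {thr.pollinator_c:.2f}, z = {thr.pollinator_z:.2f}"
    )
    roles = pn.classify_roles(pn.cz_values(net, part), thr)
    from pollinet.roles import roles_to_frame

    roles_to_frame(roles).to_csv(OUT / "roles.csv", index=False)

    for level in ("plants", "pollinators"):
        summary = pn.influence_summary(pn.mueller_matrix(net, level))
        summary.to_csv(OUT / f"mueller_{level}.csv", index=False)
        top = summary.iloc[0]
        print(
            f"top {level} influence: {top['species']} "
            f"(sum {top['sum']:.2f}, mean {top['mean']:.2f})"
        )


if __name__ == "__main__":
    main()
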