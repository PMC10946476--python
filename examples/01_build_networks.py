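"""Build weighted bipartite networks from blood-meal records.

A minimal record set: one study that sampled in two habitats.  Each row is
a (fly species, host species) pairing with the number of blood meals in
which it was identified.
"""

import pandas as pd

from bloodmealnet import RecordTable, aggregate_global, split_networks

rows = []
for habitat, dip, host, count in [
    ("Agricultural", "Culex pipiens", "cattle", 14),
    ("Agricultural", "Culex pipiens", "human", 2),
    ("Agricultural", "Aedes vexans", "cattle", 9),
    ("NearNatural", "Culex pipiens", "Vulpes vulpes", 3),
    ("NearNatural", "Aedes vexans", "Turdus merula", 5),
    ("NearNatural", "Aedes vexans", "Vulpes vulpes", 2),
]:
    rows.append({"study_id": "S1", "site_id": "site1", "latitude": 48.2,
                 "habitat": habitat, "diptera_taxon": dip,
                 "diptera_rank": "species", "diptera_family": "Culicidae",
                 "host_taxon": host, "host_rank": "species", "count": count})

records = RecordTable(pd.DataFrame(rows))
nets = split_networks(records)

print(f"{len(nets)} networks from {records.total_count()} blood meals")
for net in nets:
    print(f"  {net.network_id}: {net.n_diptera} flies x {net.n_hosts} hosts, "
          f"{net.links} links, matrix size m={net.m}")

agg = aggregate_global(nets)
print(f"aggregated: {agg.n_diptera} flies, {agg.n_hosts} hosts, "
      f"{agg.links} links")
# One network per (study, habitat); the aggregate pools every pairing, so
# its matrix size equals the total number of blood meals.
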