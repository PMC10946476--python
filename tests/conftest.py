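import numpy as np
import pandas as pd
import pytest

from bloodmealnet.networks import InteractionMatrix
from bloodmealnet.records import RecordTable


def mk_matrix(cells, habitat="Agricultural", latitude=10.0, family="Culicidae",
              study="S001", diptera=None, hosts=None, families=None):
    """Build an InteractionMatrix straight from a 2-D array of counts."""
    cells = np.asarray(cells, dtype=int)
    nr, nc = cells.shape
    diptera = diptera or [f"Fly {chr(97 + i)}" for i in range(nr)]
    hosts = hosts or [f"Host {chr(97 + j)}" for j in range(nc)]
    w = pd.DataFrame(cells, index=diptera, columns=hosts)
    fam = pd.Series(families or family, index=w.index)
    return InteractionMatrix(weights=w, row_families=fam,
                             network_id=(study, habitat), latitude=latitude,
                             habitat=habitat)


def record_rows(*rows):
    """Rows of (study, habitat, diptera, host, count[, extra dict])."""
    out = []
    for row in rows:
        study, habitat, dip, host, count = row[:5]
        extra = row[5] if len(row) > 5 else {}
        base = {"study_id": study, "site_id": "site1", "latitude": 10.0,
                "habitat": habitat, "diptera_taxon": dip,
                "diptera_rank": "species", "diptera_family": "Culicidae",
                "host_taxon": host, "host_rank": "species", "count": count}
        base.update(extra)
        out.append(base)
    return pd.DataFrame(out)


@pytest.fixture
def simple_records():
    return RecordTable(record_rows(
        ("S1", "Agricultural", "Aedes aegypti", "cattle", 2),
        ("S1", "Agricultural", "Aedes aegypti", "human", 1),
        ("S1", "Agricultural", "Culex pipiens", "cattle", 3),
    ))


@pytest.fixture
def two_habitat_records():
    return RecordTable(record_rows(
        ("S1", "Agricultural", "Aedes aegypti", "cattle", 2),
        ("S1", "Agricultural", "Culex pipiens", "cattle", 3),
        ("S1", "NearNatural", "Aedes aegypti", "Vulpes vulpes", 1),
        ("S1", "NearNatural", "Culex pipiens", "Vulpes vulpes", 4),
    ))
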