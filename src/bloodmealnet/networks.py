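"""Per-study, per-habitat weighted bipartite interaction matrices.

Records are split into one network per (study, habitat) pair — a study
sampling several habitats contributes one network per habitat, and several
sites of the same study within one habitat are pooled.  Each network is a
nonnegative integer Diptera-by-host matrix whose cells count blood meals.
Studies contributing a single Diptera taxon are excluded: a one-consumer
matrix is a host list, not a network.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bloodmealnet.records import RecordTable


@dataclass
class InteractionMatrix:
    """Weighted bipartite Diptera x host interaction matrix for one network.

    ``weights`` has Diptera taxa as the row index and host taxa as columns,
    both sorted lexicographically so the matrix is reproducible regardless
    of input row order.  ``row_families`` maps each Diptera taxon to its
    family.  No all-zero row or column is permitted.
    """

    weights: pd.DataFrame
    row_families: pd.Series
    network_id: tuple[str, str]
    latitude: float
    habitat: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = self.weights
        if (w.to_numpy() < 0).any():
            raise ValueError("negative interaction weights")
        if w.size and ((w.sum(axis=1) == 0).any() or (w.sum(axis=0) == 0).any()):
            raise ValueError("empty row or column in interaction matrix")

    # --- derived quantities -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.weights.to_numpy()

    @property
    def m(self) -> int:
        """Matrix size: the sum of all cells (total blood meals)."""
        return int(self.values.sum())

    @property
    def links(self) -> int:
        """Number of realized links (cells > 0)."""
        return int((self.values > 0).sum())

    @property
    def n_diptera(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hosts(self) -> int:
        return self.weights.shape[1]

    @property
    def richness(self) -> int:
        """S = consumer species + resource species (rows + columns)."""
        return self.n_diptera + self.n_hosts

    @property
    def is_empty(self) -> bool:
        return self.weights.size == 0

    def to_edge_list(self) -> pd.DataFrame:
        stacked = self.weights.stack()
        stacked = stacked[stacked > 0]
        out = stacked.rename("weight").reset_index()
        out.columns = ["diptera", "host", "weight"]
        return out


@dataclass
class NetworkSet:
    """The collection of networks built from one record table."""

    networks: list[InteractionMatrix]
    exclusions: list[dict] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)

    def by_habitat(self) -> dict[str, list[InteractionMatrix]]:
        out: dict[str, list[InteractionMatrix]] = {}
        for net in self.networks:
            out.setdefault(net.habitat, []).append(net)
        return out

    def total_meals(self) -> int:
        return sum(net.m for net in self.networks)


def build_matrix(records: pd.DataFrame | RecordTable,
                 latitude_policy: str = "error") -> InteractionMatrix:
    """Build one interaction matrix from rows sharing (study_id, habitat).

    Cell (i, j) is the summed count over all rows pairing Diptera i with
    host j; rows and columns are sorted lexicographically.  Conflicting
    latitudes within the network raise by default (``latitude_policy`` may
    be set to ``"mean"`` for pooled multi-site studies whose sites differ).
    """
    df = records.frame if isinstance(records, RecordTable) else records
    if df.empty:
        raise ValueError("cannot build a matrix from an empty record set")
    keys = df[["study_id", "habitat"]].drop_duplicates()
    if len(keys) > 1:
        raise ValueError(
            f"rows span multiple (study, habitat) pairs: {keys.values.tolist()}")
    study, habitat = keys.iloc[0]

    lats = sorted(df["latitude"].unique())
    if len(lats) > 1:
        if latitude_policy == "mean":
            latitude = float(np.mean(df["latitude"]))
        else:
            raise ValueError(
                f"conflicting latitudes within network ({study}, {habitat}): {lats}")
    else:
        latitude = float(lats[0])

    weights = (df.pivot_table(index="diptera_taxon", columns="host_taxon",
                              values="count", aggfunc="sum", fill_value=0)
                 .astype(int))
    weights = weights.sort_index(axis=0).sort_index(axis=1)
    weights.index.name, weights.columns.name = "diptera", "host"

    fam = df.groupby("diptera_taxon")["diptera_family"].agg(
        lambda s: s.mode().iloc[0])
    fam = fam.reindex(weights.index)

    return InteractionMatrix(weights=weights, row_families=fam,
                             network_id=(str(study), str(habitat)),
                             latitude=latitude, habitat=str(habitat))


def split_networks(records: RecordTable, min_diptera: int = 2,
                   latitude_policy: str = "error") -> NetworkSet:
    """Split records into per-(study, habitat) networks.

    Networks with fewer than ``min_diptera`` Diptera taxa are excluded
    (single-consumer studies carry no network structure) and listed in
    ``exclusions``.
    """
    df = records.frame
    if df.empty:
        warnings.warn("empty record set: no networks built", stacklevel=2)
        return NetworkSet(networks=[], provenance=_digest(df))

    networks, exclusions = [], []
    for (study, habitat), sub in df.groupby(["study_id", "habitat"],
                                            sort=True):
        mat = build_matrix(sub, latitude_policy=latitude_policy)
        if mat.n_diptera < min_diptera:
            exclusions.append({
                "network_id": (str(study), str(habitat)),
                "reason": f"fewer than {min_diptera} Diptera taxa "
                          f"({mat.n_diptera})",
                "meals": mat.m})
            continue
        networks.append(mat)
    return NetworkSet(networks=networks, exclusions=exclusions,
                      provenance=_digest(df))


def dominant_family(matrix: InteractionMatrix) -> tuple[str, bool]:
    """Family with the highest total interaction count in the network.

    Returns ``(family, tied)``; exact ties are broken alphabetically and
    flagged.
    """
    if matrix.row_families.isna().any():
        missing = matrix.row_families.index[matrix.row_families.isna()]
        raise ValueError(f"missing family annotation for {list(missing)}")
    totals = matrix.weights.sum(axis=1).groupby(matrix.row_families).sum()
    top = totals.max()
    winners = sorted(totals.index[totals == top])
    return winners[0], len(winners) > 1


def aggregate_global(networks: NetworkSet) -> InteractionMatrix:
    """Pool all networks into one aggregated matrix (union of node labels,
    cellwise sums)."""
    if not networks.networks:
        raise ValueError("cannot aggregate an empty NetworkSet")
    edge_frames = []
    fams = {}
    for net in networks:
        edge_frames.append(net.to_edge_list())
        fams.update(net.row_families.to_dict())
    edges = pd.concat(edge_frames, ignore_index=True)
    weights = (edges.pivot_table(index="diptera", columns="host",
                                 values="weight", aggfunc="sum", fill_value=0)
                    .astype(int).sort_index(axis=0).sort_index(axis=1))
    fam = pd.Series(fams).reindex(weights.index)
    return InteractionMatrix(weights=weights, row_families=fam,
                             network_id=("aggregate", "all"),
                             latitude=float("nan"), habitat="all")


def _digest(df: pd.DataFrame) -> str:
    payload = df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
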