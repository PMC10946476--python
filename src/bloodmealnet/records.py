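"""Reading, validation and taxonomic resolution of blood-meal interaction records.

A record table holds one row per (study, site, habitat, Diptera taxon, host
taxon) with the number of blood meals observed for that pairing.  Taxa that
could not be identified to species are carried with their rank (``genus`` or
``family``); :func:`resolve_taxa` applies the node-labelling and exclusion
rules used when compiling literature networks: a single unidentified species
within a genus becomes a ``"<Genus> spp."`` node, several unidentified
species in one genus are kept as a single node only when a sympatry lookup
says no congeneric (or confamilial) species co-occur at the study location,
and anything that cannot be placed at genus or family level is removed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import InitVar, dataclass, field
from pathlib import Path

import pandas as pd

HABITATS = ("Agricultural", "NearNatural", "VillageUrban")
FAMILIES = ("Ceratopogonidae", "Culicidae", "Glossinidae", "Psychodidae",
            "Simuliidae", "Other")
RANKS = ("species", "genus", "family")

COLUMNS = ("study_id", "site_id", "latitude", "habitat", "diptera_taxon",
           "diptera_rank", "diptera_family", "host_taxon", "host_rank",
           "count")

#: key identifying a unique interaction record; duplicates are summed on read
DEDUP_KEY = ["study_id", "site_id", "latitude", "habitat", "diptera_taxon",
             "diptera_rank", "diptera_family", "host_taxon", "host_rank"]

_SP_MARKER = re.compile(r"\s+(spp?\.?)(\s+[A-Z0-9]+)?$")


class SchemaError(ValueError):
    """The file or frame does not match the canonical record schema."""


class RecordError(ValueError):
    """Individual rows violate a field-level invariant."""


@dataclass
class RecordTable:
    """Validated table of blood-meal interaction records.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; rows are
    guaranteed to satisfy the field invariants (count >= 1, latitude in
    [-90, 90], habitat and family drawn from their closed vocabularies).
    """

    frame: pd.DataFrame
    #: sum rows duplicated on DEDUP_KEY (kept as-is when False, e.g. after a
    #: taxon collapse where row counts must reconcile with a ResolutionLog)
    sum_duplicates: InitVar[bool] = True

    def __post_init__(self, sum_duplicates: bool) -> None:
        self.frame = validate_frame(self.frame, sum_duplicates=sum_duplicates)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecordTable):
            return NotImplemented
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        return a.equals(b)

    def total_count(self) -> int:
        return int(self.frame["count"].sum())


@dataclass
class SympatryTable:
    """Lookup (taxon base label, study) -> number of plausible sympatric
    congeneric/confamilial species at that study's location.

    A value of 1 means the unidentified material can only belong to one
    species, so a genus- or family-level node is safe; values >= 2 mean the
    node would mix species and the interactions must be discarded.
    """

    table: dict[tuple[str, str], int] = field(default_factory=dict)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SympatryTable":
        df = pd.read_csv(path, dtype=str)
        required = {"taxon", "study_id", "n_sympatric_species"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"sympatry table missing columns: {sorted(missing)}")
        table = {}
        for _, row in df.iterrows():
            n = int(row["n_sympatric_species"])
            if n < 1:
                raise RecordError(
                    f"sympatry count must be >= 1, got {n} for "
                    f"({row['taxon']}, {row['study_id']})")
            table[(str(row["taxon"]), str(row["study_id"]))] = n
        return cls(table)

    def lookup(self, taxon: str, study_id: str) -> int | None:
        return self.table.get((taxon, study_id))


@dataclass
class ResolutionLog:
    """Bookkeeping of what :func:`resolve_taxa` changed or discarded."""

    removed_hosts: int = 0
    removed_diptera: int = 0
    removed_interactions: int = 0
    collapsed_nodes: list[tuple[str, str]] = field(default_factory=list)
    dispositions: list[dict] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return (self.removed_interactions == 0 and not self.collapsed_nodes
                and not self.dispositions)


def validate_frame(df: pd.DataFrame, sum_duplicates: bool = True,
                   ) -> pd.DataFrame:
    """Validate and coerce a raw frame to the canonical record schema.

    Raises :class:`SchemaError` for structural problems (missing columns,
    labels outside the habitat/family/rank vocabularies) and
    :class:`RecordError` for row-level value problems, listing the offending
    rows.  Zero-count rows are dropped with a warning; duplicated records
    are summed with a warning.
    """
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    df = df.loc[:, list(COLUMNS)].copy()

    for col in ("study_id", "site_id", "diptera_taxon", "diptera_rank",
                "diptera_family", "host_taxon", "host_rank", "habitat"):
        df[col] = df[col].astype(str).str.strip()

    bad_habitat = sorted(set(df["habitat"]) - set(HABITATS))
    if bad_habitat:
        raise SchemaError(
            f"habitat labels {bad_habitat} not in {list(HABITATS)}")
    bad_family = sorted(set(df["diptera_family"]) - set(FAMILIES))
    if bad_family:
        raise SchemaError(
            f"diptera_family labels {bad_family} not in {list(FAMILIES)}")

    lat = pd.to_numeric(df["latitude"], errors="coerce")
    bad = df.index[lat.isna() | (lat < -90) | (lat > 90)]
    if len(bad):
        raise RecordError(f"unparseable or out-of-range latitude in rows "
                          f"{list(bad)}: {df.loc[bad, 'latitude'].tolist()}")
    df["latitude"] = lat.astype(float)

    cnt = pd.to_numeric(df["count"], errors="coerce")
    nonint = cnt.isna() | (cnt != cnt.round()) | (cnt < 0)
    bad = df.index[nonint]
    if len(bad):
        raise RecordError(f"count must be a nonnegative integer; bad rows "
                          f"{list(bad)}: {df.loc[bad, 'count'].tolist()}")
    df["count"] = cnt.round().astype(int)

    zero = df["count"] == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} zero-count rows",
                      stacklevel=2)
        df = df.loc[~zero]

    if sum_duplicates and df.duplicated(DEDUP_KEY).any():
        n_before = len(df)
        df = (df.groupby(DEDUP_KEY, as_index=False, sort=False)["count"]
                .sum())
        df = df.loc[:, list(COLUMNS)]
        warnings.warn(
            f"summed {n_before - len(df)} duplicate records", stacklevel=2)

    return df.reset_index(drop=True)


def read_records(path: str | Path, delimiter: str = ",") -> RecordTable:
    """Read a delimited record file (UTF-8, header row required)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8")
    return RecordTable(df)


def write_records(records: RecordTable, path: str | Path) -> None:
    """Write records as canonical CSV; read(write(x)) == x."""
    records.frame.to_csv(path, index=False, encoding="utf-8")


def base_label(taxon: str) -> str:
    """Strip 'sp.'/'spp.' markers: 'Culicoides sp. A' -> 'Culicoides'."""
    return _SP_MARKER.sub("", taxon.strip())


def _resolve_side(df: pd.DataFrame, side: str, sympatry: SympatryTable,
                  log: ResolutionLog) -> pd.DataFrame:
    """Apply the labelling/exclusion rules to one side (diptera or host)."""
    taxon_col, rank_col = f"{side}_taxon", f"{side}_rank"
    keep = pd.Series(True, index=df.index)

    # rule (c): anything not placeable at species/genus/family level goes
    above = ~df[rank_col].isin(RANKS)
    for idx in df.index[above]:
        log.dispositions.append({
            "side": side, "study_id": df.at[idx, "study_id"],
            "label": df.at[idx, taxon_col], "reason": "above_family_rank"})
    keep &= ~above

    unresolved = keep & df[rank_col].isin(("genus", "family"))
    relabel: dict[int, str] = {}
    groups = df.loc[unresolved].groupby(
        ["study_id", df.loc[unresolved, taxon_col].map(base_label)],
        sort=False)
    for (study, base), sub in groups:
        labels = sorted(sub[taxon_col].unique())
        node = f"{base} spp."
        if len(labels) == 1:
            # rule (a): one unidentified species -> genus/family node
            relabel.update({i: node for i in sub.index})
            if labels[0] != node:
                log.collapsed_nodes.append((labels[0], node))
            continue
        # rule (b): several unidentified species share the node only when
        # no sympatric congener/confamilial can occur at this study
        n_symp = sympatry.lookup(base, study)
        if n_symp is None:
            keep[sub.index] = False
            log.dispositions.append({
                "side": side, "study_id": study, "label": base,
                "reason": "unresolvable_no_sympatry_entry"})
        elif n_symp >= 2:
            keep[sub.index] = False
            log.dispositions.append({
                "side": side, "study_id": study, "label": base,
                "reason": f"ambiguous_multispecies(n_sympatric={n_symp})"})
        else:
            relabel.update({i: node for i in sub.index})
            for lab in labels:
                if lab != node:
                    log.collapsed_nodes.append((lab, node))

    out = df.loc[keep].copy()
    idx = [i for i in relabel if i in out.index]
    out.loc[idx, taxon_col] = [relabel[i] for i in idx]
    return out


def resolve_taxa(records: RecordTable,
                 sympatry: SympatryTable | None = None,
                 ) -> tuple[RecordTable, ResolutionLog]:
    """Resolve taxon labels and drop unresolvable interactions.

    Returns the resolved table and a :class:`ResolutionLog` whose counts
    reconcile exactly with the rows removed (input rows = output rows +
    ``removed_interactions``).  The sympatry rule is applied per ``study_id``:
    co-occurrence is a property of the study's location, so the same genus
    may be collapsible in one study and ambiguous in another.
    """
    sympatry = sympatry or SympatryTable()
    df = records.frame
    log = ResolutionLog()

    out = _resolve_side(df, "diptera", sympatry, log)
    out = _resolve_side(out, "host", sympatry, log)

    log.removed_interactions = len(df) - len(out)
    kept_hosts = set(out["host_taxon"])
    kept_dip = set(out["diptera_taxon"])
    dropped = df.loc[~df.index.isin(out.index)]
    collapsed_from = {orig for orig, _ in log.collapsed_nodes}
    log.removed_hosts = len(
        set(dropped["host_taxon"]) - kept_hosts - collapsed_from)
    log.removed_diptera = len(
        set(dropped["diptera_taxon"]) - kept_dip - collapsed_from)

    return RecordTable(out, sum_duplicates=False), log
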