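"""Dirichlet-multinomial generator of synthetic blood-meal record sets.

Each synthetic network is built in three stages that mirror how real
blood-meal data arise: (1) a host community is drawn for the site — a
Dirichlet sample whose concentration controls how strongly a few hosts
dominate, with the expected share of meals on domestic hosts (and on
cattle and humans specifically) set per habitat; (2) each Diptera species
receives a host-preference distribution, a Dirichlet draw centred on the
community weights whose concentration controls how host-specific
individual fly species are; (3) blood-meal counts are a single multinomial
draw over (fly, host) pairs.  Interaction evenness therefore responds
directly to the dominance settings, and H2' to the preference
concentration.

The default scenario reproduces the structure of the compiled literature
data: 14 Agricultural, 18 Near-natural and 15 Village/Urban networks,
about 190 blood meals per network (~9100 in total), Agricultural
communities with ~81% of meals on domestic hosts and ~51% on cattle,
Village/Urban communities with ~26% of meals on humans, Diptera drawn
from five families in roughly the observed proportions, and latitudes
spanning the tropics to ~60 degrees.  Latitude is attached to each network
but has no structural effect by default (the null latitudinal scenario);
``latitude_effect`` injects one for power experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from bloodmealnet.networks import InteractionMatrix, NetworkSet
from bloodmealnet.records import HABITATS, RecordTable

DOMESTIC = ("human", "cattle", "chicken", "dog", "cat", "goat", "horse",
            "pig", "sheep")

WILD_HOSTS = (
    "Aepyceros melampus", "Alcelaphus buselaphus", "Ardea cinerea",
    "Bubalus arnee", "Canis aureus", "Cervus elaphus",
    "Columba livia", "Connochaetes taurinus", "Corvus corone",
    "Dasypus novemcinctus", "Didelphis marsupialis", "Emberiza citrinella",
    "Erithacus rubecula", "Giraffa camelopardalis", "Hippopotamus amphibius",
    "Hirundo rustica", "Kobus ellipsiprymnus", "Lepus europaeus",
    "Loxodonta africana", "Macaca mulatta", "Meles meles",
    "Odocoileus virginianus", "Oryctolagus cuniculus", "Papio anubis",
    "Passer domesticus", "Phacochoerus africanus", "Procyon lotor",
    "Rattus rattus", "Rupicapra rupicapra", "Sciurus vulgaris",
    "Sturnus vulgaris", "Sus scrofa", "Sylvia atricapilla",
    "Syncerus caffer", "Tragelaphus scriptus", "Turdus merula",
    "Turdus philomelos", "Vulpes vulpes",
)

DIPTERA_POOL = {
    "Culicidae": (
        "Aedes aegypti", "Aedes albopictus", "Aedes vexans",
        "Anopheles arabiensis", "Anopheles funestus", "Anopheles gambiae",
        "Coquillettidia perturbans", "Culex annulirostris",
        "Culex pipiens", "Culex quinquefasciatus", "Culex tarsalis",
        "Culex theileri", "Culiseta annulata", "Mansonia uniformis",
        "Ochlerotatus cantans", "Ochlerotatus caspius",
    ),
    "Ceratopogonidae": (
        "Culicoides brevitarsis", "Culicoides imicola",
        "Culicoides impunctatus", "Culicoides kibunensis",
        "Culicoides obsoletus", "Culicoides pallidicornis",
        "Culicoides punctatus", "Culicoides scoticus",
        "Culicoides sonorensis", "Culicoides stellifer",
    ),
    "Glossinidae": (
        "Glossina fuscipes", "Glossina morsitans", "Glossina pallidipes",
        "Glossina palpalis", "Glossina swynnertoni", "Glossina tachinoides",
    ),
    "Psychodidae": (
        "Lutzomyia longipalpis", "Phlebotomus argentipes",
        "Phlebotomus ariasi", "Phlebotomus papatasi",
        "Phlebotomus perniciosus", "Sergentomyia minuta",
    ),
    "Simuliidae": (
        "Simulium damnosum", "Simulium equinum", "Simulium lineatum",
        "Simulium ornatum", "Simulium venustum", "Simulium vittatum",
    ),
}

#: per-network dominant-family frequencies observed across the compiled
#: networks (Culicidae 24, Ceratopogonidae 12, Glossinidae 4, Psychodidae 4,
#: Simuliidae 2)
FAMILY_WEIGHTS = {"Culicidae": 24, "Ceratopogonidae": 12, "Glossinidae": 4,
                  "Psychodidae": 4, "Simuliidae": 2}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; the defaults are the study conditions."""

    n_networks_per_habitat: dict = field(default_factory=lambda: {
        "Agricultural": 14, "NearNatural": 18, "VillageUrban": 15})
    latitude_range: tuple = (-34.0, 60.0)
    meals_per_network: tuple = (120, 260)
    #: Dirichlet concentration of the host community (wild hosts and the
    #: non-headline domestic hosts), per habitat; smaller = a few hosts
    #: dominate = lower interaction evenness
    dominance: dict = field(default_factory=lambda: {
        "Agricultural": 0.4, "NearNatural": 2.5, "VillageUrban": 2.5})
    #: expected share of meals on domestic hosts, per habitat
    domestic_mass: dict = field(default_factory=lambda: {
        "Agricultural": 0.81, "NearNatural": 0.63, "VillageUrban": 0.63})
    #: expected absolute share of meals on cattle / on humans, per habitat
    cattle_share: dict = field(default_factory=lambda: {
        "Agricultural": 0.51, "NearNatural": 0.10, "VillageUrban": 0.06})
    human_share: dict = field(default_factory=lambda: {
        "Agricultural": 0.10, "NearNatural": 0.10, "VillageUrban": 0.26})
    #: concentration of each fly species' host-preference Dirichlet around
    #: the community weights; smaller = more host-specific flies
    preference_strength: float = 6.0
    #: concentration of the fly-activity Dirichlet (share of meals per
    #: fly), per habitat; agricultural fly communities are dominated by a
    #: few livestock-adapted species, hence the lower concentration there
    activity_concentration: dict = field(default_factory=lambda: {
        "Agricultural": 0.25, "NearNatural": 0.6, "VillageUrban": 0.6})
    diptera_per_network: tuple = (5, 14)
    wild_hosts_per_network: tuple = (10, 22)
    #: optional structural latitude effect: added to the wild-host
    #: dominance concentration as slope * |latitude| / 60 (0 = null)
    latitude_effect: float = 0.0
    host_pool: tuple = WILD_HOSTS
    domestic_pool: tuple = DOMESTIC
    diptera_pool: dict = field(default_factory=lambda: dict(DIPTERA_POOL))
    seed: int = 0

    def validate(self) -> None:
        for hab in self.n_networks_per_habitat:
            if hab not in HABITATS:
                raise ValueError(f"unknown habitat {hab!r}")
        for hab, dm in self.domestic_mass.items():
            if not 0.0 <= dm <= 1.0:
                raise ValueError(f"domestic_mass[{hab}] outside [0, 1]")
            if dm > 0 and not self.domestic_pool:
                raise ValueError(
                    "domestic_mass > 0 but the host pool has no domestic hosts")
            cs = self.cattle_share.get(hab, 0.0)
            hs = self.human_share.get(hab, 0.0)
            if cs + hs > dm + 1e-9:
                raise ValueError(
                    f"cattle+human share exceeds domestic mass in {hab}")
        if not self.diptera_pool or not self.host_pool:
            raise ValueError("empty taxon pool")


@dataclass
class GroundTruth:
    """Per-network generative state stored for recovery tests."""

    networks: list = field(default_factory=list)  # dicts per network

    def frame(self) -> pd.DataFrame:
        rows = []
        for g in self.networks:
            rows.append({
                "study_id": g["study_id"], "habitat": g["habitat"],
                "latitude": g["latitude"], "n_meals": g["n_meals"],
                "domestic_mass": g["domestic_mass"],
                "ie_offset": g["ie_offset"]})
        return pd.DataFrame(rows)


def default_scenario(seed: int = 0) -> SyntheticConfig:
    """The study conditions: 47 networks (14/18/15), ~190 meals each,
    habitat-dependent domestic-host dominance."""
    cfg = SyntheticConfig(seed=seed)
    cfg.validate()
    return cfg


def null_scenario(n_per_habitat: int = 20, seed: int = 0) -> SyntheticConfig:
    """No structural differences between habitats (equal dominance and
    domestic mass) and no latitude effect: every model term is null."""
    cfg = SyntheticConfig(
        n_networks_per_habitat={h: n_per_habitat for h in HABITATS},
        dominance={h: 1.0 for h in HABITATS},
        domestic_mass={h: 0.6 for h in HABITATS},
        cattle_share={h: 0.2 for h in HABITATS},
        human_share={h: 0.15 for h in HABITATS},
        activity_concentration={h: 0.5 for h in HABITATS},
        seed=seed)
    cfg.validate()
    return cfg


def _community_weights(cfg: SyntheticConfig, habitat: str, abs_lat: float,
                       wild: list[str], rng) -> dict[str, float]:
    """Host community meal shares: fixed expected cattle/human shares,
    Dirichlet spread over the remaining domestic and wild hosts."""
    dm = cfg.domestic_mass[habitat]
    cattle = cfg.cattle_share.get(habitat, 0.0)
    human = cfg.human_share.get(habitat, 0.0)
    other_dom = [d for d in cfg.domestic_pool if d not in ("cattle", "human")]
    w: dict[str, float] = {}
    # jitter the headline shares so networks differ
    w["cattle"] = max(rng.normal(cattle, 0.05 * cattle), 0.0) if cattle else 0.0
    w["human"] = max(rng.normal(human, 0.05 * human), 0.0) if human else 0.0
    conc = cfg.dominance[habitat] + cfg.latitude_effect * abs_lat / 60.0
    rest_dom = max(dm - w["cattle"] - w["human"], 0.0)
    if other_dom and rest_dom > 0:
        shares = rng.dirichlet(np.full(len(other_dom), max(conc, 1e-3)))
        for name, s in zip(other_dom, shares):
            w[name] = rest_dom * s
    wild_shares = rng.dirichlet(np.full(len(wild), max(conc, 1e-3)))
    wild_mass = max(1.0 - sum(w.values()), 0.0)
    for name, s in zip(wild, wild_shares):
        w[name] = wild_mass * s
    total = sum(w.values())
    return {k: v / total for k, v in w.items() if v > 0}


def sample_network(cfg: SyntheticConfig, habitat: str, latitude: float,
                   rng) -> tuple[pd.DataFrame, dict]:
    """Draw one network's blood-meal counts.

    Returns the (diptera x host) count frame with family annotations plus
    the generative ground truth.  At least two Diptera species with meals
    are guaranteed (degenerate multinomial draws are resampled).
    """
    cfg.validate()
    fams = list(FAMILY_WEIGHTS)
    fam_p = np.array([FAMILY_WEIGHTS[f] for f in fams], dtype=float)
    family = fams[rng.choice(len(fams), p=fam_p / fam_p.sum())]
    pool = list(cfg.diptera_pool[family])
    n_dip = int(rng.integers(cfg.diptera_per_network[0],
                             cfg.diptera_per_network[1] + 1))
    n_dip = min(n_dip, len(pool))
    diptera = sorted(rng.choice(pool, size=n_dip, replace=False).tolist())

    n_wild = int(rng.integers(cfg.wild_hosts_per_network[0],
                              cfg.wild_hosts_per_network[1] + 1))
    wild = sorted(rng.choice(list(cfg.host_pool), size=n_wild,
                             replace=False).tolist())
    weights = _community_weights(cfg, habitat, abs(latitude), wild, rng)
    hosts = sorted(weights)
    w = np.array([weights[h] for h in hosts])

    # per-fly host preference centred on the community
    alpha = np.maximum(cfg.preference_strength * w, 1e-3)
    pref = rng.dirichlet(alpha, size=n_dip)
    activity = rng.dirichlet(
        np.full(n_dip, cfg.activity_concentration[habitat]))
    p = (activity[:, None] * pref).ravel()
    p = p / p.sum()

    n_meals = int(rng.integers(cfg.meals_per_network[0],
                               cfg.meals_per_network[1] + 1))
    counts = rng.multinomial(n_meals, p).reshape(n_dip, len(hosts))
    counts = _top_up(counts, pref, w, rng)

    frame = pd.DataFrame(counts, index=diptera, columns=hosts)
    truth = {"habitat": habitat, "latitude": float(latitude),
             "family": family, "n_meals": n_meals,
             "community_weights": weights, "preference": pref,
             "activity": activity,
             "domestic_mass": float(sum(
                 weights.get(d, 0.0) for d in cfg.domestic_pool)),
             "ie_offset": 0.0}
    return frame, truth


def _top_up(counts: np.ndarray, pref: np.ndarray, w: np.ndarray,
            rng) -> np.ndarray:
    """Give every sampled taxon at least one meal, moving meals from the
    largest cell.

    A compiled network contains exactly the taxa that were observed; by
    construction every sampled fly and host is observed here, so realized
    richness is set by the (habitat-independent) pool draws rather than by
    the habitat's evenness regime.  This keeps the habitat effect on
    evenness identifiable beyond the size covariates, as in the compiled
    data where it persists with S and log m controlled.
    """
    counts = counts.copy()
    for i in np.flatnonzero(counts.sum(axis=1) == 0):
        src = np.unravel_index(np.argmax(counts), counts.shape)
        if counts[src] <= 1:
            break
        counts[src] -= 1
        j = int(np.argmax(pref[i]))
        counts[i, j] += 1
    for j in np.flatnonzero(counts.sum(axis=0) == 0):
        src = np.unravel_index(np.argmax(counts), counts.shape)
        if counts[src] <= 1 or src[1] == j:
            break
        counts[src] -= 1
        i = int(np.argmax(counts.sum(axis=1)))
        counts[i, j] += 1
    return counts


def generate_networks(cfg: SyntheticConfig,
                      seed: int | None = None,
                      ) -> tuple[NetworkSet, GroundTruth]:
    """Generate the full scenario directly as interaction matrices.

    This is the fast path used by calibration experiments;
    :func:`generate_dataset` routes the same draws through the record
    table so the whole pipeline can be exercised.
    """
    cfg.validate()
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    networks, truths = [], GroundTruth()
    idx = 0
    for habitat in sorted(cfg.n_networks_per_habitat):
        for _ in range(cfg.n_networks_per_habitat[habitat]):
            idx += 1
            study = f"S{idx:03d}"
            latitude = float(root.uniform(*cfg.latitude_range))
            frame, truth = sample_network(cfg, habitat, latitude, root)
            # drop hosts/flies that drew no meals
            frame = frame.loc[frame.sum(axis=1) > 0,
                              frame.sum(axis=0) > 0]
            fam = pd.Series(truth["family"], index=frame.index)
            net = InteractionMatrix(
                weights=frame.astype(int), row_families=fam,
                network_id=(study, habitat), latitude=latitude,
                habitat=habitat)
            networks.append(net)
            truth["study_id"] = study
            truths.networks.append(truth)
    return NetworkSet(networks=networks,
                      provenance=f"synthetic(seed={cfg.seed if seed is None else seed})"
                      ), truths


def generate_dataset(cfg: SyntheticConfig,
                     seed: int | None = None,
                     ) -> tuple[RecordTable, GroundTruth]:
    """Generate the scenario as a validated record table (one row per
    fly-host pairing with its blood-meal count)."""
    nets, truth = generate_networks(cfg, seed=seed)
    rows = []
    for net in nets:
        edges = net.to_edge_list()
        for _, e in edges.iterrows():
            rows.append({
                "study_id": net.network_id[0], "site_id": "site1",
                "latitude": net.latitude, "habitat": net.habitat,
                "diptera_taxon": e["diptera"], "diptera_rank": "species",
                "diptera_family": net.row_families[e["diptera"]],
                "host_taxon": e["host"], "host_rank": "species",
                "count": int(e["weight"])})
    return RecordTable(pd.DataFrame(rows)), truth


def latitude_scenario(slope: float, seed: int = 0) -> SyntheticConfig:
    """Default scenario with an injected latitudinal dominance gradient,
    for power experiments on the latitude term."""
    return replace(default_scenario(seed=seed), latitude_effect=slope)
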