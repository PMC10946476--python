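"""Incidence-based rarefaction and extrapolation of richness (q = 0).

Sampling completeness per habitat is assessed by treating each blood meal
as one sampling unit.  The incidence frequency Y_i of a host taxon, a
Diptera taxon or an individual interaction is the number of blood meals in
which it occurs; for an interaction that is simply its total weight.
Interpolated richness uses the classical hypergeometric form

    S(t) = S_obs - sum_i C(T - Y_i, t) / C(T, t),

extrapolation beyond T uses the incidence-based Chao2 asymptote

    S(T + t*) = S_obs + Q0 * (1 - (1 - Q1 / (Q1 + T*Q0))**t*),

with Q0 the Chao2 estimate of undetected richness and Q1, Q2 the singleton
and doubleton counts.  Binomial coefficients are evaluated with
log-gamma differences so curves stay stable at large effort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from bloodmealnet.networks import NetworkSet

ENTITIES = ("host", "diptera", "interaction")


@dataclass
class IncidenceData:
    """Incidence frequencies for one entity class in one habitat."""

    entity: str
    habitat: str
    T: int                      # sampling units = total blood meals
    Y: np.ndarray               # per-taxon/link incidence frequencies

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int64)
        if self.entity not in ENTITIES:
            raise ValueError(f"unknown entity {self.entity!r}")
        if (self.Y < 1).any() or (self.Y > self.T).any():
            raise ValueError("incidence frequencies must lie in [1, T]")
        if self.entity == "interaction" and int(self.Y.sum()) != self.T:
            raise ValueError(
                "interaction incidences must sum to T: each blood meal "
                "realises exactly one interaction")

    @property
    def S_obs(self) -> int:
        return int(self.Y.size)

    @property
    def Q1(self) -> int:
        return int((self.Y == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.Y == 2).sum())


@dataclass
class RarefactionCurve:
    entity: str
    habitat: str
    grid: pd.DataFrame          # columns t, estimate, kind
    asymptote: float            # Chao2

    def at(self, t: int) -> float:
        row = self.grid.loc[self.grid["t"] == t, "estimate"]
        if row.empty:
            raise KeyError(f"t={t} not on the curve grid")
        return float(row.iloc[0])


def incidence_from_networks(networks: NetworkSet, entity: str,
                            ) -> dict[str, IncidenceData]:
    """Pool networks per habitat and tabulate incidence frequencies.

    Host/Diptera frequency = total meals involving the taxon (summed
    across the habitat's networks); interaction frequency = the link's
    total weight.
    """
    if entity not in ENTITIES:
        raise ValueError(f"unknown entity {entity!r}")
    out: dict[str, IncidenceData] = {}
    for habitat, nets in sorted(networks.by_habitat().items()):
        tallies: dict = {}
        T = 0
        for net in nets:
            T += net.m
            edges = net.to_edge_list()
            if entity == "interaction":
                keyed = edges.set_index(["diptera", "host"])["weight"]
            elif entity == "diptera":
                keyed = edges.groupby("diptera")["weight"].sum()
            else:
                keyed = edges.groupby("host")["weight"].sum()
            for key, w in keyed.items():
                tallies[key] = tallies.get(key, 0) + int(w)
        if T == 0:
            warnings.warn(f"habitat {habitat} has zero blood meals; omitted",
                          stacklevel=2)
            continue
        Y = np.array([tallies[k] for k in sorted(tallies)], dtype=np.int64)
        out[habitat] = IncidenceData(entity=entity, habitat=habitat, T=T, Y=Y)
    return out


def chao2(data: IncidenceData) -> float:
    """Incidence-based Chao2 asymptotic richness.

    S_obs + ((T-1)/T) * Q1^2 / (2 Q2) when doubletons exist, with the
    bias-corrected Q1 (Q1 - 1) / 2 form when Q2 = 0.
    """
    if data.T < 2:
        raise ValueError("Chao2 requires at least two sampling units")
    q1, q2, T = data.Q1, data.Q2, data.T
    if q2 > 0:
        extra = (T - 1) / T * q1 * q1 / (2.0 * q2)
    else:
        extra = (T - 1) / T * q1 * (q1 - 1) / 2.0
    return float(data.S_obs + extra)


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def interpolate_richness(data: IncidenceData, t: int) -> float:
    """Expected richness in t of the T sampling units, drawn without
    replacement."""
    if not 1 <= t <= data.T:
        raise ValueError(f"t={t} outside [1, {data.T}]")
    T, Y = data.T, data.Y
    keep = (T - Y) >= t
    miss = np.zeros(Y.shape, dtype=float)
    if keep.any():
        miss[keep] = np.exp(_log_comb(T - Y[keep], t) - _log_comb(T, t))
    return float(data.S_obs - miss.sum())


def extrapolate_richness(data: IncidenceData, t_star: int) -> float:
    """Expected richness at effort T + t_star (t_star >= 0 extra units)."""
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    q0 = chao2(data) - data.S_obs
    q1 = data.Q1
    if q0 <= 0 or q1 == 0 or t_star == 0:
        return float(data.S_obs)
    rate = 1.0 - (1.0 - q1 / (q1 + data.T * q0)) ** t_star
    return float(data.S_obs + q0 * rate)


def build_curve(data: IncidenceData, n_knots: int = 40,
                endpoint: int | None = None) -> RarefactionCurve:
    """Interpolation/extrapolation curve on an effort grid from 1 to 2T
    (the doubling convention), continuous at t = T."""
    endpoint = 2 * data.T if endpoint is None else endpoint
    knots = np.unique(np.round(
        np.linspace(1, endpoint, n_knots)).astype(int))
    if data.T not in knots:
        knots = np.sort(np.append(knots, data.T))
    rows = []
    for t in knots:
        if t < data.T:
            est, kind = interpolate_richness(data, int(t)), "interpolated"
        elif t == data.T:
            est, kind = float(data.S_obs), "observed"
        else:
            est, kind = extrapolate_richness(data, int(t - data.T)), "extrapolated"
        rows.append({"t": int(t), "estimate": est, "kind": kind})
    return RarefactionCurve(entity=data.entity, habitat=data.habitat,
                            grid=pd.DataFrame(rows), asymptote=chao2(data))


def curves_frame(curves) -> pd.DataFrame:
    """Flat export of a collection of curves."""
    frames = []
    for c in curves:
        g = c.grid.copy()
        g.insert(0, "habitat", c.habitat)
        g.insert(1, "entity", c.entity)
        g["chao2_asymptote"] = c.asymptote
        frames.append(g)
    return pd.concat(frames, ignore_index=True)
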