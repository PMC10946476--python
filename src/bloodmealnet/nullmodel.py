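"""Targeted domestic-host removal null model.

For each network, every host column matching the domestic list (humans and
the common domesticated animals) is deleted, Diptera rows left with no
meals are dropped, and interaction evenness is recomputed.  That targeted
value is compared against the distribution of IE obtained when the same
number of host species is removed uniformly at random (domestic or not),
by default 100 replicates, summarised as a z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bloodmealnet.metrics import UndefinedMetricError, interaction_evenness
from bloodmealnet.networks import InteractionMatrix

#: Humans plus the domesticated animals targeted by the removal experiment.
DEFAULT_DOMESTIC_HOSTS = frozenset({
    "human", "chicken", "dog", "cat", "goat", "cattle", "horse", "pig",
    "sheep",
})

#: Common scientific/vernacular synonyms mapped onto the canonical names.
DEFAULT_SYNONYMS = {
    "homo sapiens": "human", "humans": "human", "man": "human",
    "bos taurus": "cattle", "bos indicus": "cattle", "cow": "cattle",
    "bovine": "cattle", "bos spp.": "cattle",
    "gallus gallus": "chicken", "gallus gallus domesticus": "chicken",
    "canis familiaris": "dog", "canis lupus familiaris": "dog",
    "felis catus": "cat",
    "capra hircus": "goat",
    "equus caballus": "horse", "equus ferus caballus": "horse",
    "sus scrofa domesticus": "pig", "sus domesticus": "pig",
    "ovis aries": "sheep",
}


@dataclass
class NullModelResult:
    network_id: tuple[str, str]
    habitat: str
    k_removed: int = 0
    ie_observed: float = float("nan")
    ie_targeted: float = float("nan")
    ie_random: np.ndarray = field(default_factory=lambda: np.array([]))
    z: float = float("nan")
    seed: int | None = None
    n_redraws: int = 0
    skipped: bool = False
    reason: str = ""


def load_domestic_hosts(path) -> tuple[frozenset[str], dict[str, str]]:
    """Read a domestic-host file: one name per line, an optional second
    comma-separated column giving the canonical name a synonym maps to."""
    hosts, synonyms = set(), {}
    for line in open(path, encoding="utf-8"):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) == 1:
            hosts.add(parts[0].lower())
        else:
            synonyms[parts[0].lower()] = parts[1].lower()
    return frozenset(hosts), synonyms


def match_domestic(columns, domestic=DEFAULT_DOMESTIC_HOSTS,
                   synonyms: dict[str, str] | None = None) -> list:
    """Host column labels that are domestic, matched case-insensitively
    through the synonym map."""
    synonyms = DEFAULT_SYNONYMS if synonyms is None else synonyms
    out = []
    for col in columns:
        key = str(col).strip().lower()
        key = synonyms.get(key, key)
        if key in domestic:
            out.append(col)
    return out


def remove_hosts(matrix: InteractionMatrix, hosts) -> InteractionMatrix | None:
    """Delete the named host columns, then any Diptera row left with zero
    meals.  Returns None when nothing remains (flagged empty network)."""
    present = [h for h in hosts if h in matrix.weights.columns]
    absent = set(hosts) - set(present)
    if absent:
        warnings.warn(f"hosts not present in network "
                      f"{matrix.network_id}: {sorted(map(str, absent))}",
                      stacklevel=2)
    w = matrix.weights.drop(columns=present)
    w = w.loc[w.sum(axis=1) > 0]
    w = w.loc[:, w.sum(axis=0) > 0]
    if w.size == 0 or w.to_numpy().sum() == 0:
        return None
    return InteractionMatrix(
        weights=w, row_families=matrix.row_families.reindex(w.index),
        network_id=matrix.network_id, latitude=matrix.latitude,
        habitat=matrix.habitat, meta=dict(matrix.meta, removed=len(present)))


def _ie_after_removal(matrix: InteractionMatrix, cols) -> float | None:
    sub = remove_hosts(matrix, cols)
    if sub is None:
        return None
    try:
        return interaction_evenness(sub)
    except UndefinedMetricError:
        return None


def run_null_model(matrix: InteractionMatrix,
                   domestic=DEFAULT_DOMESTIC_HOSTS,
                   synonyms: dict[str, str] | None = None,
                   n_reps: int = 100,
                   seed: int | None = None) -> NullModelResult:
    """Targeted removal of the domestic hosts versus removal of an equal
    number of randomly chosen host species, ``n_reps`` replicates.

    z = (IE_targeted - mean(IE_random)) / sd(IE_random).  Replicates whose
    post-removal network has fewer than two links (IE undefined) are
    redrawn, up to ``10 * n_reps`` total redraws.  Networks with no
    domestic hosts, or where targeted removal leaves no analysable
    network, are returned skipped with a reason instead of raising.
    """
    res = NullModelResult(network_id=matrix.network_id,
                          habitat=matrix.habitat, seed=seed)
    try:
        res.ie_observed = interaction_evenness(matrix)
    except UndefinedMetricError:
        pass

    if not domestic:
        res.skipped, res.reason = True, "empty domestic-host list"
        return res
    targets = match_domestic(matrix.weights.columns, domestic, synonyms)
    k = len(targets)
    res.k_removed = k
    if k == 0:
        res.skipped, res.reason = True, "no domestic hosts in network"
        return res
    if k == matrix.n_hosts:
        res.skipped, res.reason = True, "all hosts domestic (random = targeted)"
        return res

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ie_t = _ie_after_removal(matrix, targets)
    if ie_t is None:
        res.skipped = True
        res.reason = "targeted removal leaves no analysable network (L < 2)"
        return res
    res.ie_targeted = ie_t

    rng = np.random.default_rng(seed)
    cols = list(matrix.weights.columns)
    draws: list[float] = []
    redraws = 0
    while len(draws) < n_reps:
        pick = rng.choice(len(cols), size=k, replace=False)
        ie = _ie_after_removal(matrix, [cols[i] for i in pick])
        if ie is None:
            redraws += 1
            if redraws > 10 * n_reps:
                res.skipped = True
                res.reason = f"redraw cap exceeded ({redraws} degenerate draws)"
                res.n_redraws = redraws
                return res
            continue
        draws.append(ie)
    res.ie_random = np.array(draws)
    res.n_redraws = redraws

    mean = float(res.ie_random.mean())
    sd = float(res.ie_random.std(ddof=1))
    # IE is O(1), so spread below ~1e-12 is numerical noise from summation,
    # not real variance (identical draws can yield sd of a few ulp)
    if sd > 1e-12:
        res.z = (ie_t - mean) / sd
    elif abs(ie_t - mean) <= 1e-9:
        res.z = 0.0
    else:
        res.reason = "zero variance in random-removal IE; z undefined"
    return res


def summarise_null_by_habitat(results) -> pd.DataFrame:
    """Per-habitat mean, n and SE (sd / sqrt(n)) of the targeted-removal IE
    over non-skipped networks."""
    rows = []
    habitats = {r.habitat for r in results}
    for hab in sorted(habitats):
        vals = [r.ie_targeted for r in results
                if r.habitat == hab and not r.skipped]
        if not vals:
            warnings.warn(f"all networks skipped in habitat {hab}",
                          stacklevel=2)
            continue
        n = len(vals)
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append({"habitat": hab, "mean_ie_targeted": float(np.mean(vals)),
                     "n": n, "se": se})
    return pd.DataFrame(rows, columns=["habitat", "mean_ie_targeted", "n", "se"])


def results_frame(results) -> pd.DataFrame:
    """Flat per-network export of null-model results."""
    rows = []
    for r in results:
        rows.append({
            "study_id": r.network_id[0], "habitat": r.habitat,
            "k_removed": r.k_removed, "ie_observed": r.ie_observed,
            "ie_targeted": r.ie_targeted,
            "ie_random_mean": float(r.ie_random.mean()) if r.ie_random.size else float("nan"),
            "ie_random_sd": float(r.ie_random.std(ddof=1)) if r.ie_random.size > 1 else float("nan"),
            "z": r.z, "n_reps": int(r.ie_random.size), "seed": r.seed,
            "n_redraws": r.n_redraws, "skipped": r.skipped, "reason": r.reason})
    return pd.DataFrame(rows)
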