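"""Statistical stage: habitat/latitude models on the per-network metrics.

Responses (interaction evenness, H2') are modelled with a Gaussian GLM —
fitted as ordinary least squares, to which it is identical — with habitat,
absolute latitude, species richness S, log matrix size and dominant Diptera
family as terms, plus the family x latitude and family x habitat
interactions.  Term significance is assessed by nested-model deviance
comparison: the raw deviance change is reported as the X^2 statistic, and
the p-value comes from the dispersion-scaled change (deviance difference
divided by the fuller model's estimated dispersion).  With a Gaussian
response and estimated dispersion the exactly calibrated reference
distribution for that statistic is F, which provides the primary p-value;
the chi-square variant (its large-sample equivalent) is reported
alongside.  Post-hoc habitat contrasts use Tukey's HSD on
covariate-adjusted habitat means (raw group means optionally).  Richness
trends with latitude are fitted as linear models with the number of blood
meals analysed as a sampling-effort covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from bloodmealnet.metrics import NetworkMetrics

RESPONSES = ("IE", "H2prime")

#: model terms in the order they enter the full model
MAIN_TERMS = ("habitat", "latitude", "S", "matrix_size", "family")
INTERACTION_TERMS = ("family:latitude", "family:habitat")

_TERM_SYNTAX = {
    "habitat": "C(habitat)",
    "latitude": "abs_latitude",
    "S": "S",
    "matrix_size": "log_m",
    "family": "C(family)",
    "family:latitude": "C(family):abs_latitude",
    "family:habitat": "C(family):C(habitat)",
}


@dataclass
class AnalysisTable:
    """Rectangular per-network modelling table; degenerate networks are
    excluded (and counted) so every modelled column is complete."""

    frame: pd.DataFrame
    n_excluded: int = 0
    excluded_ids: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TermTest:
    term: str
    deviance_change: float      # raw deviance difference (the printed X^2)
    df: int
    p_value: float              # F test on the dispersion-scaled change
    scaled_stat: float          # deviance change / dispersion
    dispersion: float
    p_chisq: float = float("nan")   # chi-square variant of the same test


@dataclass
class TukeyContrasts:
    response: str
    mode: str
    frame: pd.DataFrame         # group1, group2, estimate, se, p_adj


@dataclass
class FittedModel:
    result: object              # statsmodels RegressionResults
    formula: str
    response: str

    @property
    def deviance(self) -> float:
        """Residual deviance; for a Gaussian GLM this is the residual sum
        of squares."""
        return float(self.result.ssr)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.result.model.exog))

    @property
    def df_resid(self) -> int:
        return int(self.result.nobs) - self.rank

    @property
    def dispersion(self) -> float:
        return self.deviance / self.df_resid

    def summary_frame(self) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame({
            "term": r.params.index, "estimate": r.params.values,
            "se": r.bse.values, "t": r.tvalues.values,
            "p": r.pvalues.values})


def metrics_table(metrics: list[NetworkMetrics]) -> AnalysisTable:
    """Assemble the modelling table from per-network metric bundles.

    Networks flagged degenerate (undefined IE or collapsed H2' geometry)
    are excluded and counted.
    """
    if not metrics:
        raise ValueError("no network metrics supplied")
    rows, excluded = [], []
    for nm in metrics:
        if "ie_undefined" in nm.flags or "h2_degenerate" in nm.flags:
            excluded.append(nm.network_id)
            continue
        rows.append({
            "study_id": nm.network_id[0], "habitat": nm.habitat,
            "abs_latitude": nm.abs_latitude, "family": nm.dominant_family,
            "S": nm.S, "n_diptera": nm.n_diptera, "n_hosts": nm.n_hosts,
            "m": nm.m, "log_m": float(np.log(nm.m)),
            "n_bloodmeals": nm.n_bloodmeals,
            "IE": nm.IE, "H2prime": nm.H2prime})
    if not rows:
        raise ValueError("every network was excluded as degenerate")
    return AnalysisTable(frame=pd.DataFrame(rows), n_excluded=len(excluded),
                         excluded_ids=excluded)


def _formula(response: str, terms) -> str:
    rhs = " + ".join(_TERM_SYNTAX[t] for t in terms) if terms else "1"
    return f"{response} ~ {rhs}"


def _fit(table: AnalysisTable, response: str, terms) -> FittedModel:
    formula = _formula(response, terms)
    res = smf.ols(formula, data=table.frame).fit()
    return FittedModel(result=res, formula=formula, response=response)


def fit_metric_model(table: AnalysisTable, response: str = "IE",
                     include_interactions: bool = True) -> FittedModel:
    """Fit the full Gaussian model for a network metric.

    response ~ habitat + |latitude| + S + log(m) + family
               (+ family:latitude + family:habitat)

    Rank-deficient designs (a family observed in a single habitat, say)
    are fitted on the estimable subspace via the pseudoinverse; effective
    degrees of freedom come from the design-matrix rank.
    """
    if response not in RESPONSES and response not in table.frame.columns:
        raise ValueError(f"unknown response {response!r}")
    if table.frame["habitat"].nunique() < 2:
        raise ValueError("need at least two habitat levels")
    terms = list(MAIN_TERMS) + (list(INTERACTION_TERMS)
                                if include_interactions else [])
    return _fit(table, response, terms)


def term_significance(table: AnalysisTable, response: str,
                      term: str) -> TermTest:
    """Deviance-comparison test for one model term.

    Marginality is respected: main effects are tested between models
    containing only main effects; each interaction is tested against the
    full main-effects model with that interaction added.
    """
    if term in MAIN_TERMS:
        fuller_terms = list(MAIN_TERMS)
        reduced_terms = [t for t in MAIN_TERMS if t != term]
    elif term in INTERACTION_TERMS:
        fuller_terms = list(MAIN_TERMS) + [term]
        reduced_terms = list(MAIN_TERMS)
    else:
        raise ValueError(
            f"unknown term {term!r}; expected one of "
            f"{MAIN_TERMS + INTERACTION_TERMS}")

    fuller = _fit(table, response, fuller_terms)
    reduced = _fit(table, response, reduced_terms)
    d_dev = reduced.deviance - fuller.deviance
    d_dev = max(d_dev, 0.0)     # nesting guarantees nonnegativity
    df = fuller.rank - reduced.rank
    if df < 1:
        raise ValueError(f"term {term!r} adds no estimable parameters")
    phi = fuller.dispersion
    scaled = d_dev / phi
    # F is the exactly calibrated scaled-deviance test for a Gaussian
    # response with estimated dispersion; the chi-square variant (the
    # large-sample equivalent) is reported alongside
    p_f = float(stats.f.sf(scaled / df, df, fuller.df_resid))
    p_chisq = float(stats.chi2.sf(scaled, df))
    return TermTest(term=term, deviance_change=float(d_dev), df=int(df),
                    p_value=p_f, scaled_stat=float(scaled),
                    dispersion=float(phi), p_chisq=p_chisq)


def all_term_tests(table: AnalysisTable, response: str) -> pd.DataFrame:
    rows = []
    for term in MAIN_TERMS + INTERACTION_TERMS:
        tt = term_significance(table, response, term)
        rows.append({"response": response, "term": tt.term,
                     "X2": tt.deviance_change, "df": tt.df,
                     "scaled_stat": tt.scaled_stat, "p": tt.p_value,
                     "p_chisq": tt.p_chisq})
    return pd.DataFrame(rows)


def tukey_habitat(table: AnalysisTable, response: str,
                  mode: str = "adjusted") -> TukeyContrasts:
    """Pairwise Tukey HSD contrasts between the three habitat classes.

    ``mode="adjusted"`` compares habitat means adjusted for latitude, S
    and log matrix size (contrasts of the fitted main-effects model, the
    usual post-hoc practice); ``mode="raw"`` compares raw group means.
    """
    habitats = sorted(table.frame["habitat"].unique())
    if len(habitats) < 2:
        raise ValueError("need at least two habitat levels")

    if mode == "raw":
        res = pairwise_tukeyhsd(endog=table.frame[response].to_numpy(),
                                groups=table.frame["habitat"].to_numpy())
        groups = list(res.groupsunique)
        pairs = [(groups[i], groups[j])
                 for i in range(len(groups))
                 for j in range(i + 1, len(groups))]
        frame = pd.DataFrame({
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "estimate": np.asarray(res.meandiffs, dtype=float),
            "se": np.asarray(res.std_pairs, dtype=float),
            "p_adj": np.asarray(res.pvalues, dtype=float)})
        return TukeyContrasts(response=response, mode=mode, frame=frame)

    model = _fit(table, response, ["habitat", "latitude", "S", "matrix_size"])
    res = model.result
    exog_names = res.model.exog_names
    cov = res.cov_params().to_numpy()
    k = len(habitats)
    df_resid = model.df_resid

    # contrast vector for each habitat's adjusted mean: intercept + own
    # dummy + covariates at their sample means
    covariate_means = {
        "abs_latitude": table.frame["abs_latitude"].mean(),
        "S": table.frame["S"].mean(), "log_m": table.frame["log_m"].mean()}
    vecs = {}
    for hab in habitats:
        v = np.zeros(len(exog_names))
        for i, name in enumerate(exog_names):
            if name == "Intercept":
                v[i] = 1.0
            elif name == f"C(habitat)[T.{hab}]":
                v[i] = 1.0
            elif name in covariate_means:
                v[i] = covariate_means[name]
        vecs[hab] = v

    rows = []
    params = res.params.to_numpy()
    for a, b in [(habitats[i], habitats[j])
                 for i in range(k) for j in range(i + 1, k)]:
        d = vecs[b] - vecs[a]
        est = float(d @ params)
        se = float(np.sqrt(d @ cov @ d))
        q = abs(est) / se * np.sqrt(2.0)
        p_adj = float(stats.studentized_range.sf(q, k, df_resid))
        rows.append({"group1": a, "group2": b, "estimate": est,
                     "se": se, "p_adj": p_adj})
    return TukeyContrasts(response=response, mode=mode,
                          frame=pd.DataFrame(rows))


def richness_latitude_model(table: AnalysisTable,
                            response: str = "host_richness") -> FittedModel:
    """Linear model of richness against |latitude| with blood-meal count
    as a sampling-effort covariate."""
    colmap = {"host_richness": "n_hosts", "diptera_richness": "n_diptera"}
    if response not in colmap:
        raise ValueError(f"response must be one of {sorted(colmap)}")
    formula = f"{colmap[response]} ~ abs_latitude + n_bloodmeals"
    res = smf.ols(formula, data=table.frame).fit()
    return FittedModel(result=res, formula=formula, response=response)
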