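"""End-to-end orchestration: records -> networks -> metrics -> null model
-> rarefaction -> statistical models, with a manifest for reproducibility.

Each stage writes its CSV outputs as soon as it completes, so a failure
part-way through retains everything already computed; the failure is
logged with its stage name and re-raised as :class:`StageError`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import bloodmealnet
from bloodmealnet import glm as glm_stage
from bloodmealnet import metrics as metrics_stage
from bloodmealnet import nullmodel, rarefaction, records, synthetic
from bloodmealnet.networks import aggregate_global, split_networks

log = logging.getLogger("bloodmealnet")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    output_dir: str = "bloodmealnet_run"
    records_path: str | None = None         # or simulate a scenario
    simulate: str | None = None             # "default" | "null"
    sympatry_path: str | None = None
    domestic_hosts_path: str | None = None
    ie_mode: str = "realized_links"
    null_reps: int = 100
    rarefaction_knots: int = 40
    seed: int = 0
    skip_rarefaction: bool = False
    skip_null_model: bool = False
    skip_glm: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    outputs: dict = field(default_factory=dict)   # stage -> file paths
    summary: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                log.error("stage %s: FAILED (%s)", name, exc)
                raise StageError(name, exc) from exc
            log.info("stage %s: done", name)
            return out
        return inner
    return wrap


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline under one config; returns the report
    bundle and writes every stage CSV plus a manifest to the output
    directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    table = _load_records(config, outdir, report)
    nets = _build_networks(config, table, outdir, report)
    metric_rows = _metrics(config, nets, outdir, report)
    if not config.skip_null_model:
        _null_model(config, nets, outdir, report)
    if not config.skip_rarefaction:
        _rarefaction(config, nets, outdir, report)
    if not config.skip_glm:
        _glm(config, metric_rows, outdir, report)

    report.manifest = {
        "version": bloodmealnet.__version__,
        "config": asdict(config),
        "seed": config.seed,
        "provenance": nets.provenance,
        "outputs": report.outputs,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, sort_keys=True, default=str))
    (outdir / "summary.json").write_text(
        json.dumps(report.summary, indent=2, sort_keys=True, default=str))
    return report


@_stage("records")
def _load_records(config, outdir, report):
    if config.records_path:
        table = records.read_records(config.records_path)
    elif config.simulate:
        scen = {"default": synthetic.default_scenario,
                "null": synthetic.null_scenario}
        if config.simulate not in scen:
            raise ValueError(f"unknown scenario {config.simulate!r}")
        cfg = scen[config.simulate]()
        table, _ = synthetic.generate_dataset(cfg, seed=config.seed)
    else:
        raise ValueError("config needs records_path or simulate")
    sym = (records.SympatryTable.from_csv(config.sympatry_path)
           if config.sympatry_path else records.SympatryTable())
    table, res_log = records.resolve_taxa(table, sym)
    path = outdir / "records_resolved.csv"
    records.write_records(table, path)
    report.outputs["records"] = str(path)
    report.summary["records"] = {
        "rows": len(table), "total_bloodmeals": table.total_count(),
        "removed_interactions": res_log.removed_interactions,
        "removed_hosts": res_log.removed_hosts,
        "removed_diptera": res_log.removed_diptera}
    return table


def _build_networks(config, table, outdir, report):
    log.info("stage networks: start")
    try:
        nets = split_networks(table)
        edges = []
        for net in nets:
            e = net.to_edge_list()
            e.insert(0, "study_id", net.network_id[0])
            e.insert(1, "habitat", net.habitat)
            edges.append(e)
        path = outdir / "networks_edges.csv"
        pd.concat(edges, ignore_index=True).to_csv(path, index=False)
        report.outputs["networks"] = str(path)
        agg = aggregate_global(nets)
        per_hab = {h: len(v) for h, v in nets.by_habitat().items()}
        report.summary["networks"] = {
            "n_networks": len(nets), "per_habitat": per_hab,
            "excluded": len(nets.exclusions),
            "total_bloodmeals": nets.total_meals(),
            "aggregate": {"hosts": agg.n_hosts, "diptera": agg.n_diptera,
                          "links": agg.links}}
    except Exception as exc:
        log.error("stage networks: FAILED (%s)", exc)
        raise StageError("networks", exc) from exc
    log.info("stage networks: done")
    return nets


@_stage("metrics")
def _metrics(config, nets, outdir, report):
    rows = [metrics_stage.network_summary(net, ie_mode=config.ie_mode)
            for net in nets]
    alt_mode = ("all_cells" if config.ie_mode == "realized_links"
                else "realized_links")
    frame = pd.DataFrame([{
        "study_id": nm.network_id[0], "habitat": nm.habitat,
        "abs_latitude": nm.abs_latitude, "dominant_family": nm.dominant_family,
        "S": nm.S, "m": nm.m, "L": nm.L, "IE": nm.IE, "IE_mode": nm.ie_mode,
        "H2": nm.H2, "H2min": nm.H2min, "H2max": nm.H2max,
        "H2prime": nm.H2prime, "flags": ";".join(nm.flags)}
        for nm in rows])
    alt = []
    for net in nets:
        try:
            alt.append(metrics_stage.interaction_evenness(net, mode=alt_mode))
        except metrics_stage.UndefinedMetricError:
            alt.append(float("nan"))
    frame[f"IE_{alt_mode}"] = alt
    path = outdir / "metrics.csv"
    frame.to_csv(path, index=False)
    report.outputs["metrics"] = str(path)
    hab_mean = frame.groupby("habitat")["IE"].mean().round(6).to_dict()
    report.summary["metrics"] = {
        "mean_IE_by_habitat": hab_mean,
        "mean_H2prime": float(frame["H2prime"].mean()),
        "ie_mode": config.ie_mode}
    return rows


@_stage("null_model")
def _null_model(config, nets, outdir, report):
    domestic, synonyms = nullmodel.DEFAULT_DOMESTIC_HOSTS, None
    if config.domestic_hosts_path:
        domestic, synonyms = nullmodel.load_domestic_hosts(
            config.domestic_hosts_path)
    results = []
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(nets.networks))
    for net, child in zip(nets, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        results.append(nullmodel.run_null_model(
            net, domestic=domestic, synonyms=synonyms,
            n_reps=config.null_reps, seed=sub_seed))
    frame = nullmodel.results_frame(results)
    path = outdir / "null_model.csv"
    frame.to_csv(path, index=False)
    report.outputs["null_model"] = str(path)
    summary = nullmodel.summarise_null_by_habitat(results)
    spath = outdir / "null_model_by_habitat.csv"
    summary.to_csv(spath, index=False)
    report.outputs["null_model_by_habitat"] = str(spath)
    report.summary["null_model"] = summary.to_dict(orient="records")
    return results


@_stage("rarefaction")
def _rarefaction(config, nets, outdir, report):
    curves = []
    for entity in rarefaction.ENTITIES:
        for data in rarefaction.incidence_from_networks(nets, entity).values():
            curves.append(rarefaction.build_curve(
                data, n_knots=config.rarefaction_knots))
    frame = rarefaction.curves_frame(curves)
    path = outdir / "rarefaction.csv"
    frame.to_csv(path, index=False)
    report.outputs["rarefaction"] = str(path)
    report.summary["rarefaction"] = {
        f"{c.habitat}/{c.entity}": {"S_obs": c.at(_obs_t(c)),
                                    "chao2": c.asymptote}
        for c in curves}
    return curves


def _obs_t(curve) -> int:
    obs = curve.grid.loc[curve.grid["kind"] == "observed", "t"]
    return int(obs.iloc[0])


@_stage("glm")
def _glm(config, metric_rows, outdir, report):
    table = glm_stage.metrics_table(metric_rows)
    tests = pd.concat([glm_stage.all_term_tests(table, r)
                       for r in ("IE", "H2prime")], ignore_index=True)
    path = outdir / "glm_term_tests.csv"
    tests.to_csv(path, index=False)
    report.outputs["glm_term_tests"] = str(path)

    tukey = glm_stage.tukey_habitat(table, "IE")
    tpath = outdir / "glm_tukey_IE.csv"
    tukey.frame.to_csv(tpath, index=False)
    report.outputs["glm_tukey_IE"] = str(tpath)

    rich = {}
    for resp in ("host_richness", "diptera_richness"):
        model = glm_stage.richness_latitude_model(table, resp)
        sf = model.summary_frame()
        lat = sf.loc[sf["term"] == "abs_latitude"].iloc[0]
        rich[resp] = {"slope": float(lat["estimate"]), "p": float(lat["p"])}

    coef_frames = []
    for resp in ("IE", "H2prime"):
        model = glm_stage.fit_metric_model(table, resp)
        sf = model.summary_frame()
        sf.insert(0, "response", resp)
        coef_frames.append(sf)
    cpath = outdir / "glm_coefficients.csv"
    pd.concat(coef_frames, ignore_index=True).to_csv(cpath, index=False)
    report.outputs["glm_coefficients"] = str(cpath)

    hab = tests.query("response == 'IE' and term == 'habitat'").iloc[0]
    report.summary["glm"] = {
        "n_networks_modelled": len(table),
        "n_excluded_degenerate": table.n_excluded,
        "habitat_on_IE": {"X2": float(hab["X2"]), "df": int(hab["df"]),
                          "p": float(hab["p"])},
        "tukey_IE": tukey.frame.to_dict(orient="records"),
        "richness_vs_latitude": rich}
    return tests
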