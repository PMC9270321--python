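"""End-to-end orchestration: simulate → prepare → regress → network → analyse.

One :class:`RunConfig` drives a reproducible run: every stage is seeded from
stage-scoped seeds, all artefacts are plain text (CSV/JSON/YAML/GraphML),
and a manifest records versions, seeds, the config hash and per-stage row
counts.  The manifest carries no wall-clock information, so a rerun with the
same configuration produces byte-identical artefacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import (
    CohortTable,
    VariableSchema,
    compute_ipw,
    exclusion_report,
    multimorbidity_category,
    read_cohort,
    weighted_prevalence,
    write_cohort,
)
from .network_analysis import (
    flow_layers,
    node_predictability,
    to_graphml,
    walktrap,
    bootstrap_edges,
)
from .network_estimation import EBICConfig, fit_ising, fit_mgm
from .regression import fit_linear, fit_poisson_pr
from .synthetic_cohort import SimulationConfig, generate_cohort

logger = logging.getLogger("morbinet.pipeline")

STAGES = ("simulate", "prepare", "regress", "network", "analyse")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` (simulation settings) or ``cohort_csv``+``schema_yml``
    must be given.  ``weight_mode`` selects the analysis weight: the survey
    weight alone or the survey weight times the IPW multiplier (default).
    ``bootstrap_B = 0`` skips the bootstrap stage.
    """

    simulate: dict | None = None
    cohort_csv: str | None = None
    schema_yml: str | None = None
    weight_mode: str = "combined"
    gamma: float = 0.25
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    rule: str = "AND"
    bootstrap_B: int = 0
    bootstrap_seed: int = 101
    seed: int = 1
    out_dir: str = "morbinet_run"

    def __post_init__(self) -> None:
        if self.weight_mode not in ("combined", "survey"):
            raise ValueError("weight_mode must be 'combined' or 'survey'")
        if self.simulate is None and not (self.cohort_csv and self.schema_yml):
            raise ValueError("config needs either 'simulate' or cohort_csv+schema_yml")
        if self.simulate is None:
            for p, what in ((self.cohort_csv, "cohort_csv"), (self.schema_yml, "schema_yml")):
                if not Path(p).exists():
                    raise FileNotFoundError(f"{what} does not exist: {p}")
        EBICConfig(self.gamma, self.n_lambdas, self.lambda_min_ratio, self.rule)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True), encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "morbinet_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "stages": {},
    }
    stage = "simulate"
    try:
        if config.simulate is not None:
            sim = SimulationConfig(**{**config.simulate, "seed": config.simulate.get("seed", config.seed)})
            table, truth = generate_cohort(sim)
            write_cohort(table, out / "cohort.csv")
            table.schema.to_yaml(out / "schema.yml")
            truth.to_json(out / "truth.json")
            manifest["stages"]["simulate"] = {"status": "complete", "n_rows": len(table)}
        else:
            schema = VariableSchema.from_yaml(config.schema_yml)
            table = read_cohort(config.cohort_csv, schema)
            manifest["stages"]["simulate"] = {"status": "skipped (external cohort)", "n_rows": len(table)}
        logger.info("[simulate] cohort with %d rows", len(table))

        stage = "prepare"
        schema = table.schema
        analysis_vars = (
            schema.disease_names() + schema.covariate_names() + ["hospitalisation"]
        )
        ipw = compute_ipw(table, schema.covariate_names(), analysis_vars)
        report, kept = exclusion_report(table, analysis_vars)
        ipw_kept = ipw.loc[ipw.notna()].reset_index(drop=True)
        prepared = kept.copy()
        if config.weight_mode == "combined":
            prepared.df[schema.weight] = (
                prepared.df[schema.weight].astype(float) * ipw_kept.to_numpy()
            ).round(9)
        write_cohort(prepared, out / "prepared.csv")
        _json_dump(json.loads(report.to_json()), out / "exclusions.json")
        prev = weighted_prevalence(prepared, "hospitalisation")
        _json_dump(json.loads(prev.to_json()), out / "hospitalisation_prevalence.json")
        manifest["stages"]["prepare"] = {
            "status": "complete",
            "n_baseline": report.n_baseline,
            "n_final": report.n_final,
        }
        logger.info("[prepare] %d of %d rows kept", report.n_final, report.n_baseline)

        stage = "regress"
        mm = multimorbidity_category(prepared).rename("multimorbidity")
        extra = mm.to_frame()
        covs = schema.covariate_names() + ["multimorbidity"]
        pr = fit_poisson_pr(prepared, "hospitalisation", covs, extra=extra)
        pr.to_frame().to_csv(out / "pr_hospitalisation.csv", index=False)
        hosp_mask = prepared.df["hospitalisation"] == 1
        hosp = CohortTable(prepared.df.loc[hosp_mask].reset_index(drop=True), schema)
        extra_h = extra.loc[hosp_mask.to_numpy()].reset_index(drop=True)
        for outc in ("readmission", "length_of_stay"):
            res = fit_linear(hosp, outc, covs, extra=extra_h)
            res.to_frame().to_csv(out / f"beta_{outc}.csv", index=False)
        manifest["stages"]["regress"] = {
            "status": "complete",
            "n_hospitalised": int(hosp_mask.sum()),
        }
        logger.info("[regress] PR + linear models fitted (%d hospitalised)", int(hosp_mask.sum()))

        stage = "network"
        ebic_cfg = EBICConfig(config.gamma, config.n_lambdas, config.lambda_min_ratio, config.rule)
        diseases = schema.disease_names()
        nets = {}
        block_h = prepared.df[diseases + ["hospitalisation"]].astype(float)
        nets["hospitalisation"] = fit_ising(block_h, ebic_cfg)
        for outc, typ in (("readmission", "count"), ("length_of_stay", "continuous")):
            block = hosp.df[diseases + [outc]].astype(float)
            types = ["binary"] * len(diseases) + [typ]
            nets[outc] = fit_mgm(block, types, ebic_cfg)
        for name, net in nets.items():
            net.edge_list().to_csv(out / f"net_{name}_edges.csv", index=False)
            (out / f"net_{name}.json").write_text(net.to_json(), encoding="utf-8")
        manifest["stages"]["network"] = {
            "status": "complete",
            "edges": {k: int(len(v.edge_list())) for k, v in nets.items()},
        }
        logger.info("[network] edges: %s", manifest["stages"]["network"]["edges"])

        stage = "analyse"
        analyse_info = {}
        for name, net in nets.items():
            data = (
                block_h
                if name == "hospitalisation"
                else hosp.df[diseases + [name]].astype(float)
            )
            part = walktrap(np.abs(net.weights), labels=list(net.labels))
            pred = node_predictability(data, net)
            target = name if name in net.labels else net.labels[-1]
            layout = flow_layers(net, target)
            prevalence = {c: float(data[c].mean()) for c in diseases}
            to_graphml(net, out / f"net_{name}.graphml", prevalence, pred, part, layout)
            _json_dump(
                {
                    "communities": part.members(),
                    "modularity": float(part.modularity_profile[part.chosen_level]),
                    "predictability": json.loads(pred.to_frame().to_json(orient="records")),
                    "layers": layout.order,
                },
                out / f"analysis_{name}.json",
            )
            analyse_info[name] = {"n_communities": part.n_communities}
            if config.bootstrap_B >= 50:
                summary = bootstrap_edges(
                    data,
                    (lambda d, _n=name, _t=net: _refit(_t, d, ebic_cfg)),
                    B=config.bootstrap_B,
                    seed=config.bootstrap_seed,
                )
                (out / f"bootstrap_{name}.json").write_text(summary.to_json(), encoding="utf-8")
        manifest["stages"]["analyse"] = {"status": "complete", **analyse_info}
        logger.info("[analyse] %s", analyse_info)
    except Exception as exc:
        manifest["stages"].setdefault(stage, {})["status"] = f"failed: {exc}"
        _json_dump(manifest, out / "manifest.json")
        raise PipelineError(stage, exc) from exc

    _json_dump(manifest, out / "manifest.json")
    return manifest


def _refit(template, data: pd.DataFrame, cfg: EBICConfig):
    from .network_estimation import IsingNetwork

    if isinstance(template, IsingNetwork):
        return fit_ising(data[template.labels], cfg)
    return fit_mgm(data[template.labels], template.node_types, cfg)
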