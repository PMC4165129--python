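"""CSV/YAML/JSON readers and writers and the reproducible pipeline runner.

One canonical CSV schema per data kind:

- stage observations: ``plant_id, genotype, truss, fruit, obs_day, stage``
- censored intervals: ``plant_id, genotype, truss, fruit, L1, R1, L2, R2``
  (right censoring serialised as the literal ``inf``)
- qPCR wells: ``sample, gene, replicate, cq``; curves (long format):
  ``well_id, cycle, fluorescence``
- ethylene traces: ``time_s, concentration`` plus a metadata table
  ``fruit_id, genotype, stage, weight_g, flow_lph, background``

`run_pipeline` executes simulate -> censor -> fit -> covariate selection ->
summary (plus qPCR and ethylene stages when configured) and records a YAML
manifest of inputs, outputs, seeds and versions.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ethylene import EthyleneMeasurement, compare_stage_emissions, emission_rate
from .likelihood import QuadratureSpec, RipeningModelParams
from .model import (
    CENSORED_COLUMNS,
    ModelSpec,
    RipeningModel,
    RipeningResults,
    censored_to_frame,
    select_covariates,
)
from .qpcr import QpcrWell, compute_nrq, wells_to_frame
from .stages import STAGES, FruitStageSeries, derive_censoring_intervals

__all__ = [
    "read_stage_observations",
    "write_stage_observations",
    "read_censored",
    "write_censored",
    "read_qpcr_wells",
    "write_qpcr_wells",
    "write_qpcr_curves",
    "read_qpcr_curves",
    "read_ethylene",
    "write_ethylene",
    "write_ground_truth",
    "save_fit",
    "load_fit",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
]


# -- stage observations ----------------------------------------------------

def write_stage_observations(series: list[FruitStageSeries], path) -> None:
    rows = [
        {
            "plant_id": s.plant_id,
            "genotype": s.genotype,
            "truss": s.truss,
            "fruit": s.fruit,
            "obs_day": day,
            "stage": stage,
        }
        for s in series
        for day, stage in s.observations
    ]
    pd.DataFrame(
        rows, columns=["plant_id", "genotype", "truss", "fruit", "obs_day", "stage"]
    ).to_csv(path, index=False)


def read_stage_observations(path) -> list[FruitStageSeries]:
    df = pd.read_csv(path, dtype={"plant_id": str, "genotype": str})
    required = ["plant_id", "genotype", "truss", "fruit", "obs_day", "stage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for i, stage in enumerate(df["stage"]):
        if stage not in STAGES:
            raise ValueError(f"{path}, line {i + 2}: unknown stage label {stage!r}")
    out = []
    for (pid, gt, truss, fruit), grp in df.groupby(
        ["plant_id", "genotype", "truss", "fruit"], sort=True
    ):
        grp = grp.sort_values("obs_day")
        obs = list(zip(grp["obs_day"].astype(float), grp["stage"]))
        out.append(
            FruitStageSeries(
                plant_id=str(pid), genotype=str(gt), truss=int(truss), fruit=int(fruit),
                observations=obs,
            )
        )
    return out


# -- censored intervals ----------------------------------------------------

def write_censored(obs_or_frame, path) -> None:
    df = obs_or_frame if isinstance(obs_or_frame, pd.DataFrame) else censored_to_frame(obs_or_frame)
    df.to_csv(path, index=False)


def read_censored(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plant_id": str, "genotype": str})
    missing = [c for c in CENSORED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for c in ["L1", "R1", "L2", "R2"]:
        df[c] = df[c].astype(float)
    return df[CENSORED_COLUMNS]


# -- qPCR ------------------------------------------------------------------

def write_qpcr_wells(wells: list[QpcrWell], path) -> None:
    wells_to_frame(wells).to_csv(path, index=False)


def read_qpcr_wells(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample": str, "gene": str})
    missing = [c for c in ["sample", "gene", "replicate", "cq"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _well_id(w: QpcrWell) -> str:
    return f"{w.sample}:{w.gene}:{w.replicate}"


def write_qpcr_curves(wells: list[QpcrWell], path) -> None:
    rows = []
    for w in wells:
        if w.curve is None:
            continue
        for cyc, fl in w.curve:
            rows.append({"well_id": _well_id(w), "cycle": cyc, "fluorescence": fl})
    pd.DataFrame(rows, columns=["well_id", "cycle", "fluorescence"]).to_csv(path, index=False)


def read_qpcr_curves(path) -> dict:
    """Curves keyed by well id as (cycle, fluorescence) arrays."""
    df = pd.read_csv(path, dtype={"well_id": str})
    return {
        wid: grp[["cycle", "fluorescence"]].to_numpy(float)
        for wid, grp in df.groupby("well_id", sort=True)
    }


# -- ethylene --------------------------------------------------------------

def write_ethylene(measurements: list[EthyleneMeasurement], trace_dir, metadata_path) -> None:
    trace_dir = Path(trace_dir)
    trace_dir.mkdir(parents=True, exist_ok=True)
    meta = []
    for i, m in enumerate(measurements):
        fruit_id = f"fruit{i + 1:03d}"
        pd.DataFrame(m.trace, columns=["time_s", "concentration"]).to_csv(
            trace_dir / f"{fruit_id}.csv", index=False
        )
        meta.append(
            {
                "fruit_id": fruit_id,
                "plant_id": m.plant_id,
                "genotype": m.genotype,
                "stage": m.stage,
                "weight_g": m.fresh_weight,
                "flow_lph": m.flow,
                "background": m.background,
            }
        )
    pd.DataFrame(meta).to_csv(metadata_path, index=False)


def read_ethylene(trace_dir, metadata_path) -> list[EthyleneMeasurement]:
    trace_dir = Path(trace_dir)
    meta = pd.read_csv(metadata_path, dtype={"fruit_id": str, "plant_id": str, "genotype": str, "stage": str})
    out = []
    for r in meta.itertuples(index=False):
        trace = pd.read_csv(trace_dir / f"{r.fruit_id}.csv")[["time_s", "concentration"]].to_numpy(float)
        out.append(
            EthyleneMeasurement(
                trace=trace,
                background=float(r.background),
                flow=float(r.flow_lph),
                fresh_weight=float(r.weight_g),
                stage=str(r.stage),
                genotype=str(r.genotype),
                plant_id=str(r.plant_id),
            )
        )
    return out


# -- ground truth & fits ---------------------------------------------------

def write_ground_truth(truth, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = truth.params
    payload = {
        "mu": p.mu.tolist(),
        "alpha": {g: v.tolist() for g, v in p.alpha.items()},
        "beta": None if p.beta is None else {str(k): v.tolist() for k, v in p.beta.items()},
        "gamma": None if p.gamma is None else {str(k): v.tolist() for k, v in p.gamma.items()},
        "gamma_linear": None if p.gamma_linear is None else p.gamma_linear.tolist(),
        "sigma0": p.sigma0.tolist(),
        "sigma": p.sigma.tolist(),
        "n_clamped": truth.n_clamped,
    }
    with open(out_dir / "truth_params.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    truth.latent_times.to_csv(out_dir / "truth_latent_times.csv", index=False)


def save_fit(result: RipeningResults, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)


def load_fit(path, data, compute_se: bool = False) -> RipeningResults:
    """Rebuild a results object from a saved fit and its dataset."""
    with open(path) as fh:
        d = json.load(fh)
    spec = ModelSpec(
        genotypes=tuple(d["spec"]["genotypes"]),
        reference=d["spec"]["reference"],
        include_truss=d["spec"]["include_truss"],
        include_fruit=d["spec"]["include_fruit"],
        quad=QuadratureSpec(nodes_per_dim=d["spec"]["quad_nodes"]),
    )
    model = RipeningModel(data, spec)
    theta = np.asarray(d["theta"], float)
    cov, singular = (model._cov_params(theta)) if compute_se else (None, False)
    return RipeningResults(
        model=model,
        theta=theta,
        llf=float(d["loglik"]),
        converged=bool(d["converged"]),
        cov_params_=cov,
        information_singular=singular,
        optimizer_trace=[],
    )


# -- pipeline --------------------------------------------------------------

_TOP_KEYS = {"version", "seed", "ripening", "qpcr", "ethylene"}
_RIPENING_KEYS = {
    "simulate", "observations", "design", "params", "model",
    "select_covariates", "alpha", "summary_stars",
}
_DESIGN_KEYS = {
    "genotypes", "reference", "plants_per_genotype", "trusses_per_plant",
    "fruits_per_truss", "observation_days",
}
_PARAM_KEYS = {"mu", "alpha", "beta", "gamma", "gamma_linear", "sigma0", "sigma"}
_MODEL_KEYS = {"include_truss", "include_fruit", "quad_nodes", "restarts"}
_QPCR_KEYS = {"wells", "curves", "reference_genes", "alpha", "group_of_sample"}
_ETHYLENE_KEYS = {"traces", "metadata", "alpha"}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML schema version 1)."""

    version: int
    seed: int
    ripening: dict | None = None
    qpcr: dict | None = None
    ethylene: dict | None = None
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        _check_keys(raw, _TOP_KEYS, "top level")
        version = int(raw.get("version", 1))
        if version != 1:
            raise ValueError(f"unsupported config schema version {version}")
        seed = int(raw.get("seed", 0))
        rip = raw.get("ripening")
        if rip is not None:
            _check_keys(rip, _RIPENING_KEYS, "ripening")
            if "design" in rip:
                _check_keys(rip["design"], _DESIGN_KEYS, "ripening.design")
            if "params" in rip:
                _check_keys(rip["params"], _PARAM_KEYS, "ripening.params")
            if "model" in rip:
                _check_keys(rip["model"], _MODEL_KEYS, "ripening.model")
            alpha = rip.get("alpha", 0.05)
            if not 0 < alpha < 1:
                raise ValueError("ripening.alpha must lie in (0, 1)")
            if not rip.get("simulate", False) and "observations" not in rip:
                raise ValueError("ripening stage needs simulate: true or an observations path")
            if "observations" in rip and not Path(rip["observations"]).exists():
                raise ValueError(f"observations file not found: {rip['observations']}")
        qp = raw.get("qpcr")
        if qp is not None:
            _check_keys(qp, _QPCR_KEYS, "qpcr")
            for key in ("wells", "curves"):
                if key in qp and not Path(qp[key]).exists():
                    raise ValueError(f"qpcr.{key} file not found: {qp[key]}")
        eth = raw.get("ethylene")
        if eth is not None:
            _check_keys(eth, _ETHYLENE_KEYS, "ethylene")
            for key in ("traces", "metadata"):
                if key in eth and not Path(eth[key]).exists():
                    raise ValueError(f"ethylene.{key} not found: {eth[key]}")
        return cls(version=version, seed=seed, ripening=rip, qpcr=qp, ethylene=eth, raw=raw)


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, outputs and provenance."""

    config_hash: str
    seed: int
    package_version: str
    stages: dict
    started: str
    finished: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "package_version": self.package_version,
                    "stages": self.stages,
                    "started": self.started,
                    "finished": self.finished,
                },
                fh,
                sort_keys=False,
            )


def _design_from_config(d: dict | None):
    from .simulate import ExperimentDesign, default_design

    if not d:
        return default_design()
    base = default_design()
    return ExperimentDesign(
        genotypes=tuple(d.get("genotypes", base.genotypes)),
        reference=d.get("reference", d.get("genotypes", base.genotypes)[0] if d.get("genotypes") else base.reference),
        plants_per_genotype=d.get("plants_per_genotype", base.plants_per_genotype),
        trusses_per_plant=d.get("trusses_per_plant", base.trusses_per_plant),
        fruits_per_truss=d.get("fruits_per_truss", base.fruits_per_truss),
        observation_days=tuple(d.get("observation_days", base.observation_days)),
    )


def _params_from_config(d: dict | None) -> RipeningModelParams:
    from .simulate import default_params

    if not d:
        return default_params()
    base = default_params()
    return RipeningModelParams(
        mu=d.get("mu", base.mu),
        alpha={g: np.asarray(v, float) for g, v in d.get("alpha", base.alpha).items()},
        beta=None if d.get("beta") is None else {int(k): np.asarray(v, float) for k, v in d["beta"].items()},
        gamma=None if d.get("gamma") is None else {int(k): np.asarray(v, float) for k, v in d["gamma"].items()},
        gamma_linear=d.get("gamma_linear", None if d.get("gamma") is not None else base.gamma_linear),
        sigma0=d.get("sigma0", base.sigma0),
        sigma=d.get("sigma", base.sigma),
    )


def run_pipeline(config: PipelineConfig, out_dir, verbose: bool = False) -> RunManifest:
    """Execute the configured stages and write a manifest.

    Stage order: simulate (or read) -> censor -> fit -> covariate selection
    -> genotype summary; then qPCR NRQ/ANOVA and ethylene rates/comparison
    when configured.  A stage failure writes the manifest of completed
    stages before propagating.
    """
    import logging

    from .simulate import simulate_ripening_experiment

    log = logging.getLogger("ripetime.pipeline")
    if verbose:
        logging.basicConfig(level=logging.INFO)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config.raw, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=config.seed,
        package_version=_package_version(),
        stages={},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest_path = out_dir / "manifest.yaml"
    try:
        if config.ripening is not None:
            rip = config.ripening
            if rip.get("simulate", False):
                design = _design_from_config(rip.get("design"))
                params = _params_from_config(rip.get("params"))
                series, truth = simulate_ripening_experiment(design, params, seed=config.seed)
                obs_path = out_dir / "observations.csv"
                write_stage_observations(series, obs_path)
                write_ground_truth(truth, out_dir / "truth")
                manifest.stages["simulate"] = {
                    "observations": str(obs_path),
                    "truth": str(out_dir / "truth"),
                    "n_fruits": len(series),
                }
                log.info("simulated %d fruits (seed %d)", len(series), config.seed)
            else:
                obs_path = rip["observations"]
                series = read_stage_observations(obs_path)
            censored = [derive_censoring_intervals(s) for s in series]
            cens_path = out_dir / "censored.csv"
            write_censored(censored, cens_path)
            manifest.stages["censor"] = {"censored": str(cens_path), "n_fruits": len(censored)}

            mopts = rip.get("model", {})
            data = censored_to_frame(censored)
            quad = QuadratureSpec(nodes_per_dim=int(mopts.get("quad_nodes", 15)))
            spec = ModelSpec.infer(
                data,
                reference=rip.get("design", {}).get("reference") if rip.get("simulate") else None,
                include_truss=bool(mopts.get("include_truss", True)),
                include_fruit=mopts.get("include_fruit", "categorical"),
                quad=quad,
            )
            restarts = int(mopts.get("restarts", 3))
            alpha = float(rip.get("alpha", 0.05))
            tests = []
            if rip.get("select_covariates", True):
                spec, tests, fit = select_covariates(
                    data, spec, alpha=alpha, return_fit=True,
                    restarts=restarts, seed=config.seed,
                )
                fit.compute_se()
            else:
                fit = RipeningModel(data, spec).fit(restarts=restarts, seed=config.seed)
            log.info(
                "fit: loglik=%.4f converged=%s nodes=%d",
                fit.llf, fit.converged, spec.quad.nodes_per_dim,
            )
            fit_path = out_dir / "fit.json"
            save_fit(fit, fit_path)
            manifest.stages["fit"] = {
                "fit": str(fit_path),
                "converged": fit.converged,
                "loglik": float(fit.llf),
                "covariate_tests": [
                    {"label": t.label, "statistic": t.statistic, "df": t.df, "p": t.p_value}
                    for t in tests
                ],
            }
            summary = fit.genotype_summary(stars=bool(rip.get("summary_stars", True)))
            sum_path = out_dir / "genotype_summary.csv"
            summary.to_csv(sum_path, index=False)
            manifest.stages["summarize"] = {"summary": str(sum_path)}

        if config.qpcr is not None:
            qp = config.qpcr
            wells = read_qpcr_wells(qp["wells"])
            refs = list(qp.get("reference_genes", []))
            eff = {g: 2.0 for g in wells["gene"].unique()}
            if "curves" in qp:
                from .qpcr import efficiency_window_of_linearity, plate_mean_efficiency

                curves = read_qpcr_curves(qp["curves"])
                effs = []
                for arr in curves.values():
                    try:
                        effs.append(efficiency_window_of_linearity(arr))
                    except ValueError:
                        continue
                plate_eff = plate_mean_efficiency(effs)
                eff = {g: plate_eff for g in eff}
            table = compute_nrq(wells, refs, eff)
            nrq_path = out_dir / "nrq.csv"
            table.nrq.to_csv(nrq_path)
            manifest.stages["qpcr"] = {"nrq": str(nrq_path)}

        if config.ethylene is not None:
            eth = config.ethylene
            measurements = read_ethylene(eth["traces"], eth["metadata"])
            rates = [emission_rate(m) for m in measurements]
            rate_path = out_dir / "ethylene_rates.csv"
            pd.DataFrame(
                [
                    {
                        "plant_id": r.plant_id, "genotype": r.genotype, "stage": r.stage,
                        "rate_nl_h_g": r.value, "below_background": r.below_background,
                    }
                    for r in rates
                ]
            ).to_csv(rate_path, index=False)
            letters = {}
            for stage in sorted({r.stage for r in rates}):
                sub = [r for r in rates if r.stage == stage]
                if len({r.genotype for r in sub}) >= 2:
                    res = compare_stage_emissions(sub, alpha=float(eth.get("alpha", 0.05)))
                    letters[stage] = res.letters
            letters_path = out_dir / "ethylene_letters.csv"
            pd.DataFrame(
                [
                    {"stage": st, "genotype": g, "letters": lt}
                    for st, d in letters.items()
                    for g, lt in d.items()
                ],
                columns=["stage", "genotype", "letters"],
            ).to_csv(letters_path, index=False)
            manifest.stages["ethylene"] = {"rates": str(rate_path), "letters": str(letters_path)}
    except Exception:
        manifest.finished = None
        manifest.to_yaml(manifest_path)
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_yaml(manifest_path)
    return manifest


def _package_version() -> str:
    from . import __version__

    return __version__
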