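"""Config-driven pipeline: simulate/load -> fit -> predict -> fluxes, with artifacts.

A YAML config names either a data file or a generator, a model structure,
priors, optimizer settings, a test grid and (optionally) a stoichiometry.
All randomness flows from one top-level seed, split deterministically per
stage (generator noise, optimizer starts).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .flux import Stoichiometry, estimate_fluxes
from .io import TimeSeriesSet, read_timeseries
from .model import (
    HyperParams,
    ModelSpec,
    PriorSpec,
    ecoli_three_output_spec,
    map_estimate,
    single_output_spec,
    standard_two_output_spec,
)
from .predict import posterior_joint, posterior_joint_hyperavg
from .simulate import (
    SimulationResult,
    gen_branched_pathway,
    gen_linear_pathway,
    gen_nitrogen_like,
    gen_oscillators,
)

__all__ = ["ConfigError", "load_config", "validate_config", "run_pipeline"]

log = logging.getLogger("fluxgp")

GENERATORS = {
    "oscillators": gen_oscillators,
    "linear_pathway": gen_linear_pathway,
    "branched_pathway": gen_branched_pathway,
    "nitrogen": gen_nitrogen_like,
}
MODEL_KINDS = {
    "single_output": single_output_spec,
    "two_output": standard_two_output_spec,
    "ecoli_three_output": ecoli_three_output_spec,
}


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every problem found."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    return cfg


def validate_config(cfg: Mapping) -> list[str]:
    """Return the full list of problems (empty when the config is usable)."""
    problems = []
    data = cfg.get("data")
    if not isinstance(data, Mapping):
        problems.append("missing 'data' section")
    else:
        has_path = "path" in data
        has_gen = "generator" in data
        if has_path == has_gen:
            problems.append("'data' needs exactly one of 'path' or 'generator'")
        if has_gen:
            name = (data.get("generator") or {}).get("name") if isinstance(
                data.get("generator"), Mapping) else None
            if name not in GENERATORS:
                problems.append(
                    f"unknown generator {name!r}; choose from {sorted(GENERATORS)}")
    model = cfg.get("model")
    if not isinstance(model, Mapping):
        problems.append("missing 'model' section")
    else:
        kind = model.get("kind", "custom")
        if kind not in MODEL_KINDS and kind != "custom":
            problems.append(f"unknown model kind {kind!r}")
        if kind == "custom" and not all(k in model for k in ("outputs", "sources", "edges")):
            problems.append("custom model needs 'outputs', 'sources' and 'edges'")
    grid = cfg.get("test_grid")
    if not isinstance(grid, Mapping) or not all(k in grid for k in ("start", "stop", "num")):
        problems.append("'test_grid' needs 'start', 'stop' and 'num'")
    seed = cfg.get("seed")
    if seed is not None and not isinstance(seed, int):
        problems.append("'seed' must be an integer")
    stoich = cfg.get("stoichiometry")
    if stoich is not None:
        if not isinstance(stoich, Mapping) or not all(
                k in stoich for k in ("metabolites", "fluxes", "S")):
            problems.append("'stoichiometry' needs 'metabolites', 'fluxes' and 'S'")
    return problems


def _build_model(cfg: Mapping) -> ModelSpec:
    model = cfg["model"]
    kind = model.get("kind", "custom")
    if kind in MODEL_KINDS:
        if "outputs" in model:
            return MODEL_KINDS[kind](tuple(model["outputs"])) if kind != "single_output" \
                else single_output_spec(model["outputs"][0])
        return MODEL_KINDS[kind]()
    return ModelSpec.from_dict(model)


def _build_data(cfg: Mapping, seed: int, base_dir: Path):
    data = cfg["data"]
    if "path" in data:
        path = Path(data["path"])
        if not path.is_absolute():
            path = base_dir / path
        return read_timeseries(path, dialect=data.get("dialect")), None
    gspec = dict(data["generator"])
    name = gspec.pop("name")
    gspec.setdefault("seed", seed)
    sim: SimulationResult = GENERATORS[name](**gspec)
    return sim.observations, sim


def _build_stoichiometry(cfg: Mapping, sim: SimulationResult | None, base_dir: Path):
    stoich = cfg.get("stoichiometry")
    if stoich is None:
        if sim is not None and sim.stoichiometry is not None and cfg.get(
                "use_generator_stoichiometry", True):
            return sim.stoichiometry
        return None
    known = {}
    for f, spec in (stoich.get("known_fluxes") or {}).items():
        if isinstance(spec, Mapping) and "constant" in spec:
            known[f] = float(spec["constant"])
        elif isinstance(spec, Mapping) and "table" in spec:
            import pandas as pd
            tab = pd.read_csv(base_dir / spec["table"])
            known[f] = (tab["time"].to_numpy(float), tab["value"].to_numpy(float))
        elif isinstance(spec, Mapping) and spec.get("from_truth"):
            if sim is None:
                raise ConfigError([f"known flux {f!r}: 'from_truth' needs a generator"])
            known[f] = (sim.times, sim.fluxes[f])
        else:
            raise ConfigError([f"known flux {f!r}: give 'constant', 'table' or 'from_truth'"])
    return Stoichiometry(
        metabolites=tuple(stoich["metabolites"]),
        fluxes=tuple(stoich["fluxes"]),
        S=np.asarray(stoich["S"], float),
        known_fluxes=known,
    )


def run_pipeline(
    cfg: Mapping,
    out_dir: str | Path,
    seed: int | None = None,
    base_dir: str | Path | None = None,
    stages: Sequence[str] = ("fit", "predict", "fluxes"),
) -> dict:
    """Run the configured pipeline and write artifacts under ``out_dir``.

    Artifacts: ``hyperparams.yaml`` (fitted theta + objective + seed),
    ``predictions.csv`` (tidy mean/sd per output, function and derivative),
    ``fluxes.csv`` (when a stoichiometry is configured), ``run_log.json``.
    Returns a dict of artifact paths and in-memory results.
    """
    problems = validate_config(cfg)
    if problems:
        raise ConfigError(problems)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base_dir = Path(base_dir) if base_dir is not None else Path.cwd()

    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    ss = np.random.SeedSequence(seed)
    data_seed, fit_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))

    t0 = time.time()
    data, sim = _build_data(cfg, data_seed, base_dir)
    data.validate_for_fit(min_points=int(cfg.get("min_points", 3)))
    spec = _build_model(cfg)

    priors_cfg = cfg.get("priors") or {}
    priors = PriorSpec.from_data(spec, data, scale=float(priors_cfg.get("scale", 1.0)))
    if priors_cfg.get("overrides"):
        priors = priors.with_overrides(
            spec, {k: tuple(v) for k, v in priors_cfg["overrides"].items()})

    opt = cfg.get("optimizer") or {}
    grid = cfg["test_grid"]
    test_grid = np.linspace(float(grid["start"]), float(grid["stop"]), int(grid["num"]))
    test_times = {o: test_grid for o in spec.outputs}

    artifacts: dict = {"out_dir": out_dir, "seed": seed}

    fit = None
    if "fit" in stages:
        log.info("fitting %d hyperparameters with %d starts", spec.n_params,
                 int(opt.get("n_starts", 10)))
        fit = map_estimate(
            spec, priors, data,
            n_starts=int(opt.get("n_starts", 10)),
            seed=fit_seed,
            fixed=cfg.get("fixed") or None,
            center=bool(cfg.get("center", False)),
            max_iter=int(opt.get("max_iter", 2000)),
        )
        hp_path = out_dir / "hyperparams.yaml"
        with open(hp_path, "w") as fh:
            yaml.safe_dump({"model": spec.to_dict(), **fit.to_dict(spec)}, fh,
                           sort_keys=False)
        artifacts["hyperparams"] = hp_path
        artifacts["fit"] = fit
    else:
        hp_path = out_dir / "hyperparams.yaml"
        if not hp_path.exists():
            raise FileNotFoundError(
                f"{hp_path} not found; run the 'fit' stage first")
        with open(hp_path) as fh:
            saved = yaml.safe_load(fh)
        theta = HyperParams.from_dict(spec, saved["hyperparameters"])
        offsets = saved.get("output_means", {})
        fit = type("LoadedFit", (), {})()
        fit.theta, fit.output_means = theta, offsets

    pred = None
    if "predict" in stages or "fluxes" in stages:
        offsets = getattr(fit, "output_means", {}) or {}
        pdata = data
        if offsets:  # theta was fitted on centred data; condition on the same
            df = data.frame.copy()
            df["value"] = df["value"] - df["output"].map(offsets).fillna(0.0)
            pdata = TimeSeriesSet(df, allow_replicates=data.allow_replicates)
        hyper_draws = int((cfg.get("prediction") or {}).get("hyper_draws", 0))
        if hyper_draws > 0 and hasattr(fit, "log_posterior"):
            pred = posterior_joint_hyperavg(
                spec, priors, pdata, fit, test_times,
                n_draws=hyper_draws, seed=fit_seed, mean_offsets=offsets)
        else:
            pred = posterior_joint(spec, fit.theta, pdata, test_times,
                                   mean_offsets=offsets)
        pred_path = out_dir / "predictions.csv"
        pred.to_frame().to_csv(pred_path, index=False)
        artifacts["predictions"] = pred_path
        artifacts["prediction"] = pred

    if "fluxes" in stages:
        st = _build_stoichiometry(cfg, sim, base_dir)
        if st is None:
            log.info("no stoichiometry configured; flux stage skipped")
            artifacts["fluxes"] = None
        else:
            est = estimate_fluxes(
                st, pred,
                min_norm=bool(cfg.get("min_norm", False)),
                interpolate_known=bool(cfg.get("interpolate_known", True)),
            )
            flux_path = out_dir / "fluxes.csv"
            est.to_frame().to_csv(flux_path, index=False)
            artifacts["fluxes"] = flux_path
            artifacts["flux_estimate"] = est

    run_log = {
        "seed": seed,
        "data_seed": data_seed,
        "fit_seed": fit_seed,
        "fluxgp_version": __version__,
        "numpy_version": np.__version__,
        "n_observations": data.n_obs,
        "outputs": list(spec.outputs),
        "elapsed_s": round(time.time() - t0, 3),
    }
    if fit is not None and hasattr(fit, "log_posterior"):
        run_log["log_posterior"] = float(fit.log_posterior)
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(run_log, indent=2))
    artifacts["run_log"] = log_path
    return artifacts
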