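"""Reproducible multi-stage runs: configuration, execution, manifest.

A RunConfig is a plain, fully serializable description of a run (structure,
seeds, stage sizes, output directory).  ``run_pipeline`` executes the
requested stages in dependency order -- network report, simulation,
ensemble, synthetic data, calibration, predictions -- writing long-format
CSV artifacts plus a JSON manifest recording the configuration, package
version and SHA-256 of every artifact, so a rerun with the same config is
verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import (
    CalibrationProblem,
    ExperimentalDataset,
    default_fit_parameterization,
    run_fits,
    select_best,
)
from .ensemble import run_ensemble, correlate_features
from .network import (
    ConfigurationError,
    ModelStructure,
    build_network,
    default_parameters,
    structure_report,
)
from .predict import dose_response, perturbation_grid
from .simulate import compile_network, observables, simulate
from .synth import generate_dataset

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("network", "simulate", "ensemble", "synth", "calibrate", "predict")


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=lambda: ["network", "simulate"])
    structure: str = "abc"
    seed: int = 0
    dose_ng_ml: float = 200.0
    horizon_min: float = 360.0
    ensemble_n: int = 200
    ensemble_structures: str = "all"  # 'all' or a single label
    synth_noise: float = 0.05
    chains: int = 2
    iterations: int = 500
    retain: int | None = None
    mh_step: float = 0.05
    dataset_path: str | None = None
    doses: list[float] = field(default_factory=lambda: [0, 20, 100, 200, 500, 1000])
    perturb_pair: list[str] = field(default_factory=lambda: ["k2", "k12"])
    posterior_subsample: int = 20
    out_dir: str = "runs/out"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    structure = ModelStructure.from_label(config.structure)
    artifacts: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        artifacts[name] = _sha256(path)

    posterior = None
    fit = None

    for stage in STAGES:
        if stage not in config.stages:
            continue
        if stage == "network":
            rep = structure_report(build_network(structure))
            save(rep.listing, "reactions.csv")
            save(build_network(structure).species_frame(), "species.csv")
            save(default_parameters(structure).to_frame(), "parameters.csv")
        elif stage == "simulate":
            tr = simulate(
                compile_network(structure), default_parameters(structure),
                dose_ng_ml=config.dose_ng_ml, horizon_min=config.horizon_min,
            )
            save(observables(tr).frame(), "observables.csv")
        elif stage == "ensemble":
            structs = (
                None if config.ensemble_structures == "all"
                else [ModelStructure.from_label(config.ensemble_structures)]
            )
            res = run_ensemble(
                structures=structs, n_per_structure=config.ensemble_n,
                seed=config.seed, dose_ng_ml=config.dose_ng_ml,
            )
            save(res.tally(), "ensemble_tally.csv")
            save(res.tally(coarse=True), "ensemble_tally_coarse.csv")
            save(res.draws, "ensemble_draws.csv")
            if "abc" in res.structures and config.ensemble_n >= 50:
                save(correlate_features(res), "ensemble_correlations.csv")
        elif stage == "synth":
            fit = default_fit_parameterization(structure)
            synth = generate_dataset(
                fit.center_log10(), fit, structure,
                noise=config.synth_noise, seed=config.seed,
                dose_ng_ml=config.dose_ng_ml,
            )
            synth.dataset.to_csv(out / "synthetic_dataset.csv")
            artifacts["synthetic_dataset.csv"] = _sha256(out / "synthetic_dataset.csv")
        elif stage == "calibrate":
            if config.dataset_path:
                dataset = ExperimentalDataset.read_csv(
                    config.dataset_path, dose_ng_ml=config.dose_ng_ml
                )
            elif (out / "synthetic_dataset.csv").exists():
                dataset = ExperimentalDataset.read_csv(
                    out / "synthetic_dataset.csv", dose_ng_ml=config.dose_ng_ml
                )
            else:
                raise ConfigurationError(
                    "calibrate stage needs a dataset: set dataset_path or run the "
                    "synth stage first (missing artifact: synthetic_dataset.csv)"
                )
            fit = fit or default_fit_parameterization(structure)
            problem = CalibrationProblem(dataset, structure, fit)
            chains = run_fits(
                problem, n_chains=config.chains, n_iter=config.iterations,
                seed=config.seed, step=config.mh_step, n_retain=config.retain,
            )
            posterior = select_best(chains, structure)
            save(posterior.frame(), "posterior.csv")
            medians = pd.DataFrame(
                {
                    "chain": range(len(chains)),
                    "median_sse": [c.median_retained_sse() for c in chains],
                    "acceptance": [c.acceptance_rate for c in chains],
                }
            )
            save(medians, "chain_summary.csv")
        elif stage == "predict":
            if posterior is None or fit is None:
                raise ConfigurationError(
                    "predict stage needs a posterior: run the calibrate stage first "
                    "(missing artifact: posterior.csv)"
                )
            dr = dose_response(
                posterior, fit, doses_ng_ml=config.doses,
                subsample=config.posterior_subsample, seed=config.seed,
            )
            save(dr.frame(), "dose_response.csv")
            grid = perturbation_grid(
                posterior, fit, pair=tuple(config.perturb_pair),
                n_grid=7, subsample=min(10, config.posterior_subsample),
                seed=config.seed,
            )
            save(grid.frame(), "perturbation_grid.csv")

    manifest = {
        "package": "prlstat5",
        "version": __version__,
        "config": config.to_dict(),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
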