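"""End-to-end orchestration: data in, fitted models, comparison tables,
cross-validation, loadings, omegas and information curves out.

A single run seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so each stage (simulation, split,
rotation starts) is individually reproducible; the seed and a hash of the
configuration are recorded in every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import Codebook, FitResult, GRMParameters, ResponseMatrix
from .estimation import (
    ModelSpec,
    QuadratureSpec,
    fit,
    model1_spec,
    model2_spec,
    model3_spec,
    model4_spec,
)
from .model_selection import CrossValidationResult, compare, cross_validate
from .psychometrics import (
    classify_salient,
    instrument_information_curves,
    omega_decomposition,
)
from .rotation import geomin_rotate
from .synthetic_data import SimulationPlan, default_plan, generate, split_sample

logger = logging.getLogger("irtcal.pipeline")

_STAGES = ("simulate", "split", "rotation", "extra")


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    seed: int
    out_dir: str = "irtcal_out"
    mode: str = "synthetic"               # "synthetic" | "csv"
    models: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    plan_yaml: str | None = None          # synthetic mode: optional plan file
    responses_csv: str | None = None      # csv mode
    codebook_file: str | None = None      # csv mode (yaml or json)
    one_based: bool = False
    n_exploratory_factors: int = 3
    max_iter: int = 100
    tol: float = 0.01
    n_nodes: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "csv" and not (self.responses_csv and self.codebook_file):
            raise ValueError("csv mode needs responses_csv and codebook_file")
        bad = [m for m in self.models if m not in (1, 2, 3, 4)]
        if bad:
            raise ValueError(f"unknown models requested: {bad}")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "out_dir": str(self.out_dir), "mode": self.mode,
            "models": list(self.models), "plan_yaml": self.plan_yaml,
            "responses_csv": self.responses_csv, "codebook_file": self.codebook_file,
            "one_based": self.one_based,
            "n_exploratory_factors": self.n_exploratory_factors,
            "max_iter": self.max_iter, "tol": self.tol, "n_nodes": self.n_nodes,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        est = d.pop("estimation", {})
        d.update(est)
        d.update(overrides)
        return cls(**d)


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (all below 2**31)."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def _controls(config: RunConfig) -> dict:
    return {
        "max_iter": config.max_iter,
        "tol": config.tol,
        "quadrature": QuadratureSpec(n_nodes=config.n_nodes),
    }


def build_spec(model: int, codebook: Codebook, config: RunConfig) -> ModelSpec:
    c = _controls(config)
    if model == 1:
        return model1_spec(codebook, **c)
    if model == 2:
        return model2_spec(codebook, n_factors=config.n_exploratory_factors, **c)
    if model == 3:
        return model3_spec(codebook, **c)
    return model4_spec(codebook, **c)


def load_data(config: RunConfig):
    """Returns (data, truth-or-None, plan-or-None) according to the mode."""
    seeds = stage_seeds(config.seed)
    if config.mode == "csv":
        path = Path(config.codebook_file)
        cb = (Codebook.from_json(path) if path.suffix == ".json"
              else Codebook.from_yaml(path))
        data = ResponseMatrix.from_csv(config.responses_csv, cb, one_based=config.one_based)
        return data, None, None
    plan = (SimulationPlan.from_yaml(config.plan_yaml) if config.plan_yaml
            else default_plan(seeds["simulate"]))
    data, truth = generate(plan)
    return data, truth, plan


# ---------------------------------------------------------------------------
# Fit bundles (round-trippable JSON for the file-level CLI workflow)
# ---------------------------------------------------------------------------

def fitresult_to_dict(res: FitResult) -> dict:
    return {
        "model_name": res.model_name,
        "log_likelihood": res.log_likelihood,
        "n_params": res.n_params,
        "n_obs": res.n_obs,
        "bic": res.bic,
        "bic_adj": res.bic_adj,
        "converged": res.converged,
        "n_em_iterations": res.n_em_iterations,
        "messages": list(res.messages),
        "category_merges": res.category_merges,
        "params": res.params.to_dict(),
    }


def fitresult_from_dict(d: dict) -> FitResult:
    params = GRMParameters.from_dict(d["params"])
    return FitResult(
        model_name=d["model_name"],
        log_likelihood=d["log_likelihood"],
        n_params=d["n_params"],
        n_obs=d["n_obs"],
        bic=d["bic"],
        bic_adj=d["bic_adj"],
        converged=d["converged"],
        n_em_iterations=d["n_em_iterations"],
        params=params,
        loadings=params.standardized_loadings(),
        messages=list(d.get("messages", [])),
        category_merges=d.get("category_merges", {}),
    )


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, header: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=index)


def _loadings_table(res: FitResult, rotated=None) -> pd.DataFrame:
    loadings = rotated if rotated is not None else res.loadings
    frame = loadings.to_frame().round(4)
    sal = classify_salient(loadings)
    for f in frame.columns:
        frame[f"{f}_salient"] = sal.flags[f].values
    return frame


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole calibration pipeline and write the report bundle.

    Synthetic mode: generate the study-shaped data, split person-disjointly
    by household, fit the requested models on the estimation half, compare
    them, cross-validate the bifactor models on the validation half, and
    derive salience tables, omegas and information curves from the richest
    bifactor model fitted.  Returns the bundle manifest as a dict.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    header = f"# irtcal run seed={config.seed} config_hash={config.config_hash()}\n"
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "config": config.to_dict(),
        "outputs": [],
    }

    def record(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    data, truth, plan = load_data(config)
    if plan is not None:
        plan.to_yaml(record("plan.yaml"))
        truth.to_json(record("truth.json"))
    data.to_csv(record("responses.csv"))
    est, val = split_sample(data, seeds["split"])
    manifest["n_total"] = int(data.n_persons)
    manifest["n_estimation"] = int(est.n_persons)
    manifest["n_validation"] = int(val.n_persons)
    manifest["n_estimation_nonempty"] = int(est.n_nonempty())
    manifest["n_validation_nonempty"] = int(val.n_nonempty())

    cb = data.codebook
    fits: dict[int, FitResult] = {}
    specs: dict[int, ModelSpec] = {}
    for m in sorted(config.models):
        spec = build_spec(m, cb, config)
        logger.info("fitting %s on n = %d", spec.name, est.n_persons)
        res = fit(est, spec)
        logger.info("%s: LL = %.1f, p = %d, BIC = %.1f, converged = %s (%d iterations)",
                    res.model_name, res.log_likelihood, res.n_params, res.bic,
                    res.converged, res.n_em_iterations)
        fits[m] = res
        specs[m] = spec
        with open(record(f"fit_model{m}.json"), "w") as fh:
            json.dump(fitresult_to_dict(res), fh, indent=1)
        rotated = None
        if m == 2:
            rot = geomin_rotate(res.loadings, seed=seeds["rotation"])
            rotated = rot.loadings
            np.savetxt(record("factor_correlations_model2.csv"),
                       rot.factor_correlations, delimiter=",")
        _write_csv(_loadings_table(res, rotated), record(f"loadings_model{m}.csv"), header)

    if len(fits) >= 2:
        table = compare(list(fits.values()))
        _write_csv(table.frame, record("comparison.csv"), header)
        manifest["selected_bic"] = table.selected_bic
        manifest["selected_bic_adj"] = table.selected_bic_adj

    cv_rows = []
    for m in (3, 4):
        if m in fits:
            for variant in ("all_fixed", "free_variances"):
                cv = cross_validate(
                    fits[m].params, val, variant,
                    quadrature=QuadratureSpec(n_nodes=config.n_nodes),
                    model_name=fits[m].model_name,
                )
                row = {
                    "model": cv.model_name, "variant": cv.variant,
                    "log_likelihood": cv.log_likelihood, "n_params": cv.n_params,
                    "bic": cv.bic, "bic_adj": cv.bic_adj,
                }
                if cv.factor_variances is not None:
                    row["factor_variances"] = " ".join(
                        f"{v:.4f}" for v in cv.factor_variances
                    )
                cv_rows.append(row)
    if cv_rows:
        _write_csv(pd.DataFrame(cv_rows), record("crossval.csv"), header, index=False)

    best_bifactor = 4 if 4 in fits else (3 if 3 in fits else None)
    if best_bifactor is not None:
        res = fits[best_bifactor]
        omega = omega_decomposition(res.loadings, specs[best_bifactor], cb)
        omega.to_json(record("omega.json"))
        (out / "omega.txt").write_text(omega.to_text() + "\n")
        manifest["outputs"].append("omega.txt")
        manifest["omega"] = omega.to_dict()
        curves = instrument_information_curves(res.params, cb)
        _write_csv(curves.to_frame(), record("information_curves.csv"), header, index=False)
        manifest["information_peak_theta"] = curves.peak_theta()

    manifest["models"] = {
        str(m): {
            "log_likelihood": fits[m].log_likelihood,
            "n_params": fits[m].n_params,
            "bic": fits[m].bic,
            "bic_adj": fits[m].bic_adj,
            "converged": fits[m].converged,
        }
        for m in fits
    }
    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    with open(record("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("run complete in %.1f s; outputs in %s", manifest["elapsed_seconds"], out)
    return manifest
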