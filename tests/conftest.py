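"""Shared fixtures.

The expensive study-scale artefacts are session-scoped: one full pipeline
run on the default synthetic design (three waves, 19 290 persons, models
1-4 on the estimation half), one model-4 fit on the pooled sample for
parameter-recovery checks, and one desk-scale (n = 2000) replicate.
"""

from __future__ import annotations

from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pytest

from irtcal.core_model import (
    Codebook,
    Factor,
    GRMParameters,
    Instrument,
    Item,
    ResponseMatrix,
    default_study_codebook,
)
from irtcal.estimation import model4_spec, fit_bifactor
from irtcal.pipeline import RunConfig, run_full_analysis
from irtcal.synthetic_data import (
    SimulationPlan,
    WavePlan,
    default_truth,
    generate,
)

SEED = 73


def make_codebook(n_items: int = 10, n_cats: int = 3, n_instruments: int = 1,
                  bifactor: bool = False) -> Codebook:
    """Small synthetic codebook: items split evenly over instruments, with
    an optional general + per-instrument specific factor plan."""
    ids = tuple(f"i{j:02d}" for j in range(n_items))
    per = n_items // n_instruments
    instruments = [
        Instrument(f"inst{k}", ids[k * per:(k + 1) * per if k < n_instruments - 1 else n_items])
        for k in range(n_instruments)
    ]
    factors = [Factor("general", "general", ids)]
    if bifactor:
        factors += [
            Factor(f"spec{k}", "specific", inst.item_ids)
            for k, inst in enumerate(instruments)
        ]
    return Codebook(
        instruments=instruments,
        items=[Item(i, n_cats) for i in ids],
        factors=factors,
    )


def one_wave_plan(codebook: Codebook, truth: GRMParameters, n: int, seed: int,
                  missing: float = 0.0) -> SimulationPlan:
    return SimulationPlan(
        codebook=codebook,
        truth=truth,
        waves=[WavePlan("w1", n, tuple(i.name for i in codebook.instruments))],
        seed=seed,
        incidental_missing_rate=missing,
    )


@pytest.fixture(scope="session")
def unifactor_toy():
    """1-factor, 10 three-category items, n = 5000, known truth."""
    cb = make_codebook(10, 3)
    truth = GRMParameters(
        slopes=np.full((10, 1), 1.5),
        thresholds=[np.array([-1.0, 0.8])] * 10,
        item_ids=list(cb.item_ids),
        factor_names=["general"],
    )
    data, _ = generate(one_wave_plan(cb, truth, 5000, seed=SEED))
    return SimpleNamespace(codebook=cb, truth=truth, data=data)


@pytest.fixture(scope="session")
def bifactor_toy():
    """6 items, general + two specific factors: small enough for dense
    quadrature cross-checks."""
    cb = make_codebook(6, 3, n_instruments=2, bifactor=True)
    slopes = np.zeros((6, 3))
    slopes[:, 0] = 1.2
    slopes[:3, 1] = 0.9
    slopes[3:, 2] = 0.8
    truth = GRMParameters(
        slopes=slopes,
        thresholds=[np.array([-0.7, 0.9])] * 6,
        item_ids=list(cb.item_ids),
        factor_names=["general", "spec0", "spec1"],
    )
    data, _ = generate(one_wave_plan(cb, truth, 400, seed=SEED + 2))
    return SimpleNamespace(codebook=cb, truth=truth, data=data)


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Full pipeline on the default study-shaped design (n = 19 290)."""
    out = tmp_path_factory.mktemp("study_run")
    config = RunConfig(seed=SEED, out_dir=str(out), max_iter=100, tol=0.01)
    manifest = run_full_analysis(config)
    truth = GRMParameters.from_json(Path(out) / "truth.json")
    return SimpleNamespace(manifest=manifest, out=Path(out), config=config, truth=truth)


@pytest.fixture(scope="session")
def pooled_model4(study_run):
    """Model 4 refitted on the full pooled sample for recovery checks."""
    plan = SimulationPlan.from_yaml(study_run.out / "plan.yaml")
    data, truth = generate(plan)
    res = fit_bifactor(data, model4_spec(data.codebook, max_iter=100, tol=0.01))
    return SimpleNamespace(result=res, truth=truth, data=data)


def scaled_study_plan(n_per_wave: tuple[int, int, int], seed: int) -> SimulationPlan:
    cb = default_study_codebook()
    return SimulationPlan(
        codebook=cb,
        truth=default_truth(cb),
        waves=[WavePlan(w.name, n, w.instruments) for w, n in zip(cb.waves, n_per_wave)],
        seed=seed,
    )


def fit_study_replicate(n_per_wave, seed, max_iter=80, tol=0.02):
    plan = scaled_study_plan(n_per_wave, seed)
    data, truth = generate(plan)
    res = fit_bifactor(data, model4_spec(data.codebook, max_iter=max_iter, tol=tol))
    return res, truth


@pytest.fixture(scope="session")
def n2000_model4():
    """One desk-scale study-shaped replicate (n = 2000)."""
    res, truth = fit_study_replicate((760, 760, 480), SEED + 1)
    return SimpleNamespace(result=res, truth=truth)


def general_loading_mae(result, truth) -> float:
    lam = result.loadings.loadings
    lam_t = truth.standardized_loadings().loadings
    g = result.params.factor_names.index("general")
    gt = truth.factor_names.index("general")
    return float(np.abs(lam[:, g] - lam_t[:, gt]).mean())
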