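"""Study-shaped synthetic data with known truth.

The generator emulates the pooled three-wave household survey design: three
waves of sizes 7255, 7246 and 4789 (19 290 persons in total), the second
wave omitting the GHQ-12 (planned missingness), up to two selected
respondents per household, and a small completely-at-random incidental
missingness rate on top.  Latent factors are drawn independent standard
normal (an orthogonal bifactor truth) unless a factor covariance is given;
responses follow the graded response model of :mod:`irtcal.core_model`.

The default truth parameters are fixtures chosen to mimic the qualitative
pattern the pipeline is meant to detect -- a dominant general factor that
the GHQ-like items measure almost exclusively, a sizeable specific factor
for the WEMWBS-like items, and an EQ-5D-like instrument whose items (bar
the anxiety/depression one) mostly stand apart -- not estimates from any
real survey.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core_model import (
    D_SCALE,
    MISSING,
    Codebook,
    GRMParameters,
    ResponseMatrix,
    default_study_codebook,
    grm_cumulative,
)

logger = logging.getLogger("irtcal.synthetic_data")

DEFAULT_WAVE_SIZES = (7255, 7246, 4789)
DEFAULT_TWO_RESPONDENT_RATE = 0.5
DEFAULT_INCIDENTAL_MISSING = 0.01


@dataclass
class WavePlan:
    name: str
    size: int
    instruments: tuple[str, ...]


@dataclass
class SimulationPlan:
    """Everything needed to generate one study-shaped dataset."""

    codebook: Codebook
    truth: GRMParameters
    waves: list[WavePlan]
    seed: int
    two_respondent_rate: float = DEFAULT_TWO_RESPONDENT_RATE
    incidental_missing_rate: float = DEFAULT_INCIDENTAL_MISSING
    factor_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for simulation plans")
        inst_names = {i.name for i in self.codebook.instruments}
        for w in self.waves:
            unknown = set(w.instruments) - inst_names
            if unknown:
                raise ValueError(f"wave {w.name!r} references unknown instruments {unknown}")
        if not (0.0 <= self.incidental_missing_rate < 1.0):
            raise ValueError("incidental_missing_rate must be in [0, 1)")

    @property
    def n_persons(self) -> int:
        return sum(w.size for w in self.waves)

    def to_yaml(self, path) -> None:
        d = {
            "seed": self.seed,
            "two_respondent_rate": self.two_respondent_rate,
            "incidental_missing_rate": self.incidental_missing_rate,
            "waves": [
                {"name": w.name, "size": w.size, "instruments": list(w.instruments)}
                for w in self.waves
            ],
            "codebook": self.codebook.to_dict(),
            "truth": self.truth.to_dict(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationPlan":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            codebook=Codebook.from_dict(d["codebook"]),
            truth=GRMParameters.from_dict(d["truth"]),
            waves=[WavePlan(w["name"], int(w["size"]), tuple(w["instruments"]))
                   for w in d["waves"]],
            seed=int(d["seed"]),
            two_respondent_rate=float(d.get("two_respondent_rate", DEFAULT_TWO_RESPONDENT_RATE)),
            incidental_missing_rate=float(
                d.get("incidental_missing_rate", DEFAULT_INCIDENTAL_MISSING)
            ),
        )


# ---------------------------------------------------------------------------
# Default truth
# ---------------------------------------------------------------------------

def _slopes_from_std(lams: np.ndarray) -> np.ndarray:
    """Invert the standardized-loading map: a = D lam / sqrt(1 - sum lam^2)."""
    comm = np.sum(lams**2, axis=1, keepdims=True)
    if np.any(comm >= 1.0):
        raise ValueError("communality >= 1 in truth loadings")
    return D_SCALE * lams / np.sqrt(1.0 - comm)


_JITTER = (-0.04, -0.02, 0.0, 0.02, 0.04)
_SHIFT = (-0.3, -0.15, 0.0, 0.15, 0.3)


def default_truth(codebook: Codebook | None = None) -> GRMParameters:
    """Fixture truth on the standardized-loading scale.

    GHQ-like items: general ~0.75 with a weak (0.20) specific factor and a
    0.30 wording loading for the negatively phrased six; WEMWBS-like items:
    general ~0.60, specific 0.45, social/interest 0.35 for the designated
    five; EQ-5D-like: the anxiety/depression item 0.70 general / 0.40
    specific, the other four 0.20 general / 0.70 specific.  Thresholds place
    most of the distress items' measurement below the population mean.
    """
    cb = codebook or default_study_codebook()
    factor_names = [f.name for f in cb.factors]
    J, K = cb.n_items, len(factor_names)
    lam = np.zeros((J, K))
    thresholds: list[np.ndarray] = []
    col = {name: k for k, name in enumerate(factor_names)}
    fac_items = {f.name: set(f.item_ids) for f in cb.factors}

    base_diffs = {
        "GHQ-12": np.array([-1.7, -0.7, 0.3]),
        "WEMWBS": np.array([-1.9, -0.9, 0.1, 1.1]),
        "EQ-5D": np.array([0.4, 1.9]),
    }
    for idx, iid in enumerate(cb.item_ids):
        inst = cb.instrument_of(iid)
        jit = _JITTER[idx % len(_JITTER)]
        if inst == "GHQ-12":
            lam[idx, col["general"]] = 0.75 + jit
            lam[idx, col["spec_ghq"]] = 0.20
            if iid in fac_items.get("meth_wording", ()):
                lam[idx, col["meth_wording"]] = 0.30
        elif inst == "WEMWBS":
            lam[idx, col["general"]] = 0.60 + jit
            lam[idx, col["spec_wemwbs"]] = 0.45
            if iid in fac_items.get("meth_social", ()):
                lam[idx, col["meth_social"]] = 0.35
        else:  # EQ-5D
            if iid == "eq_anxiety":
                lam[idx, col["general"]] = 0.70
                lam[idx, col["spec_eq5d"]] = 0.40
            else:
                lam[idx, col["general"]] = 0.20 + jit
                lam[idx, col["spec_eq5d"]] = 0.70
    slopes = _slopes_from_std(lam)
    for idx, iid in enumerate(cb.item_ids):
        inst = cb.instrument_of(iid)
        d = base_diffs[inst] + _SHIFT[idx % len(_SHIFT)]
        a_gen = slopes[idx, col["general"]]
        thresholds.append(d * a_gen)
    return GRMParameters(
        slopes=slopes,
        thresholds=thresholds,
        item_ids=list(cb.item_ids),
        factor_names=factor_names,
    )


def default_plan(seed: int) -> SimulationPlan:
    """The study-shaped default: waves of 7255/7246/4789 persons with the
    GHQ-12 absent from the second wave."""
    cb = default_study_codebook()
    waves = [
        WavePlan(w.name, size, w.instruments)
        for w, size in zip(cb.waves, DEFAULT_WAVE_SIZES)
    ]
    return SimulationPlan(codebook=cb, truth=default_truth(cb), waves=waves, seed=seed)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate(plan: SimulationPlan) -> tuple[ResponseMatrix, GRMParameters]:
    """Draw a response matrix from the plan; returns (data, truth record).

    Latent factors are standard normal and independent unless
    ``plan.factor_cov`` is given; responses come from the GRM category
    probabilities; instruments not administered in a wave are MISSING for
    that wave's rows, and incidental missingness is added completely at
    random.
    """
    rng = np.random.default_rng(plan.seed)
    cb = plan.codebook
    truth = plan.truth
    n = plan.n_persons
    K = truth.n_factors

    # households: up to two selected respondents each, sizes drawn per wave
    household_ids = np.empty(n, dtype=np.int64)
    waves = np.empty(n, dtype=object)
    hh = 0
    pos = 0
    for w in plan.waves:
        remaining = w.size
        while remaining > 0:
            size = 2 if (remaining >= 2 and rng.random() < plan.two_respondent_rate) else 1
            household_ids[pos:pos + size] = hh
            waves[pos:pos + size] = w.name
            hh += 1
            pos += size
            remaining -= size

    if plan.factor_cov is not None:
        chol = np.linalg.cholesky(np.asarray(plan.factor_cov))
        theta = rng.standard_normal((n, K)) @ chol.T
    else:
        theta = rng.standard_normal((n, K))

    A = truth.effective_slopes()
    values = np.empty((n, cb.n_items), dtype=np.int64)
    for j in range(cb.n_items):
        W = grm_cumulative(A[j], truth.thresholds[j], theta)      # (n, C-1)
        u = rng.random(n)
        values[:, j] = (u[:, None] < W).sum(axis=1)

    # planned (structural) missingness by wave
    administered = {w.name: set(w.instruments) for w in plan.waves}
    for j, iid in enumerate(cb.item_ids):
        inst = cb.instrument_of(iid)
        for wname, admin in administered.items():
            if inst not in admin:
                values[waves == wname, j] = MISSING

    # incidental missingness, completely at random
    if plan.incidental_missing_rate > 0:
        drop = rng.random(values.shape) < plan.incidental_missing_rate
        values[drop] = MISSING

    data = ResponseMatrix(
        values=values,
        item_ids=list(cb.item_ids),
        codebook=cb,
        person_ids=np.arange(n),
        household_ids=household_ids,
        waves=waves.astype(str),
    )
    logger.info("generated %d persons in %d households", n, hh)
    return data, truth


# ---------------------------------------------------------------------------
# Estimation/validation split
# ---------------------------------------------------------------------------

def split_sample(data: ResponseMatrix, seed: int) -> tuple[ResponseMatrix, ResponseMatrix]:
    """Person-disjoint estimation/validation split.

    From each two-respondent household one person goes to each half; single
    respondents are assigned by an independent fair coin, which is where the
    small size imbalance between the halves comes from.  Without household
    IDs the split degrades to a simple random person split (warned).
    """
    rng = np.random.default_rng(seed)
    n = data.n_persons
    if data.household_ids is None:
        logger.warning("no household IDs: falling back to a simple random person split")
        to_est = rng.random(n) < 0.5
    else:
        to_est = np.zeros(n, dtype=bool)
        order = {}
        for i, h in enumerate(data.household_ids):
            order.setdefault(h, []).append(i)
        for members in order.values():
            if len(members) == 1:
                to_est[members[0]] = rng.random() < 0.5
            else:
                members = list(members)
                rng.shuffle(members)
                # alternate so households contribute at most one person per half
                for rank, i in enumerate(members):
                    to_est[i] = rank % 2 == 0
    est = data.subset_persons(np.where(to_est)[0])
    val = data.subset_persons(np.where(~to_est)[0])
    logger.info("split %d persons into %d (estimation) + %d (validation)",
                n, est.n_persons, val.n_persons)
    return est, val
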