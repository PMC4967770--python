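"""Post-fit analytics: salient-loading classification, test information
curves and omega reliability decomposition.

Information is reported about the general factor with all other factors held
at their population mean of 0 (the conditional "partial information" that is
standard for bifactor models); the theta axis is the standardized general
dimension, so 0 marks the population mean.  Omegas are the model-based
reliabilities of unit-weighted sum scores computed from standardized
loadings of an orthogonal bifactor solution:

    omega    = [ (sum lam_g)^2 + sum_f (sum lam_f)^2 ] / [ ... + sum resid ]
    omega_h  =   (sum lam_g)^2                         / same denominator
    omega_s  = per instrument, the non-general numerator share of that
               instrument's sum-score variance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    Codebook,
    GRMParameters,
    ParameterError,
    StandardizedLoadings,
    item_information,
)
from .estimation import ModelSpec

logger = logging.getLogger("irtcal.psychometrics")

SALIENCE_THRESHOLD = 0.40

DEFAULT_THETA_GRID = np.round(np.arange(-4.0, 4.0 + 1e-9, 0.05), 10)


# ---------------------------------------------------------------------------
# Salient loadings
# ---------------------------------------------------------------------------

@dataclass
class SalienceReport:
    flags: pd.DataFrame                    # item x factor booleans
    threshold: float
    by_factor: dict[str, list[str]]        # factor -> salient items

    def to_frame(self) -> pd.DataFrame:
        return self.flags


def classify_salient(loadings: StandardizedLoadings,
                     threshold: float = SALIENCE_THRESHOLD) -> SalienceReport:
    """Flag loadings with |lambda| >= threshold (boundary counts as salient)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    flags = np.abs(loadings.loadings) >= threshold
    frame = pd.DataFrame(flags, index=loadings.item_ids, columns=loadings.factor_names)
    by_factor = {
        f: [iid for iid, hit in zip(loadings.item_ids, frame[f]) if hit]
        for f in loadings.factor_names
    }
    return SalienceReport(frame, threshold, by_factor)


# ---------------------------------------------------------------------------
# Test information
# ---------------------------------------------------------------------------

@dataclass
class InformationCurve:
    """Total and per-group test information on a standardized theta grid."""

    theta: np.ndarray
    total: np.ndarray
    partials: dict[str, np.ndarray] = field(default_factory=dict)
    target_factor: str = "general"

    def relative_efficiency(self, numerator: str, denominator: str) -> np.ndarray:
        """Pointwise ratio of two partial information functions."""
        num, den = self.partials[numerator], self.partials[denominator]
        return num / np.maximum(den, 1e-12)

    def peak_theta(self) -> float:
        return float(self.theta[int(np.argmax(self.total))])

    def to_frame(self) -> pd.DataFrame:
        cols = {"theta": self.theta, "total": self.total}
        cols.update(self.partials)
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _resolve_target(params: GRMParameters, target_factor: str | None) -> str:
    if target_factor is not None:
        return target_factor
    if "general" in params.factor_names:
        return "general"
    if params.n_factors == 1:
        return params.factor_names[0]
    raise ParameterError("target_factor required when no 'general' factor exists")


def test_information(params: GRMParameters, items: list[str] | None = None,
                     theta_grid: np.ndarray | None = None,
                     target_factor: str | None = None) -> InformationCurve:
    """Pointwise sum of item information over ``items`` (default: all).

    Information is about the general factor unless ``target_factor`` names
    another one; it is additive over items, so the curve for all items
    equals the sum of any partition's curves.
    """
    target_factor = _resolve_target(params, target_factor)
    grid = DEFAULT_THETA_GRID if theta_grid is None else np.asarray(theta_grid, dtype=float)
    if items is None:
        items = list(params.item_ids)
    if len(items) == 0:
        logger.warning("empty item subset: returning a zero information curve")
        return InformationCurve(grid, np.zeros_like(grid), target_factor=target_factor)
    total = np.zeros_like(grid)
    for iid in items:
        total += item_information(params, iid, grid, target_factor)
    return InformationCurve(grid, total, target_factor=target_factor)


def instrument_information_curves(params: GRMParameters, codebook: Codebook,
                                  theta_grid: np.ndarray | None = None,
                                  target_factor: str | None = None) -> InformationCurve:
    """Total curve plus one partial information curve per instrument."""
    target_factor = _resolve_target(params, target_factor)
    grid = DEFAULT_THETA_GRID if theta_grid is None else np.asarray(theta_grid, dtype=float)
    partials = {}
    for inst in codebook.instruments:
        partials[inst.name] = test_information(
            params, codebook.instrument_items(inst.name), grid, target_factor
        ).total
    total = np.sum(list(partials.values()), axis=0)
    return InformationCurve(grid, total, partials, target_factor)


# ---------------------------------------------------------------------------
# Omega decomposition
# ---------------------------------------------------------------------------

@dataclass
class OmegaReport:
    """Reliability decomposition of sum scores under an orthogonal bifactor
    solution: 0 <= omega_h <= omega <= 1 overall and 0 <= omega_s <= omega
    per instrument."""

    omega_total: float
    omega_h: float
    per_instrument: dict[str, dict[str, float]]   # name -> {omega, omega_s}

    def to_dict(self) -> dict:
        return {
            "omega": self.omega_total,
            "omega_h": self.omega_h,
            "instruments": self.per_instrument,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_text(self) -> str:
        lines = [
            f"omega   (all factors)   {self.omega_total:6.3f}",
            f"omega_h (general only)  {self.omega_h:6.3f}",
        ]
        for name, vals in self.per_instrument.items():
            lines.append(
                f"{name:<10s} omega {vals['omega']:6.3f}   omega_s {vals['omega_s']:6.3f}"
            )
        return "\n".join(lines)


def _omega_terms(lam: np.ndarray, rows: np.ndarray, general: int):
    """(general term, specific terms, residual sum) for a row subset."""
    sub = lam[rows]
    gen = float(sub[:, general].sum()) ** 2
    specs = [
        float(sub[:, k].sum()) ** 2
        for k in range(lam.shape[1]) if k != general
    ]
    resid = float(np.sum(1.0 - np.sum(sub**2, axis=1)))
    return gen, specs, resid


def omega_decomposition(loadings: StandardizedLoadings, structure: ModelSpec,
                        codebook: Codebook | None = None,
                        subset: str | None = None) -> OmegaReport:
    """Omega, omega-hierarchical and per-instrument omega-s from an
    orthogonal bifactor solution.

    ``structure`` supplies the factor kinds; the solution must contain a
    general factor and orthogonal group factors (exploratory/rotated
    solutions are rejected).  ``subset`` restricts the per-instrument block
    to a single instrument.
    """
    kinds = dict(zip(structure.factor_names, structure.factor_kinds))
    if "exploratory" in kinds.values():
        raise ParameterError("omegas are defined here only for orthogonal bifactor solutions")
    general_names = [n for n, k in kinds.items() if k == "general"]
    if len(general_names) != 1:
        raise ParameterError("need exactly one general factor")
    g = loadings.factor_names.index(general_names[0])
    lam = loadings.loadings

    all_rows = np.arange(lam.shape[0])
    gen, specs, resid = _omega_terms(lam, all_rows, g)
    denom = gen + sum(specs) + resid
    omega_total = (gen + sum(specs)) / denom if denom > 0 else 0.0
    omega_h = gen / denom if denom > 0 else 0.0

    per_instrument: dict[str, dict[str, float]] = {}
    if codebook is not None:
        instruments = (
            [i for i in codebook.instruments if i.name == subset]
            if subset else codebook.instruments
        )
        if subset and not instruments:
            raise ParameterError(f"unknown instrument {subset!r}")
        item_pos = {iid: j for j, iid in enumerate(loadings.item_ids)}
        for inst in instruments:
            rows = np.array([item_pos[iid] for iid in inst.item_ids])
            i_gen, i_specs, i_resid = _omega_terms(lam, rows, g)
            i_denom = i_gen + sum(i_specs) + i_resid
            per_instrument[inst.name] = {
                "omega": (i_gen + sum(i_specs)) / i_denom if i_denom > 0 else 0.0,
                "omega_s": sum(i_specs) / i_denom if i_denom > 0 else 0.0,
            }
    return OmegaReport(omega_total, omega_h, per_instrument)
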