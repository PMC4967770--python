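"""Information criteria, parameter counting, model comparison and
fixed-parameter cross-validation.

The comparison logic mirrors the usual latent-variable workflow: candidate
models are ranked by BIC = -2LL + p ln(n) and by the sample-size-adjusted
BIC = -2LL + p ln((n+2)/24); the holdout check freezes the estimation-sample
loadings and thresholds and either evaluates the holdout likelihood as-is
("all parameters fixed", zero free parameters) or frees one variance per
factor ("free variances"), which measures whether the latent metric carries
over to the independent sample.

``n`` for the criteria is the number of persons with at least one observed
response, not the nominal sample size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core_model import Codebook, FitResult, GRMParameters, ParameterError, ResponseMatrix
from .estimation import ModelSpec, QuadratureSpec, reported_loglik, total_loglik

logger = logging.getLogger("irtcal.model_selection")

VARIANTS = ("all_fixed", "free_variances")


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------

def bic(LL: float, p: int, n: int) -> float:
    """Bayesian information criterion, -2 LL + p ln(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if p < 0:
        raise ValueError("p must be >= 0")
    return -2.0 * LL + p * math.log(n)


def bic_adj(LL: float, p: int, n: int) -> float:
    """Sample-size-adjusted BIC, -2 LL + p ln((n + 2) / 24)."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if n < 23:
        logger.warning("adjusted BIC with n = %d has a sub-unit effective sample size", n)
    return -2.0 * LL + p * math.log((n + 2) / 24.0)


def count_parameters(spec: ModelSpec, codebook: Codebook,
                     category_counts: dict[str, int] | None = None) -> int:
    """Free parameters of a GRM model: one threshold per category boundary
    plus one slope per permitted item-factor pair.  Echelon identification
    zeros of exploratory models are already absent from the pattern, which
    realises the usual "slopes minus m(m-1)/2" count."""
    cats = [
        (category_counts or {}).get(iid, codebook.n_categories(iid))
        for iid in codebook.item_ids
    ]
    n_thresholds = sum(c - 1 for c in cats)
    return n_thresholds + int(spec.pattern.sum())


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    """Holdout evaluation of a fitted model at (mostly) fixed parameters."""

    model_name: str
    variant: str
    log_likelihood: float
    n_params: int           # free parameters in the holdout evaluation
    n_obs: int
    bic: float
    bic_adj: float
    factor_variances: np.ndarray | None = None
    converged: bool = True


def cross_validate(params: GRMParameters, holdout: ResponseMatrix, variant: str,
                   quadrature: QuadratureSpec | int | None = None,
                   model_name: str = "model") -> CrossValidationResult:
    """Evaluate estimation-sample parameters on a person-disjoint holdout.

    ``all_fixed`` evaluates the holdout log-likelihood at the given
    loadings/thresholds (0 free parameters, so BIC = -2 LL); the
    ``free_variances`` variant re-estimates one variance per factor while
    keeping all loadings and thresholds fixed.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if list(params.item_ids) != list(holdout.item_ids):
        raise ParameterError("holdout data and parameters use different item sets")
    n = holdout.n_nonempty()
    q = (quadrature if isinstance(quadrature, QuadratureSpec)
         else QuadratureSpec(n_nodes=quadrature))
    if variant == "all_fixed":
        ll = reported_loglik(params, holdout, q)
        return CrossValidationResult(
            model_name, variant, ll, 0, n, bic(ll, 0, n), bic_adj(ll, 0, n)
        )

    K = params.n_factors
    base = params

    def with_variances(log_var: np.ndarray) -> GRMParameters:
        return GRMParameters(
            slopes=base.slopes,
            thresholds=base.thresholds,
            item_ids=base.item_ids,
            factor_names=base.factor_names,
            factor_variances=np.exp(log_var),
        )

    # optimise on the (cheap) estimation grid, report on the dense grid
    def negll(log_var: np.ndarray) -> float:
        return -total_loglik(with_variances(log_var), holdout, q)

    res = minimize(
        negll, np.zeros(K), method="L-BFGS-B",
        bounds=[(-3.0, 3.0)] * K,
        options={"maxiter": 40, "ftol": 1e-10},
    )
    variances = np.exp(res.x)
    ll = reported_loglik(with_variances(res.x), holdout, q)
    return CrossValidationResult(
        model_name, "free_variances", ll, K, n,
        bic(ll, K, n), bic_adj(ll, K, n),
        factor_variances=variances, converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# Comparison tables
# ---------------------------------------------------------------------------

@dataclass
class ComparisonTable:
    """Per-model LL, p, BIC and adjusted BIC with the criterion argmins."""

    frame: pd.DataFrame
    selected_bic: str
    selected_bic_adj: str
    messages: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.frame.round(0).to_csv(path)

    def to_dict(self) -> dict:
        return {
            "table": self.frame.to_dict(orient="index"),
            "selected_bic": self.selected_bic,
            "selected_bic_adj": self.selected_bic_adj,
        }


def compare(models: list[FitResult | CrossValidationResult]) -> ComparisonTable:
    """Rank models fitted to the same sample by BIC and adjusted BIC."""
    if not models:
        raise ValueError("no models to compare")
    ns = {m.n_obs for m in models}
    if len(ns) > 1:
        raise ValueError(f"models were fitted on different sample sizes: {sorted(ns)}")
    rows = {}
    for m in models:
        name = m.model_name
        rows[name] = {
            "log_likelihood": m.log_likelihood,
            "n_params": m.n_params,
            "bic": m.bic,
            "bic_adj": m.bic_adj,
        }
    frame = pd.DataFrame(rows).T
    sel_bic = frame["bic"].idxmin()
    sel_adj = frame["bic_adj"].idxmin()
    messages = []
    if sel_bic != sel_adj:
        messages.append(f"BIC selects {sel_bic!r} but adjusted BIC selects {sel_adj!r}")
        logger.info(messages[-1])
    return ComparisonTable(frame, sel_bic, sel_adj, messages)
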