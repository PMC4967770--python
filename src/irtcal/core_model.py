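"""Domain types and the graded response measurement model.

The measurement model throughout the package is Samejima's logistic graded
response model (GRM): for an ordinal item j with categories 0..C-1 and a
latent factor vector theta,

    P(Y_j >= c | theta) = sigmoid( sum_k a_jk theta_k - b_jc ),  c = 1..C-1,

with strictly increasing thresholds b_j1 < ... < b_j,C-1, and category
probabilities given by adjacent differences of these cumulative curves.
Factors are standard normal during estimation; a per-factor variance is
carried separately and folded into the slopes (``effective_slopes``) so the
same quadrature machinery serves both fixed- and free-variance analyses.

Slopes are reported on the logistic metric; standardized loadings use the
conventional D = 1.7 bridge so they approximate the normal-ogive
(correlation) metric:  lambda_jk = (a_jk/D) / sqrt(1 + sum_k (a_jk/D)^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

MISSING: int = -1
"""Sentinel for a missing response in integer response arrays."""

D_SCALE: float = 1.7
"""Logistic-to-normal-ogive scaling constant used for standardized loadings."""

FACTOR_KINDS = ("general", "specific", "method", "exploratory")


# ---------------------------------------------------------------------------
# Codebook
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Item:
    item_id: str
    n_categories: int


@dataclass(frozen=True)
class Instrument:
    name: str
    item_ids: tuple[str, ...]


@dataclass(frozen=True)
class Factor:
    name: str
    kind: str
    item_ids: tuple[str, ...]


@dataclass(frozen=True)
class Wave:
    name: str
    instruments: tuple[str, ...]


class CodebookError(ValueError):
    pass


@dataclass
class Codebook:
    """Declarative description of instruments, items, factors and waves.

    Invariants enforced on construction: every item belongs to exactly one
    instrument, every factor references existing items, and every item has
    at least two response categories.
    """

    instruments: list[Instrument]
    items: list[Item]
    factors: list[Factor] = field(default_factory=list)
    waves: list[Wave] = field(default_factory=list)
    has_households: bool = True

    def __post_init__(self) -> None:
        self.instruments = [
            i if isinstance(i, Instrument) else Instrument(i[0], tuple(i[1]))
            for i in self.instruments
        ]
        self.items = [
            i if isinstance(i, Item) else Item(i[0], int(i[1])) for i in self.items
        ]
        self.factors = [
            f if isinstance(f, Factor) else Factor(f[0], f[1], tuple(f[2]))
            for f in self.factors
        ]
        self.waves = [
            w if isinstance(w, Wave) else Wave(w[0], tuple(w[1])) for w in self.waves
        ]
        self._validate()
        self._item_index = {it.item_id: j for j, it in enumerate(self.items)}

    def _validate(self) -> None:
        item_ids = [it.item_id for it in self.items]
        if len(set(item_ids)) != len(item_ids):
            raise CodebookError("duplicate item ids")
        known = set(item_ids)
        owner: dict[str, str] = {}
        for inst in self.instruments:
            for iid in inst.item_ids:
                if iid not in known:
                    raise CodebookError(f"instrument {inst.name!r} references unknown item {iid!r}")
                if iid in owner:
                    raise CodebookError(f"item {iid!r} assigned to two instruments")
                owner[iid] = inst.name
        missing = known - set(owner)
        if missing:
            raise CodebookError(f"items without an instrument: {sorted(missing)}")
        for it in self.items:
            if it.n_categories < 2:
                raise CodebookError(f"item {it.item_id!r} has fewer than 2 categories")
        for f in self.factors:
            if f.kind not in FACTOR_KINDS:
                raise CodebookError(f"unknown factor kind {f.kind!r}")
            for iid in f.item_ids:
                if iid not in known:
                    raise CodebookError(f"factor {f.name!r} references unknown item {iid!r}")
        inst_names = {i.name for i in self.instruments}
        for w in self.waves:
            for name in w.instruments:
                if name not in inst_names:
                    raise CodebookError(f"wave {w.name!r} references unknown instrument {name!r}")

    # -- lookups ------------------------------------------------------------

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def n_items(self) -> int:
        return len(self.items)

    def item_index(self, item_id: str) -> int:
        try:
            return self._item_index[item_id]
        except KeyError:
            raise CodebookError(f"unknown item {item_id!r}") from None

    def n_categories(self, item_id: str) -> int:
        return self.items[self.item_index(item_id)].n_categories

    def instrument_of(self, item_id: str) -> str:
        for inst in self.instruments:
            if item_id in inst.item_ids:
                return inst.name
        raise CodebookError(f"unknown item {item_id!r}")

    def instrument_items(self, name: str) -> list[str]:
        for inst in self.instruments:
            if inst.name == name:
                return list(inst.item_ids)
        raise CodebookError(f"unknown instrument {name!r}")

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise CodebookError(f"unknown factor {name!r}")

    def loading_pattern(self, factor_names: Sequence[str] | None = None) -> np.ndarray:
        """Boolean item x factor matrix of permitted loadings."""
        names = list(factor_names) if factor_names is not None else [f.name for f in self.factors]
        pattern = np.zeros((self.n_items, len(names)), dtype=bool)
        for k, name in enumerate(names):
            fac = self.factor(name)
            for iid in fac.item_ids:
                pattern[self.item_index(iid), k] = True
        return pattern

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "instruments": [{"name": i.name, "items": list(i.item_ids)} for i in self.instruments],
            "items": [{"id": it.item_id, "n_categories": it.n_categories} for it in self.items],
            "factors": [
                {"name": f.name, "kind": f.kind, "items": list(f.item_ids)} for f in self.factors
            ],
            "waves": [{"name": w.name, "instruments": list(w.instruments)} for w in self.waves],
            "has_households": self.has_households,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        for key in ("instruments", "items"):
            if key not in d:
                raise CodebookError(f"codebook is missing required section {key!r}")
        return cls(
            instruments=[Instrument(i["name"], tuple(i["items"])) for i in d["instruments"]],
            items=[Item(i["id"], int(i["n_categories"])) for i in d["items"]],
            factors=[Factor(f["name"], f["kind"], tuple(f["items"])) for f in d.get("factors", [])],
            waves=[Wave(w["name"], tuple(w["instruments"])) for w in d.get("waves", [])],
            has_households=bool(d.get("has_households", True)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_json(cls, path) -> "Codebook":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# GHQ-12 items with negative phrasing in the standard ordering.
GHQ_NEGATIVE_ITEMS = ("ghq02", "ghq05", "ghq06", "ghq09", "ghq10", "ghq11")

# WEMWBS items treated as the social/interest method set ("useful",
# "interested in other people", "close to other people", "loved",
# "interested in new things").  The exact set is a synthetic designation
# chosen to be consistent with the instruments' published item content.
WEMWBS_SOCIAL_ITEMS = ("wb02", "wb04", "wb09", "wb12", "wb13")

EQ5D_ITEMS = ("eq_mobility", "eq_selfcare", "eq_activities", "eq_pain", "eq_anxiety")


def default_study_codebook() -> Codebook:
    """Codebook emulating the pooled survey design: GHQ-12 (12 four-category
    items), WEMWBS (14 five-category items) and EQ-5D (5 three-category
    items), with a bifactor factor plan (general + three instrument-specific
    factors + wording and social/interest method factors) and three waves,
    the second of which omits the GHQ-12."""
    ghq = tuple(f"ghq{i:02d}" for i in range(1, 13))
    wem = tuple(f"wb{i:02d}" for i in range(1, 15))
    eq = EQ5D_ITEMS
    items = (
        [Item(i, 4) for i in ghq] + [Item(i, 5) for i in wem] + [Item(i, 3) for i in eq]
    )
    all_ids = ghq + wem + eq
    return Codebook(
        instruments=[
            Instrument("GHQ-12", ghq),
            Instrument("WEMWBS", wem),
            Instrument("EQ-5D", eq),
        ],
        items=items,
        factors=[
            Factor("general", "general", all_ids),
            Factor("spec_ghq", "specific", ghq),
            Factor("spec_wemwbs", "specific", wem),
            Factor("spec_eq5d", "specific", eq),
            Factor("meth_wording", "method", GHQ_NEGATIVE_ITEMS),
            Factor("meth_social", "method", WEMWBS_SOCIAL_ITEMS),
        ],
        waves=[
            Wave("wave1", ("GHQ-12", "WEMWBS", "EQ-5D")),
            Wave("wave2", ("WEMWBS", "EQ-5D")),
            Wave("wave3", ("GHQ-12", "WEMWBS", "EQ-5D")),
        ],
    )


# ---------------------------------------------------------------------------
# ResponseMatrix
# ---------------------------------------------------------------------------

class ResponseError(ValueError):
    pass


@dataclass
class ResponseMatrix:
    """Person x item ordinal responses aligned to a codebook.

    ``values`` holds 0-based category codes with :data:`MISSING` (-1) for
    absent cells, covering both incidental and structural (planned, by wave
    design) missingness.
    """

    values: np.ndarray
    item_ids: list[str]
    codebook: Codebook
    person_ids: np.ndarray | None = None
    household_ids: np.ndarray | None = None
    waves: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ResponseError("values must be a 2-d person x item array")
        if list(self.item_ids) != list(self.codebook.item_ids):
            # allow column subsets/reordering by realigning to the codebook
            idx = [self.item_ids.index(i) for i in self.codebook.item_ids
                   if i in self.item_ids]
            if len(idx) != self.codebook.n_items:
                raise ResponseError("response columns do not cover the codebook items")
            self.values = self.values[:, idx]
            self.item_ids = list(self.codebook.item_ids)
        n = self.values.shape[0]
        if self.person_ids is None:
            self.person_ids = np.arange(n)
        self.person_ids = np.asarray(self.person_ids)
        if self.household_ids is not None:
            self.household_ids = np.asarray(self.household_ids)
        if self.waves is not None:
            self.waves = np.asarray(self.waves)
        for attr in ("person_ids", "household_ids", "waves"):
            v = getattr(self, attr)
            if v is not None and len(v) != n:
                raise ResponseError(f"{attr} length {len(v)} != n persons {n}")
        self._validate_ranges()

    def _validate_ranges(self) -> None:
        for j, iid in enumerate(self.item_ids):
            col = self.values[:, j]
            cmax = self.codebook.n_categories(iid)
            bad = (col != MISSING) & ((col < 0) | (col >= cmax))
            if bad.any():
                raise ResponseError(
                    f"item {iid!r}: codes outside 0..{cmax - 1} at rows {np.where(bad)[0][:5]}"
                )

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def n_nonempty(self) -> int:
        """Persons with at least one observed response (the n used by
        information criteria)."""
        return int((self.values != MISSING).any(axis=1).sum())

    def subset_persons(self, mask_or_index) -> "ResponseMatrix":
        idx = np.asarray(mask_or_index)
        return ResponseMatrix(
            values=self.values[idx],
            item_ids=list(self.item_ids),
            codebook=self.codebook,
            person_ids=self.person_ids[idx],
            household_ids=None if self.household_ids is None else self.household_ids[idx],
            waves=None if self.waves is None else self.waves[idx],
        )

    def check_structural_missingness(self) -> None:
        """Verify that instruments absent from a person's wave plan are MISSING."""
        if self.waves is None or not self.codebook.waves:
            return
        plans = {w.name: set(w.instruments) for w in self.codebook.waves}
        for j, iid in enumerate(self.item_ids):
            inst = self.codebook.instrument_of(iid)
            for wname, admin in plans.items():
                if inst in admin:
                    continue
                rows = self.waves == wname
                if (self.values[rows, j] != MISSING).any():
                    raise ResponseError(
                        f"item {iid!r} observed in wave {wname!r} where {inst!r} was not administered"
                    )

    # -- IO -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.astype(float), columns=self.item_ids)
        df[df < 0] = np.nan
        meta = {"person_id": self.person_ids}
        if self.household_ids is not None:
            meta["household_id"] = self.household_ids
        if self.waves is not None:
            meta["wave"] = self.waves
        return pd.concat([pd.DataFrame(meta), df], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, codebook: Codebook, one_based: bool = False) -> "ResponseMatrix":
        df = pd.read_csv(path)
        if "person_id" not in df.columns:
            raise ResponseError("response CSV must have a person_id column")
        vals = df[codebook.item_ids].to_numpy(dtype=float)
        out = np.where(np.isnan(vals), MISSING, vals).astype(np.int64)
        if one_based:
            out = np.where(out == MISSING, MISSING, out - 1)
        return cls(
            values=out,
            item_ids=list(codebook.item_ids),
            codebook=codebook,
            person_ids=df["person_id"].to_numpy(),
            household_ids=df["household_id"].to_numpy() if "household_id" in df else None,
            waves=df["wave"].to_numpy() if "wave" in df else None,
        )


# ---------------------------------------------------------------------------
# Parameters and loadings
# ---------------------------------------------------------------------------

class ParameterError(ValueError):
    pass


@dataclass
class GRMParameters:
    """Slopes and ordered thresholds of a (multidimensional) GRM.

    ``slopes`` is item x factor on the logistic metric with structural zeros
    where the loading pattern excludes a pair; ``thresholds[j]`` is the
    strictly increasing vector b_j of length n_categories(j) - 1.  Factor
    variances default to 1 and are folded into ``effective_slopes`` so the
    latent scale stays standard normal inside all quadrature code.
    """

    slopes: np.ndarray
    thresholds: list[np.ndarray]
    item_ids: list[str]
    factor_names: list[str]
    factor_variances: np.ndarray | None = None
    factor_correlations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.thresholds = [np.asarray(t, dtype=float) for t in self.thresholds]
        if self.slopes.shape != (len(self.item_ids), len(self.factor_names)):
            raise ParameterError("slopes shape does not match item/factor lists")
        if len(self.thresholds) != len(self.item_ids):
            raise ParameterError("one threshold vector per item required")
        for iid, t in zip(self.item_ids, self.thresholds):
            if t.size and np.any(np.diff(t) <= 0):
                raise ParameterError(f"thresholds for item {iid!r} not strictly increasing")
        if self.factor_variances is None:
            self.factor_variances = np.ones(len(self.factor_names))
        self.factor_variances = np.asarray(self.factor_variances, dtype=float)
        if np.any(self.factor_variances <= 0):
            raise ParameterError("factor variances must be positive")
        if self.factor_correlations is not None:
            self.factor_correlations = np.asarray(self.factor_correlations, dtype=float)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def item_index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise ParameterError(f"unknown item {item_id!r}") from None

    def factor_index(self, name: str) -> int:
        try:
            return self.factor_names.index(name)
        except ValueError:
            raise ParameterError(f"unknown factor {name!r}") from None

    def effective_slopes(self) -> np.ndarray:
        """Slopes on the standard-normal latent scale (variances folded in)."""
        return self.slopes * np.sqrt(self.factor_variances)

    def check_pattern(self, codebook: Codebook, factor_names: Sequence[str] | None = None) -> None:
        pattern = codebook.loading_pattern(factor_names or self.factor_names)
        if np.any((self.slopes != 0) & ~pattern):
            raise ParameterError("nonzero slope outside the codebook loading pattern")

    def standardized_loadings(self) -> "StandardizedLoadings":
        a = self.effective_slopes() / D_SCALE
        denom = np.sqrt(1.0 + np.sum(a**2, axis=1, keepdims=True))
        return StandardizedLoadings(
            loadings=a / denom,
            item_ids=list(self.item_ids),
            factor_names=list(self.factor_names),
        )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "item_ids": list(self.item_ids),
            "factor_names": list(self.factor_names),
            "slopes": self.slopes.tolist(),
            "thresholds": [t.tolist() for t in self.thresholds],
            "factor_variances": self.factor_variances.tolist(),
        }
        if self.factor_correlations is not None:
            d["factor_correlations"] = self.factor_correlations.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GRMParameters":
        return cls(
            slopes=np.asarray(d["slopes"]),
            thresholds=[np.asarray(t) for t in d["thresholds"]],
            item_ids=list(d["item_ids"]),
            factor_names=list(d["factor_names"]),
            factor_variances=np.asarray(d["factor_variances"]) if "factor_variances" in d else None,
            factor_correlations=(
                np.asarray(d["factor_correlations"]) if "factor_correlations" in d else None
            ),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GRMParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class StandardizedLoadings:
    """Item x factor loadings on the correlation metric, |lambda| < 1."""

    loadings: np.ndarray
    item_ids: list[str]
    factor_names: list[str]

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        comm = self.communalities()
        if np.any(comm >= 1.0):
            raise ParameterError("item communality >= 1")

    def communalities(self) -> np.ndarray:
        return np.sum(self.loadings**2, axis=1)

    def residual_variances(self) -> np.ndarray:
        return 1.0 - self.communalities()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=self.item_ids, columns=self.factor_names)


@dataclass
class FitResult:
    """Outcome of a marginal maximum likelihood fit."""

    model_name: str
    log_likelihood: float
    n_params: int
    n_obs: int
    bic: float
    bic_adj: float
    converged: bool
    n_em_iterations: int
    params: GRMParameters
    loadings: StandardizedLoadings
    ll_history: list[float] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)
    category_merges: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# GRM probability machinery
# ---------------------------------------------------------------------------

def grm_cumulative(a: np.ndarray, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """P(Y >= c | theta) for c = 1..C-1; theta is (N, K), returns (N, C-1)."""
    u = np.atleast_2d(theta) @ np.asarray(a, dtype=float)
    z = u[:, None] - np.asarray(b, dtype=float)[None, :]
    return expit(z)


def grm_probs(a: np.ndarray, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Category probabilities (N, C) as adjacent differences of the
    cumulative curves; rows sum to 1 by construction."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    W = grm_cumulative(a, b, theta)
    N = theta.shape[0]
    P = np.empty((N, W.shape[1] + 1))
    P[:, 0] = 1.0 - W[:, 0]
    if W.shape[1] > 1:
        P[:, 1:-1] = W[:, :-1] - W[:, 1:]
    P[:, -1] = W[:, -1]
    return P


def grm_logprobs(a: np.ndarray, b: np.ndarray, theta: np.ndarray,
                 floor: float = 1e-300) -> np.ndarray:
    return np.log(np.maximum(grm_probs(a, b, theta), floor))


def category_probabilities(params: GRMParameters, item: str, theta) -> np.ndarray:
    """Probability vector over an item's categories at a latent point.

    ``theta`` must have one coordinate per factor of ``params``.
    """
    theta = np.asarray(theta, dtype=float)
    single = theta.ndim == 1
    theta = np.atleast_2d(theta)
    if theta.shape[1] != params.n_factors:
        raise ParameterError(
            f"theta has {theta.shape[1]} coordinates, model has {params.n_factors} factors"
        )
    j = params.item_index(item)
    P = grm_probs(params.effective_slopes()[j], params.thresholds[j], theta)
    return P[0] if single else P


# ---------------------------------------------------------------------------
# Quadrature grids and the marginal person likelihood
# ---------------------------------------------------------------------------

def hermite_rule(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights for a standard normal density (weights
    sum to 1)."""
    from scipy.special import roots_hermitenorm

    x, w = roots_hermitenorm(int(n_nodes))
    return x, w / w.sum()


def tensor_grid(n_nodes: int, n_dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Full tensor-product grid: (nodes, logweights) with nodes (M, n_dims)."""
    x, w = hermite_rule(n_nodes)
    grids = np.meshgrid(*([x] * n_dims), indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)
    lw = np.log(w)
    logw = sum(g.ravel() for g in np.meshgrid(*([lw] * n_dims), indexing="ij"))
    return nodes, np.asarray(logw)


def bifactor_layout(pattern: np.ndarray) -> tuple[int, list[tuple[list[int], list[int]]]]:
    """Decompose a loading pattern into (general_column, blocks).

    The general column is the one loading every item.  Remaining columns are
    grouped into connected components that share items; each block is a pair
    (factor columns, item rows).  Items loading only the general factor form
    a block with no extra columns.  Raises if no bifactor structure exists.
    """
    pattern = np.asarray(pattern, dtype=bool)
    J, K = pattern.shape
    general_candidates = [k for k in range(K) if pattern[:, k].all()]
    if not general_candidates:
        raise ParameterError("no general factor (column loading all items) in pattern")
    g = general_candidates[0]
    rest = [k for k in range(K) if k != g]
    # union-find over non-general columns sharing items
    parent = {k: k for k in rest}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for j in range(J):
        cols = [k for k in rest if pattern[j, k]]
        for a_, b_ in zip(cols, cols[1:]):
            parent[find(a_)] = find(b_)
    comps: dict[int, list[int]] = {}
    for k in rest:
        comps.setdefault(find(k), []).append(k)
    blocks: list[tuple[list[int], list[int]]] = []
    claimed = np.zeros(J, dtype=bool)
    for cols in comps.values():
        rows = [j for j in range(J) if pattern[j, cols].any()]
        claimed[rows] = True
        blocks.append((sorted(cols), rows))
    lone = [j for j in range(J) if not claimed[j]]
    if lone:
        blocks.append(([], lone))
    return g, blocks


def _resolve_nodes(quadrature) -> int:
    if quadrature is None:
        return 21
    if isinstance(quadrature, int):
        return quadrature
    return int(getattr(quadrature, "n_nodes"))


def person_loglik(params: GRMParameters, responses, quadrature=None) -> float:
    """Log marginal probability of one person's observed responses.

    The latent factors are integrated out on a Gauss-Hermite grid
    (``quadrature`` is an int or anything with an ``n_nodes`` attribute).
    Missing items contribute nothing (missing-at-random FIML); a person with
    no observed responses contributes 0 by convention.  For models with more
    than three factors a bifactor pattern is required and the integral is
    evaluated with general x block dimension reduction.
    """
    from scipy.special import logsumexp

    resp = np.asarray(responses, dtype=np.int64).ravel()
    if resp.size != params.n_items:
        raise ParameterError("response vector length does not match the item list")
    obs = np.where(resp != MISSING)[0]
    if obs.size == 0:
        return 0.0
    n_nodes = _resolve_nodes(quadrature)
    A = params.effective_slopes()
    K = params.n_factors
    if K <= 3:
        nodes, logw = tensor_grid(n_nodes, K)
        tot = logw.copy()
        for j in obs:
            tot += grm_logprobs(A[j], params.thresholds[j], nodes)[:, resp[j]]
        return float(logsumexp(tot))
    g, blocks = bifactor_layout(A != 0)
    xg, wg = hermite_rule(n_nodes)
    acc = np.log(wg)
    for cols, rows in blocks:
        rows_obs = [j for j in rows if resp[j] != MISSING]
        if not rows_obs:
            continue
        if not cols:
            for j in rows_obs:
                theta = np.zeros((xg.size, K))
                theta[:, g] = xg
                acc += grm_logprobs(A[j], params.thresholds[j], theta)[:, resp[j]]
            continue
        inner_nodes, inner_logw = tensor_grid(n_nodes, len(cols))
        M = inner_nodes.shape[0]
        block_ll = np.tile(inner_logw, (xg.size, 1))  # (Ng, M)
        theta = np.zeros((xg.size * M, K))
        theta[:, g] = np.repeat(xg, M)
        for c, col in enumerate(cols):
            theta[:, col] = np.tile(inner_nodes[:, c], xg.size)
        for j in rows_obs:
            lp = grm_logprobs(A[j], params.thresholds[j], theta)[:, resp[j]]
            block_ll += lp.reshape(xg.size, M)
        acc += logsumexp(block_ll, axis=1)
    return float(logsumexp(acc))


# ---------------------------------------------------------------------------
# Item information
# ---------------------------------------------------------------------------

def item_information(params: GRMParameters, item: str, theta, target_factor: str) -> np.ndarray:
    """Fisher information about ``target_factor`` contributed by one item.

    ``theta`` is the position on the target factor; all other factors are
    held at 0 (their population mean), the usual conditional ("partial")
    information for bifactor models.  Vectorised over theta.
    """
    t = params.factor_index(target_factor)
    j = params.item_index(item)
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    full = np.zeros((theta_arr.size, params.n_factors))
    full[:, t] = theta_arr
    a = params.effective_slopes()[j]
    b = params.thresholds[j]
    W = grm_cumulative(a, b, full)                      # (N, C-1)
    dW = a[t] * W * (1.0 - W)                           # d/dtheta_t of each curve
    P = grm_probs(a, b, full)
    dP = np.empty_like(P)
    dP[:, 0] = -dW[:, 0]
    if W.shape[1] > 1:
        dP[:, 1:-1] = dW[:, :-1] - dW[:, 1:]
    dP[:, -1] = dW[:, -1]
    info = np.sum(dP**2 / np.maximum(P, 1e-300), axis=1)
    return info if np.ndim(theta) else float(info[0])
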