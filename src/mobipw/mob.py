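"""Model-based recursive partitioning of weighted logistic exposure-outcome models.

Each tree node fits the two-parameter weighted binary logistic model

    logit P(Y = 1) = beta0 + beta1 * E

by IRLS on the weighted Bernoulli log-likelihood (weights enter as frequency
weights).  Parameter-instability tests over the candidate moderator
covariates (see :mod:`mobipw.scoretest`) pick a splitting variable; the split
point/partition is the one maximizing the summed maximized log-likelihoods of
the two children, subject to a minimum node size.  Growth stops when no
moderator shows significant instability (Bonferroni-adjusted by default),
when a split would violate the minimum node size, or at the maximum depth.

:class:`MOBLogisticTree` is a scikit-learn style estimator (``get_params`` /
``set_params``, fitted attributes with a trailing underscore); the
module-level functions are thin wrappers over its internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .scoretest import (
    InstabilityResult,
    SingularScoreCovariance,
    nominal_instability,
    ordered_instability,
    whiten_scores,
)

__all__ = [
    "DegenerateModelError",
    "NodeFit",
    "Split",
    "MOBNode",
    "MOBControls",
    "MOBLogisticTree",
    "fit_weighted_logistic",
    "weighted_logistic",
    "instability_test",
    "select_split_variable",
    "search_split",
    "grow_tree",
]

_MAX_ABS_BETA = 30.0  # beyond this the fit is treated as separated
_MAX_THRESHOLDS = 200  # quantile-thin candidate cuts for continuous moderators


class DegenerateModelError(ValueError):
    """Node model cannot be fitted (single outcome class, constant exposure...)."""


# ---------------------------------------------------------------------------
# weighted logistic IRLS with scores and sandwich covariance
# ---------------------------------------------------------------------------

@dataclass
class NodeFit:
    beta: np.ndarray                 # coefficient vector
    loglik: float                    # maximized weighted log-likelihood
    scores: np.ndarray               # n x k weighted score contributions
    cov_model: np.ndarray            # inverse observed information
    cov_robust: np.ndarray           # sandwich (HC0 or HC1)
    n: int
    weight_sum: float
    converged: bool

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def beta1(self) -> float:
        return float(self.beta[1])

    def se(self, robust: bool = True) -> np.ndarray:
        cov = self.cov_robust if robust else self.cov_model
        return np.sqrt(np.diag(cov))


def weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    robust: str = "HC0",
) -> NodeFit:
    """Weighted Bernoulli ML fit of ``logit p = X beta`` by Newton/IRLS.

    Weights are frequency-style: they multiply each record's log-likelihood,
    score, and information contribution.  Raises
    :class:`DegenerateModelError` when only one outcome class is present or a
    non-intercept column is constant.  Separation / non-convergence within
    the iteration cap is reported via ``converged=False`` (the caller decides
    whether that invalidates a node or a candidate split).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if y.min() == y.max():
        raise DegenerateModelError("outcome takes a single value; logistic fit undefined")
    for j in range(1, k):
        if X[:, j].min() == X[:, j].max():
            raise DegenerateModelError(f"design column {j} is constant; coefficient undefined")

    beta = np.zeros(k)
    ybar = np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6)
    beta[0] = np.log(ybar / (1 - ybar))

    def loglik_of(b):
        eta = X @ b
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    ll = loglik_of(beta)
    converged = False
    for _ in range(max_iter):
        p = expit(X @ beta)
        grad = X.T @ (w * (y - p))
        H = (X * (w * p * (1 - p))[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving to guarantee likelihood ascent
        new_ll, shrink = -np.inf, 1.0
        for _ in range(30):
            cand = beta + shrink * step
            new_ll = loglik_of(cand)
            if new_ll >= ll - 1e-12:
                break
            shrink *= 0.5
        beta = beta + shrink * step
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if np.abs(beta).max() > _MAX_ABS_BETA:
        converged = False

    p = expit(X @ beta)
    scores = (w * (y - p))[:, None] * X
    H = (X * (w * p * (1 - p))[:, None]).T @ X
    try:
        cov_model = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_model = np.full((k, k), np.nan)
        converged = False
    B = scores.T @ scores
    cov_robust = cov_model @ B @ cov_model
    if robust == "HC1":
        cov_robust = cov_robust * n / max(n - k, 1)
    return NodeFit(beta, ll, scores, cov_model, cov_robust, n, float(w.sum()), converged)


def fit_weighted_logistic(
    outcome, exposure, weights=None, robust: str = "HC0"
) -> NodeFit:
    """Two-parameter node model: intercept + exposure slope."""
    e = np.asarray(exposure, dtype=float)
    X = np.column_stack([np.ones(len(e)), e])
    return weighted_logistic(X, outcome, weights, robust=robust)


# ---------------------------------------------------------------------------
# controls, nodes, splits
# ---------------------------------------------------------------------------

@dataclass
class MOBControls:
    alpha: float = 0.05
    minsize: int = 100
    maxdepth: int = 3
    bonferroni: bool = True
    trim: float = 0.1
    max_nominal_levels: int = 10
    robust: str = "HC0"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.minsize < 2:
            raise ValueError("minsize must be >= 2")
        if self.maxdepth < 1:
            raise ValueError("maxdepth must be >= 1")
        if not 0.0 < self.trim < 0.5:
            raise ValueError("trim must be in (0, 0.5)")


@dataclass
class Split:
    variable: str
    kind: str                       # ordered | nominal
    threshold: float | None = None  # ordered: left iff z <= threshold
    left_levels: tuple | None = None  # nominal: left iff z in left_levels

    def goes_left(self, z: np.ndarray) -> np.ndarray:
        if self.kind == "ordered":
            return np.asarray(z, dtype=float) <= self.threshold
        return pd.Series(z).isin(list(self.left_levels)).to_numpy()

    def describe(self) -> str:
        if self.kind == "ordered":
            return f"{self.variable} <= {self.threshold:g}"
        return f"{self.variable} in {{{', '.join(map(str, self.left_levels))}}}"


@dataclass
class MOBNode:
    id: int
    depth: int
    fit: NodeFit
    indices: np.ndarray
    split: Split | None = None
    children: list = field(default_factory=list)
    instability: list[InstabilityResult] = field(default_factory=list)
    stop_reason: str | None = None

    @property
    def is_terminal(self) -> bool:
        return not self.children

    @property
    def n(self) -> int:
        return self.fit.n


# ---------------------------------------------------------------------------
# instability testing / split selection / split search
# ---------------------------------------------------------------------------

def instability_test(
    fit: NodeFit, z, covariate: str = "z", kind: str = "ordered",
    controls: MOBControls | None = None,
) -> InstabilityResult:
    """Parameter-instability test of a fitted node model against one moderator."""
    controls = controls or MOBControls()
    whitened = whiten_scores(fit.scores)
    z = np.asarray(z)
    if kind == "nominal":
        return nominal_instability(whitened, z, covariate)
    return ordered_instability(whitened, z.astype(float), covariate, controls.trim)


def select_split_variable(
    results: list[InstabilityResult], controls: MOBControls | None = None
) -> InstabilityResult | None:
    """Smallest Bonferroni-adjusted p-value below alpha, ties by input order."""
    controls = controls or MOBControls()
    if not results:
        return None
    m = len(results)
    for r in results:
        r.p_adjusted = min(1.0, m * r.p_value) if controls.bonferroni else r.p_value
    best = min(results, key=lambda r: r.p_adjusted)  # min() is first-wins on ties
    return best if best.p_adjusted < controls.alpha else None


def _candidate_thresholds(z: np.ndarray) -> np.ndarray:
    vals = np.unique(z)
    if len(vals) - 1 > _MAX_THRESHOLDS:
        qs = np.quantile(z, np.linspace(0, 1, _MAX_THRESHOLDS + 1)[1:-1])
        vals = np.unique(qs)
    return vals[:-1] if len(vals) > 1 else vals[:0]


def search_split(
    outcome, exposure, weights, z, kind: str = "ordered",
    minsize: int = 100, variable: str = "z", max_nominal_levels: int = 10,
) -> tuple[Split, float] | None:
    """Best admissible binary split of one moderator.

    Ordered moderators: threshold among observed values; nominal: exhaustive
    binary level partitions (up to ``max_nominal_levels`` levels).  Candidates
    leaving a child below ``minsize`` records, or with a degenerate /
    non-converged child fit, are discarded.  Returns the split with the
    largest summed child log-likelihood (ties keep the first candidate in
    canonical order: ascending thresholds / subset enumeration order), or
    None if no candidate is admissible.
    """
    y = np.asarray(outcome, dtype=float)
    e = np.asarray(exposure, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    z = np.asarray(z)

    def child_ll(mask) -> float | None:
        if mask.sum() < minsize or (~mask).sum() < minsize:
            return None
        total = 0.0
        for m in (mask, ~mask):
            try:
                f = fit_weighted_logistic(y[m], e[m], w[m])
            except DegenerateModelError:
                return None
            if not f.converged:
                return None
            total += f.loglik
        return total

    best: tuple[Split, float] | None = None
    if kind == "ordered":
        zf = z.astype(float)
        for thr in _candidate_thresholds(zf):
            ll = child_ll(zf <= thr)
            if ll is not None and (best is None or ll > best[1] + 1e-9):
                best = (Split(variable, "ordered", threshold=float(thr)), ll)
    else:
        levels = sorted(pd.unique(pd.Series(z)).tolist(), key=str)
        if len(levels) > max_nominal_levels:
            raise ValueError(
                f"moderator {variable!r} has {len(levels)} levels; "
                f"exhaustive partition search capped at {max_nominal_levels}"
            )
        zs = pd.Series(z)
        rest = levels[1:]
        for r in range(len(rest) + 1):
            for extra in combinations(rest, r):
                left = (levels[0], *extra)
                if len(left) == len(levels):
                    continue
                ll = child_ll(zs.isin(left).to_numpy())
                if ll is not None and (best is None or ll > best[1] + 1e-9):
                    best = (Split(variable, "nominal", left_levels=left), ll)
    return best


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class MOBLogisticTree(BaseEstimator):
    """Model-based recursive partitioning with a weighted logistic node model.

    Parameters
    ----------
    exposure : str
        Name of the exposure column in ``X``.
    moderators : list of str, optional
        Candidate splitting covariates; defaults to every column of ``X``
        except the exposure.
    kinds : dict, optional
        Maps moderator name to ``binary`` / ``ordinal`` / ``continuous``
        (treated as ordered) or ``nominal``.  Unlisted moderators are
        inferred: non-numeric -> nominal, else ordered.
    alpha, minsize, maxdepth, bonferroni, trim
        Stopping-rule controls: significance level of the instability tests
        (applied to Bonferroni-adjusted p-values when ``bonferroni``),
        minimum records per node, maximum tree depth, and the trimming
        fraction of the continuum supLM statistic.

    Attributes
    ----------
    tree_ : MOBNode
        Root of the grown tree.
    nodes_ : list of MOBNode
        All nodes in preorder (ids are preorder positions, root = 1).
    terminal_nodes_ : list of MOBNode
    """

    def __init__(self, exposure: str = "exposure", moderators: list[str] | None = None,
                 kinds: dict[str, str] | None = None, alpha: float = 0.05,
                 minsize: int = 100, maxdepth: int = 3, bonferroni: bool = True,
                 trim: float = 0.1, max_nominal_levels: int = 10, robust: str = "HC0"):
        self.exposure = exposure
        self.moderators = moderators
        self.kinds = kinds
        self.alpha = alpha
        self.minsize = minsize
        self.maxdepth = maxdepth
        self.bonferroni = bonferroni
        self.trim = trim
        self.max_nominal_levels = max_nominal_levels
        self.robust = robust

    # -- helpers -----------------------------------------------------------
    def _controls(self) -> MOBControls:
        return MOBControls(self.alpha, self.minsize, self.maxdepth, self.bonferroni,
                           self.trim, self.max_nominal_levels, self.robust)

    def _kind_of(self, X: pd.DataFrame, name: str) -> str:
        kinds = self.kinds or {}
        k = kinds.get(name)
        if k in ("binary", "ordinal", "continuous"):
            return "ordered"
        if k == "nominal":
            return "nominal"
        return "nominal" if not pd.api.types.is_numeric_dtype(X[name]) else "ordered"

    # -- estimator API -----------------------------------------------------
    def fit(self, X: pd.DataFrame, y, sample_weight=None) -> "MOBLogisticTree":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame with named columns")
        if self.exposure not in X.columns:
            raise ValueError(f"exposure column {self.exposure!r} not in X")
        controls = self._controls()
        mods = list(self.moderators) if self.moderators is not None else [
            c for c in X.columns if c != self.exposure
        ]
        missing = [m for m in mods if m not in X.columns]
        if missing:
            raise ValueError(f"moderator columns not in X: {missing}")
        if not mods:
            raise ValueError("no moderator covariates")
        if X[mods + [self.exposure]].isna().any().any() or pd.Series(y).isna().any():
            raise ValueError("MOB requires complete cases; filter missing values first")

        y = np.asarray(y, dtype=float)
        e = X[self.exposure].to_numpy(dtype=float)
        n = len(y)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        if len(w) != n or (w <= 0).any():
            raise ValueError("sample_weight must be positive and match X")

        zcols = {m: X[m].to_numpy() for m in mods}
        kinds = {m: self._kind_of(X, m) for m in mods}

        self._counter = 0
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.moderators_ = mods
        self.tree_ = self._grow(np.arange(n), 0, y, e, w, zcols, kinds, controls)
        self.nodes_ = []
        self._collect(self.tree_)
        self.terminal_nodes_ = [nd for nd in self.nodes_ if nd.is_terminal]
        return self

    def _next_id(self) -> int:
        self._counter += 1
        return self._counter

    def _grow(self, idx, depth, y, e, w, zcols, kinds, controls) -> MOBNode:
        node_id = self._next_id()
        # children were pre-validated during split search; a degenerate root
        # propagates as DegenerateModelError
        fit = fit_weighted_logistic(y[idx], e[idx], w[idx], robust=controls.robust)
        node = MOBNode(node_id, depth, fit, idx)
        if not fit.converged:
            node.stop_reason = "nonconverged_fit"
            return node
        if depth >= controls.maxdepth:
            node.stop_reason = "maxdepth"
            return node
        if len(idx) < 2 * controls.minsize:
            node.stop_reason = "minsize"
            return node

        try:
            whitened = whiten_scores(fit.scores)
        except SingularScoreCovariance:
            node.stop_reason = "singular_scores"
            return node

        results = []
        for m in self.moderators_:
            zv = zcols[m][idx]
            if len(pd.unique(pd.Series(zv))) < 2:
                continue
            try:
                if kinds[m] == "nominal":
                    r = nominal_instability(whitened, zv, m)
                else:
                    r = ordered_instability(whitened, zv.astype(float), m, controls.trim)
            except (ValueError, np.linalg.LinAlgError):
                continue
            results.append(r)
        node.instability = results
        best = select_split_variable(results, controls)
        if best is None:
            node.stop_reason = "no_instability"
            return node

        found = search_split(
            y[idx], e[idx], w[idx], zcols[best.covariate][idx], kinds[best.covariate],
            controls.minsize, best.covariate, controls.max_nominal_levels,
        )
        if found is None:
            node.stop_reason = "no_admissible_split"
            return node
        split, _ = found
        node.split = split
        left = split.goes_left(zcols[split.variable][idx])
        node.children = [
            self._grow(idx[left], depth + 1, y, e, w, zcols, kinds, controls),
            self._grow(idx[~left], depth + 1, y, e, w, zcols, kinds, controls),
        ]
        return node

    def _collect(self, node: MOBNode) -> None:
        self.nodes_.append(node)
        for c in node.children:
            self._collect(c)

    # -- prediction / inspection ------------------------------------------
    def _route(self, node: MOBNode, X: pd.DataFrame, mask: np.ndarray, out: np.ndarray):
        if node.is_terminal:
            out[mask] = node.id
            return
        left = node.split.goes_left(X[node.split.variable].to_numpy())
        self._route(node.children[0], X, mask & left, out)
        self._route(node.children[1], X, mask & ~left, out)

    def apply(self, X: pd.DataFrame) -> np.ndarray:
        """Terminal-node id for every record."""
        self._check_fitted()
        out = np.zeros(len(X), dtype=int)
        self._route(self.tree_, X, np.ones(len(X), dtype=bool), out)
        return out

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        ids = self.apply(X)
        e = X[self.exposure].to_numpy(dtype=float)
        by_id = {nd.id: nd for nd in self.terminal_nodes_}
        p1 = np.empty(len(X))
        for nid in np.unique(ids):
            nd = by_id[nid]
            m = ids == nid
            p1[m] = expit(nd.fit.beta0 + nd.fit.beta1 * e[m])
        return np.column_stack([1 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def _check_fitted(self):
        if not hasattr(self, "tree_"):
            raise RuntimeError("tree not fitted; call fit() first")

    # -- export ------------------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()

        def encode(node: MOBNode) -> dict:
            se = node.fit.se(robust=True)
            d = {
                "id": node.id,
                "depth": node.depth,
                "n": node.n,
                "weight_sum": node.fit.weight_sum,
                "beta0": node.fit.beta0,
                "beta1": node.fit.beta1,
                "se_robust": se.tolist(),
                "loglik": node.fit.loglik,
                "converged": node.fit.converged,
                "terminal": node.is_terminal,
                "stop_reason": node.stop_reason,
            }
            if node.split is not None:
                d["split"] = {
                    "variable": node.split.variable,
                    "kind": node.split.kind,
                    "threshold": node.split.threshold,
                    "left_levels": list(node.split.left_levels or []) or None,
                    "rule": node.split.describe(),
                }
                d["children"] = [encode(c) for c in node.children]
            return d

        return {"controls": vars(self._controls()), "root": encode(self.tree_)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def format_tree(self) -> str:
        self._check_fitted()
        lines: list[str] = []

        def walk(node: MOBNode, prefix: str, label: str):
            se1 = node.fit.se(robust=True)[1]
            lines.append(
                f"{prefix}{label}[{node.id}] n={node.n} "
                f"beta0={node.fit.beta0:+.3f} beta1={node.fit.beta1:+.3f} "
                f"OR={np.exp(node.fit.beta1):.3f} (robust se {se1:.3f})"
                + (f"  split: {node.split.describe()}" if node.split else "  <terminal>")
            )
            for i, c in enumerate(node.children):
                walk(c, prefix + "  ", "L " if i == 0 else "R ")

        walk(self.tree_, "", "")
        return "\n".join(lines)

    def membership_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-record terminal node id (CSV-exportable membership table)."""
        return pd.DataFrame({"record": np.arange(len(X)), "node": self.apply(X)})


def grow_tree(
    table, outcome, exposure, weights=None, moderators=None,
    controls: MOBControls | None = None, kinds: dict[str, str] | None = None,
) -> MOBLogisticTree:
    """Functional wrapper: grow a tree from a DataFrame / CohortTable."""
    controls = controls or MOBControls()
    df = table.df if hasattr(table, "df") else table
    if kinds is None and hasattr(table, "schema"):
        kinds = {c: m.kind for c, m in table.schema.items()}
    est = MOBLogisticTree(
        exposure=exposure, moderators=moderators, kinds=kinds,
        alpha=controls.alpha, minsize=controls.minsize, maxdepth=controls.maxdepth,
        bonferroni=controls.bonferroni, trim=controls.trim,
        max_nominal_levels=controls.max_nominal_levels, robust=controls.robust,
    )
    return est.fit(df, df[outcome].to_numpy(), sample_weight=weights)
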