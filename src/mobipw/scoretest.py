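"""Parameter-instability (M-fluctuation / structural-change) tests.

Given the per-record score contributions of a fitted node model, these tests
ask whether ordering the records by a candidate moderator produces systematic
drift in the cumulative score process — evidence that the model parameters
are not constant across that moderator.

* Ordered (numeric / ordinal / binary) moderators use the max-LM statistic:
  the maximum over candidate cut points of the squared, decorrelated
  cumulative score process normalized by t(1-t).  For moderators with many
  distinct values the supremum is taken over the trimmed interval
  [trim, 1 - trim] and compared against the continuum limit (the supremum of
  a normalized squared Brownian bridge); for few-valued moderators the
  statistic is evaluated only at the observed cut fractions and its p-value
  comes from the exact finite-dimensional bridge marginal.  A single cut
  point reduces to a chi-square(k) tail.
* Nominal moderators aggregate scores within levels; the statistic is
  asymptotically chi-square with (C - 1) * k degrees of freedom.

All simulated null distributions use fixed internal seeds and are cached per
(df, trim) or (df, cut fractions); p-values are therefore deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["InstabilityResult", "SingularScoreCovariance", "ordered_instability",
           "nominal_instability", "whiten_scores", "BridgeNull", "bridge_null"]

_CONT_GRID = 1000
_CONT_PATHS = 50_000
_DISC_PATHS = 40_000
MANY_CUTS = 40  # ordered moderators with more cut points use the continuum limit
_SEED_BASE = 0x5C04E


class SingularScoreCovariance(RuntimeError):
    """Score outer-product matrix is numerically singular in this node."""


@dataclass
class InstabilityResult:
    covariate: str
    statistic: float
    p_value: float
    kind: str            # "suplm" (continuum), "maxlm" (discrete cuts), "chisq"
    df: int              # model parameter count (chisq: total degrees of freedom)
    n_cutpoints: int
    trim: float | None = None
    p_adjusted: float | None = None


# ---------------------------------------------------------------------------
# simulated null distributions of the bridge functionals
# ---------------------------------------------------------------------------

class BridgeNull:
    """Cache of simulated null distributions for the bridge max statistics."""

    def __init__(self, cont_paths: int = _CONT_PATHS, disc_paths: int = _DISC_PATHS,
                 grid: int = _CONT_GRID):
        self.cont_paths = cont_paths
        self.disc_paths = disc_paths
        self.grid = grid
        self._cont: dict = {}
        self._disc: dict = {}

    # continuum supremum over [trim, 1 - trim] ------------------------------
    def _continuum_sups(self, df: int, trim: float) -> np.ndarray:
        key = (df, round(trim, 4))
        if key not in self._cont:
            rng = np.random.default_rng(
                np.random.SeedSequence([_SEED_BASE, 1, df, int(round(trim * 1e4))])
            )
            m = self.grid
            t = np.arange(1, m + 1) / m
            inner = (t >= trim) & (t <= 1.0 - trim) & (t < 1.0)
            denom = (t * (1.0 - t))[inner]
            sups = np.empty(self.cont_paths)
            chunk = 2000
            done = 0
            while done < self.cont_paths:
                c = min(chunk, self.cont_paths - done)
                z = rng.standard_normal((c, m, df)) / np.sqrt(m)
                w = np.cumsum(z, axis=1)
                b = w - t[None, :, None] * w[:, -1:, :]
                q = (b[:, inner, :] ** 2).sum(axis=2) / denom[None, :]
                sups[done:done + c] = q.max(axis=1)
                done += c
            self._cont[key] = np.sort(sups)
        return self._cont[key]

    def pvalue_continuum(self, stat: float, df: int, trim: float) -> float:
        sups = self._continuum_sups(df, trim)
        n = len(sups)
        exceed = n - np.searchsorted(sups, stat, side="left")
        return float((1 + exceed) / (n + 1))

    # max over a finite set of cut fractions --------------------------------
    def _discrete_sups(self, df: int, fractions: tuple[float, ...]) -> np.ndarray:
        key = (df, fractions)
        if key not in self._disc:
            t = np.asarray(fractions)
            m = len(t)
            cov = np.minimum.outer(t, t) - np.outer(t, t)
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(m))
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [_SEED_BASE, 2, df] + [int(round(f * 1e4)) for f in fractions]
                )
            )
            q = np.zeros((self.disc_paths, m))
            for _ in range(df):
                b = rng.standard_normal((self.disc_paths, m)) @ L.T
                q += b * b
            q /= (t * (1.0 - t))[None, :]
            self._disc[key] = np.sort(q.max(axis=1))
        return self._disc[key]

    def pvalue_discrete(self, stat: float, df: int, fractions: tuple[float, ...]) -> float:
        if len(fractions) == 1:
            # bridge at a single point: exact chi-square(df) tail
            return float(stats.chi2.sf(stat, df))
        sups = self._discrete_sups(df, fractions)
        n = len(sups)
        exceed = n - np.searchsorted(sups, stat, side="left")
        return float((1 + exceed) / (n + 1))


bridge_null = BridgeNull()  # module-level cache shared by all trees


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def whiten_scores(scores: np.ndarray) -> np.ndarray:
    """Decorrelate scores with the inverse root of their outer-product matrix.

    Raises :class:`SingularScoreCovariance` when the matrix is numerically
    singular (e.g., the exposure is nearly constant in the node).
    """
    n = len(scores)
    J = scores.T @ scores / n
    vals, vecs = np.linalg.eigh(J)
    if vals[0] <= 1e-12 * max(vals[-1], 1e-300):
        raise SingularScoreCovariance("singular score covariance")
    root_inv = (vecs / np.sqrt(vals)) @ vecs.T
    return scores @ root_inv


def ordered_instability(
    whitened: np.ndarray,
    z: np.ndarray,
    covariate: str,
    trim: float = 0.1,
    null: BridgeNull | None = None,
) -> InstabilityResult:
    """Max-LM test of parameter constancy against an ordered moderator."""
    null = null or bridge_null
    n, k = whitened.shape
    order = np.argsort(z, kind="stable")
    zs = np.asarray(z)[order]
    w = np.cumsum(whitened[order], axis=0) / np.sqrt(n)

    boundary = np.flatnonzero(zs[:-1] != zs[1:])  # cut after index i
    if len(boundary) == 0:
        raise ValueError(f"moderator {covariate!r} is constant in this node")
    t = (boundary + 1) / n
    q = (w[boundary] ** 2).sum(axis=1) / (t * (1.0 - t))

    if len(boundary) > MANY_CUTS:
        inner = (t >= trim) & (t <= 1.0 - trim)
        if inner.any():
            stat = float(q[inner].max())
            p = null.pvalue_continuum(stat, k, trim)
            return InstabilityResult(covariate, stat, p, "suplm", k,
                                     int(inner.sum()), trim)
        # every cut lies outside the trimmed window: fall through to the
        # discrete treatment of the (extreme) observed fractions
    stat_idx = int(np.argmax(q))
    stat = float(q[stat_idx])
    fractions = tuple(sorted({round(float(f), 3) for f in t if 0.0 < round(float(f), 3) < 1.0}))
    if not fractions:
        fractions = (round(float(t[0]), 6),)
    p = null.pvalue_discrete(stat, k, fractions)
    return InstabilityResult(covariate, stat, p, "maxlm", k, len(boundary), None)


def nominal_instability(
    whitened: np.ndarray, z: np.ndarray, covariate: str
) -> InstabilityResult:
    """Chi-square test of parameter constancy against an unordered moderator."""
    n, k = whitened.shape
    levels, codes = np.unique(np.asarray(z), return_inverse=True)
    C = len(levels)
    if C < 2:
        raise ValueError(f"moderator {covariate!r} is constant in this node")
    stat = 0.0
    for c in range(C):
        mask = codes == c
        u = whitened[mask].sum(axis=0) / np.sqrt(n)
        stat += float(u @ u) / (mask.sum() / n)
    df = (C - 1) * k
    p = float(stats.chi2.sf(stat, df))
    return InstabilityResult(covariate, float(stat), p, "chisq", df, C - 1, None)
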