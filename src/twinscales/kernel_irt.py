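"""Kernel-smoothed nonparametric item response theory.

Respondents are ranked by their scale sum score (seeded tie-breaking) and
assigned latent-trait values at standard-normal quantiles of their ranks.
Option characteristic curves and cumulative item-response step functions
(IRSF) P(X_j >= x | theta) are then estimated by Nadaraya-Watson kernel
regression of the category indicators on the assigned trait, with pointwise
binomial confidence bands computed from the kernel-effective sample size.
Maximum-likelihood latent scores are obtained by exhaustive search over the
evaluation grid, and item difficulty/discrimination coordinates come from a
principal component analysis of the expected-score curves.

No parametric (logistic) item model is fitted anywhere: curves are free in
shape, which is what lets monotonicity be *checked* rather than assumed.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: default evaluation grid: 51 equally spaced points on [-3, 3], so an
#: all-lowest respondent maps exactly to the boundary score of -3
DEFAULT_GRID = np.linspace(-3.0, 3.0, 51)

PROB_FLOOR = 1e-6  # floor under smoothed probabilities in ML scoring


def default_bandwidth(n: int) -> float:
    """Classic kernel-IRT default h = 1.1 * N^(-1/5)."""
    return 1.1 * n ** (-0.2)


def _item_cols(scale_items) -> list[str]:
    return [f"item_{j}" for j in scale_items]


def _tie_jitter(person_id, tie_seed: int) -> float:
    """Uniform jitter deterministic in (person_id, tie_seed), order-free."""
    ss = np.random.SeedSequence([tie_seed & 0x7FFFFFFF, zlib.crc32(str(person_id).encode())])
    return float(np.random.default_rng(ss).random())


def rank_theta(responses: pd.DataFrame, scale_items, tie_seed: int = 0) -> pd.Series:
    """Assign theta_i = Phi^-1((r_i - 0.5)/N) from sum-score ranks.

    Persons missing any scale item are excluded from the ranking.  Ties in
    the sum score are broken by a uniform jitter keyed on person_id, so the
    assignment is invariant to input row order.
    """
    cols = _item_cols(scale_items)
    sub = responses[["person_id"] + cols].dropna()
    if len(sub) < 1:
        raise ValueError("no complete respondents on this scale")
    sums = sub[cols].to_numpy(dtype=float).sum(axis=1)
    if len(sub) >= 2 and np.ptp(sums) == 0:
        logger.warning("all respondents have identical sum scores; ordering is pure tie-break")
    jitter = np.array([_tie_jitter(p, tie_seed) for p in sub["person_id"]])
    order = np.lexsort((jitter, sums))
    ranks = np.empty(len(sub), dtype=float)
    ranks[order] = np.arange(1, len(sub) + 1)
    theta = norm.ppf((ranks - 0.5) / len(sub))
    return pd.Series(theta, index=pd.Index(sub["person_id"], name="person_id"), name="theta")


@dataclass
class ItemCurveSet:
    """Kernel-smoothed curves for a set of items on a common grid.

    For item j: ``probs[j]`` is a (3, Q) matrix of option probabilities,
    ``steps[j]`` a (2, Q) matrix of the cumulative step functions
    S_x = P(X >= x) for x in {1, 2}, with 95% bands ``lo[j]``/``hi[j]``
    (same shape), kernel-effective sample sizes ``n_eff[j]`` (Q,), expected
    scores ``expected[j]`` (Q,), and raw category counts ``counts[j]`` (3,).
    """

    grid: np.ndarray
    bandwidth: float
    items: list = field(default_factory=list)
    probs: dict = field(default_factory=dict)
    steps: dict = field(default_factory=dict)
    lo: dict = field(default_factory=dict)
    hi: dict = field(default_factory=dict)
    n_eff: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    n_respondents: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format serialization (item, step, grid_point, estimate, lo, hi, n_eff)."""
        rows = []
        for j in self.items:
            for x in (1, 2):
                for q, g in enumerate(self.grid):
                    rows.append((j, x, g, self.steps[j][x - 1, q],
                                 self.lo[j][x - 1, q], self.hi[j][x - 1, q],
                                 self.n_eff[j][q]))
        return pd.DataFrame(rows, columns=["item", "step", "grid_point",
                                           "estimate", "lo", "hi", "n_eff"])


def fit_item_curves(responses: pd.DataFrame, theta: pd.Series, scale_items,
                    grid: np.ndarray = DEFAULT_GRID,
                    bandwidth: float | None = None) -> ItemCurveSet:
    """Nadaraya-Watson estimate of option curves and IRSF with 95% bands.

    Missing responses are excluded item-wise.  Bands use the kernel-weighted
    binomial approximation with effective n = (sum w)^2 / sum w^2, clipped
    to [0, 1].
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    merged = responses.merge(theta.rename("theta"), left_on="person_id", right_index=True)
    if bandwidth is None:
        bandwidth = default_bandwidth(len(merged))
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")

    cs = ItemCurveSet(grid=grid, bandwidth=float(bandwidth), items=list(scale_items),
                      n_respondents=len(merged))
    th_all = merged["theta"].to_numpy()
    for j in scale_items:
        col = merged[f"item_{j}"].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        th, x = th_all[ok], col[ok].astype(np.int64)
        # W[q, i]: Gaussian kernel weight of respondent i at grid point q
        W = np.exp(-0.5 * ((grid[:, None] - th[None, :]) / bandwidth) ** 2)
        wsum = W.sum(axis=1)
        if np.any(wsum <= 0):
            raise FloatingPointError("zero kernel mass at a grid point")
        ind = (x[None, :] == np.arange(3)[:, None]).astype(float)  # (3, n)
        probs = (W @ ind.T).T / wsum  # (3, Q)
        steps = np.vstack([probs[1] + probs[2], probs[2]])  # S1, S2
        n_eff = wsum ** 2 / (W ** 2).sum(axis=1)
        half = 1.96 * np.sqrt(np.clip(steps * (1 - steps), 0, None) / n_eff)
        cs.probs[j] = probs
        cs.steps[j] = steps
        cs.lo[j] = np.clip(steps - half, 0.0, 1.0)
        cs.hi[j] = np.clip(steps + half, 0.0, 1.0)
        cs.n_eff[j] = n_eff
        cs.expected[j] = probs[1] + 2.0 * probs[2]
        cs.counts[j] = np.array([(x == k).sum() for k in range(3)])
    return cs


def ml_score(responses: pd.DataFrame, curves: ItemCurveSet,
             scale_items=None) -> pd.Series:
    """Grid-search ML estimate of each respondent's latent trait.

    The log-likelihood at each grid point sums log option probabilities of
    the observed responses (floored at 1e-6); ties resolve to the lowest
    tied grid point; missing items contribute nothing; a person missing all
    scale items gets NaN (logged).
    """
    items = list(scale_items) if scale_items is not None else curves.items
    Q = len(curves.grid)
    n = len(responses)
    ll = np.zeros((n, Q))
    n_obs = np.zeros(n, dtype=int)
    for j in items:
        col = responses[f"item_{j}"].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        logp = np.log(np.maximum(curves.probs[j], PROB_FLOOR))  # (3, Q)
        ll[ok] += logp[col[ok].astype(np.int64)]
        n_obs += ok
    theta_hat = curves.grid[np.argmax(ll, axis=1)].astype(float)
    none = n_obs == 0
    if none.any():
        logger.warning("%d respondent(s) missing all scale items: score set to NaN", none.sum())
        theta_hat[none] = np.nan
    return pd.Series(theta_hat, index=pd.Index(responses["person_id"], name="person_id"),
                     name="irt_score")


def difficulty_discrimination(curves: ItemCurveSet, items=None) -> pd.DataFrame:
    """Item map from PCA of the expected-score curves.

    Rows of the decomposed matrix are items, columns the grid evaluations of
    the expected item score.  PC1 is oriented so higher = easier (positive
    correlation with the item's mean expected score); PC2 so higher = more
    discriminant (positive correlation with the total variation of the
    expected-score curve).
    """
    items = list(items) if items is not None else curves.items
    if len(items) < 3:
        raise ValueError("item map requires at least 3 items")
    E = np.vstack([curves.expected[j] for j in items])  # (items, Q)
    Ec = E - E.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Ec, full_matrices=False)
    scores = U * s  # item coordinates
    pc1, pc2 = scores[:, 0], scores[:, 1]
    easiness = E.mean(axis=1)
    spread = np.abs(np.diff(E, axis=1)).sum(axis=1)

    def _corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    # The leading component usually carries difficulty, but when the items
    # vary mostly in slope it carries discrimination instead: assign the
    # two semantic axes to whichever components they actually load on.
    if abs(_corr(pc1, easiness)) + abs(_corr(pc2, spread)) >= \
            abs(_corr(pc2, easiness)) + abs(_corr(pc1, spread)):
        diff_pc, disc_pc = pc1.copy(), pc2.copy()
    else:
        diff_pc, disc_pc = pc2.copy(), pc1.copy()
    if _corr(diff_pc, easiness) < 0:       # higher = easier
        diff_pc = -diff_pc
    if _corr(disc_pc, spread) < 0:         # higher = more discriminant
        disc_pc = -disc_pc
    return pd.DataFrame({"item": items, "difficulty_pc": diff_pc,
                         "discrimination_pc": disc_pc}).set_index("item")
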