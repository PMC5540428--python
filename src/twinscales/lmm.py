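"""Block-structured Gaussian mixed models with a pedigree covariance.

Twin-family relatedness matrices are block diagonal by family, with blocks
of at most a handful of individuals.  Everything here exploits that: the
model y = X b + u + e with u ~ N(0, sg^2 K), e ~ N(0, se^2 I) is fitted by
maximum likelihood over the variance ratio after rotating each family by
the eigenvectors of its relatedness block, which diagonalises the whole
covariance and reduces every likelihood evaluation to weighted least
squares.  The :class:`BlockDiag` helper stores per-family blocks grouped by
size so that downstream code (the penalized quasi-likelihood logistic
model) can run batched linear algebra over thousands of families at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

RIDGE = 1e-8  # jitter applied to singular relatedness blocks


@dataclass
class BlockDiag:
    """Families grouped by size, with positions into the original vector.

    ``groups`` maps block size k to (index array of shape (F_k, k), block
    array of shape (F_k, k, k)).
    """

    groups: dict
    n: int

    @classmethod
    def from_labels(cls, labels: np.ndarray, block_fn) -> "BlockDiag":
        """``block_fn(family_id, member_positions) -> (k, k) matrix``."""
        labels = np.asarray(labels)
        order: dict = {}
        for pos, lab in enumerate(labels):
            order.setdefault(lab, []).append(pos)
        by_size: dict = {}
        for lab, positions in order.items():
            k = len(positions)
            blk = np.asarray(block_fn(lab, positions), dtype=float)
            by_size.setdefault(k, ([], []))
            by_size[k][0].append(positions)
            by_size[k][1].append(blk)
        groups = {k: (np.asarray(idx, dtype=np.intp), np.asarray(blks))
                  for k, (idx, blks) in by_size.items()}
        return cls(groups=groups, n=len(labels))

    def full(self) -> np.ndarray:
        out = np.zeros((self.n, self.n))
        for idx, blks in self.groups.values():
            for pos, blk in zip(idx, blks):
                out[np.ix_(pos, pos)] = blk
        return out


def kinship_blockdiag(family_ids: np.ndarray, relatedness_of) -> BlockDiag:
    return BlockDiag.from_labels(family_ids, relatedness_of)


@dataclass
class MixedFit:
    beta: np.ndarray
    se: np.ndarray
    sg2: float
    se2: float
    loglik: float
    cov_beta: np.ndarray


def gaussian_mixed_gls(y: np.ndarray, X: np.ndarray, family_ids: np.ndarray,
                       relatedness_of) -> MixedFit:
    """ML fit of y = Xb + u + e with u ~ N(0, sg^2 K), K block diagonal.

    ``relatedness_of(family_id, member_positions)`` returns the family's
    relatedness block (entries 1 / 0.5 / 0 for twin-sibling structures).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    bd = BlockDiag.from_labels(np.asarray(family_ids), relatedness_of)

    # rotate each family into the eigenbasis of its relatedness block
    ys = np.empty(n)
    Xs = np.empty((n, p))
    d = np.empty(n)
    for k, (idx, blks) in bd.groups.items():
        w, U = np.linalg.eigh(blks)  # batched (F, k), (F, k, k)
        bad = w.min(axis=1) < -1e-6
        if bad.any():
            blks = blks + RIDGE * np.eye(k)
            w, U = np.linalg.eigh(blks)
        yf = y[idx]                                 # (F, k)
        Xf = X[idx]                                 # (F, k, p)
        yr = np.einsum("fij,fi->fj", U, yf)
        Xr = np.einsum("fij,fip->fjp", U, Xf)
        flat = idx.ravel()
        ys[flat] = yr.ravel()
        Xs[flat] = Xr.reshape(-1, p)
        d[flat] = np.clip(w, 0.0, None).ravel()

    def profile_neg_loglik(log_lam: float):
        lam = np.exp(log_lam)
        v = lam * d + 1.0
        w = 1.0 / v
        XtWX = Xs.T @ (Xs * w[:, None])
        XtWy = Xs.T @ (ys * w)
        beta = np.linalg.solve(XtWX, XtWy)
        r = ys - Xs @ beta
        se2 = float(r @ (r * w) / n)
        nll = 0.5 * (n * np.log(2 * np.pi * se2) + np.log(v).sum() + n)
        return nll, beta, se2, XtWX

    # ML over the variance ratio lam = sg2/se2 (log scale, 0 included)
    res = minimize_scalar(lambda t: profile_neg_loglik(t)[0],
                          bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    cand = [res.x, -30.0]  # also consider the sg2 -> 0 boundary
    best = min(cand, key=lambda t: profile_neg_loglik(t)[0])
    nll, beta, se2, XtWX = profile_neg_loglik(best)
    lam = np.exp(best)
    # unbiased residual-variance scaling for Wald inference (matches the
    # ordinary least-squares t-test when the relatedness is the identity)
    cov_beta = np.linalg.inv(XtWX) * se2 * n / (n - p)
    return MixedFit(beta=beta, se=np.sqrt(np.diag(cov_beta)),
                    sg2=lam * se2, se2=se2, loglik=-nll, cov_beta=cov_beta)
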