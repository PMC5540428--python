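"""Twin/sibling variance-component models by full-information ML.

The classic twin design: for a trait with additive-genetic (A), common
environment (C) or dominance (D), and unique environment (E) sources of
variance, family covariance blocks are

    Var       = A + C + E            (or A + D + E)
    Cov(MZ)   = A + C                (A + D)
    Cov(DZ or twin-sibling or sibling pair) = A/2 + C   (A/2 + D/4)

Families contribute the multivariate-normal density of whichever members
are observed (full-information ML), so singletons and incomplete trios are
used without imputation.  Fixed effects (sex, age, wave) enter the mean and
are profiled out by GLS at every likelihood evaluation.  Optimization is
over unbounded path coefficients (variances are their squares) with seeded
multi-starts; standardized proportions and profile-likelihood confidence
intervals are derived afterwards.

The bivariate model uses a Cholesky parameterization per component: 2x2
lower-triangular factors L_A, L_E (and L_C) give component covariance
matrices Sigma = L L', from which the genetic correlation
rG = Sigma_A[0,1] / sqrt(Sigma_A[0,0] Sigma_A[1,1]) and its environmental
counterpart follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

MODELS = ("ACE", "ADE", "AE", "CE", "E")

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# family assembly
# ---------------------------------------------------------------------------

def _rel_coeffs(zygosity: str, roles: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(R_additive, R_dominance) for one family's observed children."""
    k = len(roles)
    R = np.eye(k)
    Rd = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            twins = {roles[i], roles[j]} == {"twin1", "twin2"}
            if twins and zygosity == "MZ":
                R[i, j] = R[j, i] = 1.0
                Rd[i, j] = Rd[j, i] = 1.0
            else:
                R[i, j] = R[j, i] = 0.5
                Rd[i, j] = Rd[j, i] = 0.25
    return R, Rd


@dataclass
class FamilyGroups:
    """Families grouped by identical covariance pattern for batched FIML.

    Each group holds the shared structure matrices (R, Rd, J, I of size m,
    where m = members x traits) and stacked data: y of shape (F, m) and the
    fixed-effect design X of shape (F, m, p).
    """

    groups: list = field(default_factory=list)   # dicts: R, Rd, J, I, y, X
    n_obs: int = 0
    p: int = 1
    n_traits: int = 1


def build_families(scores: pd.DataFrame, pedigree: pd.DataFrame,
                   trait_cols=("score",), covariate_cols=()) -> FamilyGroups:
    """Assemble grouped family data from per-person scores and a pedigree.

    ``scores`` needs person_id plus the trait column(s); covariates are
    taken from the merged frame.  A person missing some but not all traits
    contributes the observed ones (FIML).
    """
    trait_cols = list(trait_cols)
    covariate_cols = list(covariate_cols)
    T = len(trait_cols)
    df = pedigree.merge(scores, on="person_id", how="inner")
    df = df[df[trait_cols].notna().any(axis=1)]

    p = 1 + len(covariate_cols)  # per-trait intercept + covariates
    buckets: dict = {}
    for _, fam in df.groupby("family_id", sort=False):
        roles = fam["role"].to_list()
        zyg = fam["zygosity"].iloc[0]
        R, Rd = _rel_coeffs(zyg, roles)
        k = len(roles)
        y_mat = fam[trait_cols].to_numpy(float)           # (k, T)
        mask = ~np.isnan(y_mat).ravel()                   # person-major stacking
        Rb = np.kron(R, np.ones((T, T)))
        Rdb = np.kron(Rd, np.ones((T, T)))
        Pb = np.kron(np.eye(k), np.ones((T, T)))          # person blocks (E structure)
        # trait-selector pattern: entry (i*T+t, j*T+s) multiplies Sigma[t, s]
        key = (k, R.tobytes(), mask.tobytes())
        y = y_mat.ravel()[mask]
        # design: block per person x trait; per-trait intercept + covariates
        X = np.zeros((k * T, T * p))
        for i in range(k):
            for t in range(T):
                row = i * T + t
                X[row, t * p] = 1.0
                for c, col in enumerate(covariate_cols):
                    X[row, t * p + 1 + c] = fam[col].to_numpy(float)[i]
        sel = np.flatnonzero(mask)
        buckets.setdefault(key, {"R": Rb[np.ix_(sel, sel)],
                                 "Rd": Rdb[np.ix_(sel, sel)],
                                 "P": Pb[np.ix_(sel, sel)],
                                 "mask": mask, "k": k, "ys": [], "Xs": []})
        buckets[key]["ys"].append(y)
        buckets[key]["Xs"].append(X[mask])

    fg = FamilyGroups(p=T * p, n_traits=T)
    for key, b in buckets.items():
        m = b["R"].shape[0]
        tsel = np.tile(np.arange(T), b["k"])[b["mask"]]
        fg.groups.append({
            "R": b["R"], "Rd": b["Rd"], "P": b["P"],
            "J": np.ones((m, m)),
            "tsel": tsel,
            "y": np.asarray(b["ys"]), "X": np.asarray(b["Xs"])})
        fg.n_obs += m * len(b["ys"])
    return fg


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _group_sigma(g: dict, SA, SD_or_C, SE, model: str, T: int) -> np.ndarray:
    """Family covariance from per-component (T, T) matrices."""
    tsel = g["tsel"]
    def expand(S):
        return np.asarray(S)[np.ix_(tsel, tsel)]
    dom = model == "ADE"
    Sigma = g["R"] * expand(SA) + g["P"] * expand(SE)
    if SD_or_C is not None:
        Sigma = Sigma + (g["Rd"] if dom else g["J"]) * expand(SD_or_C)
    return Sigma


def fiml_loglik(fg: FamilyGroups, SA, SC_or_D, SE, model: str = "ACE",
                beta: np.ndarray | None = None) -> float:
    """FIML log-likelihood; if beta is None it is profiled out by GLS."""
    T = fg.n_traits
    pieces = []
    for g in fg.groups:
        Sigma = _group_sigma(g, SA, SC_or_D, SE, model, T)
        w = np.linalg.eigvalsh(Sigma)
        if w.min() <= 1e-10:
            return -np.inf
        Sinv = np.linalg.inv(Sigma)
        sign, logdet = np.linalg.slogdet(Sigma)
        pieces.append((g, Sigma, Sinv, logdet))
    if beta is None:
        p = fg.p
        XtSX = np.zeros((p, p))
        XtSy = np.zeros(p)
        for g, Sigma, Sinv, _ in pieces:
            Xs = np.einsum("fip,ij->fjp", g["X"], Sinv)
            XtSX += np.einsum("fjp,fjq->pq", Xs, g["X"])
            XtSy += np.einsum("fjp,fj->p", Xs, g["y"])
        beta = np.linalg.solve(XtSX, XtSy)
    ll = 0.0
    for g, Sigma, Sinv, logdet in pieces:
        r = g["y"] - np.einsum("fip,p->fi", g["X"], beta)
        m = Sigma.shape[0]
        quad = np.einsum("fi,ij,fj->f", r, Sinv, r)
        ll += -0.5 * (m * _LOG2PI + logdet) * len(r) - 0.5 * quad.sum()
    return float(ll)


def _components_from_paths(paths: np.ndarray, model: str):
    """Univariate variances (vA, vC_or_D, vE) from unbounded path params."""
    if model in ("ACE", "ADE"):
        vA, vM, vE = paths[0] ** 2, paths[1] ** 2, paths[2] ** 2
    elif model == "AE":
        vA, vM, vE = paths[0] ** 2, None, paths[1] ** 2
    elif model == "CE":
        vA, vM, vE = 0.0, paths[0] ** 2, paths[1] ** 2
    elif model == "E":
        vA, vM, vE = 0.0, None, paths[0] ** 2
    else:
        raise ValueError(f"unknown model {model!r}")
    return vA, vM, vE


def _n_paths(model: str) -> int:
    return {"ACE": 3, "ADE": 3, "AE": 2, "CE": 2, "E": 1}[model]


@dataclass
class VarianceComponents:
    model: str
    a2: float
    c2_or_d2: float
    e2: float
    variances: tuple
    beta: np.ndarray
    minus2ll: float
    aic: float
    n_params: int
    ci_a2: tuple | None = None
    ci_e2: tuple | None = None
    converged: bool = True


def _uni_loglik(fg: FamilyGroups, paths, model: str) -> float:
    vA, vM, vE = _components_from_paths(np.asarray(paths, float), model)
    SA = np.array([[vA]])
    SM = None if vM is None else np.array([[vM]])
    SE = np.array([[vE]])
    return fiml_loglik(fg, SA, SM, SE, model)


def fit_univariate(scores: pd.DataFrame, pedigree: pd.DataFrame,
                   model: str = "AE", covariates=(), trait_col: str = "score",
                   n_starts: int = 5, seed: int = 0,
                   ci: bool = False) -> VarianceComponents:
    """Fit one trait's variance components by FIML with multi-starts."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    fg = build_families(scores, pedigree, trait_cols=(trait_col,),
                        covariate_cols=covariates)
    y_all = np.concatenate([g["y"].ravel() for g in fg.groups])
    v0 = y_all.var(ddof=1)
    npar = _n_paths(model)
    rng = np.random.default_rng(seed)

    def neg(paths):
        return -_uni_loglik(fg, paths, model)

    best = None
    for s in range(n_starts):
        shares = rng.dirichlet(np.ones(npar)) if s else np.full(npar, 1.0 / npar)
        x0 = np.sqrt(v0 * shares)
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("variance-component fit failed to converge from all starts")

    vA, vM, vE = _components_from_paths(best.x, model)
    vM_val = 0.0 if vM is None else vM
    tot = vA + vM_val + vE
    ll = -best.fun
    # free params: paths + fixed effects
    n_params = npar + fg.p
    vc = VarianceComponents(
        model=model, a2=vA / tot, c2_or_d2=vM_val / tot, e2=vE / tot,
        variances=(vA, vM_val, vE), beta=_gls_beta(fg, best.x, model),
        minus2ll=-2 * ll, aic=-2 * ll + 2 * n_params, n_params=n_params,
        converged=bool(best.success or best.fun < np.inf))
    if ci:
        vc.ci_a2 = _profile_ci_share(fg, model, vc, target="a2")
        vc.ci_e2 = _profile_ci_share(fg, model, vc, target="e2")
    return vc


def _gls_beta(fg: FamilyGroups, paths, model: str) -> np.ndarray:
    vA, vM, vE = _components_from_paths(np.asarray(paths, float), model)
    SA, SE = np.array([[vA]]), np.array([[vE]])
    SM = None if vM is None else np.array([[vM]])
    return _gls_beta_matrices(fg, SA, SM, SE, model)


def _gls_beta_matrices(fg: FamilyGroups, SA, SM, SE, model: str) -> np.ndarray:
    p = fg.p
    XtSX = np.zeros((p, p))
    XtSy = np.zeros(p)
    for g in fg.groups:
        Sigma = _group_sigma(g, SA, SM, SE, model, 1)
        Sinv = np.linalg.inv(Sigma)
        Xs = np.einsum("fip,ij->fjp", g["X"], Sinv)
        XtSX += np.einsum("fjp,fjq->pq", Xs, g["X"])
        XtSy += np.einsum("fjp,fj->p", Xs, g["y"])
    return np.linalg.solve(XtSX, XtSy)


def _profile_ci_share(fg: FamilyGroups, model: str, vc: VarianceComponents,
                      target: str = "a2", level: float = 0.95) -> tuple:
    """Profile-likelihood CI on a standardized proportion by bisection."""
    crit = stats.chi2.ppf(level, 1) / 2.0
    llmax = -vc.minus2ll / 2.0
    tot = sum(vc.variances)

    def ll_at(q):
        # fix the target share at q; profile total variance (and third share)
        def neg(x):
            V = np.exp(x[0])
            if model in ("ACE", "ADE"):
                s = 1 / (1 + np.exp(-x[1]))  # split of the remaining mass
                rest = 1 - q
                if target == "a2":
                    vA, vM, vE = q * V, rest * s * V, rest * (1 - s) * V
                else:
                    vE, vM, vA = q * V, rest * s * V, rest * (1 - s) * V
            else:  # AE / CE: two components
                if model == "AE":
                    vA, vM, vE = (q * V, None, (1 - q) * V) if target == "a2" \
                        else ((1 - q) * V, None, q * V)
                else:
                    vA, vM, vE = 0.0, (1 - q) * V, q * V
            SA = np.array([[vA]])
            SM = None if vM is None else np.array([[vM]])
            SE = np.array([[max(vE, 1e-12)]])
            return -fiml_loglik(fg, SA, SM, SE, model)

        x0 = [np.log(tot), 0.0] if model in ("ACE", "ADE") else [np.log(tot)]
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8})
        return -res.fun

    qhat = getattr(vc, target if target != "a2" else "a2") if target == "a2" else vc.e2

    def bound(lo, hi, increasing):
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if llmax - ll_at(mid) > crit:
                lo, hi = (mid, hi) if increasing else (lo, mid)
            else:
                lo, hi = (lo, mid) if increasing else (mid, hi)
        return 0.5 * (lo + hi)

    eps = 1e-6
    lo = bound(eps, qhat, increasing=True) if llmax - ll_at(eps) > crit else 0.0
    hi = bound(qhat, 1 - eps, increasing=False) if llmax - ll_at(1 - eps) > crit else 1.0
    return (float(lo), float(hi))


def compare_models(scores, pedigree, models=("ACE", "ADE", "AE", "CE", "E"),
                   covariates=(), trait_col="score", seed=0) -> pd.DataFrame:
    """AIC table plus LRTs of each nested submodel against its parent."""
    fits = {m: fit_univariate(scores, pedigree, m, covariates, trait_col, seed=seed)
            for m in models}
    rows = []
    parent_of = {"AE": "ACE", "CE": "ACE", "E": "AE"}
    for m, f in fits.items():
        row = {"model": m, "a2": f.a2, "c2_or_d2": f.c2_or_d2, "e2": f.e2,
               "minus2ll": f.minus2ll, "aic": f.aic}
        parent = parent_of.get(m)
        if parent in fits:
            lrt = f.minus2ll - fits[parent].minus2ll
            ddf = fits[parent].n_params - f.n_params
            row["lrt_vs_parent"] = lrt
            row["lrt_p"] = float(stats.chi2.sf(max(lrt, 0.0), ddf))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assumption tests (complete twin pairs)
# ---------------------------------------------------------------------------

def _complete_pairs(scores: pd.DataFrame, pedigree: pd.DataFrame,
                    trait_col: str = "score") -> dict:
    """Per-zygosity (n, 2) arrays of complete twin-pair scores."""
    df = pedigree.merge(scores, on="person_id")
    out = {}
    for zyg in ("MZ", "DZ"):
        z = df[(df["zygosity"] == zyg) & df["role"].isin(["twin1", "twin2"])]
        wide = z.pivot_table(index="family_id", columns="role", values=trait_col,
                             aggfunc="first")
        if {"twin1", "twin2"} <= set(wide.columns):
            pairs = wide[["twin1", "twin2"]].dropna().to_numpy()
            if len(pairs):
                out[zyg] = pairs
    return out


def twin_correlations(scores, pedigree, trait_col="score") -> dict:
    pairs = _complete_pairs(scores, pedigree, trait_col)
    return {zyg: float(np.corrcoef(x[:, 0], x[:, 1])[0, 1]) for zyg, x in pairs.items()}


def omnibus_homogeneity_test(scores: pd.DataFrame, pedigree: pd.DataFrame,
                             trait_col: str = "score") -> tuple[float, int, float]:
    """LRT of equal means and variances across zygosity x birth-order groups.

    Saturated model: per-zygosity bivariate normal with free means,
    variances and covariance (closed-form MLE).  Constrained model: one
    common mean and variance, per-zygosity correlation (fitted
    numerically).  Returns (statistic, df, p).
    """
    pairs = _complete_pairs(scores, pedigree, trait_col)
    if len(pairs) < 2:
        raise ValueError("need complete pairs in at least two zygosity groups")

    ll_sat = 0.0
    n_sat = 0
    for x in pairs.values():
        mu = x.mean(axis=0)
        S = np.cov(x, rowvar=False, ddof=0)
        ll_sat += np.sum(stats.multivariate_normal.logpdf(x, mu, S, allow_singular=True))
        n_sat += 5

    zygs = list(pairs)

    def neg(params):
        mu, log_sd = params[0], params[1]
        rs = np.tanh(params[2:])
        sd = np.exp(log_sd)
        ll = 0.0
        for r, zyg in zip(rs, zygs):
            x = pairs[zyg]
            S = sd ** 2 * np.array([[1.0, r], [r, 1.0]])
            ll += np.sum(stats.multivariate_normal.logpdf(x, [mu, mu], S))
        return -ll

    allx = np.concatenate([x.ravel() for x in pairs.values()])
    x0 = np.concatenate([[allx.mean(), np.log(allx.std())],
                         np.arctanh(np.clip([np.corrcoef(pairs[z].T)[0, 1] for z in zygs],
                                            -0.99, 0.99))])
    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    ll_con = -res.fun
    n_con = 2 + len(zygs)
    lrt = max(0.0, 2 * (ll_sat - ll_con))
    df = n_sat - n_con
    return float(lrt), int(df), float(stats.chi2.sf(lrt, df))


def sex_limitation_check(scores: pd.DataFrame, pedigree: pd.DataFrame,
                         trait_col: str = "score") -> dict:
    """LRT of sex-specific A/E paths using the five zygosity-by-sex groups.

    Free model: separate paths (a_F, e_F, a_M, e_M) with opposite-sex DZ
    covariance 0.5 a_F a_M; null: a, e shared.  Means are per-sex in both
    models.  Missing groups restrict the comparison (flagged).
    """
    df = pedigree.merge(scores, on="person_id")
    tw = df[df["role"].isin(["twin1", "twin2"])]
    wide = tw.pivot_table(index=["family_id", "zygosity"], columns="role",
                          values=trait_col, aggfunc="first").dropna().reset_index()
    sex = tw.pivot_table(index=["family_id"], columns="role", values="sex",
                         aggfunc="first")
    wide = wide.merge(sex, left_on="family_id", right_index=True,
                      suffixes=("", "_sex"))
    wide.columns = ["family_id", "zygosity", "y1", "y2", "s1", "s2"]

    def grp(zyg, s1, s2):
        sel = wide[(wide["zygosity"] == zyg)
                   & (wide["s1"] == s1) & (wide["s2"] == s2)]
        a = sel[["y1", "y2"]].to_numpy()
        if s1 == s2:
            return a
        sel2 = wide[(wide["zygosity"] == zyg)
                    & (wide["s1"] == s2) & (wide["s2"] == s1)]
        b = sel2[["y2", "y1"]].to_numpy()  # order females first
        return np.vstack([a, b])

    groups = {"MZF": grp("MZ", "F", "F"), "MZM": grp("MZ", "M", "M"),
              "DZF": grp("DZ", "F", "F"), "DZM": grp("DZ", "M", "M"),
              "DZOS": grp("DZ", "F", "M")}
    missing = [k for k, v in groups.items() if len(v) < 5]
    groups = {k: v for k, v in groups.items() if len(v) >= 5}

    def loglik(aF, eF, aM, eM, muF, muM):
        ll = 0.0
        for name, x in groups.items():
            if name == "DZOS":
                mu = [muF, muM]
                S = np.array([[aF ** 2 + eF ** 2, 0.5 * aF * aM],
                              [0.5 * aF * aM, aM ** 2 + eM ** 2]])
            else:
                female = name.endswith("F")
                a, e = (aF, eF) if female else (aM, eM)
                mu = [muF, muF] if female else [muM, muM]
                rho = 1.0 if name.startswith("MZ") else 0.5
                S = np.array([[a ** 2 + e ** 2, rho * a ** 2],
                              [rho * a ** 2, a ** 2 + e ** 2]])
            w = np.linalg.eigvalsh(S)
            if w.min() <= 1e-12:
                return -np.inf
            ll += np.sum(stats.multivariate_normal.logpdf(x, mu, S))
        return ll

    allx = np.concatenate([x.ravel() for x in groups.values()])
    sd0, mu0 = allx.std(), allx.mean()

    def fit(free, extra_starts=()):
        if free:
            def neg(p):
                return -loglik(p[0], p[1], p[2], p[3], p[4], p[5])
            starts = [[sd0 * r, sd0 * np.sqrt(max(1 - r ** 2, 0.1)),
                       sd0 * r, sd0 * np.sqrt(max(1 - r ** 2, 0.1)), mu0, mu0]
                      for r in (0.4, 0.65, 0.85)]
        else:
            def neg(p):
                return -loglik(p[0], p[1], p[0], p[1], p[2], p[3])
            starts = [[sd0 * r, sd0 * np.sqrt(max(1 - r ** 2, 0.1)), mu0, mu0]
                      for r in (0.4, 0.65, 0.85)]
        starts += [list(s) for s in extra_starts]
        best = None
        for x0 in starts:
            res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-7, "fatol": 1e-9,
                                             "maxiter": 6000})
            if best is None or res.fun < best.fun:
                best = res
        return -best.fun, best.x

    ll_null, xn = fit(False)
    # seed the free fit from the null solution as well
    ll_free, _ = fit(True, extra_starts=[[xn[0], xn[1], xn[0], xn[1], xn[2], xn[3]]])
    lrt = max(0.0, 2 * (ll_free - ll_null))
    return {"lrt": float(lrt), "df": 2, "p": float(stats.chi2.sf(lrt, 2)),
            "minus2ll_free": -2 * ll_free, "minus2ll_equal": -2 * ll_null,
            "missing_groups": missing}


# ---------------------------------------------------------------------------
# bivariate Cholesky
# ---------------------------------------------------------------------------

def _chol2(params3) -> np.ndarray:
    l11, l21, l22 = params3
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


def _corr_of(S: np.ndarray) -> float:
    den = np.sqrt(S[0, 0] * S[1, 1])
    return float(S[0, 1] / den) if den > 0 else 0.0


@dataclass
class BivariateFit:
    model: str
    a2: tuple
    c2_or_d2: tuple
    e2: tuple
    rG: float
    rC_or_rD: float
    rE: float
    r_phenotypic: float
    sigma_a: np.ndarray
    sigma_e: np.ndarray
    sigma_c: np.ndarray | None
    beta: np.ndarray
    minus2ll: float
    aic: float
    p_rg_zero: float | None = None
    p_rg_one: float | None = None
    p_re_one: float | None = None


def _biv_neg_loglik(fg: FamilyGroups, x: np.ndarray, model: str,
                    constraint: str | None) -> float:
    xa = list(x[:3])
    rest = list(x[3:])
    if constraint == "rg_one":
        xa = [x[0], x[1], 0.0]
        rest = list(x[2:])
    elif constraint == "rg_zero":
        xa = [x[0], 0.0, x[1]]
        rest = list(x[2:])
    SA = _chol2(xa)
    if model in ("ACE", "ADE"):
        SM = _chol2(rest[:3])
        xe = rest[3:]
    else:
        SM = None
        xe = rest
    if constraint == "re_one":
        SE = _chol2([xe[0], xe[1], 0.0])
    else:
        SE = _chol2(xe[:3])
    ll = fiml_loglik(fg, SA, SM, SE, model)
    return -ll if np.isfinite(ll) else 1e12


def fit_bivariate(scores: pd.DataFrame, pedigree: pd.DataFrame,
                  model: str = "AE", covariates=(),
                  trait_cols=("score_0", "score_1"), n_starts: int = 3,
                  seed: int = 0, lrt: bool = False) -> BivariateFit:
    """Bivariate Cholesky FIML fit; rG/rE (and rC/rD) from component factors."""
    fg = build_families(scores, pedigree, trait_cols=trait_cols,
                        covariate_cols=covariates)
    ys = np.concatenate([g["y"].ravel() for g in fg.groups])
    sd0 = np.std(ys)
    rng = np.random.default_rng(seed)

    def n_free(constraint):
        base = 3 + (3 if model in ("ACE", "ADE") else 0) + 3
        return base - (1 if constraint else 0)

    def fit_once(constraint=None):
        best = None
        for s in range(n_starts):
            scl = sd0 * (0.6 if s == 0 else rng.uniform(0.3, 0.9))
            if constraint in ("rg_one", "rg_zero"):
                xa0 = [scl, 0.1 * scl]
            else:
                xa0 = [scl, 0.1 * scl, scl]
            xm0 = [scl * 0.5, 0.0, scl * 0.5] if model in ("ACE", "ADE") else []
            xe0 = [scl, 0.1 * scl] if constraint == "re_one" else [scl, 0.1 * scl, scl]
            x0 = np.array(xa0 + xm0 + xe0)
            res = optimize.minimize(lambda x: _biv_neg_loglik(fg, x, model, constraint),
                                    x0, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-8,
                                             "maxiter": 8000, "maxfev": 12000})
            if best is None or res.fun < best.fun:
                best = res
        return best

    best = fit_once(None)
    x = best.x
    SA = _chol2(x[:3])
    if model in ("ACE", "ADE"):
        SM = _chol2(x[3:6])
        SE = _chol2(x[6:9])
    else:
        SM, SE = None, _chol2(x[3:6])
    SMv = SM if SM is not None else np.zeros((2, 2))
    tot = np.diag(SA) + np.diag(SMv) + np.diag(SE)
    a2 = tuple(np.diag(SA) / tot)
    m2 = tuple(np.diag(SMv) / tot)
    e2 = tuple(np.diag(SE) / tot)
    cross = SA[0, 1] + SMv[0, 1] + SE[0, 1]
    r_phen = float(cross / np.sqrt(tot[0] * tot[1]))
    ll = -best.fun
    beta_hat = _gls_beta_matrices(fg, SA, SM, SE, model)
    n_params = n_free(None) + fg.p
    fit = BivariateFit(model=model, a2=a2, c2_or_d2=m2, e2=e2,
                       rG=_corr_of(SA), rC_or_rD=_corr_of(SMv) if SM is not None else 0.0,
                       rE=_corr_of(SE), r_phenotypic=r_phen,
                       sigma_a=SA, sigma_e=SE, sigma_c=SM,
                       beta=beta_hat, minus2ll=-2 * ll,
                       aic=-2 * ll + 2 * n_params)
    if lrt:
        for name, attr in (("rg_zero", "p_rg_zero"), ("rg_one", "p_rg_one"),
                           ("re_one", "p_re_one")):
            sub = fit_once(name)
            stat = max(0.0, 2 * (ll - (-sub.fun)))
            setattr(fit, attr, float(stats.chi2.sf(stat, 1)))
    return fit
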