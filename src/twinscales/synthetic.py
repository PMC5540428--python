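"""Synthetic twin-family cohort generator.

Emulates the data structure of an adolescent twin registry administered a
polytomous symptom questionnaire: MZ/DZ twin pairs with an optional third
sibling and singleton participants, two correlated latent traits
(anxiety-depression and chronic fatigue) with an ACE variance structure,
graded-response items scored 0/1/2 (including deliberately pathological
items), short-interval retest administrations, and later binary diagnoses
linked to the latent traits through a kinship-structured logistic model.

The generator draws additive-genetic (A), common-environment (C) and unique
environment (E) component scores per person so that MZ co-twins share A
exactly, DZ co-twins and twin-sibling pairs share A with expected
correlation 0.5, and C is identical within a family.  Cross-trait
correlations of the component scores (rG, rC, rE) are imposed at the level
of each independent standard-normal draw, so the implied genetic/environment
correlations between the two traits equal the configured values exactly in
expectation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class ItemSpec:
    """Generating parameters of one graded-response item (categories 0/1/2).

    The two cumulative step functions are logistic with a common
    discrimination ``a`` and ordered thresholds ``b1 < b2``, scaled by an
    upper asymptote ``d`` in (0, 1] (d < 1 yields a low-endorsement item
    whose curve never reaches 1).  ``dif_shift`` adds a group-specific shift
    to both thresholds (item bias).  ``dip`` subtracts a Gaussian bump
    (center, width, depth) from the first step function, producing a
    controlled violation of monotonicity; curves are clipped afterwards so
    that P(X>=1) >= P(X>=2) always holds.
    """

    item_id: int
    a: float = 1.5
    b1: float = 0.5
    b2: float = 1.7
    d: float = 1.0
    trait: int = 0
    dif_shift: dict[str, float] | None = None
    dip: tuple[float, float, float] | None = None  # (center, width, depth)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ConfigurationError(f"item {self.item_id}: discrimination must be > 0")
        if not self.b1 < self.b2:
            raise ConfigurationError(f"item {self.item_id}: thresholds must satisfy b1 < b2")
        if not 0 < self.d <= 1:
            raise ConfigurationError(f"item {self.item_id}: asymptote d must be in (0, 1]")

    def step_functions(self, theta: np.ndarray, group: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Analytic cumulative curves S1(theta)=P(X>=1), S2(theta)=P(X>=2)."""
        theta = np.asarray(theta, dtype=float)
        shift = np.zeros_like(theta)
        if self.dif_shift and group is not None:
            group = np.asarray(group)
            for g, s in self.dif_shift.items():
                shift = np.where(group == g, s, shift)
        s1 = self.d * expit(self.a * (theta - (self.b1 + shift)))
        s2 = self.d * expit(self.a * (theta - (self.b2 + shift)))
        if self.dip is not None:
            m, w, depth = self.dip
            s1 = s1 - depth * np.exp(-0.5 * ((theta - m) / w) ** 2)
        s1 = np.clip(s1, 0.0, 1.0)
        s2 = np.minimum(np.clip(s2, 0.0, 1.0), s1)
        return s1, s2


def default_item_bank() -> list[ItemSpec]:
    """Well-behaved 24-item bank: 14 items on trait 0, 10 on trait 1.

    Item ids follow the packaged 21-item questionnaire definition (the three
    shared items are generated twice under their own id only once; here each
    id appears once and scale definitions decide membership).  Thresholds
    span [0.2, 2.4] with discriminations 1.2-2.2 so that, with standard
    normal latent traits, roughly a fifth of respondents endorse nothing on
    a 14-item scale — the zero-score share observed in community samples of
    this kind.
    """
    ad_ids = [2, 3, 5, 9, 11, 12, 20, 23, 26, 27, 28, 30, 32, 33]
    cf_ids = [7, 15, 17, 22, 25, 29, 31]  # 3, 30, 32 shared with trait 0
    bank: list[ItemSpec] = []
    rng = np.random.default_rng(20170501)  # fixed: the bank is a constant, not a sample
    for k, iid in enumerate(ad_ids):
        b1 = 0.2 + 2.0 * k / (len(ad_ids) - 1)
        bank.append(ItemSpec(item_id=iid, a=float(1.2 + rng.uniform(0, 1.0)),
                             b1=round(b1, 3), b2=round(b1 + 1.2, 3), trait=0))
    for k, iid in enumerate(cf_ids):
        b1 = 0.3 + 1.9 * k / (len(cf_ids) - 1)
        bank.append(ItemSpec(item_id=iid, a=float(1.2 + rng.uniform(0, 1.0)),
                             b1=round(b1, 3), b2=round(b1 + 1.2, 3), trait=1))
    return bank


def screening_item_bank() -> dict[str, list[ItemSpec]]:
    """Item bank exercising the screening protocol: 9 clean anchor items,
    6 pathological items (3 low-endorsement with ceilings 0.25-0.4, 3
    non-monotone with a broad decline after their peak) and 2 clean,
    discriminant candidate items for admission.

    Pathology magnitudes are gross on purpose: rank-based latent scoring
    plus kernel smoothing attenuates narrow response-curve features, so only
    violations a reviewer would see on a plot are represented.
    """
    clean = [ItemSpec(item_id=i, a=2.2, b1=-1.1 + 0.25 * i, b2=0.1 + 0.25 * i)
             for i in range(1, 10)]
    pathological = [
        ItemSpec(item_id=114, a=1.5, b1=0.5, b2=4.5, d=0.3),
        ItemSpec(item_id=124, a=1.5, b1=1.0, b2=5.0, d=0.25),
        ItemSpec(item_id=113, a=1.8, b1=2.6, b2=4.2, d=0.4),
        ItemSpec(item_id=106, a=2.8, b1=-1.0, b2=0.5, dip=(2.2, 1.2, 0.6)),
        ItemSpec(item_id=110, a=3.0, b1=-1.2, b2=0.3, dip=(2.4, 1.3, 0.65)),
        ItemSpec(item_id=116, a=2.8, b1=-0.8, b2=0.7, dip=(2.0, 1.1, 0.55)),
    ]
    candidates = [ItemSpec(item_id=15, a=2.2, b1=-0.2, b2=1.0),
                  ItemSpec(item_id=22, a=2.0, b1=0.6, b2=1.8)]
    return {"clean": clean, "pathological": pathological, "candidates": candidates}


@dataclass(frozen=True)
class TraitParams:
    """Standardized variance proportions of one trait (must sum to 1)."""

    a2: float
    c2: float
    e2: float

    def __post_init__(self) -> None:
        for v in (self.a2, self.c2, self.e2):
            if v < 0 or v > 1:
                raise ConfigurationError("variance proportions must lie in [0, 1]")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-12:
            raise ConfigurationError("a2 + c2 + e2 must equal 1 (tolerance 1e-12)")


@dataclass(frozen=True)
class DiagnosisParams:
    """Generating model of one binary outcome: logit p = b0 + slope*theta + u."""

    intercept: float = logit(0.16)
    slope: float = float(np.log(1.39))
    polygenic_var: float = 0.3
    trait: int = 0

    def __post_init__(self) -> None:
        if self.polygenic_var < 0:
            raise ConfigurationError("polygenic variance must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    n_mz_pairs: int = 226
    n_dz_pairs: int = 408
    p_extra_sib: float = 84 / 634
    n_singletons: int = 28
    trait_params: tuple[TraitParams, TraitParams] = (
        TraitParams(0.41, 0.0, 0.59),
        TraitParams(0.42, 0.0, 0.58),
    )
    rG: float = 0.87
    rC: float = 0.0
    rE: float = 0.44
    item_bank: tuple[ItemSpec, ...] = field(default_factory=lambda: tuple(default_item_bank()))
    sex_effect: tuple[float, float] = (0.0, 0.0)   # additive shift for females
    age_effect: tuple[float, float] = (0.0, 0.0)   # per year of age, centred
    age_mean: float = 12.0
    age_sd: float = 0.4
    retest_reliability: float = 0.47
    diagnosis_params: tuple[DiagnosisParams, ...] = (DiagnosisParams(),)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_extra_sib, self.retest_reliability, self.missing_rate):
            if not 0 <= p <= 1:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        for r in (self.rG, self.rC, self.rE):
            if not -1 <= r <= 1:
                raise ConfigurationError("component correlations must lie in [-1, 1]")

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        d = {
            "n_mz_pairs": self.n_mz_pairs, "n_dz_pairs": self.n_dz_pairs,
            "p_extra_sib": self.p_extra_sib, "n_singletons": self.n_singletons,
            "trait_params": [vars(t) for t in self.trait_params],
            "rG": self.rG, "rC": self.rC, "rE": self.rE,
            "sex_effect": list(self.sex_effect), "age_effect": list(self.age_effect),
            "age_mean": self.age_mean, "age_sd": self.age_sd,
            "retest_reliability": self.retest_reliability,
            "missing_rate": self.missing_rate, "seed": self.seed,
            "item_bank": [
                {"item_id": s.item_id, "a": s.a, "b1": s.b1, "b2": s.b2, "d": s.d,
                 "trait": s.trait, "dif_shift": s.dif_shift, "dip": list(s.dip) if s.dip else None}
                for s in self.item_bank
            ],
            "diagnosis_params": [vars(p) for p in self.diagnosis_params],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(plain(d), fh)


@dataclass
class CohortTruth:
    """Generating-model ground truth retained for recovery experiments."""

    theta: pd.DataFrame          # person_id, trait_0, trait_1 (first administration)
    components: pd.DataFrame     # person_id, A_0, C_0, E_0, A_1, C_1, E_1
    family: pd.DataFrame         # person_id, family_id, zygosity, role
    liabilities: pd.DataFrame | None = None


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent, label-addressable random substream of a global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


def _corr_pair(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """n draws of a standard bivariate normal with correlation rho, shape (n, 2)."""
    z = rng.standard_normal((n, 2))
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    out[:, 1] = rho * z[:, 0] + np.sqrt(max(0.0, 1 - rho ** 2)) * z[:, 1]
    return out


def build_pedigree(config: SimConfig) -> pd.DataFrame:
    """Family structure table: one row per person."""
    rng = _substream(config.seed, "pedigree")
    rows = []
    fam = 0
    for zyg, npairs in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        for _ in range(npairs):
            fam += 1
            if zyg == "MZ":
                sexes = [("F", "M")[rng.integers(2)]] * 2
            else:
                sexes = [("F", "M")[rng.integers(2)] for _ in range(2)]
            age = float(rng.normal(config.age_mean, config.age_sd))
            rows.append((fam, f"P{fam:05d}_1", zyg, "twin1", sexes[0], age))
            rows.append((fam, f"P{fam:05d}_2", zyg, "twin2", sexes[1], age))
            if rng.random() < config.p_extra_sib:
                rows.append((fam, f"P{fam:05d}_3", zyg, "sib",
                             ("F", "M")[rng.integers(2)],
                             age + float(rng.normal(2.0, 1.0))))
    for _ in range(config.n_singletons):
        fam += 1
        rows.append((fam, f"P{fam:05d}_1", "none", "singleton",
                     ("F", "M")[rng.integers(2)],
                     float(rng.normal(config.age_mean, config.age_sd))))
    return pd.DataFrame(rows, columns=["family_id", "person_id", "zygosity", "role", "sex", "age"])


def _draw_components(pedigree: pd.DataFrame, config: SimConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """A/C/E standard-normal component scores for both traits per person.

    A is built from a family-level and a person-level part in equal halves
    so that any two non-MZ children correlate 0.5 while MZ co-twins (who
    share the person-level part) correlate 1.  C is one family-level draw.
    Cross-trait correlation is imposed on every independent draw.
    """
    n = len(pedigree)
    fam_ids, fam_idx = np.unique(pedigree["family_id"].to_numpy(), return_inverse=True)
    nfam = len(fam_ids)

    a_fam = _corr_pair(rng, nfam, config.rG)
    c_fam = _corr_pair(rng, nfam, config.rC)
    a_pers = _corr_pair(rng, n, config.rG)
    e_pers = _corr_pair(rng, n, config.rE)

    # MZ twin2 reuses twin1's person-level A draw
    is_mz = (pedigree["zygosity"] == "MZ").to_numpy()
    role = pedigree["role"].to_numpy()
    pos = {(f, r): i for i, (f, r) in enumerate(zip(pedigree["family_id"], role))}
    for i in np.flatnonzero(is_mz & (role == "twin2")):
        a_pers[i] = a_pers[pos[(pedigree["family_id"].iat[i], "twin1")]]

    A = np.sqrt(0.5) * a_fam[fam_idx] + np.sqrt(0.5) * a_pers
    C = c_fam[fam_idx]
    E = e_pers
    out = pd.DataFrame({"person_id": pedigree["person_id"]})
    for t in (0, 1):
        out[f"A_{t}"] = A[:, t]
        out[f"C_{t}"] = C[:, t]
        out[f"E_{t}"] = E[:, t]
    return out


def _compose_theta(pedigree: pd.DataFrame, comps: pd.DataFrame,
                   config: SimConfig) -> pd.DataFrame:
    theta = pd.DataFrame({"person_id": pedigree["person_id"]})
    female = (pedigree["sex"] == "F").to_numpy(float)
    age_c = pedigree["age"].to_numpy() - config.age_mean
    for t, tp in enumerate(config.trait_params):
        raw = (np.sqrt(tp.a2) * comps[f"A_{t}"].to_numpy()
               + np.sqrt(tp.c2) * comps[f"C_{t}"].to_numpy()
               + np.sqrt(tp.e2) * comps[f"E_{t}"].to_numpy())
        theta[f"trait_{t}"] = raw + config.sex_effect[t] * female + config.age_effect[t] * age_c
    return theta


def simulate_items(theta: np.ndarray, item_bank, group_labels=None,
                   rng: np.random.Generator | None = None,
                   warn=None) -> pd.DataFrame:
    """Draw 0/1/2 responses from each item's (possibly pathological) curves.

    ``theta`` may be a vector (single trait for all items) or an (n, T)
    matrix indexed by each item's ``trait`` attribute.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    if rng is None:
        rng = np.random.default_rng(0)
    multi = theta.ndim == 2
    out = {}
    for spec in item_bank:
        th = theta[:, spec.trait] if multi else theta
        if spec.dif_shift and group_labels is None:
            raise ValueError(f"item {spec.item_id} has a dif_shift but no group labels given")
        s1, s2 = spec.step_functions(th, group_labels)
        u = rng.random(th.shape[0])
        out[f"item_{spec.item_id}"] = ((u < s1).astype(np.int64) + (u < s2).astype(np.int64))
    return pd.DataFrame(out)


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate (responses, pedigree, truth) for one administration wave."""
    pedigree = build_pedigree(config)
    comp_rng = _substream(config.seed, "components")
    comps = _draw_components(pedigree, config, comp_rng)
    theta = _compose_theta(pedigree, comps, config)

    item_rng = _substream(config.seed, "items")
    th = theta[["trait_0", "trait_1"]].to_numpy()
    items = simulate_items(th, config.item_bank, pedigree["sex"].to_numpy(), item_rng)

    responses = pd.concat(
        [pedigree[["person_id", "family_id", "zygosity", "role", "sex", "age"]]
         .assign(wave=1).reset_index(drop=True),
         items.reset_index(drop=True)], axis=1)
    if config.missing_rate > 0:
        mask_rng = _substream(config.seed, "missing")
        item_cols = [c for c in responses.columns if c.startswith("item_")]
        mask = mask_rng.random((len(responses), len(item_cols))) < config.missing_rate
        vals = responses[item_cols].to_numpy(dtype=float)
        vals[mask] = np.nan
        responses[item_cols] = vals

    truth = CohortTruth(theta=theta,
                        components=comps,
                        family=pedigree[["person_id", "family_id", "zygosity", "role"]].copy())
    return responses, pedigree, truth


def simulate_retest(truth: CohortTruth, config: SimConfig,
                    pedigree: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Second administration: theta' = rho*theta + sqrt(1-rho^2)*noise.

    Returns (responses at wave 2, second-administration theta table).
    """
    rho = config.retest_reliability
    rng = _substream(config.seed, "retest")
    th1 = truth.theta[["trait_0", "trait_1"]].to_numpy()
    noise = rng.standard_normal(th1.shape)
    th2 = rho * th1 + np.sqrt(max(0.0, 1 - rho ** 2)) * noise
    item_rng = _substream(config.seed, "retest_items")
    if pedigree is None:
        pedigree = truth.family.assign(sex="F", age=config.age_mean)
    items = simulate_items(th2, config.item_bank, pedigree["sex"].to_numpy(), item_rng)
    resp = pd.concat(
        [pedigree[["person_id", "family_id", "zygosity", "role", "sex", "age"]]
         .assign(wave=2).reset_index(drop=True),
         items.reset_index(drop=True)], axis=1)
    theta2 = pd.DataFrame({"person_id": truth.theta["person_id"],
                           "trait_0": th2[:, 0], "trait_1": th2[:, 1]})
    return resp, theta2


def simulate_diagnoses(truth: CohortTruth, relatedness: np.ndarray,
                       params=None, seed: int = 0,
                       age_at_interview: np.ndarray | None = None) -> pd.DataFrame:
    """Binary diagnoses from logit p = b0 + slope*theta + u, u ~ N(0, s2*K).

    ``relatedness`` must be ordered like ``truth.theta`` rows and PSD.
    """
    if params is None:
        params = (DiagnosisParams(),)
    if isinstance(params, DiagnosisParams):
        params = (params,)
    rng = _substream(seed, "diagnoses")
    K = np.asarray(relatedness, dtype=float)
    n = len(truth.theta)
    if K.shape != (n, n):
        raise ValueError("relatedness matrix does not match the cohort size")
    out = pd.DataFrame({"person_id": truth.theta["person_id"]})
    liab = {}
    # K is block diagonal by family: factor it family-wise, never densely
    fam = truth.family["family_id"].to_numpy()
    factors = []  # (positions, L) per family
    for pos in pd.Series(range(n)).groupby(fam, sort=False).indices.values():
        pos = np.asarray(pos)
        Kf = K[np.ix_(pos, pos)]
        w, V = np.linalg.eigh(Kf)
        if w.min() < -1e-8:
            raise ConfigurationError("relatedness matrix is not PSD")
        factors.append((pos, V * np.sqrt(np.clip(w, 0.0, None))))
    for k, p in enumerate(params):
        th = truth.theta[f"trait_{p.trait}"].to_numpy()
        z = rng.standard_normal(n)
        u = np.empty(n)
        for pos, L in factors:
            u[pos] = L @ z[pos]
        u *= np.sqrt(p.polygenic_var)
        eta = p.intercept + p.slope * th + u
        y = (rng.random(n) < expit(eta)).astype(np.int64)
        out[f"dx_{k}"] = y
        liab[f"dx_{k}"] = eta
    out["age_at_interview"] = (age_at_interview if age_at_interview is not None
                               else 22.0 + rng.normal(0, 2.0, n))
    truth.liabilities = pd.DataFrame({"person_id": truth.theta["person_id"], **liab})
    return out


def write_cohort(outdir, responses: pd.DataFrame, pedigree: pd.DataFrame,
                 truth: CohortTruth, diagnoses: pd.DataFrame | None = None,
                 config: SimConfig | None = None) -> None:
    """Serialize a simulated cohort as plain CSV (plus YAML config)."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    responses.to_csv(outdir / "responses.csv", index=False)
    pedigree.to_csv(outdir / "pedigree.csv", index=False)
    truth.theta.merge(truth.components, on="person_id").to_csv(outdir / "truth.csv", index=False)
    if diagnoses is not None:
        diagnoses.to_csv(outdir / "diagnoses.csv", index=False)
    if config is not None:
        config.to_yaml(outdir / "config.yaml")


def make_config(**kwargs) -> SimConfig:
    """Convenience constructor accepting plain tuples for trait params."""
    tp = kwargs.get("trait_params")
    if tp is not None and not isinstance(tp[0], TraitParams):
        kwargs["trait_params"] = tuple(TraitParams(*t) for t in tp)
    return SimConfig(**kwargs)
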