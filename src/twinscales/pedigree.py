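"""Pedigree handling for twin-sibling-singleton family structures.

Covers construction of the expected additive-genetic relatedness matrix
(1 on the diagonal and for MZ co-twins, 0.5 for DZ co-twins, twin-sibling
and sibling-sibling pairs, 0 across families), demographically matched
familial pruning to one individual per family, cross-wave observation
selection, half-open age binning, and restriction of family size to one
twin pair plus at most one extra sibling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .lmm import BlockDiag

logger = logging.getLogger(__name__)

AGE_BIN_EDGES = [9.0, 13.0, 15.0, 17.0, 28.0]  # [9,13), [13,15), [15,17), [17,28]
AGE_BIN_LABELS = ["9-12", "13-14", "15-16", "17-28"]


def pairwise_relatedness(zygosity: str, role_i: str, role_j: str) -> float:
    """Expected additive relatedness of two children of one family."""
    if role_i == role_j:
        return 1.0
    twins = {"twin1", "twin2"}
    if {role_i, role_j} == twins:
        return 1.0 if zygosity == "MZ" else 0.5
    return 0.5  # twin-sibling or sibling-sibling


def family_block(pedigree_family: pd.DataFrame) -> np.ndarray:
    roles = pedigree_family["role"].to_list()
    zyg = pedigree_family["zygosity"].iloc[0]
    k = len(roles)
    K = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            K[i, j] = K[j, i] = pairwise_relatedness(zyg, roles[i], roles[j])
    return K


def relatedness_matrix(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Dense persons x persons expected-relatedness matrix (block diagonal)."""
    if pedigree["person_id"].duplicated().any():
        raise ValueError("duplicate person_id in pedigree")
    ids = pedigree["person_id"].to_list()
    K = np.zeros((len(ids), len(ids)))
    for _, fam in pedigree.groupby("family_id", sort=False):
        pos = fam.index.map(lambda i: pedigree.index.get_loc(i)).to_numpy()
        K[np.ix_(pos, pos)] = family_block(fam)
    return pd.DataFrame(K, index=ids, columns=ids)


def relatedness_block_fn(data: pd.DataFrame, pedigree: pd.DataFrame):
    """Exact block function for arbitrary person subsets of ``data`` rows."""
    role_of = dict(zip(pedigree["person_id"], pedigree["role"]))
    zyg_of = dict(zip(pedigree["person_id"], pedigree["zygosity"]))
    persons = data["person_id"].to_numpy()

    def block(fam_id, positions):
        pids = persons[list(positions)]
        roles = [role_of[p] for p in pids]
        zyg = zyg_of[pids[0]]
        k = len(pids)
        K = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                if pids[i] == pids[j]:
                    K[i, j] = K[j, i] = 1.0
                else:
                    K[i, j] = K[j, i] = pairwise_relatedness(zyg, roles[i], roles[j])
        return K

    return block


def _pruning_objective(subset: pd.DataFrame, full: pd.DataFrame) -> float:
    """Unweighted sum of standardized demographic deviations from the full sample."""
    sd = full["age"].std(ddof=1)
    d_mean = abs(subset["age"].mean() - full["age"].mean()) / (sd if sd > 0 else 1.0)
    var_full = full["age"].var(ddof=1)
    var_ratio = subset["age"].var(ddof=1) / var_full if var_full > 0 else 1.0
    d_var = abs(var_ratio - 1.0)
    d_sex = abs((subset["sex"] == "F").mean() - (full["sex"] == "F").mean())
    return float(d_mean + d_var + d_sex)


def prune_unrelated(responses: pd.DataFrame, n_iter: int = 1000,
                    seed: int = 0) -> pd.DataFrame:
    """Select one person per family, demographically matched to the full sample.

    Among ``n_iter`` seeded random draws, returns the draw minimizing the
    sum of standardized deviations in age mean, age variance and female
    fraction relative to the full sample.
    """
    rng = np.random.default_rng(seed)
    fams = responses.groupby("family_id", sort=False).indices
    fam_positions = [np.asarray(v) for v in fams.values()]
    best, best_obj = None, np.inf
    for _ in range(n_iter):
        pick = np.array([pos[rng.integers(len(pos))] for pos in fam_positions])
        subset = responses.iloc[pick]
        obj = _pruning_objective(subset, responses)
        if obj < best_obj:
            best, best_obj = pick, obj
    out = responses.iloc[np.sort(best)].reset_index(drop=True)
    out.attrs["pruning_objective"] = best_obj
    return out


def cross_wave_select(responses: pd.DataFrame, n_iter: int = 100,
                      seed: int = 0) -> pd.DataFrame:
    """One observation per family across two waves, balancing wave sizes.

    Participants observed in both waves are preferentially assigned to the
    smaller wave; ``n_iter`` seeded draws are audited and the one with the
    most similar wave sizes (then best demographic match) is kept.
    """
    waves = sorted(responses["wave"].unique())
    if len(waves) != 2:
        raise ValueError("cross-wave selection expects exactly two waves")
    rng = np.random.default_rng(seed)
    wave_sizes = responses["wave"].value_counts()
    small = wave_sizes.idxmin()
    best, best_key = None, None
    fams = list(responses.groupby("family_id", sort=False))
    for _ in range(n_iter):
        picks = []
        n_by_wave = {w: 0 for w in waves}
        for _, grp in fams:
            # choose one person, then one wave for that person
            person = rng.choice(grp["person_id"].unique())
            obs = grp[grp["person_id"] == person]
            if obs["wave"].nunique() == 2:
                # prefer the currently smaller wave (ties -> globally smaller)
                w = min(waves, key=lambda w: (n_by_wave[w], w != small))
                row = obs[obs["wave"] == w].index[0]
            else:
                row = obs.index[rng.integers(len(obs))]
            picks.append(row)
            n_by_wave[responses.loc[row, "wave"]] += 1
        imbalance = abs(n_by_wave[waves[0]] - n_by_wave[waves[1]])
        key = (imbalance, _pruning_objective(responses.loc[picks], responses))
        if best_key is None or key < best_key:
            best, best_key = picks, key
    return responses.loc[best].sort_index().reset_index(drop=True)


def assign_age_bins(responses: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Half-open age bins with one observation per person per bin.

    Bins are [9,13), [13,15), [15,17), [17,28]; observations outside [9,28]
    are dropped with a warning; duplicate observations of a person within a
    bin are resolved by a seeded random choice.
    """
    rng = np.random.default_rng(seed)
    age = responses["age"].to_numpy(float)
    out = responses.copy()
    labels = np.full(len(out), "", dtype=object)
    for lo, hi, lab in zip(AGE_BIN_EDGES[:-1], AGE_BIN_EDGES[1:], AGE_BIN_LABELS):
        closed_right = hi == AGE_BIN_EDGES[-1]
        sel = (age >= lo) & ((age <= hi) if closed_right else (age < hi))
        labels[sel] = lab
    dropped = (labels == "").sum()
    if dropped:
        logger.warning("%d observation(s) outside the 9-28 age range dropped", dropped)
    out["age_bin"] = labels
    out = out[out["age_bin"] != ""].copy()
    keep_rows = []
    for (_, _), grp in out.groupby(["person_id", "age_bin"], sort=False):
        keep_rows.append(grp.index[rng.integers(len(grp))] if len(grp) > 1 else grp.index[0])
    return out.loc[sorted(keep_rows)].reset_index(drop=True)


def restrict_family_size(pedigree: pd.DataFrame, max_children: int = 3,
                         seed: int = 0) -> pd.DataFrame:
    """Keep the twin pair plus at most one seeded-random extra sibling."""
    rng = np.random.default_rng(seed)
    keep = []
    for _, fam in pedigree.groupby("family_id", sort=False):
        twins = fam[fam["role"].isin(["twin1", "twin2"])]
        sibs = fam[fam["role"] == "sib"]
        others = fam[~fam.index.isin(twins.index) & ~fam.index.isin(sibs.index)]
        chosen = list(twins.index)
        budget = max_children - len(chosen)
        if len(sibs) and budget > 0:
            extra = rng.choice(sibs.index.to_numpy(),
                               size=min(budget, len(sibs)), replace=False)
            chosen.extend(np.atleast_1d(extra).tolist())
        chosen.extend(others.index.tolist())
        keep.extend(chosen[:max(max_children, len(twins))])
    return pedigree.loc[sorted(keep)].reset_index(drop=True)
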