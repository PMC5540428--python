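"""Item screening and scale assembly.

Implements the two-stage screening protocol used to reduce a 34-item
symptom questionnaire to its validated 21-item form:

1. *Refinement* — fit kernel item curves, exclude (in batches, then refit)
   items whose step functions are non-monotone in the central 95% of the
   latent distribution, items with low endorsement (upper confidence band
   never approaching 1), and items with an empty response category; then
   admit candidate items that, added singly, are unflagged and sufficiently
   discriminant.  Flags raised only from poorly fitting co-items disappear
   after the first batch of exclusions, which is why exclusion is
   batch-then-refit rather than one-at-a-time.
2. *DIF screening* — remove items with substantive, significant differential
   functioning between sexes or administration waves (see
   :mod:`twinscales.dif`).

The packaged 21-item definition (14-item anxiety-depression, 10-item
chronic fatigue, 3 shared items) ships as :func:`sphere21_definition`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import dif as dif_mod
from .kernel_irt import DEFAULT_GRID, ItemCurveSet, difficulty_discrimination, fit_item_curves, rank_theta

logger = logging.getLogger(__name__)

MONO_DELTA = 0.05          # tolerated step-function decrease
CENTRAL_RANGE = (-1.96, 1.96)  # central 95% of the latent density
ENDORSE_BAND = 0.95        # the upper band of S1 must reach this somewhere
ENDORSE_MIN_NEFF = 30.0    # grid points with less kernel mass are uninformative
MIN_SCALE_SIZE = 6         # stochastic ordering by the sum score needs > 5 items


@dataclass
class ItemFlag:
    item_id: int
    flags: set = field(default_factory=set)
    evidence: dict = field(default_factory=dict)

    def __bool__(self) -> bool:
        return bool(self.flags)


@dataclass
class ScaleDefinition:
    """Named ordered set of item ids with per-item screening provenance."""

    name: str
    items: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError("scale items must be unique")
        for j in self.items:
            self.provenance.setdefault(j, "original")

    @property
    def active(self) -> list:
        return [j for j in self.items if not str(self.provenance.get(j, "")).startswith("excluded")]

    def exclude(self, item, reason: str) -> None:
        self.provenance[item] = f"excluded:{reason}"

    def add(self, item, reason: str = "added") -> None:
        if item not in self.items:
            self.items.append(item)
        self.provenance[item] = reason

    def to_json(self) -> dict:
        return {"items": list(self.items),
                "provenance": {str(k): v for k, v in self.provenance.items()}}


def check_monotonicity(curves: ItemCurveSet, item) -> ItemFlag:
    """Flag a decrease > 0.05 sustained over >= 2 consecutive grid points
    within the central 95% of the latent density; decreases confined to the
    tails are recorded as evidence but not flagged."""
    flag = ItemFlag(item)
    grid = curves.grid
    central = (grid >= CENTRAL_RANGE[0]) & (grid <= CENTRAL_RANGE[1])
    for x in (0, 1):
        s = curves.steps[item][x]
        drop = np.maximum.accumulate(s) - s  # drop below the running maximum
        viol = drop > MONO_DELTA
        # sustained run of >= 2 consecutive violating points
        run = viol & np.roll(viol, 1)
        run[0] = False
        if np.any(run & central):
            flag.flags.add("non_monotone")
            where = grid[run & central]
            flag.evidence[f"step{x + 1}_dip"] = {
                "grid": [float(where.min()), float(where.max())],
                "max_drop": float(drop[run & central].max())}
        elif np.any(run):
            flag.evidence[f"step{x + 1}_tail_dip"] = {
                "grid": [float(g) for g in grid[run][:2]],
                "max_drop": float(drop[run].max()),
                "note": "outside central 95%, not flagged"}
    return flag


def check_endorsement(curves: ItemCurveSet, item) -> ItemFlag:
    """Flag items rarely endorsed even at high latent trait, or with an
    entirely unused response category.

    An item is low-endorsement when the upper 95% band of its first step
    function never reaches 0.95 anywhere the kernel fit is informative
    (effective n of at least 10; the extreme grid points carry so little
    kernel mass that their bands always touch 1 and say nothing).
    """
    flag = ItemFlag(item)
    informative = curves.n_eff[item] >= ENDORSE_MIN_NEFF
    if not informative.any():
        informative = np.ones_like(informative, dtype=bool)
    band_max = float(curves.hi[item][0, informative].max())
    if band_max < ENDORSE_BAND:
        flag.flags.add("low_endorsement")
        flag.evidence["s1_upper_band_max"] = band_max
    counts = curves.counts[item]
    empty = [int(k) for k in range(3) if counts[k] == 0]
    if empty:
        flag.flags.add("empty_category")
        flag.evidence["empty_categories"] = empty
    return flag


def screen_items(curves: ItemCurveSet, items=None) -> dict:
    items = list(items) if items is not None else curves.items
    out = {}
    for j in items:
        f = check_monotonicity(curves, j)
        g = check_endorsement(curves, j)
        f.flags |= g.flags
        f.evidence.update(g.evidence)
        out[j] = f
    return out


@dataclass
class RefinementReport:
    iterations: list = field(default_factory=list)
    admitted: dict = field(default_factory=dict)
    rejected_candidates: dict = field(default_factory=dict)


def refine_scale(responses, initial_scale: ScaleDefinition, candidate_items=(),
                 grid=DEFAULT_GRID, tie_seed: int = 0,
                 admission_quantile: float = 0.25) -> tuple[ScaleDefinition, RefinementReport]:
    """Iterative exclusion of flagged items, then single-item candidate admission.

    Candidates (disjoint from the initial scale) are admitted when, added
    singly to the refined scale, they raise no flag and their discrimination
    coordinate exceeds the scale's lower ``admission_quantile``.
    """
    cand = [c for c in candidate_items]
    if set(cand) & set(initial_scale.items):
        raise ValueError("candidate items must be disjoint from the initial scale")
    scale = ScaleDefinition(initial_scale.name, list(initial_scale.items),
                            dict(initial_scale.provenance))
    report = RefinementReport()

    while True:
        active = scale.active
        if len(active) < MIN_SCALE_SIZE:
            raise RuntimeError(
                f"scale {scale.name!r} shrank to {len(active)} items; "
                f"sum-score ordering needs at least {MIN_SCALE_SIZE}")
        theta = rank_theta(responses, active, tie_seed=tie_seed)
        curves = fit_item_curves(responses, theta, active, grid=grid)
        flags = screen_items(curves)
        flagged = {j: f for j, f in flags.items() if f}
        report.iterations.append(
            {"active": list(active),
             "flagged": {j: sorted(f.flags) for j, f in flagged.items()},
             "evidence": {j: f.evidence for j, f in flagged.items()}})
        if not flagged:
            break
        for j, f in flagged.items():
            scale.exclude(j, "+".join(sorted(f.flags)))

    # candidate admission against the refined scale
    active = scale.active
    theta = rank_theta(responses, active, tie_seed=tie_seed)
    base_curves = fit_item_curves(responses, theta, active, grid=grid)
    base_map = difficulty_discrimination(base_curves)
    disc_cut = float(base_map["discrimination_pc"].quantile(admission_quantile))
    for c in cand:
        trial_items = active + [c]
        theta_c = rank_theta(responses, trial_items, tie_seed=tie_seed)
        curves_c = fit_item_curves(responses, theta_c, trial_items, grid=grid)
        flag = screen_items(curves_c, [c])[c]
        item_map = difficulty_discrimination(curves_c)
        disc = float(item_map.loc[c, "discrimination_pc"])
        if not flag and disc > disc_cut:
            scale.add(c, "added")
            report.admitted[c] = {"discrimination_pc": disc, "cutoff": disc_cut}
            active = scale.active
        else:
            report.rejected_candidates[c] = {
                "flags": sorted(flag.flags), "discrimination_pc": disc, "cutoff": disc_cut}
    return scale, report


def dif_screen(responses, scale: ScaleDefinition, group_columns=("sex",),
               benchmark: dict | None = None, grid=DEFAULT_GRID,
               tie_seed: int = 0) -> ScaleDefinition:
    """Remove items with substantive, significant DIF for any grouping.

    For a grouping with more than two levels (e.g. administration wave),
    each level is compared against a benchmark level (largest group unless
    given in ``benchmark``).
    """
    out = ScaleDefinition(scale.name, list(scale.items), dict(scale.provenance))
    for col in group_columns:
        levels = sorted(responses[col].dropna().unique())
        if len(levels) < 2:
            logger.warning("grouping %r has a single level; skipped", col)
            continue
        if len(levels) == 2:
            pairs = [(levels[0], levels[1])]
        else:
            bench = (benchmark or {}).get(col, responses[col].value_counts().idxmax())
            pairs = [(g, bench) for g in levels if g != bench]
        for g, b in pairs:
            sub = responses[responses[col].isin([g, b])]
            active = out.active
            results, _ = dif_mod.compare_groups(sub, active, col, grid=grid, tie_seed=tie_seed)
            for r in results:
                if r.excluded:
                    out.exclude(r.item_id, f"high_dif:{col}:{g}_vs_{b}:dif={r.item_dif:.2f}")
    return out


# ---------------------------------------------------------------------------
# Packaged 21-item questionnaire definition
# ---------------------------------------------------------------------------

#: 14-item anxiety-depression scale (ids on the 34-item questionnaire)
ANXIETY_DEPRESSION_ITEMS = [2, 3, 5, 9, 11, 12, 20, 23, 26, 27, 28, 30, 32, 33]
#: 10-item chronic fatigue scale; items 15 and 22 were admitted during
#: screening, items 1, 6, 10, 13, 14, 16 and 24 of the somatic/fatigue pool
#: were excluded (item bias, non-monotonicity or low endorsement)
CHRONIC_FATIGUE_ITEMS = [3, 7, 15, 17, 22, 25, 29, 30, 31, 32]


def sphere21_definition() -> tuple[ScaleDefinition, ScaleDefinition]:
    """The validated 21-item questionnaire: (anxiety-depression, chronic fatigue)."""
    ad = ScaleDefinition("anxiety_depression", list(ANXIETY_DEPRESSION_ITEMS))
    cf = ScaleDefinition("chronic_fatigue", list(CHRONIC_FATIGUE_ITEMS),
                         {15: "added", 22: "added"})
    return ad, cf


def write_scales_json(path, *scales: ScaleDefinition) -> None:
    with open(path, "w") as fh:
        json.dump({s.name: s.to_json() for s in scales}, fh, indent=2)


def read_scales_json(path) -> dict[str, ScaleDefinition]:
    with open(path) as fh:
        raw = json.load(fh)
    return {name: ScaleDefinition(name, d["items"],
                                  {int(k): v for k, v in d.get("provenance", {}).items()})
            for name, d in raw.items()}
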