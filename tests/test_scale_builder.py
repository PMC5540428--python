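"""Screening protocol: monotonicity/endorsement flags, iterative refinement
with candidate admission, DIF screening, and the packaged 21-item fixture."""

import numpy as np
import pandas as pd
import pytest

import twinscales as ts
from twinscales.kernel_irt import DEFAULT_GRID, ItemCurveSet, fit_item_curves, rank_theta
from twinscales.scale_builder import (
    ScaleDefinition,
    check_endorsement,
    check_monotonicity,
    refine_scale,
    sphere21_definition,
)


def _analytic_curves(spec, n_eff=500.0):
    cs = ItemCurveSet(grid=DEFAULT_GRID, bandwidth=0.2, items=[spec.item_id])
    s1, s2 = spec.step_functions(DEFAULT_GRID)
    cs.steps[spec.item_id] = np.vstack([s1, s2])
    half = 1.96 * np.sqrt(np.clip(cs.steps[spec.item_id] * (1 - cs.steps[spec.item_id]), 0, None) / n_eff)
    cs.lo[spec.item_id] = np.clip(cs.steps[spec.item_id] - half, 0, 1)
    cs.hi[spec.item_id] = np.clip(cs.steps[spec.item_id] + half, 0, 1)
    cs.n_eff[spec.item_id] = np.full(len(DEFAULT_GRID), n_eff)
    cs.counts[spec.item_id] = np.array([100, 100, 100])
    return cs


class TestMonotonicityCheck:
    def test_logistic_curves_not_flagged(self):
        spec = ts.ItemSpec(item_id=1, a=2.0, b1=-0.5, b2=0.7)
        assert not check_monotonicity(_analytic_curves(spec), 1)

    def test_central_dip_flagged_with_evidence(self):
        bank = ts.screening_item_bank()
        dip_item = bank["pathological"][3]  # broad post-peak decline
        cfg = ts.make_config(n_mz_pairs=0, n_dz_pairs=0, n_singletons=2000,
                             item_bank=bank["clean"] + [dip_item], seed=51)
        resp, _, _ = ts.simulate_cohort(cfg)
        items = [s.item_id for s in bank["clean"]] + [dip_item.item_id]
        th = rank_theta(resp, items)
        curves = fit_item_curves(resp, th, items)
        flag = check_monotonicity(curves, dip_item.item_id)
        assert "non_monotone" in flag.flags
        assert any(k.endswith("_dip") for k in flag.evidence)

    def test_decrease_confined_to_top_tail_not_flagged(self):
        # decline centered at theta = 2.3 (top 2.5% of the latent density)
        spec = ts.ItemSpec(item_id=1, a=2.5, b1=-1.5, b2=0.0, dip=(2.55, 0.2, 0.4))
        flag = check_monotonicity(_analytic_curves(spec), 1)
        assert "non_monotone" not in flag.flags
        assert any("tail" in k for k in flag.evidence)  # reported, not flagged


class TestEndorsementCheck:
    def test_low_asymptote_item_flagged(self, unrelated_cohort_2000):
        bank, _, _, _ = unrelated_cohort_2000
        low = ts.ItemSpec(item_id=99, a=1.5, b1=0.5, b2=4.5, d=0.4)
        cfg = ts.make_config(n_mz_pairs=0, n_dz_pairs=0, n_singletons=2000,
                             item_bank=bank + [low], seed=52)
        resp, _, _ = ts.simulate_cohort(cfg)
        items = [s.item_id for s in bank] + [99]
        th = rank_theta(resp, items)
        curves = fit_item_curves(resp, th, items)
        assert "low_endorsement" in check_endorsement(curves, 99).flags

    def test_full_range_item_not_flagged(self, unrelated_cohort_2000):
        bank, resp, _, _ = unrelated_cohort_2000
        items = [s.item_id for s in bank]
        th = rank_theta(resp, items)
        curves = fit_item_curves(resp, th, items)
        assert not check_endorsement(curves, items[2]).flags

    def test_unused_category_flagged(self):
        df = pd.DataFrame({"person_id": [f"p{i}" for i in range(60)],
                           "item_1": np.tile([0, 1, 2], 20),
                           "item_2": np.tile([0, 1, 1], 20)})
        th = rank_theta(df, [1])
        curves = fit_item_curves(df, th, [1, 2])
        assert "empty_category" in check_endorsement(curves, 2).flags


@pytest.fixture(scope="module")
def screening_cohort():
    bank = ts.screening_item_bank()
    specs = bank["clean"] + bank["pathological"] + bank["candidates"]
    cfg = ts.make_config(n_mz_pairs=0, n_dz_pairs=0, n_singletons=1200,
                         item_bank=specs, seed=7000)
    resp, _, _ = ts.simulate_cohort(cfg)
    return bank, resp


class TestRefineScale:
    def test_fifteen_start_six_excluded_two_added(self, screening_cohort):
        bank, resp = screening_cohort
        init = ScaleDefinition("cf", [s.item_id for s in bank["clean"] + bank["pathological"]])
        refined, report = refine_scale(resp, init,
                                       candidate_items=[s.item_id for s in bank["candidates"]])
        assert len(refined.active) == 15 - 6 + 2
        assert set(refined.active) == {s.item_id for s in bank["clean"] + bank["candidates"]}
        for s in bank["pathological"]:
            assert str(refined.provenance[s.item_id]).startswith("excluded:")
        # every exclusion carries evidence in the iteration log
        flagged_anywhere = set()
        for it in report.iterations:
            assert set(it["flagged"]) == set(it["evidence"])
            flagged_anywhere |= set(it["flagged"])
        assert {s.item_id for s in bank["pathological"]} <= flagged_anywhere

    def test_clean_scale_unchanged_and_idempotent(self, screening_cohort):
        bank, resp = screening_cohort
        init = ScaleDefinition("clean", [s.item_id for s in bank["clean"]])
        refined, _ = refine_scale(resp, init)
        assert refined.active == init.items
        again, _ = refine_scale(resp, refined)
        assert again.active == refined.active

    def test_deterministic_given_inputs(self, screening_cohort):
        bank, resp = screening_cohort
        init = ScaleDefinition("cf", [s.item_id for s in bank["clean"] + bank["pathological"]])
        r1, rep1 = refine_scale(resp, init, candidate_items=[15, 22])
        r2, rep2 = refine_scale(resp, init, candidate_items=[15, 22])
        assert r1.active == r2.active
        assert rep1.iterations == rep2.iterations

    def test_overlapping_candidates_rejected(self, screening_cohort):
        bank, resp = screening_cohort
        init = ScaleDefinition("x", [s.item_id for s in bank["clean"]])
        with pytest.raises(ValueError):
            refine_scale(resp, init, candidate_items=[bank["clean"][0].item_id])

    def test_shrinking_below_six_items_aborts(self):
        bank = ts.screening_item_bank()
        # five items whose top category is never reachable: all flagged in
        # one batch, leaving fewer than six active items
        dead = [ts.ItemSpec(item_id=200 + i, a=1.5, b1=0.0, b2=12.0) for i in range(5)]
        specs = bank["clean"][:3] + dead
        cfg = ts.make_config(n_mz_pairs=0, n_dz_pairs=0, n_singletons=1200,
                             item_bank=specs, seed=53)
        resp, _, _ = ts.simulate_cohort(cfg)
        init = ScaleDefinition("tiny", [s.item_id for s in specs])
        with pytest.raises(RuntimeError):
            refine_scale(resp, init)


def test_replicated_screening_is_reliable():
    """Pathological items excluded and clean items retained in >= 18 of 20
    replicate cohorts (n = 1200)."""
    bank = ts.screening_item_bank()
    specs = bank["clean"] + bank["pathological"]
    clean_ids = {s.item_id for s in bank["clean"]}
    path_ids = {s.item_id for s in bank["pathological"]}
    n_path_ok = n_clean_ok = 0
    for seed in range(20):
        cfg = ts.make_config(n_mz_pairs=0, n_dz_pairs=0, n_singletons=1200,
                             item_bank=specs, seed=7000 + seed)
        resp, _, _ = ts.simulate_cohort(cfg)
        refined, _ = refine_scale(resp, ScaleDefinition("s", [s.item_id for s in specs]))
        active = set(refined.active)
        n_path_ok += not (path_ids & active)
        n_clean_ok += clean_ids <= active
    assert n_path_ok >= 18
    assert n_clean_ok >= 18


class TestDifScreen:
    def test_injected_sex_dif_item_removed(self):
        bank = [ts.ItemSpec(item_id=i, a=1.5, b1=0.2 + 0.1 * i, b2=1.4 + 0.1 * i)
                for i in range(1, 9)]
        bank.append(ts.ItemSpec(item_id=9, a=1.5, b1=0.5, b2=1.7, dif_shift={"F": 1.0}))
        cfg = ts.make_config(n_mz_pairs=0, n_dz_pairs=0, n_singletons=2000,
                             item_bank=bank, seed=54)
        resp, _, _ = ts.simulate_cohort(cfg)
        scale = ScaleDefinition("s", list(range(1, 10)))
        out = ts.dif_screen(resp, scale, group_columns=("sex",))
        assert 9 not in out.active
        assert set(out.active) == set(range(1, 9))
        assert str(out.provenance[9]).startswith("excluded:high_dif:sex")

    def test_single_level_grouping_is_noop(self, unrelated_cohort_2000):
        bank, resp, _, _ = unrelated_cohort_2000
        resp = resp.copy()
        resp["sex"] = "F"
        scale = ScaleDefinition("s", [s.item_id for s in bank])
        out = ts.dif_screen(resp, scale, group_columns=("sex",))
        assert out.active == scale.items


class TestSphere21Fixture:
    def test_union_has_21_items(self):
        ad, cf = sphere21_definition()
        assert len(set(ad.items) | set(cf.items)) == 21
        assert len(ad.items) == 14 and len(cf.items) == 10

    def test_three_shared_items(self):
        ad, cf = sphere21_definition()
        assert set(ad.items) & set(cf.items) == {3, 30, 32}

    def test_fatigue_scale_composition(self):
        _, cf = sphere21_definition()
        assert {15, 22} <= set(cf.items)
        assert not {1, 14, 24, 6, 10, 16, 13} & set(cf.items)
        assert cf.provenance[15] == "added" and cf.provenance[22] == "added"
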