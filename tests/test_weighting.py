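import numpy as np
import pandas as pd
import pytest

from svikit import (
    IndicatorTable,
    align_direction,
    apply_weights,
    availability_profile,
    build_weights,
    classify_tier,
    handle_missing,
    zscore_normalize,
)
from svikit.errors import ConsistencyError, TierRoutingError
from svikit.hierarchy import VULNERABILITY_REDUCING
from svikit.simulate import SimulationSpec, degrade, generate

from ._oracle import naive_svi
from .conftest import make_random_fixture


def _profile(cfg, scenario="tier1_full", targets=(), seed=5, n=40):
    table, _, _ = generate(SimulationSpec(hierarchy=cfg, n_areas=n, seed=seed))
    if scenario != "tier1_full":
        table = degrade(table, scenario, targets, cfg)
    return availability_profile(cfg, table), table


class TestClassifyTier:
    def test_cork_is_tier_1(self, cork):
        prof, _ = _profile(cork)
        assert classify_tier(prof).tier == 1

    def test_logrono_is_tier_2(self, logrono):
        prof, _ = _profile(logrono)
        t = classify_tier(prof)
        assert t.tier == 2
        assert any("health" in r for r in t.reasons)

    def test_milan_is_tier_3_with_caveats(self, milan):
        prof, _ = _profile(milan)
        t = classify_tier(prof)
        assert t.tier == 3
        assert t.robustness_caveats

    def test_missing_dimension_is_tier_4_with_caveats(self, cork):
        prof, _ = _profile(cork, "tier4_drop_dimension", ("enhanced_exposure",))
        t = classify_tier(prof)
        assert t.tier == 4
        assert t.robustness_caveats

    def test_precedence_is_non_decreasing_under_nested_degradation(self, cork):
        """Remove ever more of a tier-2 situation until a dimension empties:
        the reported tier walks 2 → 3 → 4 without skipping backwards."""
        table, _, _ = generate(SimulationSpec(hierarchy=cork, n_areas=40, seed=5))
        # deplete health (drop a required indicator) → tier 2
        t2 = degrade(table, "tier2_deplete", ("poor_health",), cork)
        # additionally strip enhanced_exposure to a single domain → tier 3
        t3 = degrade(t2, "tier3_single_domain_dimension", ("enhanced_exposure",), cork)
        # finally drop the dimension entirely → tier 4
        t4 = degrade(t3, "tier4_drop_dimension", ("enhanced_exposure",), cork)
        tiers = [
            classify_tier(availability_profile(cork, t)).tier
            for t in (table, t2, t3, t4)
        ]
        assert tiers == [1, 2, 3, 4]


class TestBuildWeights:
    def test_tier1_equal_split_sums_to_one(self, cork):
        prof, _ = _profile(cork)
        ws = build_weights(prof, classify_tier(prof))
        income = ws.domain_indicator_weights("income")
        assert len(income) == 5
        assert all(abs(w - 0.2) < 1e-15 for w in income.values())
        for dom, s in ws.domain_weight_sums.items():
            assert abs(s - 1.0) < 1e-12

    def test_depleted_single_indicator_weight_is_half(self, logrono):
        prof, _ = _profile(logrono)
        ws = build_weights(prof, classify_tier(prof))
        health = ws.domain_indicator_weights("health")
        assert health == {"disability_preventing_work": 0.5}
        assert ws.domain_weight_sums["health"] == 0.5
        assert ws.weights[("health", "poor_health")] == 0.0

    def test_depleted_two_of_three_each_quarter(self, cork):
        # income designed with 5; drop 3 incl. required → m=2 depleted
        prof, _ = _profile(
            cork,
            "tier2_deplete",
            ("unemployment", "farming_employment", "low_skilled_employment"),
        )
        tier = classify_tier(prof)
        assert tier.tier == 2
        ws = build_weights(prof, tier)
        income = ws.domain_indicator_weights("income")
        assert len(income) == 2
        assert all(abs(w - 0.25) < 1e-15 for w in income.values())
        assert abs(ws.domain_weight_sums["income"] - 0.5) < 1e-15

    def test_tier4_routes_to_pca(self, cork):
        prof, _ = _profile(cork, "tier4_drop_dimension", ("enhanced_exposure",))
        with pytest.raises(TierRoutingError, match="pca"):
            build_weights(prof, classify_tier(prof))

    def test_weight_sums_conserved_across_scenarios(self, cork, logrono, milan):
        cases = [
            (cork, "tier1_full", ()),
            (cork, "tier2_deplete", ("poor_health",)),
            (logrono, "tier1_full", ()),
            (milan, "tier1_full", ()),
            (cork, "tier3_single_domain_dimension", ("sensitivity",)),
        ]
        for cfg, scenario, targets in cases:
            prof, _ = _profile(cfg, scenario, targets)
            tier = classify_tier(prof)
            ws = build_weights(prof, tier)
            for dom, s in ws.domain_weight_sums.items():
                expected = 0.5 if dom in prof.depleted_domains and tier.tier > 1 else 1.0
                if prof.available_count[dom] == 0:
                    expected = 0.0
                assert s == pytest.approx(expected, abs=1e-12)


def _score(cfg, table, policy="renormalize_weights"):
    table, report = handle_missing(table, policy)
    z = align_direction(zscore_normalize(table), cfg)
    prof = availability_profile(cfg, table)
    tier = classify_tier(prof)
    ws = build_weights(prof, tier)
    return apply_weights(z, ws, report), z


class TestApplyWeights:
    def test_single_domain_hand_example(self):
        """1 area of interest, domain of two z=+2.0/−1.0 at weight 0.5 each
        → domain score 0.5 = svi."""
        from svikit.weighting import ScoreTable, TierAssignment, WeightScheme

        z_df = pd.DataFrame(
            {"i1": [2.0, -2.0, 0.0], "i2": [-1.0, 1.0, 0.0]},
            index=["A1", "A2", "A3"],
        )
        from svikit.normalize import ZScoreMatrix

        z = ZScoreMatrix(
            df=z_df,
            normalization_params=pd.DataFrame(index=z_df.columns),
            aligned=True,
        )
        ws = WeightScheme(
            weights={("d", "i1"): 0.5, ("d", "i2"): 0.5},
            tier=TierAssignment(1, ("test",)),
            domain_weight_sums={"d": 1.0},
        )
        st = apply_weights(z, ws)
        assert st.domain_scores.loc["A1", "d"] == pytest.approx(0.5, abs=1e-12)
        assert st.svi.loc["A1"] == pytest.approx(0.5, abs=1e-12)

    def test_svi_is_row_sum_of_domain_scores(self, cork):
        table, _, _ = generate(SimulationSpec(hierarchy=cork, n_areas=30, seed=11))
        st, _ = _score(cork, table)
        np.testing.assert_allclose(
            st.svi.to_numpy(),
            st.domain_scores.sum(axis=1).to_numpy(),
            atol=1e-12,
        )

    def test_all_zero_z_gives_zero_svi(self, mini_cfg):
        from svikit.normalize import ZScoreMatrix
        from svikit.weighting import TierAssignment, WeightScheme

        z = ZScoreMatrix(
            df=pd.DataFrame(
                0.0, index=["A1", "A2"], columns=["over_75", "poor_health"]
            ),
            normalization_params=pd.DataFrame(),
            aligned=True,
        )
        ws = WeightScheme(
            weights={("d_age", "over_75"): 1.0, ("d_health", "poor_health"): 1.0},
            tier=TierAssignment(1, ()),
            domain_weight_sums={"d_age": 1.0, "d_health": 1.0},
        )
        assert apply_weights(z, ws).svi.tolist() == [0.0, 0.0]

    def test_weighted_indicator_absent_from_z_is_error(self, mini_cfg, mini_table):
        z = align_direction(zscore_normalize(mini_table), mini_cfg)
        z_small = type(z)(
            df=z.df.drop(columns=["renting"]),
            normalization_params=z.normalization_params,
            aligned=True,
        )
        prof = availability_profile(mini_cfg, mini_table)
        ws = build_weights(prof, classify_tier(prof))
        with pytest.raises(ConsistencyError, match="renting"):
            apply_weights(z_small, ws)

    def test_renormalization_preserves_domain_weight_sum(self, cork):
        table, _, _ = generate(SimulationSpec(hierarchy=cork, n_areas=30, seed=2))
        df = table.df.copy()
        df.iloc[0, df.columns.get_loc("unemployment")] = np.nan
        st, z = _score(cork, IndicatorTable(df))
        # area 0's income score uses the remaining 4 indicators at weight 1/4
        cols = ["one_parent_households", "children_per_family",
                "low_skilled_employment", "farming_employment"]
        expected = z.df.loc[df.index[0], cols].sum() / 4
        assert st.domain_scores.loc[df.index[0], "income"] == pytest.approx(
            float(expected), abs=1e-12
        )

    def test_frozen_params_monotonicity(self, mini_cfg, mini_table):
        """Holding μ/σ fixed, raising one raw indicator for one area strictly
        raises that area's SVI (its weight is positive)."""
        st0, z0 = _score(mini_cfg, mini_table)
        params = z0.normalization_params
        bumped = mini_table.df.copy()
        bumped.loc["A3", "unemployment"] += 1.0
        z_bumped = z0.df.copy()
        z_bumped.loc["A3", "unemployment"] = (
            bumped.loc["A3", "unemployment"] - params.loc["unemployment", "mu"]
        ) / params.loc["unemployment", "sigma"]
        from svikit.normalize import ZScoreMatrix

        z1 = ZScoreMatrix(df=z_bumped, normalization_params=params, aligned=True)
        prof = availability_profile(mini_cfg, mini_table)
        ws = build_weights(prof, classify_tier(prof))
        st1 = apply_weights(z1, ws)
        assert st1.svi.loc["A3"] > st0.svi.loc["A3"]
        unchanged = [a for a in st0.svi.index if a != "A3"]
        np.testing.assert_allclose(
            st1.svi.loc[unchanged], st0.svi.loc[unchanged], atol=1e-12
        )


class TestOracleEquivalence:
    def _check(self, cfg, table):
        st, _ = _score(cfg, table)
        prof = availability_profile(cfg, table)
        directions = {
            i.indicator_id: -1.0 if i.direction == VULNERABILITY_REDUCING else 1.0
            for i in cfg.indicators
        }
        raw = {c: table.df[c].tolist() for c in table.df.columns}
        domain_of = {i.indicator_id: i.domain_id for i in cfg.indicators}
        tier = classify_tier(prof)
        depleted = prof.depleted_domains if tier.tier in (2, 3) else frozenset()
        svi, dscores = naive_svi(
            raw, directions, domain_of, depleted, len(table.area_ids)
        )
        np.testing.assert_allclose(st.svi.to_numpy(), svi, atol=1e-12)
        for dom, vals in dscores.items():
            np.testing.assert_allclose(
                st.domain_scores[dom].to_numpy(), vals, atol=1e-12
            )

    def test_hand_fixture_matches_naive_double_loop(self, mini_cfg, mini_table):
        self._check(mini_cfg, mini_table)

    def test_fifty_random_fixtures_match_naive_double_loop(self):
        rng = np.random.default_rng(20240917)
        checked = 0
        while checked < 50:
            cfg, table = make_random_fixture(rng)
            if rng.random() < 0.5:  # also exercise depleted-domain weighting
                multi = [
                    d.domain_id
                    for d in cfg.domains
                    if cfg.designed_size(d.domain_id) > 1
                ]
                if multi:
                    dom = multi[int(rng.integers(len(multi)))]
                    drop = cfg.domain_indicators(dom)[0].indicator_id
                    table = IndicatorTable(table.df.drop(columns=[drop]))
            prof = availability_profile(cfg, table)
            if classify_tier(prof).tier == 4:
                continue
            self._check(cfg, table)
            checked += 1
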