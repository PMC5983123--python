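import math

import pytest

from socer import (
    AffinityTable,
    DataError,
    Dominance,
    ScorePair,
    SeedType,
    SeedWeightConfig,
    apply_socer_band,
    binding_affinity,
    classify_dominance,
    normalize_scores,
    per_mirna_term,
    rank_pccs,
    relative_binding_affinity,
    socer_raw,
    total_binding_affinity,
)

from conftest import make_site


class TestBindingAffinity:
    def test_identity_factors(self):
        w = SeedWeightConfig(1.0, 1.0, 1.0, 1.0)
        assert binding_affinity(make_site(c=1, e=-1, a=1), w) == 1.0

    def test_zero_factor_annihilates(self):
        assert binding_affinity(make_site(c=0, e=-20, a=150)) == 0.0

    def test_direct_product(self):
        # 0.5 * |-10| * 100 * 0.75 = 375 with the 7mer-m8 default weight
        site = make_site(c=0.5, e=-10, a=100, seed_type=SeedType.MER7_M8)
        assert binding_affinity(site, SeedWeightConfig()) == 375.0

    def test_stronger_energy_gives_larger_affinity(self):
        weak = binding_affinity(make_site(e=-5))
        strong = binding_affinity(make_site(e=-25))
        assert strong > weak

    def test_seed_weight_ordering_enforced(self):
        with pytest.raises(ValueError):
            SeedWeightConfig(weight_8mer=0.2, weight_6mer=0.9)


class TestRelativeBindingAffinity:
    def test_self_competition_is_unity(self):
        assert relative_binding_affinity(5.0, 5.0) == 1.0

    def test_three_to_one(self):
        assert relative_binding_affinity(3.0, 1.0) == 1.5

    def test_zero_numerator(self):
        assert relative_binding_affinity(0.0, 1.0) == 0.0

    def test_bounded_by_z(self):
        assert 0 < relative_binding_affinity(1e6, 1e-6) < 2.0

    def test_both_zero_undefined(self):
        with pytest.raises(DataError):
            relative_binding_affinity(0.0, 0.0)


class TestTotalBindingAffinity:
    def test_empty_sum(self):
        assert total_binding_affinity([], {"miR-1": 1.0}, e_pcc=5.0) == 0.0

    def test_balanced_mre_returns_expression(self):
        w = SeedWeightConfig(1.0, 1.0, 1.0, 1.0)
        site = make_site(c=1, e=-1, a=1)  # b = 1
        assert total_binding_affinity([site], {"miR-1": 1.0}, e_pcc=7.0, weights=w) == 7.0

    def test_term_by_term(self):
        # MREs with b = 3 and b = 1 vs GOI aggregate b = 1, E_pcc = 2:
        # 2*(3*2/4) + 2*(1*2/2) = 3 + 2 = 5
        w = SeedWeightConfig(1.0, 1.0, 1.0, 1.0)
        sites = [make_site(c=1, e=-3, a=1), make_site(c=1, e=-1, a=1)]
        assert total_binding_affinity(sites, {"miR-1": 1.0}, e_pcc=2.0, weights=w) == 5.0


class TestPerMirnaTerm:
    def test_symmetric_pull_is_zero(self):
        assert per_mirna_term(4.0, 4.0, 10.0) == 0.0

    def test_three_to_one_imbalance(self):
        assert per_mirna_term(6.0, 2.0, 10.0) == 5.0

    def test_complete_dominance_captures_whole_pool(self):
        assert per_mirna_term(5.0, 0.0, 3.0) == 3.0

    def test_degenerate_masses_contribute_nothing(self):
        assert per_mirna_term(0.0, 0.0, 3.0) == 0.0

    def test_bounded_by_pool(self):
        assert abs(per_mirna_term(123.4, 0.01, 7.0)) <= 7.0


def table(site_specs, gene_expr):
    sites = [make_site(**s) for s in site_specs]
    return AffinityTable.from_sites(sites, gene_expr, SeedWeightConfig(1.0, 1.0, 1.0, 1.0))


class TestSocerRaw:
    def test_no_shared_mirna_scores_zero(self):
        t = table(
            [dict(mirna="miR-1", gene="GOI"), dict(mirna="miR-2", gene="PCC")],
            {"GOI": 5.0, "PCC": 5.0},
        )
        sp = socer_raw("GOI", "PCC", t, {"miR-1": 1.0, "miR-2": 1.0})
        assert sp.raw_score == 0.0 and sp.shared_mirnas == ()

    def test_swap_negates(self):
        t = table(
            [
                dict(mirna="miR-1", gene="GA", e=-2.0),
                dict(mirna="miR-1", gene="GB", e=-7.0),
                dict(mirna="miR-2", gene="GA", e=-1.0),
                dict(mirna="miR-2", gene="GB", e=-3.0),
            ],
            {"GA": 2.0, "GB": 9.0},
        )
        expr = {"miR-1": 4.0, "miR-2": 0.5}
        ab = socer_raw("GA", "GB", t, expr)
        ba = socer_raw("GB", "GA", t, expr)
        assert ab.raw_score == -ba.raw_score != 0.0

    def test_terms_sum_to_raw_score(self):
        t = table(
            [
                dict(mirna="miR-1", gene="GA", e=-2.0),
                dict(mirna="miR-1", gene="GB", e=-7.0),
                dict(mirna="miR-2", gene="GA", e=-1.0),
                dict(mirna="miR-2", gene="GB", e=-3.0),
            ],
            {"GA": 2.0, "GB": 9.0},
        )
        sp = socer_raw("GA", "GB", t, {"miR-1": 4.0, "miR-2": 0.5})
        assert math.isclose(sp.raw_score, sum(sp.per_mirna_terms.values()), rel_tol=1e-12)
        assert sp.n_shared_mirna == 2

    def test_hand_computed_two_mirna_score(self):
        # miR-1: M_pcc = 9*7 = 63, M_goi = 2*2 = 4, E = 4 -> 4*59/67
        # miR-2 expression missing -> skipped
        t = table(
            [
                dict(mirna="miR-1", gene="GA", e=-2.0),
                dict(mirna="miR-1", gene="GB", e=-7.0),
                dict(mirna="miR-2", gene="GA", e=-1.0),
                dict(mirna="miR-2", gene="GB", e=-3.0),
            ],
            {"GA": 2.0, "GB": 9.0},
        )
        sp = socer_raw("GA", "GB", t, {"miR-1": 4.0})
        assert math.isclose(sp.raw_score, 4.0 * 59.0 / 67.0, rel_tol=1e-12)
        assert sp.shared_mirnas == ("miR-1",)

    def test_union_pool_counts_one_sided_mirna(self):
        t = table(
            [dict(mirna="miR-1", gene="GA"), dict(mirna="miR-2", gene="GB")],
            {"GA": 5.0, "GB": 5.0},
        )
        expr = {"miR-1": 2.0, "miR-2": 3.0}
        assert socer_raw("GA", "GB", t, expr, pool="shared").raw_score == 0.0
        sp = socer_raw("GA", "GB", t, expr, pool="union")
        # miR-1 pulls wholly to the GOI (-2), miR-2 wholly to the PCC (+3)
        assert sp.raw_score == 1.0

    def test_gene_without_sites_rejected(self):
        t = table([dict(mirna="miR-1", gene="GA")], {"GA": 1.0, "GB": 1.0})
        with pytest.raises(DataError):
            socer_raw("GA", "GB", t, {"miR-1": 1.0})


def pairs_from_raws(raws, goi="GOI"):
    return [
        ScorePair(goi=goi, pcc=f"P{i}", shared_mirnas=("miR-1",),
                  per_mirna_terms={"miR-1": r}, raw_score=r)
        for i, r in enumerate(raws)
    ]


class TestNormalizeClassifyBandRank:
    def test_normalize_divides_by_max_abs(self):
        pairs = normalize_scores(pairs_from_raws([-4.0, 2.0, 1.0]))
        assert [p.norm_score for p in pairs] == [-1.0, 0.5, 0.25]

    def test_all_zero_raws_normalize_to_zero(self):
        pairs = normalize_scores(pairs_from_raws([0.0, 0.0]))
        assert [p.norm_score for p in pairs] == [0.0, 0.0]

    def test_single_pair_attains_unit_magnitude(self):
        (pair,) = normalize_scores(pairs_from_raws([-7.0]))
        assert pair.norm_score == -1.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            normalize_scores([])

    def test_mixed_gois_rejected(self):
        pairs = pairs_from_raws([1.0]) + pairs_from_raws([2.0], goi="OTHER")
        with pytest.raises(ValueError):
            normalize_scores(pairs)

    @pytest.mark.parametrize(
        "score, expected",
        [
            (0.9, Dominance.DOMINANT),
            (-0.9, Dominance.DOMINANT),
            (0.5, Dominance.DOMINANT),
            (0.05, Dominance.DEPENDENT),
            (-0.49, Dominance.DEPENDENT),
            (0.0, Dominance.NONE),
        ],
    )
    def test_dominance_classification(self, score, expected):
        assert classify_dominance(score) is expected

    def test_band_filter_keeps_inside_only(self):
        pairs = normalize_scores(pairs_from_raws([0.5, 0.001, 1.0, -0.6]))
        kept = apply_socer_band(pairs)
        # 0.001 is below the lower cut, 1.0 above the upper cut
        assert [p.norm_score for p in kept] == [0.5, -0.6]

    def test_band_bounds_validated(self):
        with pytest.raises(ValueError):
            apply_socer_band([], lo=0.9, hi=0.1)

    def test_rank_directions(self):
        pairs = normalize_scores(pairs_from_raws([0.2, -0.5, 0.9]))
        asc = rank_pccs(pairs, "ascending")
        assert [p.norm_score for p in asc] == pytest.approx([-0.5555555555555556, 0.2222222222222222, 1.0])
        desc = rank_pccs(pairs, "descending")
        assert [p.norm_score for p in desc] == list(reversed([p.norm_score for p in asc]))

    def test_rank_tie_break_prefers_more_shared_mirna(self):
        a = ScorePair("GOI", "PA", ("m1", "m2", "m3"), {}, 1.0, norm_score=0.5)
        b = ScorePair("GOI", "PB", tuple(f"m{i}" for i in range(7)), {}, 1.0, norm_score=0.5)
        assert rank_pccs([a, b], "descending")[0].pcc == "PB"

    def test_rank_single_element(self):
        pairs = normalize_scores(pairs_from_raws([3.0]))
        assert rank_pccs(pairs) == pairs
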