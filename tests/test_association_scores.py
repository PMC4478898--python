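import math
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbnet.association_scores import (
    EnrichmentQuery,
    ScoreConfig,
    UndefinedScoreError,
    adamic_adar,
    bh_fdr,
    hypergeom_pvalue,
    interaction_score,
    jaccard_association,
    mutual_info_weight,
    shared_count,
    similarity,
)
from comorbnet.data_model import AssociationTable, DiseaseID, EntityKind, PatientRecords

GENE = EntityKind.GENE


def table_from_profiles(profiles: dict[str, set[str]]) -> AssociationTable:
    t = AssociationTable()
    for code, genes in profiles.items():
        for g in genes:
            t.add(DiseaseID.parse(code), g, GENE)
    return t


def enumerate_tail(N: int, M: int, n: int, k: int) -> float:
    """Brute-force P(X >= k): fraction of all n-subsets of a population
    with M marked members that contain at least k marked ones."""
    population = list(range(N))
    marked = set(range(M))
    hits = sum(
        1 for draw in combinations(population, n) if len(marked & set(draw)) >= k
    )
    return hits / math.comb(N, n)


class TestSharedCountAndSimilarity:
    def test_shared_count_hand_example(self):
        t = table_from_profiles({"100": {"a", "b", "c"}, "101": {"b", "c", "d"}})
        assert shared_count(t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101")) == 2

    def test_disjoint_profiles_share_nothing(self):
        t = table_from_profiles({"100": {"a"}, "101": {"b"}})
        assert shared_count(t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101")) == 0

    def test_self_intersection_is_profile_size(self):
        t = table_from_profiles({"100": {"a", "b", "c", "d", "e"}})
        i = DiseaseID.parse("100")
        assert shared_count(t, GENE, i, i) == 5

    @pytest.mark.parametrize(
        "profiles, expected",
        [
            ({"100": {"a"}, "101": {"a"}}, 1.0),
            ({"100": {"a", "b"}, "101": {"a", "c"}}, 0.25),
            ({"100": {"a"}, "101": {"b"}}, 0.0),
        ],
    )
    def test_similarity_product_denominator(self, profiles, expected):
        t = table_from_profiles(profiles)
        got = similarity(t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101"))
        assert got == pytest.approx(expected)

    def test_similarity_empty_profile_is_undefined(self):
        t = table_from_profiles({"100": {"a"}})
        with pytest.raises(UndefinedScoreError):
            similarity(t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101"))


class TestHypergeometric:
    def test_k_zero_is_one(self):
        assert hypergeom_pvalue(EnrichmentQuery(10, 5, 5, 0)) == 1.0

    def test_extreme_draw_matches_enumeration(self):
        # all 5 marked in a draw of 5 from 10: exactly 1 of C(10,5) draws
        p = hypergeom_pvalue(EnrichmentQuery(10, 5, 5, 5))
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_mid_tail_matches_enumeration(self):
        p = hypergeom_pvalue(EnrichmentQuery(10, 5, 5, 3))
        assert p == pytest.approx(enumerate_tail(10, 5, 5, 3), rel=1e-12)

    def test_exhaustive_oracle_small_universe(self):
        """Survival form equals draw enumeration for every (N<=7, M, n, k)."""
        for N in range(1, 8):
            for M in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(M, n) + 1):
                        p = hypergeom_pvalue(EnrichmentQuery(N, M, n, k))
                        assert p == pytest.approx(
                            enumerate_tail(N, M, n, k), rel=1e-10
                        ), (N, M, n, k)

    def test_nonincreasing_in_k(self):
        ps = [hypergeom_pvalue(EnrichmentQuery(12, 6, 6, k)) for k in range(7)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentQuery(10, 5, 5, 6)
        with pytest.raises(ValueError):
            EnrichmentQuery(10, 11, 5, 2)


class TestBHFDR:
    def test_single_value_identity(self):
        assert bh_fdr([0.01]) == [0.01]

    def test_hand_computed_adjustment(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_inputs_stay_equal(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_adjusted_at_least_raw_and_bounded(self):
        raw = [0.001, 0.2, 0.04, 0.9, 0.5]
        adj = bh_fdr(raw)
        assert all(0 <= a <= 1 and a >= r for r, a in zip(raw, adj))

    def test_order_equivariance(self):
        raw = [0.03, 0.001, 0.7, 0.2]
        adj = bh_fdr(raw)
        perm = [2, 0, 3, 1]
        adj_perm = bh_fdr([raw[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestJaccard:
    def test_identical_sets(self):
        t = table_from_profiles({"100": {"a", "b"}, "101": {"a", "b"}})
        assert jaccard_association(t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101")) == 1.0

    def test_hand_count(self):
        t = table_from_profiles({"100": {"a", "b", "c"}, "101": {"b", "c", "d"}})
        got = jaccard_association(t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101"))
        assert got == pytest.approx(0.5)

    def test_disjoint_and_undefined(self):
        t = table_from_profiles({"100": {"a"}, "101": {"b"}})
        assert jaccard_association(t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101")) == 0.0
        with pytest.raises(UndefinedScoreError):
            jaccard_association(t, GENE, DiseaseID.parse("102"), DiseaseID.parse("103"))


class TestAdamicAdar:
    def test_single_shared_entity_degree_two(self):
        t = table_from_profiles({"100": {"a"}, "101": {"a"}})
        got = adamic_adar(t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101"))
        assert got == pytest.approx(1 / math.log(2))

    def test_no_shared_entities(self):
        t = table_from_profiles({"100": {"a"}, "101": {"b"}})
        assert adamic_adar(t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101")) == 0.0

    def test_two_terms_with_degrees_two_and_four(self):
        t = table_from_profiles(
            {
                "100": {"a", "b"},
                "101": {"a", "b"},
                "102": {"b"},
                "103": {"b"},
            }
        )
        got = adamic_adar(t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101"))
        assert got == pytest.approx(1 / math.log(2) + 1 / math.log(4))

    def test_degree_one_entities_excluded(self):
        # a degree-1 entity would divide by log(1) = 0; the min-degree
        # threshold removes it from the sum
        t = table_from_profiles({"100": {"a"}})
        i = DiseaseID.parse("100")
        assert adamic_adar(t, GENE, i, i) == 0.0


class TestInteractionScore:
    def test_all_zero_guard(self):
        t = AssociationTable()
        got = interaction_score(
            t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101"), N_total=100
        )
        assert got == 0.0

    def test_hand_evaluation(self):
        t = table_from_profiles(
            {"100": {"a", "b", "g1", "g2"}, "101": {"a", "b", "h1", "h2", "h3"}}
        )
        got = interaction_score(
            t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101"), N_total=100
        )
        assert got == pytest.approx(math.log(201) - math.log(21))

    def test_sign_tracks_over_and_under_representation(self):
        over = table_from_profiles({"100": {"a"}, "101": {"a"}})
        got = interaction_score(
            over, GENE, DiseaseID.parse("100"), DiseaseID.parse("101"), N_total=50
        )
        assert got > 0
        under = table_from_profiles(
            {"100": {f"g{i}" for i in range(10)}, "101": {f"h{i}" for i in range(10)} | {"g0"}}
        )
        got = interaction_score(
            under, GENE, DiseaseID.parse("100"), DiseaseID.parse("101"), N_total=5
        )
        assert got < 0


class TestMutualInfoWeight:
    def build(self, n, p_i, p_j, c) -> PatientRecords:
        r = PatientRecords()
        for m in range(n):
            r.register_patient(f"pt{m}")
        for m in range(c):
            r.add(f"pt{m}", DiseaseID.parse("200"))
            r.add(f"pt{m}", DiseaseID.parse("201"))
        for m in range(c, p_i):
            r.add(f"pt{m}", DiseaseID.parse("200"))
        for m in range(p_i, p_i + p_j - c):
            r.add(f"pt{m}", DiseaseID.parse("201"))
        return r

    def test_independence_is_zero(self):
        r = self.build(100, 10, 10, 1)  # 1*100 == 10*10
        got = mutual_info_weight(r, DiseaseID.parse("200"), DiseaseID.parse("201"))
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluation(self):
        r = self.build(100, 10, 10, 5)
        got = mutual_info_weight(r, DiseaseID.parse("200"), DiseaseID.parse("201"))
        assert got == pytest.approx(math.log(5))

    def test_zero_cooccurrence_omitted_by_default(self):
        r = self.build(100, 10, 10, 0)
        assert mutual_info_weight(r, DiseaseID.parse("200"), DiseaseID.parse("201")) is None

    def test_zero_prevalence_undefined(self):
        r = self.build(100, 10, 10, 5)
        with pytest.raises(UndefinedScoreError):
            mutual_info_weight(r, DiseaseID.parse("200"), DiseaseID.parse("999"))


@st.composite
def random_profiles(draw):
    genes = [f"g{i}" for i in range(8)]
    gi = draw(st.sets(st.sampled_from(genes), min_size=1, max_size=6))
    gj = draw(st.sets(st.sampled_from(genes), min_size=1, max_size=6))
    return gi, gj


class TestSymmetryProperties:
    @given(random_profiles())
    @settings(max_examples=50, deadline=None)
    def test_pairwise_scores_symmetric(self, profiles):
        gi, gj = profiles
        t = table_from_profiles({"100": gi, "101": gj})
        i, j = DiseaseID.parse("100"), DiseaseID.parse("101")
        assert shared_count(t, GENE, i, j) == shared_count(t, GENE, j, i)
        assert similarity(t, GENE, i, j) == similarity(t, GENE, j, i)
        assert jaccard_association(t, GENE, i, j) == jaccard_association(t, GENE, j, i)
        assert adamic_adar(t, GENE, i, j) == adamic_adar(t, GENE, j, i)
        assert interaction_score(t, GENE, i, j, 20) == interaction_score(t, GENE, j, i, 20)

    @given(random_profiles())
    @settings(max_examples=50, deadline=None)
    def test_jaccard_bounded_with_equality_iff_identical(self, profiles):
        gi, gj = profiles
        t = table_from_profiles({"100": gi, "101": gj})
        jac = jaccard_association(t, GENE, DiseaseID.parse("100"), DiseaseID.parse("101"))
        assert 0.0 <= jac <= 1.0
        assert (jac == 1.0) == (gi == gj)

    def test_row_order_never_changes_scores(self):
        rows = [("100", "a"), ("100", "b"), ("101", "a"), ("101", "c")]
        t1 = AssociationTable()
        for code, g in rows:
            t1.add(DiseaseID.parse(code), g, GENE)
        t2 = AssociationTable()
        for code, g in reversed(rows):
            t2.add(DiseaseID.parse(code), g, GENE)
        i, j = DiseaseID.parse("100"), DiseaseID.parse("101")
        assert similarity(t1, GENE, i, j) == similarity(t2, GENE, i, j)
        assert adamic_adar(t1, GENE, i, j) == adamic_adar(t2, GENE, i, j)


class TestScoreConfig:
    def test_log_base_config(self):
        cfg = ScoreConfig(log_base=2.0)
        assert cfg.log(8.0) == pytest.approx(3.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScoreConfig(z=-1.0)
        with pytest.raises(ValueError):
            ScoreConfig(log_base=1.0)
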