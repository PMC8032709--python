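"""Unit tests for the consensus-filter building blocks."""

import numpy as np
import pytest

from clonalsnv.errors import (
    IncompleteSiteError,
    NoCoverageError,
    UndefinedTestError,
)
from clonalsnv.filtering import (
    CallSet,
    FilterConfig,
    ReadRecord,
    SiteObservation,
    apply_site_filters,
    assign_vaf_genotype,
    distance_bias_p,
    intersect_callers,
    read_passes_edit_filter,
    strand_bias_p,
)

from oracles import fisher_two_sided, ranksum_two_sided


def make_obs(clone="c1", dp=30, alt=15, ref_fwd=None, alt_fwd=None,
             alt_offsets=None, ref_offsets=None, pos=100):
    ref_n = dp - alt
    ref_fwd = ref_n // 2 if ref_fwd is None else ref_fwd
    alt_fwd = alt // 2 if alt_fwd is None else alt_fwd
    return SiteObservation(
        clone=clone, chrom="chr1", pos=pos, ref="A", alt="G",
        dp=dp, alt_count=alt,
        strand_table=[[ref_fwd, ref_n - ref_fwd], [alt_fwd, alt - alt_fwd]],
        alt_offsets=list(alt_offsets or range(alt)),
        ref_offsets=list(ref_offsets or range(ref_n)),
    )


class TestEditFilter:
    @pytest.mark.parametrize(
        "length,ed,expected",
        [
            (125, 5, True),   # floor(125/25) = 5
            (125, 6, False),
            (25, 1, True),
            (24, 1, False),   # budget floor(24/25) = 0
            (24, 0, True),
            (0, 0, False),    # no budget at all
            (150, 6, True),
            (150, 7, False),
        ],
    )
    def test_budget_is_one_per_25_bases(self, length, ed, expected):
        read = ReadRecord(length=length, edit_distance=ed, strand="forward",
                          variant_offset=0)
        assert read_passes_edit_filter(read) is expected


class TestVAFGenotype:
    @pytest.mark.parametrize(
        "dp,alt,expected",
        [
            (100, 50, "het"),
            (100, 25, "het"),
            (100, 75, "het"),
            (100, 2, "hom_ref"),
            (100, 3, "ambiguous"),   # 0.03 in the (0.025, 0.25) gap
            (100, 20, "ambiguous"),  # 0.20, the L1-chimeric signature
            (100, 80, "ambiguous"),  # 0.80 in the (0.75, 0.95) gap
            (100, 95, "hom_alt"),
            (100, 0, "hom_ref"),
            (100, 100, "hom_alt"),
        ],
    )
    def test_window_assignment(self, dp, alt, expected):
        assert assign_vaf_genotype(make_obs(dp=dp, alt=alt)) == expected

    def test_zero_depth_raises(self):
        with pytest.raises(NoCoverageError):
            assign_vaf_genotype(make_obs(dp=0, alt=0))


class TestStrandBias:
    def test_perfect_balance_gives_one(self):
        assert strand_bias_p([[10, 10], [10, 10]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[20, 20], [15, 0]],
            [[5, 25], [12, 3]],
            [[30, 28], [1, 19]],
            [[8, 2], [3, 7]],
        ],
    )
    def test_matches_hypergeometric_enumeration(self, table):
        assert strand_bias_p(table) == pytest.approx(fisher_two_sided(table), rel=1e-6)

    def test_all_zero_table_is_undefined(self):
        with pytest.raises(UndefinedTestError):
            strand_bias_p([[0, 0], [0, 0]])


class TestDistanceBias:
    def test_identical_multisets_give_one(self):
        assert distance_bias_p([3, 7, 11], [3, 7, 11]) == pytest.approx(1.0)

    def test_single_equal_elements_give_one(self):
        assert distance_bias_p([5], [5]) == pytest.approx(1.0)

    def test_empty_list_is_undefined(self):
        with pytest.raises(UndefinedTestError):
            distance_bias_p([], [1, 2])

    def test_matches_exhaustive_rank_enumeration(self):
        alt = [1.0, 2.5, 4.0]
        ref = [10.0, 12.0, 15.0, 20.0]
        assert distance_bias_p(alt, ref) == pytest.approx(
            ranksum_two_sided(alt, ref), rel=1e-9
        )

    def test_clustered_alt_offsets_are_significant(self):
        # alt reads all place the variant in the first 5 bases; ref spread out
        alt = list(range(5)) * 4            # 20 offsets <= 5
        ref = list(range(3, 124, 6))[:20]   # 20 offsets spread over the read
        assert distance_bias_p(alt, ref) < 1e-4


class TestIntersectCallers:
    def _cs(self, name, keys, geno="het"):
        calls = {
            k: {"c1": geno, "c2": "hom_ref", "c3": "hom_ref", "c4": "hom_ref"}
            for k in keys
        }
        return CallSet(name, calls)

    def test_site_in_two_callers_only_is_excluded(self):
        k1, k2 = ("chr1", 10, "A", "G"), ("chr1", 20, "C", "T")
        a = self._cs("a", [k1, k2])
        b = self._cs("b", [k1, k2])
        c = self._cs("c", [k1])
        assert set(intersect_callers(a, b, c).calls) == {k1}

    def test_genotype_disagreement_excludes_site(self):
        k = ("chr1", 10, "A", "G")
        a = self._cs("a", [k], geno="het")
        b = self._cs("b", [k], geno="het")
        c = self._cs("c", [k], geno="hom_alt")
        assert intersect_callers(a, b, c).calls == {}

    def test_idempotent_on_identical_inputs(self):
        keys = [("chr1", i, "A", "G") for i in (5, 10, 15)]
        a = self._cs("a", keys)
        out = intersect_callers(a, a, a)
        assert out.calls == a.calls

    def test_output_subset_and_commutative(self, rng):
        def random_cs(name, seed):
            r = np.random.default_rng(seed)
            keys = [("chr1", int(p), "A", "G")
                    for p in r.choice(100, size=30, replace=False)]
            return self._cs(name, keys)

        a, b, c = (random_cs(n, s) for n, s in (("a", 1), ("b", 2), ("c", 3)))
        out = intersect_callers(a, b, c)
        for cs in (a, b, c):
            assert set(out.calls) <= set(cs.calls)
        assert set(intersect_callers(c, a, b).calls) == set(out.calls)

    def test_differing_clone_sets_rejected(self):
        k = ("chr1", 10, "A", "G")
        a = CallSet("a", {k: {"c1": "het"}})
        b = CallSet("b", {k: {"c2": "het"}})
        with pytest.raises(IncompleteSiteError):
            intersect_callers(a, b, a)


class TestSiteFilters:
    def test_low_depth_fails_with_depth_reason(self):
        obs = {"c1": make_obs("c1", dp=14, alt=7),
               "c2": make_obs("c2", dp=30, alt=15)}
        res = apply_site_filters(obs)
        assert not res.passed
        assert "depth" in res.reasons["c1"]
        assert res.reasons["c2"] == []

    def test_clean_site_passes(self):
        obs = {"c1": make_obs("c1", dp=30, alt=0),
               "c2": make_obs("c2", dp=30, alt=15)}
        res = apply_site_filters(obs)
        assert res.passed and res.all_reasons == []

    def test_strand_biased_site_fails(self):
        # all 20 alt reads forward against 30F/30R ref reads
        obs = {"c1": make_obs("c1", dp=80, alt=20, ref_fwd=30, alt_fwd=20)}
        assert fisher_two_sided([[30, 30], [20, 0]]) < 1e-4  # oracle sanity
        res = apply_site_filters(obs)
        assert not res.passed and "strand_bias" in res.reasons["c1"]

    def test_missing_clone_observation_rejected(self):
        obs = {"c1": make_obs("c1")}
        with pytest.raises(IncompleteSiteError):
            apply_site_filters(obs, clones=["c1", "c2"])

    def test_pass_set_shrinks_as_thresholds_tighten(self, rng):
        sites = []
        for i in range(40):
            dp = int(rng.integers(10, 60))
            alt = int(rng.integers(0, dp + 1))
            sites.append({"c1": make_obs("c1", dp=dp, alt=alt, pos=i + 1)})
        loose = FilterConfig(dp_min=10, dp_max=200)
        tight = FilterConfig(dp_min=20, dp_max=40)
        passed_loose = {i for i, s in enumerate(sites)
                        if apply_site_filters(s, loose).passed}
        passed_tight = {i for i, s in enumerate(sites)
                        if apply_site_filters(s, tight).passed}
        assert passed_tight <= passed_loose
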