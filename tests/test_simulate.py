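"""Synthetic-data generator: genealogies, planted mutations, reads, callers."""

import dataclasses

import numpy as np
import pytest

from clonalsnv.simulate import (
    CallerProfile,
    SimulationConfig,
    expected_vaf,
    plant_mutations,
    simulate_callers,
    simulate_chip_cohort,
    simulate_genealogy,
    simulate_read_counts,
)


class TestGenealogy:
    def test_four_clone_design(self, sim_config):
        g = simulate_genealogy(4, sim_config)
        assert len(g.clones) == 4
        labels = [g.lineage_label[c] for c in g.clones]
        assert labels.count("Ar") == 2 and labels.count("Fr") == 2
        roots = [n for n, p in g.parent_of.items() if p is None]
        assert len(roots) == 1

    def test_deterministic_under_seed(self, sim_config):
        a = simulate_genealogy(4, sim_config)
        b = simulate_genealogy(4, sim_config)
        assert a == b

    def test_single_clone_rejected(self, sim_config):
        with pytest.raises(ValueError):
            simulate_genealogy(1, sim_config)


class TestPlantMutations:
    def test_zero_rate_plants_nothing(self, genealogy):
        cfg = SimulationConfig(mu=0.0, seed=3)
        truth = plant_mutations(genealogy, cfg, 500)
        assert truth.mutations == {}
        # all clones genotypically identical at every site
        for site in truth.variant_sites():
            assert len(set(truth.genotypes(site).values())) == 1

    def test_shared_branch_mutations_mark_the_clone_pair(self, genealogy, sim_config):
        truth = plant_mutations(genealogy, sim_config, 20_000)
        shared = [m for m in truth.mutations.values()
                  if m.branch.startswith("anc_") and m.kind == "gain"]
        assert shared, "expected mutations on internal lineage branches"
        for m in shared:
            assert m.expected_class == "Sh_het"
            assert m.focal == m.carriers
            assert len(m.carriers) == 2
            labels = {genealogy.lineage_label[c] for c in m.carriers}
            assert len(labels) == 1  # the pair belongs to one lineage

    def test_carriers_descend_from_branch(self, genealogy, sim_config):
        truth = plant_mutations(genealogy, sim_config, 10_000)
        for m in truth.mutations.values():
            assert m.carriers == genealogy.leaves_below(m.branch)

    def test_tstv_converges_to_configured_ratio(self, genealogy):
        cfg = SimulationConfig(seed=5, mu=2e-3, tstv_ratio=4.1,
                               founder_het_fraction=0.0, loh_fraction=0.0)
        truth = plant_mutations(genealogy, cfg, 10_000)
        subs = [m.substitution for m in truth.mutations.values()]
        assert len(subs) > 1000
        ts = subs.count("transition")
        tv = subs.count("transversion")
        assert abs(ts / tv - 4.1) < 0.5

    def test_mutation_sites_unique(self, genealogy, sim_config):
        truth = plant_mutations(genealogy, sim_config, 10_000)
        assert len(truth.mutations) == len(set(truth.mutations))


class TestReadCounts:
    def _vaf_by_layer(self, layer, n_sites=4000):
        cfg = SimulationConfig(
            seed=9, mu=5e-4, seq_error=0.0, founder_het_fraction=0.0,
            loh_fraction=0.0, l1_tissue_fraction=0.4,
            chimeric_l1_fraction=1.0 if layer == "L1" else 0.0,
            chimeric_l2_fraction=1.0 if layer == "L2" else 0.0,
        )
        g = simulate_genealogy(4, cfg)
        truth = plant_mutations(g, cfg, n_sites)
        obs = simulate_read_counts(truth, cfg)
        by_key = {}
        for ob in obs:
            by_key.setdefault(ob.key, {})[ob.clone] = ob
        vafs = []
        for site, mut in truth.mutations.items():
            for clone in mut.carriers:
                ob = by_key[truth.site_key(site)][clone]
                if ob.dp:
                    vafs.append(ob.alt_count / ob.dp)
        return np.array(vafs)

    def test_full_plant_het_vaf_near_half(self):
        vafs = self._vaf_by_layer("full")
        assert abs(vafs.mean() - 0.5) < 0.02

    def test_l2_chimeric_vaf_near_0_3(self):
        vafs = self._vaf_by_layer("L2")
        assert abs(vafs.mean() - 0.3) < 0.02

    def test_l1_chimeric_vaf_near_0_2_and_mostly_below_het_window(self):
        vafs = self._vaf_by_layer("L1")
        assert abs(vafs.mean() - 0.2) < 0.02
        assert (vafs < 0.25).mean() > 0.5

    def test_expected_vaf_helper(self):
        cfg = SimulationConfig(l1_tissue_fraction=0.4)
        assert expected_vaf("het", "full", cfg) == 0.5
        assert expected_vaf("het", "L2", cfg) == pytest.approx(0.3)
        assert expected_vaf("het", "L1", cfg) == pytest.approx(0.2)
        assert expected_vaf("hom_ref", "full", cfg) == 0.0
        assert expected_vaf("hom_alt", "full", cfg) == 1.0


class TestCallers:
    def _perfect(self):
        return tuple(CallerProfile(n, 0.0, 0.0) for n in ("a", "b", "c"))

    def test_error_free_callers_reproduce_truth(self, genealogy):
        cfg = SimulationConfig(seed=2, caller_profiles=self._perfect())
        truth = plant_mutations(genealogy, cfg, 2000)
        a, b, c = simulate_callers(truth, cfg)
        assert a.calls == b.calls == c.calls
        assert len(a.calls) == len(truth.variant_sites())
        for site in truth.variant_sites():
            assert a.calls[truth.site_key(site)] == truth.genotypes(site)

    def test_false_positives_are_caller_private(self, genealogy):
        profiles = tuple(CallerProfile(n, 0.0, 0.01) for n in ("a", "b", "c"))
        cfg = SimulationConfig(seed=4, mu=1e-5, founder_het_fraction=0.01,
                               caller_profiles=profiles)
        truth = plant_mutations(genealogy, cfg, 10_000)
        a, b, c = simulate_callers(truth, cfg)
        true_keys = {truth.site_key(s) for s in truth.variant_sites()}
        fp = [set(cs.calls) - true_keys for cs in (a, b, c)]
        for f in fp:
            assert 50 <= len(f) <= 150  # ~100 expected at rate 0.01
        assert len(fp[0] & fp[1] & fp[2]) <= 1  # (0.01)^3 x sites ~ 0

    def test_deterministic_under_seed(self, genealogy, sim_config):
        truth = plant_mutations(genealogy, sim_config, 2000)
        first = simulate_callers(truth, sim_config)
        second = simulate_callers(truth, sim_config)
        for x, y in zip(first, second):
            assert x.calls == y.calls

    def test_wrong_profile_count_rejected(self, genealogy, sim_config):
        truth = plant_mutations(genealogy, sim_config, 500)
        bad = dataclasses.replace(
            sim_config, caller_profiles=(CallerProfile("a"), CallerProfile("b"))
        )
        with pytest.raises(ValueError):
            simulate_callers(truth, bad)


class TestChipCohort:
    def test_pure_inheritance_gives_two_genotypes(self, genealogy):
        from clonalsnv.genotypes import collapse_genotypes

        m, groups = simulate_chip_cohort(
            genealogy, 20, 12, missing_rate=0.0, seed=8,
            private_mutation_rate=0.0,
        )
        mlgs = collapse_genotypes(m)
        assert len(mlgs) == 2
        assert set(groups.values()) == {"Ar", "Fr"}

    def test_all_missing_rejected(self, genealogy):
        with pytest.raises(ValueError):
            simulate_chip_cohort(genealogy, 5, 8, missing_rate=1.0, seed=1)

    def test_deterministic_under_seed(self, genealogy):
        a, _ = simulate_chip_cohort(genealogy, 10, 10, 0.05, seed=6)
        b, _ = simulate_chip_cohort(genealogy, 10, 10, 0.05, seed=6)
        assert a.data.equals(b.data)

    def test_sample_counts_and_labels(self, genealogy):
        m, groups = simulate_chip_cohort(genealogy, 107, 41, 0.01, seed=3)
        assert len(m.samples) == 214 and len(m.markers) == 41
        assert sum(1 for v in groups.values() if v == "Ar") == 107
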