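"""End-to-end orchestration of the clonal-diversity workflow.

Stage order follows the analysis: simulate (or load) call sets, consensus
filter, classify, design the chip panel, simulate the chip cohort, collapse
multilocus genotypes, and run the network / tree / ordination / AMOVA
analyses.  A single global seed is fanned out to per-stage substreams so
toggling one stage does not perturb another's randomness.  Every run writes
a manifest with parameter snapshots, per-stage counts and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as cio
from .classify import CloneGenotypeVector, partition_variants
from .errors import PipelineDependencyError
from .filtering import CallSet, FilterConfig, apply_site_filters, intersect_callers
from .genotypes import collapse_genotypes, median_joining
from .njtree import bootstrap_supports, code_genotypes, root_with_outgroup
from .panel import MarkerCandidate, PanelConfig, informativeness, select_panel
from .popgen import amova_phipt, pcoa, squared_distance_matrix
from .simulate import (
    SimulationConfig,
    plant_mutations,
    simulate_callers,
    simulate_chip_cohort,
    simulate_genealogy,
    simulate_read_counts,
)

ALL_STAGES = (
    "simulate", "filter", "classify", "panel",
    "cohort", "collapse", "network", "njtree", "pcoa", "amova",
)

_DEPENDS = {
    "filter": ("simulate",),
    "classify": ("filter",),
    "panel": ("classify",),
    "cohort": ("simulate",),
    "collapse": ("cohort",),
    "network": ("collapse",),
    "njtree": ("collapse",),
    "pcoa": ("collapse",),
    "amova": ("collapse", "cohort"),
}


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    stages: Tuple[str, ...] = ALL_STAGES
    n_clones: int = 4
    n_sites: int = 10_000
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    n_samples_per_lineage: int = 107
    n_cohort_markers: int = 41
    cohort_missing_rate: float = 0.01
    n_bootstrap: int = 200
    n_perm: int = 900
    epsilon: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for stage in self.stages:
            for dep in _DEPENDS.get(stage, ()):
                if dep not in self.stages:
                    raise PipelineDependencyError(
                        f"stage {stage!r} requires {dep!r} to be enabled"
                    )

    def stage_seed(self, stage: str) -> int:
        idx = ALL_STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2**31))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    seed: int
    stages: Dict[str, Dict] = field(default_factory=dict)

    def log(self, stage: str, counts: Dict, outputs: Sequence[str] = ()) -> None:
        if stage in self.stages:
            raise ValueError(f"stage {stage} logged twice")
        self.stages[stage] = {
            "counts": counts,
            "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stages": self.stages}, fh, indent=2,
                      default=str)


def run_pipeline(config: PipelineConfig, return_state: bool = False):
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    out = lambda name: os.path.join(config.out_dir, name)

    sim_cfg = dataclasses.replace(config.sim, seed=config.stage_seed("simulate"))
    state: Dict[str, object] = {}

    if "simulate" in config.stages:
        genealogy = simulate_genealogy(config.n_clones, sim_cfg)
        truth = plant_mutations(genealogy, sim_cfg, config.n_sites)
        observations = simulate_read_counts(truth, sim_cfg)
        callsets = simulate_callers(truth, sim_cfg)
        state.update(genealogy=genealogy, truth=truth,
                     observations=observations, callsets=callsets)
        paths = []
        for cs in callsets:
            p = out(f"calls_{cs.caller}.vcf")
            cio.write_vcf(cs, p, clones=genealogy.clones)
            paths.append(p)
        manifest.log("simulate", {
            "n_sites": config.n_sites,
            "n_mutations": len(truth.mutations),
            "n_variant_sites": len(truth.variant_sites()),
        }, paths)

    if "filter" in config.stages:
        callsets = state["callsets"]
        consensus = intersect_callers(*callsets)
        obs_by_site: Dict[Tuple, Dict[str, object]] = {}
        for ob in state["observations"]:
            obs_by_site.setdefault(ob.key, {})[ob.clone] = ob
        retained = {}
        results = []
        reason_counts: Dict[str, int] = {}
        for key in consensus.sorted_keys():
            site_obs = obs_by_site.get(key)
            if not site_obs:
                continue
            res = apply_site_filters(site_obs, config.filters)
            results.append(res)
            if res.passed:
                retained[key] = consensus.calls[key]
            else:
                for reason in res.all_reasons:
                    reason_counts[reason] = reason_counts.get(reason, 0) + 1
        filtered = CallSet(caller="filtered", calls=retained)
        state["filtered"] = filtered
        p_vcf, p_audit = out("filtered.vcf"), out("filter_audit.tsv")
        cio.write_vcf(filtered, p_vcf, clones=state["genealogy"].clones)
        cio.write_audit_table(results, p_audit, obs_by_site)
        manifest.log("filter", {
            "consensus_sites": len(consensus.calls),
            "retained_sites": len(retained),
            "failed_per_reason": reason_counts,
        }, [p_vcf, p_audit])

    if "classify" in config.stages:
        filtered: CallSet = state["filtered"]
        vectors = [
            CloneGenotypeVector(key, genos)
            for key, genos in sorted(filtered.calls.items())
            if set(genos.values()) != {"hom_ref"}
        ]
        summary, per_class = partition_variants(vectors)
        state["summary"], state["per_class"] = summary, per_class
        manifest.log("classify", {
            "class_counts": summary.class_counts,
            "tstv_ratio": summary.tstv_ratio,
        })

    if "panel" in config.stages:
        per_class = state["per_class"]
        positions = sorted(
            (v.key[0], v.key[1]) for vs in per_class.values() for v in vs
        )
        by_chrom: Dict[str, List[int]] = {}
        for chrom, pos in positions:
            by_chrom.setdefault(chrom, []).append(pos)
        candidates = []
        for cls in ("SC_het", "Sh_het"):
            for v in per_class[cls]:
                chrom, pos = v.key[0], v.key[1]
                half = 300
                neighbors = [
                    p for p in by_chrom[chrom]
                    if p != pos and pos - half <= p <= pos + half
                ]
                candidates.append(MarkerCandidate(v, 601, neighbors))
        genealogy = state["genealogy"]
        pairs = [
            {c for c in genealogy.clones if genealogy.lineage_label[c] == lab}
            for lab in ("Ar", "Fr")
        ]
        panel = select_panel(candidates, config.panel,
                             seed=config.stage_seed("panel"), lineage_pairs=pairs)
        state["panel"] = panel
        manifest.log("panel", {
            "n_candidates": len(candidates),
            "panel_size": len(panel),
            "sc": sum(1 for c in panel if c.variant.var_class == "SC_het"),
            "sh": sum(1 for c in panel if c.variant.var_class == "Sh_het"),
        })

    if "cohort" in config.stages:
        matrix, groups = simulate_chip_cohort(
            state["genealogy"], config.n_samples_per_lineage,
            config.n_cohort_markers, config.cohort_missing_rate,
            seed=config.stage_seed("cohort"),
        )
        state["matrix"], state["groups"] = matrix, groups
        p = out("cohort_genotypes.tsv")
        cio.write_genotype_table(matrix, p)
        report = informativeness(matrix)
        state["informativeness"] = report
        manifest.log("cohort", {
            "n_samples": len(matrix.samples),
            "n_markers": len(matrix.markers),
            "n_informative": len(report.informative_markers),
        }, [p])

    if "collapse" in config.stages:
        mlgs = collapse_genotypes(state["matrix"])
        state["mlgs"] = mlgs
        manifest.log("collapse", {
            "n_genotypes": len(mlgs),
            "n_singletons": sum(1 for g in mlgs if g.singleton),
            "largest": max(len(g.members) for g in mlgs),
        })

    if "network" in config.stages:
        net = median_joining(state["mlgs"], epsilon=config.epsilon)
        p_edges, p_nexus = out("network_edges.tsv"), out("network.nex")
        cio.write_network_edges(net, p_edges)
        cio.write_network_nexus(net, p_nexus)
        state["network"] = net
        manifest.log("network", {
            "n_nodes": net.graph.number_of_nodes(),
            "n_medians": len(net.medians),
            "n_edges": net.graph.number_of_edges(),
        }, [p_edges, p_nexus])

    if "njtree" in config.stages or "pcoa" in config.stages or "amova" in config.stages:
        mlgs = state["mlgs"]
        profiles = {g.name: g.profile for g in mlgs}
        groups = state["groups"]
        # majority lineage of each genotype's members, for grouping
        mlg_groups = {
            g.name: max(("Ar", "Fr"), key=lambda lab: sum(
                1 for s in g.members if groups[s] == lab))
            for g in mlgs
        }
        state["mlg_groups"] = mlg_groups

    if "njtree" in config.stages:
        import pandas as pd
        from .genotypes import GenotypeMatrix

        frame = pd.DataFrame(
            {name: list(profile) for name, profile in profiles.items()}
        ).T
        frame.columns = state["matrix"].markers
        seqs = code_genotypes(GenotypeMatrix(frame), outgroup="PN40024")
        tree, supports = bootstrap_supports(
            seqs, n_reps=config.n_bootstrap, seed=config.stage_seed("njtree")
        )
        tree = root_with_outgroup(tree, "PN40024")
        p = out("njtree.nwk")
        cio.write_newick(tree, p)
        state["tree"], state["supports"] = tree, supports
        manifest.log("njtree", {
            "n_taxa": len(seqs),
            "n_bootstrap": config.n_bootstrap,
        }, [p])

    if "pcoa" in config.stages:
        names, dmat = squared_distance_matrix(profiles)
        res = pcoa(dmat, names)
        p = out("pcoa.tsv")
        cio.write_pcoa_table(res, p)
        state["pcoa"] = res
        manifest.log("pcoa", {
            "pco1_pct": float(res.percent_variance[0]) if len(res.percent_variance) else 0.0,
        }, [p])

    if "amova" in config.stages:
        names, dmat = squared_distance_matrix(profiles)
        res = amova_phipt(dmat, state["mlg_groups"], names=names,
                          n_perm=config.n_perm, seed=config.stage_seed("amova"))
        p = out("amova.tsv")
        cio.write_amova_table(res, p)
        state["amova"] = res
        manifest.log("amova", {
            "phi_pt": res.phi_pt, "p_value": res.p_value,
        }, [p])

    manifest.save(out("manifest.json"))
    if return_state:
        return manifest, state
    return manifest
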