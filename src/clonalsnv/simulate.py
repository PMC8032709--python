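"""Synthetic clone genealogies, somatic mutations and sequencing evidence.

The generator emulates the study design the package targets: a handful of
clonal accessions of one cultivar, resequenced at ~30x, that differ only by
somatic mutations accumulated along their propagation histories.  Two clonal
lineages ("Ar" and "Fr") diverge at the founder; each clone sits at the end
of a terminal branch whose length is its years of independent propagation.

Mutations are planted with a clock-like model (Poisson per branch, rate
``mu * branch_years * n_sites``), are heterozygous gains on a homozygous
background or losses of heterozygosity at ancestrally heterozygous sites,
show a transition excess, and may be chimeric: confined to the L1 meristem
layer (~40% of tissue by default) or to L2, which depresses the observed
variant allele fraction below the nominal 0.5 of a full-plant heterozygote.

Read evidence is Poisson depth with binomial allele sampling, uniform read
offsets and unbiased strands (a strand bias can be switched on to create
filterable sites).  Three virtual callers apply independent false-negative
and false-positive errors to the truth.  A separate generator emits a
chip-stage cohort: many samples descending from the two lineage founders
with rare private mutations and missing data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .filtering import CallSet, SiteObservation
from .genotypes import GenotypeMatrix

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_NUCS = "ACGT"


@dataclass(frozen=True)
class CallerProfile:
    name: str
    fn_rate: float = 0.0
    fp_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.fn_rate <= 1 and 0 <= self.fp_rate <= 1):
            raise ValueError("caller error rates must be in [0, 1]")


def _default_callers() -> Tuple[CallerProfile, ...]:
    return (
        CallerProfile("callerA", fn_rate=0.05, fp_rate=0.002),
        CallerProfile("callerB", fn_rate=0.08, fp_rate=0.004),
        CallerProfile("callerC", fn_rate=0.10, fp_rate=0.003),
    )


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    mu is mutations per site per branch-year (a scaled rate chosen so a
    10-kb benchmark region accumulates a few hundred somatic variants);
    tstv_ratio is the expected transition/transversion ratio of de novo
    mutations; l1_tissue_fraction is the share of somatic tissue derived
    from the L1 meristem layer, so an L2-confined heterozygous mutation has
    expected VAF 0.5 * (1 - l1_tissue_fraction) and an L1-confined one
    0.5 * l1_tissue_fraction.
    """

    mu: float = 2e-4
    tstv_ratio: float = 4.1
    chimeric_l1_fraction: float = 0.1
    chimeric_l2_fraction: float = 0.2
    l1_tissue_fraction: float = 0.4
    depth_mean: float = 30.0
    seq_error: float = 0.001
    read_length: int = 150
    caller_profiles: Tuple[CallerProfile, ...] = field(default_factory=_default_callers)
    seed: int = 0
    # genealogy shape
    lineage_branch_years: float = 40.0
    leaf_branch_years: Tuple[float, ...] = (70.0, 75.0, 25.0, 90.0)
    # background variation
    founder_het_fraction: float = 0.15
    loh_fraction: float = 0.05
    loh_to_ref_prob: float = 0.9
    site_spacing: int = 200
    strand_bias: float = 0.5  # P(forward) per read; 0.5 = unbiased

    def __post_init__(self) -> None:
        rates = (
            self.chimeric_l1_fraction,
            self.chimeric_l2_fraction,
            self.l1_tissue_fraction,
            self.seq_error,
            self.founder_het_fraction,
            self.loh_fraction,
            self.loh_to_ref_prob,
            self.strand_bias,
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.chimeric_l1_fraction + self.chimeric_l2_fraction > 1:
            raise ValueError("chimeric fractions must sum to at most 1")
        if self.depth_mean <= 0 or self.tstv_ratio <= 0 or self.mu < 0:
            raise ValueError("depth_mean and tstv_ratio must be positive, mu >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stage of the simulation."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class CloneGenealogy:
    """Propagation history: leaves are sampled clones, internal nodes are
    unsampled ancestors; ``branch_years`` is the edge length above a node."""

    clones: List[str]
    parent_of: Dict[str, Optional[str]]
    branch_years: Dict[str, float]
    lineage_label: Dict[str, str]

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent_of.items() if p is None]
        if len(roots) != 1:
            raise ValueError("genealogy must have exactly one root")
        for clone in self.clones:
            if clone not in self.lineage_label:
                raise ValueError(f"clone {clone} lacks a lineage label")
            seen = set()
            node: Optional[str] = clone
            while node is not None:
                if node in seen:
                    raise ValueError("parent links contain a cycle")
                seen.add(node)
                node = self.parent_of[node]

    @property
    def root(self) -> str:
        return next(n for n, p in self.parent_of.items() if p is None)

    def leaves_below(self, node: str) -> frozenset:
        children: Dict[str, List[str]] = {}
        for n, p in self.parent_of.items():
            if p is not None:
                children.setdefault(p, []).append(n)
        stack, leaves = [node], []
        while stack:
            n = stack.pop()
            kids = children.get(n, [])
            if not kids and n in self.clones:
                leaves.append(n)
            stack.extend(kids)
        return frozenset(leaves)

    def branches(self) -> List[str]:
        """Non-root nodes, i.e. the mutable branches, in a stable order."""
        return sorted(n for n, p in self.parent_of.items() if p is not None)


MutationKind = str  # "gain" | "loh_ref" | "loh_alt"


@dataclass(frozen=True)
class Mutation:
    site: int
    branch: str
    carriers: frozenset  # leaf clones descending from the branch
    kind: MutationKind
    layer: str  # "full" | "L1" | "L2"
    substitution: str  # transition | transversion
    expected_class: str
    focal: frozenset


@dataclass
class TruthTable:
    """Planted ground truth: background genotypes plus somatic mutations."""

    n_sites: int
    clones: List[str]
    site_alleles: Dict[int, Tuple[str, str, int, str]]  # site -> (ref, alt, pos, chrom)
    founder_het_sites: frozenset
    mutations: Dict[int, Mutation]

    def genotype(self, clone: str, site: int) -> str:
        base = "het" if site in self.founder_het_sites else "hom_ref"
        mut = self.mutations.get(site)
        if mut is None or clone not in mut.carriers:
            return base
        if mut.kind == "gain":
            return "het"
        return "hom_ref" if mut.kind == "loh_ref" else "hom_alt"

    def genotypes(self, site: int) -> Dict[str, str]:
        return {c: self.genotype(c, site) for c in self.clones}

    def variant_sites(self) -> List[int]:
        """Sites where at least one clone differs from homozygous reference."""
        out = set(self.founder_het_sites) | set(self.mutations)
        return sorted(
            s for s in out
            if any(g != "hom_ref" for g in self.genotypes(s).values())
        )

    def site_key(self, site: int) -> Tuple[str, int, str, str]:
        ref, alt, pos, chrom = self.site_alleles[site]
        return (chrom, pos, ref, alt)


def simulate_genealogy(n_clones: int, config: SimulationConfig) -> CloneGenealogy:
    """Two-lineage genealogy with ``n_clones`` leaves.

    Clones alternate between the Ar and Fr lineages (Ar1, Fr1, Ar2, ...);
    each lineage descends from an internal ancestor hanging off the founder,
    and terminal branch lengths cycle through ``config.leaf_branch_years``.
    """
    if n_clones < 2:
        raise ValueError("need at least two clones")
    parent: Dict[str, Optional[str]] = {"founder": None}
    years: Dict[str, float] = {"founder": 0.0}
    labels: Dict[str, str] = {}
    clones: List[str] = []
    counts = {"Ar": 0, "Fr": 0}
    for anc, lab in (("anc_Ar", "Ar"), ("anc_Fr", "Fr")):
        parent[anc] = "founder"
        years[anc] = config.lineage_branch_years
        labels[anc] = lab
    year_cycle = itertools.cycle(config.leaf_branch_years)
    for i in range(n_clones):
        lab = "Ar" if i % 2 == 0 else "Fr"
        counts[lab] += 1
        name = f"{lab}{counts[lab]}"
        clones.append(name)
        parent[name] = f"anc_{lab}"
        years[name] = next(year_cycle)
        labels[name] = lab
    return CloneGenealogy(clones, parent, years, labels)


def _expected_class(kind: MutationKind, carriers: frozenset, genealogy: CloneGenealogy,
                    founder_het: bool) -> Tuple[str, frozenset]:
    others = frozenset(genealogy.clones) - carriers
    k = len(carriers)
    if kind == "gain":
        if k == 1:
            return "SC_het", carriers
        if k == 2 and len(others) == 2:
            return "Sh_het", carriers
        if not others:
            return "SNP", frozenset()
        if len(others) == 1:
            # three clones het, one still hom-ref: the untouched clone is focal
            return "SC_ref", others
        return "complex", frozenset()
    # LoH at a founder-heterozygous site
    if kind == "loh_ref":
        if k == 1:
            return "SC_ref", carriers
        if k == 2 and len(others) == 2:
            return "Sh_het", others  # remaining het pair carries the alt state
        return "complex", frozenset()
    if k == 1:
        return "SC_hom", carriers
    if k == 2 and len(others) == 2:
        return "Sh_hom", carriers
    return "complex", frozenset()


def plant_mutations(
    genealogy: CloneGenealogy, config: SimulationConfig, n_sites: int
) -> TruthTable:
    """Plant somatic mutations along the genealogy over ``n_sites`` loci.

    Per branch the mutation count is Poisson(mu * branch_years * n_sites);
    each mutation occupies a fresh site.  Gains are heterozygous on a
    homozygous-reference background; with probability ``loh_fraction`` an
    event is instead a loss of heterozygosity at an ancestrally (founder-)
    heterozygous site.  Transitions are drawn with probability
    tstv_ratio / (tstv_ratio + 1).
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = config.rng(1)
    chrom = "sim1"

    refs = rng.choice(list(_NUCS), size=n_sites)
    founder_het = np.flatnonzero(rng.random(n_sites) < config.founder_het_fraction)
    site_alleles: Dict[int, Tuple[str, str, int, str]] = {}

    def draw_alt(ref: str, transition: bool) -> str:
        if transition:
            return _TS_PARTNER[ref]
        return _TV_PARTNERS[ref][rng.integers(2)]

    p_ts = config.tstv_ratio / (config.tstv_ratio + 1.0)
    for s in founder_het:
        is_ts = rng.random() < p_ts
        site_alleles[int(s)] = (
            str(refs[s]), draw_alt(str(refs[s]), is_ts), (int(s) + 1) * config.site_spacing, chrom
        )

    free_hom = list(np.setdiff1d(np.arange(n_sites), founder_het))
    rng.shuffle(free_hom)
    free_het = list(founder_het.copy())
    rng.shuffle(free_het)

    mutations: Dict[int, Mutation] = {}
    founder_het_set = frozenset(int(s) for s in founder_het)
    for branch in genealogy.branches():
        n_mut = rng.poisson(config.mu * genealogy.branch_years[branch] * n_sites)
        carriers = genealogy.leaves_below(branch)
        if not carriers:
            continue
        for _ in range(n_mut):
            want_loh = rng.random() < config.loh_fraction and free_het
            if want_loh:
                site = int(free_het.pop())
                kind = "loh_ref" if rng.random() < config.loh_to_ref_prob else "loh_alt"
                sub = (
                    "transition"
                    if {site_alleles[site][0], site_alleles[site][1]} in ({"A", "G"}, {"C", "T"})
                    else "transversion"
                )
            else:
                if not free_hom:
                    break
                site = int(free_hom.pop())
                kind = "gain"
                is_ts = rng.random() < p_ts
                ref = str(refs[site])
                site_alleles[site] = (
                    ref, draw_alt(ref, is_ts), (site + 1) * config.site_spacing, chrom
                )
                sub = "transition" if is_ts else "transversion"
            u = rng.random()
            layer = (
                "L1" if u < config.chimeric_l1_fraction
                else "L2" if u < config.chimeric_l1_fraction + config.chimeric_l2_fraction
                else "full"
            )
            cls, focal = _expected_class(kind, carriers, genealogy, site in founder_het_set)
            mutations[site] = Mutation(
                site=site, branch=branch, carriers=carriers, kind=kind,
                layer=layer, substitution=sub, expected_class=cls, focal=focal,
            )
    return TruthTable(
        n_sites=n_sites,
        clones=list(genealogy.clones),
        site_alleles=site_alleles,
        founder_het_sites=founder_het_set,
        mutations=mutations,
    )


def expected_vaf(genotype: str, layer: str, config: SimulationConfig) -> float:
    """Expected variant allele fraction of a genotype given its chimeric layer."""
    if genotype == "hom_ref":
        return 0.0
    if genotype == "hom_alt":
        return 1.0
    if layer == "L1":
        return 0.5 * config.l1_tissue_fraction
    if layer == "L2":
        return 0.5 * (1.0 - config.l1_tissue_fraction)
    return 0.5


def simulate_read_counts(
    truth: TruthTable, config: SimulationConfig
) -> List[SiteObservation]:
    """Simulate per-clone read evidence at every variant site of the truth.

    Depth is Poisson(depth_mean); alt reads are binomial around the expected
    VAF contaminated by the per-base error rate; strands are Bernoulli
    (``strand_bias`` forward) and read offsets uniform on the read length.
    """
    sites = truth.variant_sites()
    if not sites:
        raise ValueError("truth table contains no variant sites")
    rng = config.rng(2)
    e = config.seq_error
    out: List[SiteObservation] = []
    for site in sites:
        chrom, pos, ref, alt = truth.site_key(site)
        mut = truth.mutations.get(site)
        layer = mut.layer if mut is not None else "full"
        for clone in truth.clones:
            gt = truth.genotype(clone, site)
            in_layer = mut is None or clone in mut.carriers
            vaf = expected_vaf(gt, layer if (mut and clone in mut.carriers) else "full", config)
            p_alt = vaf * (1 - e) + (1 - vaf) * e / 3
            dp = int(rng.poisson(config.depth_mean))
            alt_n = int(rng.binomial(dp, p_alt)) if dp else 0
            ref_n = dp - alt_n
            alt_fwd = int(rng.binomial(alt_n, config.strand_bias)) if alt_n else 0
            ref_fwd = int(rng.binomial(ref_n, 0.5)) if ref_n else 0
            table = np.array(
                [[ref_fwd, ref_n - ref_fwd], [alt_fwd, alt_n - alt_fwd]], dtype=int
            )
            out.append(
                SiteObservation(
                    clone=clone, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    dp=dp, alt_count=alt_n, strand_table=table,
                    alt_offsets=list(rng.integers(0, config.read_length, size=alt_n)),
                    ref_offsets=list(rng.integers(0, config.read_length, size=ref_n)),
                )
            )
    return out


def simulate_callers(
    truth: TruthTable, config: SimulationConfig
) -> Tuple[CallSet, CallSet, CallSet]:
    """Three imperfect call sets derived from the truth.

    Each caller independently drops variant sites at its false-negative rate
    and injects private spurious heterozygous sites at its false-positive
    rate over the unused site space.
    """
    if len(config.caller_profiles) != 3:
        raise ValueError("exactly three caller profiles required")
    rng = config.rng(3)
    variant_sites = truth.variant_sites()
    used = set(truth.site_alleles)
    free_sites = np.array(sorted(set(range(truth.n_sites)) - used))
    call_sets = []
    for profile in config.caller_profiles:
        calls = {}
        keep = rng.random(len(variant_sites)) >= profile.fn_rate
        for site, kept in zip(variant_sites, keep):
            if kept:
                calls[truth.site_key(site)] = truth.genotypes(site)
        n_fp = rng.binomial(len(free_sites), profile.fp_rate) if len(free_sites) else 0
        fp_sites = rng.choice(free_sites, size=n_fp, replace=False)
        for site in fp_sites:
            ref = _NUCS[rng.integers(4)]
            alt = rng.choice([b for b in _NUCS if b != ref])
            clone = truth.clones[rng.integers(len(truth.clones))]
            genos = {c: "hom_ref" for c in truth.clones}
            genos[clone] = "het"
            calls[("sim1", (int(site) + 1) * config.site_spacing, ref, str(alt))] = genos
        call_sets.append(CallSet(caller=profile.name, calls=calls))
    return tuple(call_sets)


def simulate_chip_cohort(
    genealogy: CloneGenealogy,
    n_samples_per_lineage: int,
    n_markers: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    private_mutation_rate: float = 0.05,
    diagnostic_fraction: float = 0.55,
) -> Tuple[GenotypeMatrix, Dict[str, str]]:
    """Chip-stage cohort: samples inherit a lineage founder profile plus rare
    private mutations, with entries missing at ``missing_rate``.

    Markers alternate between the two lineages; a lineage's founder is
    heterozygous at its own diagnostic markers and homozygous reference
    elsewhere.  ``diagnostic_fraction`` < 1 leaves a tail of markers
    non-diagnostic (monomorphic across founders).
    """
    if n_markers < 4:
        raise ValueError("need at least four markers")
    if n_samples_per_lineage < 1:
        raise ValueError("need at least one sample per lineage")
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must be in [0, 1]")
    if missing_rate >= 1:
        raise ValueError("missing_rate=1 leaves no usable genotypes")
    rng = np.random.default_rng([seed, 4])
    lineages = ("Ar", "Fr")
    markers = [f"snv{j + 1:02d}" for j in range(n_markers)]
    n_diag = int(round(diagnostic_fraction * n_markers))
    founders = {lab: np.zeros(n_markers) for lab in lineages}
    for j in range(n_diag):
        founders[lineages[j % 2]][j] = 1.0

    rows, names, groups = [], [], {}
    for lab in lineages:
        for i in range(n_samples_per_lineage):
            name = f"{lab}_{i + 1:03d}"
            profile = founders[lab].copy()
            for _ in range(rng.poisson(private_mutation_rate)):
                j = rng.integers(n_markers)
                profile[j] = min(profile[j] + 1, 2)
            rows.append(profile)
            names.append(name)
            groups[name] = lab
    data = pd.DataFrame(np.array(rows), index=names, columns=markers)
    if missing_rate > 0:
        mask = rng.random(data.shape) < missing_rate
        data = data.mask(mask)
    return GenotypeMatrix(data), groups
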