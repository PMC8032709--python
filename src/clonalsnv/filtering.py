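"""Consensus somatic-variant retention.

Reliable somatic variants in a clonally propagated cultivar are rare relative
to sequencing artifacts, so retention is deliberately stringent: a site is
kept only when three independent callers agree on the call, the supporting
reads are clean (bounded edit distance), and per-clone evidence passes depth,
variant-allele-frequency (VAF), strand-bias and read-position-bias filters.

The VAF windows double as a genotype assignment: VAF <= 0.025 is homozygous
reference, 0.25-0.75 heterozygous, >= 0.95 homozygous alternative.  The gap
zones are deliberate -- a heterozygous mutation confined to the L1 meristem
layer (~30-40% of tissue) has an expected VAF near 0.5 * l1_fraction < 0.25
and lands in a gap, so the filter trades those chimeric variants away in
exchange for precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import (
    IncompleteSiteError,
    NoCoverageError,
    UndefinedTestError,
)

SiteKey = Tuple[str, int, str, str]  # (chrom, pos 1-based, ref, alt)

GENOTYPES = ("hom_ref", "het", "hom_alt")
_NUCS = frozenset("ACGT")


@dataclass(frozen=True)
class ReadRecord:
    """Alignment summary of one read overlapping a candidate site."""

    length: int
    edit_distance: int
    strand: str  # "forward" | "reverse"
    variant_offset: int  # 0-based offset of the site within the read

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("read length must be nonnegative")
        if not 0 <= self.edit_distance:
            raise ValueError("edit distance must be nonnegative")
        if self.length and not 0 <= self.variant_offset < self.length:
            raise ValueError("variant_offset must lie within the read")


@dataclass
class SiteObservation:
    """Per-clone sequencing evidence at one candidate site.

    ``strand_table`` is a 2x2 array: rows (ref, alt) x columns
    (forward, reverse).  Offsets are 0-based positions of the site within
    each supporting read.
    """

    clone: str
    chrom: str
    pos: int
    ref: str
    alt: str
    dp: int
    alt_count: int
    strand_table: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), dtype=int))
    alt_offsets: List[int] = field(default_factory=list)
    ref_offsets: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.strand_table = np.asarray(self.strand_table, dtype=int)
        if self.strand_table.shape != (2, 2):
            raise ValueError("strand_table must be 2x2 (ref/alt x fwd/rev)")
        if self.alt_count > self.dp:
            raise ValueError("alt_count cannot exceed depth")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        if self.dp == 0:
            raise NoCoverageError(f"zero depth at {self.chrom}:{self.pos}")
        return self.alt_count / self.dp


@dataclass
class FilterConfig:
    """Retention thresholds.

    Defaults are the stringent whole-genome-resequencing settings for ~30x
    data: depth window [15, 150], VAF(ref) <= 0.025, VAF(het) in
    [0.25, 0.75], VAF(hom) >= 0.95, and bias tests significant at 1e-4.
    """

    dp_min: int = 15
    dp_max: int = 150
    vaf_ref_max: float = 0.025
    vaf_het_min: float = 0.25
    vaf_het_max: float = 0.75
    vaf_hom_min: float = 0.95
    bias_alpha: float = 0.0001
    edit_per_bases: int = 25
    exact_rank_sum_max_n: int = 30

    def __post_init__(self) -> None:
        if not (0 <= self.vaf_ref_max < self.vaf_het_min <= self.vaf_het_max
                < self.vaf_hom_min <= 1):
            raise ValueError("VAF windows must be ordered and disjoint")
        if self.dp_min > self.dp_max:
            raise ValueError("dp_min must not exceed dp_max")


@dataclass
class CallSet:
    """One caller's biallelic SNV genotype calls for all clones."""

    caller: str
    calls: Dict[SiteKey, Dict[str, str]]  # key -> clone -> genotype

    def __post_init__(self) -> None:
        for (chrom, pos, ref, alt), genos in self.calls.items():
            if len(ref) != 1 or len(alt) != 1 or ref not in _NUCS or alt not in _NUCS:
                raise ValueError(
                    f"only biallelic SNVs supported, got {chrom}:{pos} {ref}>{alt}"
                )
            for gt in genos.values():
                if gt not in GENOTYPES:
                    raise ValueError(f"unknown genotype {gt!r}")

    @property
    def clones(self) -> frozenset:
        clones: set = set()
        for genos in self.calls.values():
            clones.update(genos)
        return frozenset(clones)

    def sorted_keys(self) -> List[SiteKey]:
        return sorted(self.calls)


def read_passes_edit_filter(read: ReadRecord, config: FilterConfig | None = None) -> bool:
    """Whether a read satisfies the edit-distance budget.

    The budget is 1 mismatch per ``edit_per_bases`` nucleotides of query,
    i.e. ``floor(length / edit_per_bases)``.  Zero-length reads carry no
    budget and never pass.
    """
    config = config or FilterConfig()
    if read.length <= 0:
        return False
    return read.edit_distance <= read.length // config.edit_per_bases


def assign_vaf_genotype(obs: SiteObservation, config: FilterConfig | None = None) -> str:
    """Genotype a clone at a site from its VAF.

    Returns one of ``hom_ref``, ``het``, ``hom_alt`` or ``ambiguous`` (VAF in
    a gap zone, e.g. an L1-chimeric signature near 0.2).
    """
    config = config or FilterConfig()
    vaf = obs.vaf  # raises NoCoverageError at DP=0
    if vaf <= config.vaf_ref_max:
        return "hom_ref"
    if config.vaf_het_min <= vaf <= config.vaf_het_max:
        return "het"
    if vaf >= config.vaf_hom_min:
        return "hom_alt"
    return "ambiguous"


def strand_bias_p(strand_table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value on the ref/alt x fwd/rev table."""
    table = np.asarray(strand_table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("strand table must be 2x2")
    if table.sum() == 0:
        raise UndefinedTestError("all-zero strand table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def distance_bias_p(
    alt_offsets: Sequence[int],
    ref_offsets: Sequence[int],
    exact_max_n: int = 30,
) -> float:
    """Two-sided rank-sum p comparing alt- vs ref-read variant offsets.

    Uses the exact Mann-Whitney null when both samples are small and tie-free,
    the tie-corrected normal approximation otherwise.  Identical constant
    samples carry no positional information and return 1.0.
    """
    alt = np.asarray(alt_offsets, dtype=float)
    ref = np.asarray(ref_offsets, dtype=float)
    if alt.size == 0 or ref.size == 0:
        raise UndefinedTestError("both offset lists must be non-empty")
    combined = np.concatenate([alt, ref])
    if np.ptp(combined) == 0:
        return 1.0
    has_ties = len(np.unique(combined)) < combined.size
    small = max(alt.size, ref.size) <= exact_max_n
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(alt, ref, alternative="two-sided", method=method)
    return min(float(res.pvalue), 1.0)


def intersect_callers(a: CallSet, b: CallSet, c: CallSet) -> CallSet:
    """Strict three-caller consensus.

    A site is retained only if all three callers report the same
    (chrom, pos, ref, alt) key with identical per-clone genotypes.
    """
    sets = (a, b, c)
    clone_sets = {cs.clones for cs in sets if cs.calls}
    if len(clone_sets) > 1:
        raise IncompleteSiteError("callers genotyped different clone sets")
    retained: Dict[SiteKey, Dict[str, str]] = {}
    for key in sorted(set(a.calls) & set(b.calls) & set(c.calls)):
        if a.calls[key] == b.calls[key] == c.calls[key]:
            retained[key] = dict(a.calls[key])
    return CallSet(caller="consensus", calls=retained)


@dataclass
class SiteFilterResult:
    """Outcome of the per-site evidence filters."""

    key: SiteKey
    passed: bool
    reasons: Dict[str, List[str]]  # clone -> violated rules (empty if clean)

    @property
    def all_reasons(self) -> List[str]:
        out = sorted({r for rs in self.reasons.values() for r in rs})
        return out


def apply_site_filters(
    observations: Mapping[str, SiteObservation],
    config: FilterConfig | None = None,
    clones: Iterable[str] | None = None,
) -> SiteFilterResult:
    """Evaluate depth, VAF-class, strand-bias and distance-bias per clone.

    The site passes only if every clone is clean; a single ambiguous VAF or
    biased clone fails the whole site (sites, not genotypes, are filtered).
    """
    config = config or FilterConfig()
    observations = dict(observations)
    if clones is not None:
        missing = set(clones) - set(observations)
        if missing:
            raise IncompleteSiteError(f"missing observations for clones {sorted(missing)}")
    if not observations:
        raise IncompleteSiteError("no observations supplied")

    key = next(iter(observations.values())).key
    reasons: Dict[str, List[str]] = {}
    for clone, obs in observations.items():
        clone_reasons: List[str] = []
        if not config.dp_min <= obs.dp <= config.dp_max:
            clone_reasons.append("depth")
        if obs.dp == 0:
            clone_reasons.append("no_coverage")
        else:
            if assign_vaf_genotype(obs, config) == "ambiguous":
                clone_reasons.append("vaf_ambiguous")
            if obs.strand_table.sum() > 0 and obs.strand_table[1].sum() > 0:
                if strand_bias_p(obs.strand_table) <= config.bias_alpha:
                    clone_reasons.append("strand_bias")
            if obs.alt_offsets and obs.ref_offsets:
                p = distance_bias_p(
                    obs.alt_offsets, obs.ref_offsets, config.exact_rank_sum_max_n
                )
                if p <= config.bias_alpha:
                    clone_reasons.append("distance_bias")
        reasons[clone] = clone_reasons
    passed = all(not r for r in reasons.values())
    return SiteFilterResult(key=key, passed=passed, reasons=reasons)
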