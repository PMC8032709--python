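"""Classification of retained variants among four resequenced clones.

Variants fall into two tiers.  A SNP is a cultivar-level polymorphism: all
four clones carry the same non-reference genotype, so the site distinguishes
the cultivar from the reference genome but not the clones from each other.
An SNV distinguishes clones of the cultivar and is of presumed somatic
origin.  SNVs subdivide by the genotype pattern relative to the (effectively
homozygous) reference:

* SC (single-clone): exactly one clone differs from the other three —
  ``SC_het`` (one het, three hom-ref), ``SC_ref`` (one hom-ref, three het),
  ``SC_hom`` (one hom-alt, the other three sharing het or hom-ref).
* Sh (shared): a 2+2 split into exactly two genotype states; the focal pair
  is the one carrying the higher-dosage (more alternative) state —
  ``Sh_het`` when that state is het, ``Sh_hom`` when homozygous alternative.
* ``complex``: any other pattern.

Sites are also annotated by genomic region (exonic / intronic / intergenic)
against a gene model, and by substitution type (transition / transversion).
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import InvariantSiteError
from .filtering import SiteKey

CLASSES = ("SNP", "SC_het", "SC_ref", "SC_hom", "Sh_het", "Sh_hom", "complex")
_DOSAGE = {"hom_ref": 0, "het": 1, "hom_alt": 2}
_TRANSITIONS = ({"A", "G"}, {"C", "T"})


@dataclass(frozen=True)
class CloneGenotypeVector:
    """Genotypes of all clones at one biallelic site."""

    key: SiteKey
    genotypes: Mapping[str, str]  # clone -> hom_ref | het | hom_alt

    def __post_init__(self) -> None:
        if len(self.genotypes) < 2:
            raise ValueError("need genotypes for at least two clones")
        for gt in self.genotypes.values():
            if gt not in _DOSAGE:
                raise ValueError(f"unknown genotype {gt!r}")


@dataclass
class ClassifiedVariant:
    key: SiteKey
    var_class: str
    focal: frozenset  # clone ids: 1 for SC, 2 for Sh, empty otherwise
    substitution: str  # transition | transversion
    region: Optional[str] = None  # exonic | intronic | intergenic

    def __post_init__(self) -> None:
        if self.var_class.startswith("SC") and len(self.focal) != 1:
            raise ValueError("SC classes have exactly one focal clone")
        if self.var_class.startswith("Sh") and len(self.focal) != 2:
            raise ValueError("Sh classes have exactly two focal clones")


@dataclass
class GeneModel:
    """Sorted, non-overlapping 1-based inclusive gene spans and exons."""

    genes: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    exons: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.genes, self.exons):
            for chrom, ivs in table.items():
                table[chrom] = sorted(tuple(iv) for iv in ivs)


def substitution_type(ref: str, alt: str) -> str:
    """Transition (purine<->purine, pyrimidine<->pyrimidine) or transversion."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"invalid alleles {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    pair = {ref, alt}
    return "transition" if pair in _TRANSITIONS else "transversion"


def _contains(intervals: List[Tuple[int, int]], pos: int) -> bool:
    i = bisect.bisect_right(intervals, (pos, float("inf"))) - 1
    return i >= 0 and intervals[i][0] <= pos <= intervals[i][1]


def annotate_region(chrom: str, pos: int, model: GeneModel, strict: bool = False) -> str:
    """Region class of a position: exonic beats intronic beats intergenic."""
    if pos < 1:
        raise ValueError("positions are 1-based")
    if chrom not in model.genes and chrom not in model.exons:
        if strict:
            raise KeyError(f"unknown chromosome {chrom!r}")
        warnings.warn(f"chromosome {chrom!r} absent from gene model; intergenic")
        return "intergenic"
    if _contains(model.exons.get(chrom, []), pos):
        return "exonic"
    if _contains(model.genes.get(chrom, []), pos):
        return "intronic"
    return "intergenic"


def classify_site(v: CloneGenotypeVector) -> ClassifiedVariant:
    """Assign the SNP / SC / Sh / complex class of a four-clone site."""
    if len(v.genotypes) != 4:
        raise ValueError("classification is defined for exactly four clones")
    gts = dict(v.genotypes)
    states = set(gts.values())
    if states == {"hom_ref"}:
        raise InvariantSiteError(f"{v.key}: all clones homozygous reference")

    sub = substitution_type(v.key[2], v.key[3])

    def result(cls: str, focal: Iterable[str] = ()) -> ClassifiedVariant:
        return ClassifiedVariant(v.key, cls, frozenset(focal), sub)

    if len(states) == 1:
        return result("SNP")

    by_state: Dict[str, List[str]] = {}
    for clone, gt in gts.items():
        by_state.setdefault(gt, []).append(clone)

    if len(states) == 2:
        counts = sorted(by_state.items(), key=lambda kv: len(kv[1]))
        (minor_gt, minor), (major_gt, major) = counts
        if len(minor) == 1:
            if minor_gt == "het" and major_gt == "hom_ref":
                return result("SC_het", minor)
            if minor_gt == "hom_ref" and major_gt == "het":
                return result("SC_ref", minor)
            if minor_gt == "hom_alt" and major_gt in ("het", "hom_ref"):
                return result("SC_hom", minor)
            return result("complex")
        # 2+2 split: focal pair carries the higher-dosage state
        focal_gt = max(states, key=lambda s: _DOSAGE[s])
        focal = by_state[focal_gt]
        return result("Sh_hom" if focal_gt == "hom_alt" else "Sh_het", focal)

    return result("complex")


@dataclass
class ClassificationSummary:
    class_counts: Dict[str, int]
    region_substitution_counts: Dict[Tuple[str, str], int]
    tstv_ratio: Optional[float]

    @property
    def n_snv(self) -> int:
        return sum(n for c, n in self.class_counts.items() if c != "SNP")


def partition_variants(
    vectors: Sequence[CloneGenotypeVector],
    model: Optional[GeneModel] = None,
) -> Tuple[ClassificationSummary, Dict[str, List[ClassifiedVariant]]]:
    """Classify every site and tabulate counts per class, region and ts/tv."""
    seen: set = set()
    per_class: Dict[str, List[ClassifiedVariant]] = {c: [] for c in CLASSES}
    region_sub: Dict[Tuple[str, str], int] = {}
    n_ts = n_tv = 0
    for v in vectors:
        if v.key in seen:
            raise ValueError(f"duplicate site key {v.key}")
        seen.add(v.key)
        cv = classify_site(v)
        if model is not None:
            cv.region = annotate_region(v.key[0], v.key[1], model)
        per_class[cv.var_class].append(cv)
        if cv.substitution == "transition":
            n_ts += 1
        else:
            n_tv += 1
        rkey = (cv.region or "unannotated", cv.substitution)
        region_sub[rkey] = region_sub.get(rkey, 0) + 1
    summary = ClassificationSummary(
        class_counts={c: len(vs) for c, vs in per_class.items()},
        region_substitution_counts=region_sub,
        tstv_ratio=(n_ts / n_tv) if n_tv else None,
    )
    return summary, per_class
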