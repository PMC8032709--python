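"""Genotyping-chip marker selection and informativeness scoring.

A chip assays a small panel of SNVs chosen from the classified list.  Only
heterozygous-alternative variants (SC_het, Sh_het) are eligible: a chip
probe needs an unambiguous biallelic target, and the flanking sequence must
be free of other variable sites near the target and near the window ends
where probes and primers anneal.  Single-clone markers are balanced across
focal clones and spread across chromosomes; shared markers that separate
the two lineage-defining clone pairs are prioritised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .classify import ClassifiedVariant
from .errors import InfeasiblePanelError
from .genotypes import GenotypeMatrix

ELIGIBLE_CLASSES = ("SC_het", "Sh_het")


@dataclass
class MarkerCandidate:
    """A classified variant plus its sequence neighbourhood.

    ``window_length`` is the odd length of the window centred on the target;
    ``neighbor_variants`` are absolute positions of other variants inside it;
    ``flank`` optionally carries the reference bases of the window.
    """

    variant: ClassifiedVariant
    window_length: int = 601
    neighbor_variants: List[int] = field(default_factory=list)
    flank: Optional[str] = None

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0:
            raise ValueError("window length must be odd (target at center)")
        if self.flank is not None and len(self.flank) != self.window_length:
            raise ValueError("flank length must equal window_length")

    @property
    def pos(self) -> int:
        return self.variant.key[1]

    @property
    def chrom(self) -> str:
        return self.variant.key[0]


@dataclass
class PanelConfig:
    panel_size: int = 48
    sc_quota: int = 42
    sh_quota: int = 6
    clear_window_bp: int = 50
    per_clone_balance: bool = True
    chromosome_spread: bool = True

    def __post_init__(self) -> None:
        if self.sc_quota + self.sh_quota != self.panel_size:
            raise ValueError("sc_quota + sh_quota must equal panel_size")


def flank_is_clear(candidate: MarkerCandidate, config: PanelConfig) -> bool:
    """No neighbouring variant within ``clear_window_bp`` of the target or of
    either window end (distance exactly clear_window_bp is acceptable)."""
    half = candidate.window_length // 2
    if candidate.window_length < 2 * config.clear_window_bp + 1:
        raise ValueError("window shorter than twice the clearance distance")
    lo, hi = candidate.pos - half, candidate.pos + half
    for p in candidate.neighbor_variants:
        if p == candidate.pos or not lo <= p <= hi:
            continue
        if abs(p - candidate.pos) < config.clear_window_bp:
            return False
        if p - lo < config.clear_window_bp or hi - p < config.clear_window_bp:
            return False
    return True


def _round_robin_by_chrom(
    cands: List[MarkerCandidate], k: int, rng: np.random.Generator, spread: bool
) -> List[MarkerCandidate]:
    if not spread:
        pool = list(cands)
        rng.shuffle(pool)
        return pool[:k]
    by_chrom: Dict[str, List[MarkerCandidate]] = {}
    for c in sorted(cands, key=lambda c: (c.chrom, c.pos)):
        by_chrom.setdefault(c.chrom, []).append(c)
    for lst in by_chrom.values():
        rng.shuffle(lst)
    chosen: List[MarkerCandidate] = []
    chroms = sorted(by_chrom)
    while len(chosen) < k and any(by_chrom.values()):
        for chrom in chroms:
            if by_chrom[chrom] and len(chosen) < k:
                chosen.append(by_chrom[chrom].pop())
    return chosen


def select_panel(
    candidates: Sequence[MarkerCandidate],
    config: PanelConfig,
    seed: int = 0,
    lineage_pairs: Optional[Sequence[Set[str]]] = None,
) -> List[MarkerCandidate]:
    """Select the chip panel.

    SC_het markers are split as evenly as possible across focal clones;
    Sh_het markers whose focal pair matches one of ``lineage_pairs`` are
    taken first.  Raises :class:`InfeasiblePanelError` naming the shortfall
    when a quota cannot be met.
    """
    rng = np.random.default_rng(seed)
    eligible = [
        c for c in candidates
        if c.variant.var_class in ELIGIBLE_CLASSES and flank_is_clear(c, config)
    ]
    sc = [c for c in eligible if c.variant.var_class == "SC_het"]
    sh = [c for c in eligible if c.variant.var_class == "Sh_het"]

    if len(sh) < config.sh_quota:
        raise InfeasiblePanelError(
            f"need {config.sh_quota} Sh markers, only {len(sh)} eligible"
        )

    panel: List[MarkerCandidate] = []
    if config.per_clone_balance:
        by_clone: Dict[str, List[MarkerCandidate]] = {}
        for c in sc:
            (focal,) = c.variant.focal
            by_clone.setdefault(focal, []).append(c)
        clones = sorted(by_clone)
        if not clones:
            raise InfeasiblePanelError(f"need {config.sc_quota} SC markers, none eligible")
        base, extra = divmod(config.sc_quota, len(clones))
        quotas = {c: base + (1 if i < extra else 0) for i, c in enumerate(clones)}
        for clone in clones:
            picked = _round_robin_by_chrom(
                by_clone[clone], quotas[clone], rng, config.chromosome_spread
            )
            if len(picked) < quotas[clone]:
                raise InfeasiblePanelError(
                    f"clone {clone}: need {quotas[clone]} SC markers, "
                    f"only {len(picked)} eligible"
                )
            panel.extend(picked)
    else:
        picked = _round_robin_by_chrom(sc, config.sc_quota, rng, config.chromosome_spread)
        if len(picked) < config.sc_quota:
            raise InfeasiblePanelError(
                f"need {config.sc_quota} SC markers, only {len(picked)} eligible"
            )
        panel.extend(picked)

    if lineage_pairs:
        pairs = [frozenset(p) for p in lineage_pairs]
        priority = [c for c in sh if frozenset(c.variant.focal) in pairs]
        rest = [c for c in sh if frozenset(c.variant.focal) not in pairs]
    else:
        priority, rest = list(sh), []
    sh_picked = _round_robin_by_chrom(priority, config.sh_quota, rng, config.chromosome_spread)
    if len(sh_picked) < config.sh_quota:
        sh_picked += _round_robin_by_chrom(
            rest, config.sh_quota - len(sh_picked), rng, config.chromosome_spread
        )
    panel.extend(sh_picked)
    return panel


@dataclass
class InformativenessReport:
    """Per-marker alternative-allele carrier counts on a genotyped cohort.

    A marker is informative when at least two samples carry the alternative
    allele (dosage >= 1); ``three_states`` flags markers where all of
    0/1/2 were observed.  All-missing markers are unusable and excluded.
    """

    table: pd.DataFrame  # index marker; columns carrier_count, informative, three_states, usable

    @property
    def informative_markers(self) -> List[str]:
        t = self.table
        return list(t.index[t["usable"] & t["informative"]])


def informativeness(matrix: GenotypeMatrix, min_carriers: int = 2) -> InformativenessReport:
    if not len(matrix.samples):
        raise ValueError("empty genotype matrix")
    rows = []
    for marker in matrix.markers:
        col = matrix.data[marker]
        observed = col.dropna()
        usable = len(observed) > 0
        carriers = int((observed >= 1).sum()) if usable else 0
        states = set(observed.unique()) if usable else set()
        rows.append(
            {
                "marker": marker,
                "carrier_count": carriers,
                "informative": usable and carriers >= min_carriers,
                "three_states": states == {0.0, 1.0, 2.0},
                "usable": usable,
            }
        )
    table = pd.DataFrame(rows).set_index("marker")
    return InformativenessReport(table)
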