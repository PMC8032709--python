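"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (enumeration,
closed forms, path sums) and never calls the package code it checks.
"""

from __future__ import annotations

import itertools
from math import comb
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np


# -- Fisher exact, two-sided, by hypergeometric enumeration ------------------

def fisher_two_sided(table) -> float:
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point_prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(n, r1, c1)
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = point_prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        p = point_prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


# -- exact two-sided rank-sum via enumeration (tie-free, tiny n) -------------

def ranksum_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    # exhaustive null: every assignment of nx ranks out of nx+ny
    us = []
    for subset in itertools.combinations(range(1, nx + ny + 1), nx):
        us.append(sum(subset) - nx * (nx + 1) / 2)
    us = np.array(us)
    mean_u = nx * ny / 2
    extreme = np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-9
    return float(extreme.mean())


# -- four-clone genotype pattern classification, literal rule table ----------

def classify_oracle(pattern: Tuple[str, str, str, str]) -> Tuple[str, FrozenSet[int]]:
    """Classify a 4-tuple of genotypes; returns (class, focal clone indices).

    Written as a direct transcription of the class definitions, structured
    differently from the implementation (explicit pattern matching on sorted
    state counts).
    """
    gts = list(pattern)
    if all(g == "hom_ref" for g in gts):
        return ("invariant", frozenset())
    distinct = sorted(set(gts))
    if len(distinct) == 1:
        return ("SNP", frozenset())
    if len(distinct) >= 3:
        return ("complex", frozenset())
    # exactly two states
    g1, g2 = distinct
    idx1 = frozenset(i for i, g in enumerate(gts) if g == g1)
    idx2 = frozenset(i for i, g in enumerate(gts) if g == g2)
    if len(idx1) == 2:  # 2+2 split; focal pair = higher-dosage state
        dosage = {"hom_ref": 0, "het": 1, "hom_alt": 2}
        hi = g1 if dosage[g1] > dosage[g2] else g2
        focal = idx1 if hi == g1 else idx2
        cls = "Sh_hom" if hi == "hom_alt" else "Sh_het"
        return (cls, focal)
    minority, majority = (g1, g2) if len(idx1) == 1 else (g2, g1)
    focal = idx1 if len(idx1) == 1 else idx2
    if minority == "het" and majority == "hom_ref":
        return ("SC_het", focal)
    if minority == "hom_ref" and majority == "het":
        return ("SC_ref", focal)
    if minority == "hom_alt" and majority in ("het", "hom_ref"):
        return ("SC_hom", focal)
    return ("complex", frozenset())


# -- brute-force Steiner point over dosage profiles --------------------------

def steiner_best(profiles: List[Tuple[int, ...]]) -> Tuple[Tuple[int, ...], int]:
    """Exhaustive search for the profile minimising summed Hamming distance."""
    width = len(profiles[0])
    best, best_cost = None, None
    for cand in itertools.product((0, 1, 2), repeat=width):
        cost = sum(
            sum(1 for a, b in zip(cand, p) if a != b) for p in profiles
        )
        if best_cost is None or cost < best_cost:
            best, best_cost = cand, cost
    return best, best_cost


# -- random additive trees with known splits and path-length distances -------

def random_additive_tree(
    n: int, rng: np.random.Generator
) -> Tuple[List[str], np.ndarray, Set[FrozenSet[str]]]:
    """Random binary tree over n taxa; returns names, path-length distance
    matrix, and the set of nontrivial splits (canonical side excludes the
    alphabetically first taxon)."""
    names = [f"t{chr(ord('a') + i)}" for i in range(n)]
    dist: Dict[Tuple[str, str], float] = {}
    clusters: List[Tuple[FrozenSet[str], Dict[str, float]]] = [
        (frozenset([nm]), {nm: 0.0}) for nm in names
    ]
    splits: Set[FrozenSet[str]] = set()
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (set_i, depth_i) = clusters[i]
        (set_j, depth_j) = clusters[j]
        li = float(rng.uniform(0.1, 1.0))
        lj = float(rng.uniform(0.1, 1.0))
        for a in set_i:
            for b in set_j:
                dist[(a, b)] = dist[(b, a)] = depth_i[a] + li + depth_j[b] + lj
        merged = set_i | set_j
        depths = {a: depth_i[a] + li for a in set_i}
        depths.update({b: depth_j[b] + lj for b in set_j})
        if len(clusters) > 2 and 2 <= len(merged) <= n - 2:
            splits.add(frozenset(merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, depths))
    mat = np.zeros((n, n))
    for a, b in itertools.permutations(range(n), 2):
        mat[a, b] = dist[(names[a], names[b])]
    anchor = sorted(names)[0]
    allset = frozenset(names)
    canon = set()
    for s in splits:
        side = allset - s if anchor in s else s
        if 2 <= len(side) <= n - 2:
            canon.add(side)
    return names, mat, canon


# -- closed-form one-level AMOVA on a squared-distance matrix ----------------

def amova_oracle(d: np.ndarray, labels: Sequence[str]) -> float:
    """Phi_PT by direct transcription of the sums-of-squares formulas."""
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    sizes = []
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        sizes.append(len(idx))
        ss_within += sum(
            d[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]
        ) / len(idx)
    ss_among = ss_total - ss_within
    df_a, df_w = len(groups) - 1, n - len(groups)
    vw = ss_within / df_w
    n0 = (n - sum(s * s for s in sizes) / n) / df_a
    va = (ss_among / df_a - vw) / n0
    return va / (va + vw)
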