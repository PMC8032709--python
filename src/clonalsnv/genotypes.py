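"""Multilocus genotypes and the median-joining network.

A genotyping-chip run yields a samples x markers table of biallelic allele
dosages (0 = homozygous reference, 1 = heterozygous, 2 = homozygous
alternative, missing allowed).  Samples with indistinguishable profiles are
collapsed into multilocus genotypes (MLGs); the relationships among MLGs are
summarised as a median-joining network: an epsilon-relaxed minimum spanning
network over the observed profiles, augmented with inferred median (Steiner)
profiles that shorten three-way connections, with unsupported medians pruned.

Each marker is treated as one multistate character with states {0, 1, 2}, so
a 0<->2 change counts as a single mutational step by default (character-state
semantics); set ``dosage_steps=True`` for dosage-difference steps instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

Profile = Tuple[float, ...]  # dosages, np.nan for missing

_MISSING = -1  # internal integer code for missing


@dataclass
class GenotypeMatrix:
    """Samples x markers allele-dosage table; NaN encodes missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate marker ids")
        values = self.data.to_numpy()
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def samples(self) -> List[str]:
        return list(self.data.index)

    @property
    def markers(self) -> List[str]:
        return list(self.data.columns)

    def profile(self, sample: str) -> Profile:
        return tuple(self.data.loc[sample])

    def all_missing_fraction(self) -> float:
        return float(np.isnan(self.data.to_numpy()).mean())


@dataclass
class MultilocusGenotype:
    name: str
    profile: Profile
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a genotype must have at least one member")

    @property
    def singleton(self) -> bool:
        return len(self.members) == 1


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    both = ~np.isnan(a) & ~np.isnan(b)
    return bool(np.all(a[both] == b[both]))


def collapse_genotypes(
    m: GenotypeMatrix, missing_policy: str = "match_any"
) -> List[MultilocusGenotype]:
    """Group samples with identical multilocus profiles.

    ``match_any`` (default): a missing entry is compatible with any state; a
    sample joins the first existing group it does not conflict with, and the
    group consensus fills in states the new member resolves.  ``strict``:
    profiles must be identical including missingness.

    Genotypes are named MLG01, MLG02, ... by descending member count, ties
    broken by the lexicographically smallest member id.
    """
    if missing_policy not in ("match_any", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    groups: List[Tuple[np.ndarray, List[str]]] = []  # (consensus, members)
    for sample in m.samples:
        row = m.data.loc[sample].to_numpy(dtype=float)
        placed = False
        for consensus, members in groups:
            if missing_policy == "strict":
                same = np.array_equal(consensus, row, equal_nan=True)
            else:
                same = _compatible(consensus, row)
            if same:
                members.append(sample)
                if missing_policy == "match_any":
                    fill = np.isnan(consensus) & ~np.isnan(row)
                    consensus[fill] = row[fill]
                placed = True
                break
        if not placed:
            groups.append((row.copy(), [sample]))

    order = sorted(groups, key=lambda g: (-len(g[1]), min(g[1])))
    width = max(2, len(str(len(order))))
    return [
        MultilocusGenotype(
            name=f"MLG{i + 1:0{width}d}",
            profile=tuple(consensus),
            members=frozenset(members),
        )
        for i, (consensus, members) in enumerate(order)
    ]


def hamming_steps(
    a: Profile, b: Profile, dosage_steps: bool = False
) -> int:
    """Mutational steps between two profiles; missing excluded pairwise."""
    av, bv = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("profiles must cover the same markers")
    both = ~np.isnan(av) & ~np.isnan(bv)
    if dosage_steps:
        return int(np.abs(av[both] - bv[both]).sum())
    return int(np.sum(av[both] != bv[both]))


@dataclass
class MJNetwork:
    """Median-joining network over multilocus genotypes.

    ``graph`` is an undirected networkx graph whose nodes carry ``profile``
    and ``is_median`` attributes and whose edges carry ``steps``.
    """

    graph: nx.Graph
    observed: List[str]
    medians: List[str]
    epsilon: int = 0

    @property
    def edges(self) -> List[Tuple[str, str, int]]:
        return sorted(
            (min(u, v), max(u, v), d["steps"]) for u, v, d in self.graph.edges(data=True)
        )


def _int_profiles(profiles: Mapping[str, Profile]) -> Dict[str, np.ndarray]:
    out = {}
    for name, p in profiles.items():
        arr = np.asarray(p, dtype=float)
        ints = np.where(np.isnan(arr), _MISSING, arr).astype(int)
        out[name] = ints
    return out


def _steps(a: np.ndarray, b: np.ndarray, dosage_steps: bool) -> int:
    both = (a != _MISSING) & (b != _MISSING)
    if dosage_steps:
        return int(np.abs(a[both] - b[both]).sum())
    return int(np.sum(a[both] != b[both]))


def _msn_edges(
    names: Sequence[str], vecs: Dict[str, np.ndarray], epsilon: int, dosage_steps: bool
) -> List[Tuple[str, str, int]]:
    """Epsilon-relaxed minimum spanning network.

    An edge of weight d is feasible iff its endpoints are not already
    connected using only edges of weight < d - epsilon; all tied edges at
    the connecting level are retained (Kruskal with delayed unions).
    """
    pairs = [
        (u, v, _steps(vecs[u], vecs[v], dosage_steps))
        for u, v in itertools.combinations(sorted(names), 2)
    ]
    pairs.sort(key=lambda e: (e[2], e[0], e[1]))
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(u: str, v: str) -> None:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv

    edges: List[Tuple[str, str, int]] = []
    levels = sorted({w for _, _, w in pairs})
    by_level = {d: [e for e in pairs if e[2] == d] for d in levels}
    for d in levels:
        # bring the union-find up to date with levels < d - epsilon
        for prior in levels:
            if prior < d - epsilon:
                for u, v, _ in by_level[prior]:
                    union(u, v)
        keep = [(u, v, w) for u, v, w in by_level[d] if find(u) != find(v)]
        edges.extend(keep)
    return edges


def _majority_profile(trio: Sequence[np.ndarray]) -> np.ndarray:
    """Per-character majority state; 3-way ties keep the first profile's state."""
    stacked = np.stack(trio)
    out = stacked[0].copy()
    for j in range(stacked.shape[1]):
        col = stacked[:, j]
        vals, counts = np.unique(col[col != _MISSING], return_counts=True)
        if vals.size and counts.max() >= 2:
            out[j] = vals[np.argmax(counts)]
    return out


def median_joining(
    genotypes: Sequence[MultilocusGenotype],
    epsilon: int = 0,
    dosage_steps: bool = False,
    max_rounds: int = 20,
) -> MJNetwork:
    """Build the median-joining network of a set of multilocus genotypes.

    Median (Steiner) profiles are proposed as the per-marker majority state
    of triplets that are mutually adjacent or share a neighbour in the
    current spanning network, and accepted when they strictly shorten the
    triplet's connection cost.  After closure, medians of degree <= 2 are
    pruned (their removal cannot shorten any path under a metric distance).
    """
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    widths = {len(g.profile) for g in genotypes}
    if len(widths) != 1:
        raise ValueError("genotypes cover inconsistent marker sets")
    profiles: Dict[str, Profile] = {g.name: g.profile for g in genotypes}
    vecs = _int_profiles(profiles)
    observed = sorted(profiles)
    median_count = 0

    for _ in range(max_rounds):
        edges = _msn_edges(list(vecs), vecs, epsilon, dosage_steps)
        graph = nx.Graph()
        graph.add_nodes_from(vecs)
        graph.add_weighted_edges_from(edges, weight="steps")
        new_medians: Dict[str, np.ndarray] = {}
        existing = {tuple(v) for v in vecs.values()}
        for u, v, w in sorted(
            (t for t in _candidate_triples(graph)), key=lambda t: tuple(sorted(t))
        ):
            trio = [vecs[n] for n in sorted((u, v, w))]
            med = _majority_profile(trio)
            key = tuple(med)
            if key in existing:
                continue
            d = [_steps(med, t, dosage_steps) for t in trio]
            pair = [
                _steps(trio[i], trio[j], dosage_steps)
                for i, j in ((0, 1), (0, 2), (1, 2))
            ]
            star_cost = sum(d)
            two_edge_cost = sum(pair) - max(pair)
            if star_cost < two_edge_cost:
                median_count += 1
                name = f"mv{median_count}"
                new_medians[name] = med
                existing.add(key)
        if not new_medians:
            break
        vecs.update(new_medians)

    edges = _msn_edges(list(vecs), vecs, epsilon, dosage_steps)
    graph = nx.Graph()
    for name, vec in vecs.items():
        graph.add_node(
            name,
            profile=tuple(np.where(vec == _MISSING, np.nan, vec).astype(float)),
            is_median=name not in observed,
        )
    graph.add_weighted_edges_from(edges, weight="steps")

    # prune unsupported medians (degree <= 2); reconnect through the rest
    changed = True
    while changed:
        changed = False
        for name in sorted(n for n in graph if graph.nodes[n]["is_median"]):
            if graph.degree(name) <= 2:
                neighbors = list(graph.neighbors(name))
                graph.remove_node(name)
                del vecs[name]
                if len(neighbors) == 2:
                    u, v = neighbors
                    if not nx.has_path(graph, u, v):
                        graph.add_edge(u, v, steps=_steps(vecs[u], vecs[v], dosage_steps))
                changed = True
                break

    # medians may have displaced direct links between observed genotypes with
    # longer multi-hop detours; restore the observed backbone wherever the
    # network path exceeds the direct distance, so the network always
    # contains a spanning structure of minimum-spanning-tree weight over the
    # observed genotypes
    obs_vecs = {n: vecs[n] for n in observed}
    for u, v, w in _msn_edges(observed, obs_vecs, epsilon, dosage_steps):
        if graph.has_edge(u, v):
            continue
        try:
            sp = nx.shortest_path_length(graph, u, v, weight="steps")
        except nx.NetworkXNoPath:
            sp = None
        if sp is None or sp > w:
            graph.add_edge(u, v, steps=w)

    medians = sorted(n for n in graph if graph.nodes[n]["is_median"])
    return MJNetwork(graph=graph, observed=observed, medians=medians, epsilon=epsilon)


def _candidate_triples(graph: nx.Graph):
    seen = set()
    for u in graph:
        nbrs = sorted(graph.neighbors(u))
        for v, w in itertools.combinations(nbrs, 2):
            trio = tuple(sorted((u, v, w)))
            if trio not in seen:
                seen.add(trio)
                yield trio
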