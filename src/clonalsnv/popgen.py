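"""Codominant genotypic distances, PCoA and AMOVA (Phi_PT).

The per-locus distance between two codominant biallelic genotypes is the
squared dosage difference (Smouse-Peakall): 0 for identical genotypes, 1
between a homozygote and a heterozygote, 4 between opposite homozygotes.
The summed squared distance matrix feeds a principal coordinates analysis
(Gower double-centering and eigendecomposition) and an analysis of
molecular variance whose differentiation statistic

    Phi_PT = Va / (Va + Vw)

is the among-group fraction of the total molecular variance, with a
permutation p-value obtained by shuffling individuals among groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import UndefinedDistanceError

Profile = Sequence[float]


def codominant_distance(a: Profile, b: Profile) -> float:
    """Summed per-locus squared dosage difference; missing excluded pairwise."""
    av, bv = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("profiles must cover the same loci")
    both = ~np.isnan(av) & ~np.isnan(bv)
    if not both.any():
        raise UndefinedDistanceError("no comparable loci")
    return float(np.sum((av[both] - bv[both]) ** 2))


def squared_distance_matrix(
    profiles: Mapping[str, Profile]
) -> Tuple[List[str], np.ndarray]:
    names = list(profiles)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = codominant_distance(profiles[names[i]], profiles[names[j]])
    return names, d


@dataclass
class PCoAResult:
    names: List[str]
    coordinates: np.ndarray  # taxa x axes, positive eigenvalues only
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # per positive axis, sums to 100

    def as_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.names, columns=cols)


def pcoa(d: np.ndarray, names: Optional[Sequence[str]] = None) -> PCoAResult:
    """Principal coordinates of a squared-distance matrix.

    Gower centering B = -1/2 J d J with J = I - 11'/n, eigendecomposition of
    B, coordinates scaled by the square root of each positive eigenvalue.
    Percent variance is computed over positive eigenvalues only.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("input must be a symmetric square matrix")
    if names is None:
        names = [f"t{i + 1}" for i in range(n)]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval).max()) if n else 0
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pct = 100.0 * eigval[pos] / eigval[pos].sum() if pos.any() else np.array([])
    return PCoAResult(list(names), coords, eigval, pct)


@dataclass
class AMOVAResult:
    ss_total: float
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    va: float  # among-group variance component (raw, may be negative)
    vw: float  # within-group component
    n0: float  # average group-size coefficient
    phi_pt: float  # clamped at 0 for reporting
    phi_pt_raw: float
    p_value: Optional[float]
    n_permutations: int


def _ss(d: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared deviations of a group from pairwise squared distances:
    (1/n) * sum_{i<j in group} d2_ij."""
    sub = d[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * len(idx)))


def _phi_from_labels(
    d: np.ndarray, codes: np.ndarray, n_groups: int
) -> Tuple[float, float, float, float]:
    n = d.shape[0]
    ss_total = float(d.sum() / (2 * n))
    ss_within = 0.0
    sizes = np.zeros(n_groups)
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sizes[g] = len(idx)
        ss_within += _ss(d, idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    vw = ss_within / df_within
    n0 = (n - (sizes**2).sum() / n) / df_among
    va = (ss_among / df_among - vw) / n0
    phi_raw = va / (va + vw) if (va + vw) != 0 else 0.0
    return phi_raw, ss_total, ss_among, ss_within


def amova_phipt(
    d: np.ndarray,
    groups: Mapping[str, str] | Sequence[str],
    names: Optional[Sequence[str]] = None,
    n_perm: int = 900,
    seed: int = 0,
) -> AMOVAResult:
    """One-level AMOVA on a squared codominant distance matrix.

    SS_total = (1/N) sum_{i<j} d2_ij; SS_within sums the analogous per-group
    terms; variance components follow the method-of-moments estimator with
    the unequal-group-size coefficient n0.  The p-value is the proportion of
    ``n_perm`` random reassignments of individuals to groups (sizes fixed)
    whose Phi_PT is >= the observed one, computed as (count+1)/(n_perm+1).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("AMOVA needs at least three individuals")
    if isinstance(groups, Mapping):
        if names is None:
            names = list(groups)
        labels = [groups[name] for name in names]
    else:
        labels = list(groups)
    if len(labels) != n:
        raise ValueError("one group label per individual required")
    unique = sorted(set(labels))
    if len(unique) < 2:
        raise ValueError("AMOVA needs at least two groups")
    codes = np.array([unique.index(l) for l in labels])
    if np.bincount(codes, minlength=len(unique)).min() < 1:
        raise ValueError("every group needs at least one member")

    phi_raw, ss_total, ss_among, ss_within = _phi_from_labels(d, codes, len(unique))
    df_among, df_within = len(unique) - 1, n - len(unique)
    vw = ss_within / df_within
    sizes = np.bincount(codes, minlength=len(unique)).astype(float)
    n0 = (n - (sizes**2).sum() / n) / df_among
    va = (ss_among / df_among - vw) / n0

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            phi_perm = _phi_from_labels(d, perm, len(unique))[0]
            if phi_perm >= phi_raw - 1e-12:
                count += 1
        p_value = (count + 1) / (n_perm + 1)

    return AMOVAResult(
        ss_total=ss_total, ss_among=ss_among, ss_within=ss_within,
        df_among=df_among, df_within=df_within,
        va=va, vw=vw, n0=n0,
        phi_pt=max(phi_raw, 0.0), phi_pt_raw=phi_raw,
        p_value=p_value, n_permutations=n_perm,
    )
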