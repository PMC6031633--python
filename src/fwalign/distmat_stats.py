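"""Statistics on dissimilarity matrices: PERMANOVA and PCoA.

PERMANOVA partitions the total sum of squared dissimilarities into
between- and within-group components and tests the pseudo-F ratio by
permuting group labels.  Principal coordinate analysis embeds the
matrix in Euclidean space by eigendecomposition of the Gower-centered
squared dissimilarities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .ensemble import DissimilarityMatrix

log = logging.getLogger(__name__)

__all__ = ["PermanovaResult", "PcoaResult", "permanova",
           "pairwise_permanova", "pcoa", "group_centers"]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    p_value: float
    n_permutations: int
    seed: int | None = None

    def __str__(self):
        return (f"PERMANOVA: F_{{{self.df_between},{self.df_within}}} = "
                f"{self.pseudo_F:.4g}, p = {self.p_value:.4g} "
                f"({self.n_permutations} permutations)")


@dataclass(frozen=True)
class PcoaResult:
    coordinates: np.ndarray       # n x m, column means zero
    eigenvalues: np.ndarray       # descending, all > 0
    proportion_explained: np.ndarray


def _group_vector(matrix: DissimilarityMatrix, groups) -> np.ndarray:
    if groups is None:
        groups = matrix.groups
    if groups is None:
        raise ValueError("no group labels available")
    if isinstance(groups, dict):
        return np.array([groups[i] for i in matrix.ids])
    g = np.asarray(groups)
    if g.shape[0] != len(matrix.ids):
        raise ValueError("groups length does not match matrix")
    return g


def _pseudo_F(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from squared dissimilarities.

    SS_total = (1/n) sum_{i<j} d2_ij;
    SS_within = sum_g (1/n_g) sum_{i<j in g} d2_ij;
    F = ((SS_total - SS_within)/(g - 1)) / (SS_within/(n - g)).
    """
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(codes == g)
        ng = members.size
        sub = d2[np.ix_(members, members)]
        ss_within += np.triu(sub, 1).sum() / ng
    ss_between = ss_total - ss_within
    if ss_within == 0.0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(matrix: DissimilarityMatrix, groups=None,
              n_permutations: int = 9999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    The p-value is the +1-smoothed fraction of label permutations whose
    pseudo-F meets or exceeds the observed one; it can never be 0.
    """
    g = _group_vector(matrix, groups)
    labels, codes = np.unique(g, return_inverse=True)
    n_groups = labels.size
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = labels[sizes < 2]
        raise ValueError(f"singleton group(s): {list(small)}")
    d2 = matrix.values ** 2
    n = d2.shape[0]
    f_obs = _pseudo_F(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _pseudo_F(d2, codes[perm], n_groups) >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return PermanovaResult(float(f_obs), n_groups - 1, n - n_groups, p,
                           n_permutations, seed)


def pairwise_permanova(matrix: DissimilarityMatrix, groups=None,
                       n_permutations: int = 9999,
                       correction: str = "holm", seed: int = 0
                       ) -> pd.DataFrame:
    """PERMANOVA for every unordered pair of groups, with multiplicity
    correction (Holm by default) applied to the permutation p-values."""
    from statsmodels.stats.multitest import multipletests
    g = _group_vector(matrix, groups)
    labels = np.unique(g)
    rows = []
    for k, (ga, gb) in enumerate(combinations(labels, 2)):
        keep = [i for i, lab in zip(matrix.ids, g) if lab in (ga, gb)]
        sub = matrix.submatrix(keep)
        sub_groups = {i: lab for i, lab in zip(matrix.ids, g) if lab in (ga, gb)}
        res = permanova(sub, sub_groups, n_permutations, seed=seed + k)
        rows.append({"group_a": ga, "group_b": gb,
                     "pseudo_F": res.pseudo_F, "df_between": res.df_between,
                     "df_within": res.df_within, "p_value": res.p_value})
    df = pd.DataFrame(rows)
    if correction and len(df):
        method = {"holm": "holm", "bonferroni": "bonferroni",
                  "fdr_bh": "fdr_bh"}[correction]
        df["p_adjusted"] = multipletests(df.p_value.to_numpy(),
                                         method=method)[1]
    return df


def pcoa(matrix: DissimilarityMatrix, eig_tol: float = 1e-10) -> PcoaResult:
    """Principal coordinate analysis (classical MDS).

    Gower-centers -0.5 * d^2, eigendecomposes, and keeps axes with
    eigenvalue > ``eig_tol`` (negative axes — non-Euclidean structure —
    are dropped with a log note).  Euclidean distances between the
    returned coordinates reproduce the input exactly when it is
    Euclidean-embeddable.
    """
    D = matrix.values
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_neg = int((eigvals < -eig_tol).sum())
    if n_neg:
        log.info("pcoa: dropping %d non-positive eigenvalue axes", n_neg)
    keep = eigvals > eig_tol
    vals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(vals)
    coords = coords - coords.mean(axis=0, keepdims=True)
    prop = vals / vals.sum() if vals.size else vals
    return PcoaResult(coords, vals, prop)


def group_centers(matrix: DissimilarityMatrix, groups=None,
                  n_axes: int = 2) -> pd.DataFrame:
    """Per-group median and standard deviation on the leading principal
    coordinates (the numbers behind group-dispersion ellipses)."""
    g = _group_vector(matrix, groups)
    res = pcoa(matrix)
    m = min(n_axes, res.coordinates.shape[1])
    rows = []
    for lab in np.unique(g):
        pts = res.coordinates[g == lab, :m]
        rows.append({"group": lab, "n": pts.shape[0],
                     **{f"median_axis{k + 1}": float(np.median(pts[:, k]))
                        for k in range(m)},
                     **{f"sd_axis{k + 1}": float(pts[:, k].std(ddof=1))
                        for k in range(m)}})
    return pd.DataFrame(rows)
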