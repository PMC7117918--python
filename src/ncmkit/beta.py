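"""Beta diversity: generalized UniFrac, PERMANOVA and classical PCoA.

Generalized UniFrac between samples A and B is

    d^(alpha) = sum_b L_b (pA + pB)^alpha |pA - pB| / (pA + pB)
              / sum_b L_b (pA + pB)^alpha

over tree branches b, where pA, pB are the relative abundances of the
tips descending from b.  alpha interpolates between unweighted-like
(alpha=0) and weighted-normalized (alpha=1) behavior; alpha=0.5 is the
usual default.  The root's stem branch is excluded (its descendant set is
always the whole community).  PERMANOVA partitions squared distances
(Gower decomposition) into between/within-group sums and assesses the
pseudo-F by seeded label permutation; PCoA is classical scaling of the
double-centered -d^2/2 matrix with negative eigenvalues reported, not
corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _perms

import numpy as np
import pandas as pd

from .core_io import DistanceMatrix, OtuTable, PhyloTree, to_relative_abundance

import logging

log = logging.getLogger("ncmkit")


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    seed: int | None


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame      # samples x axes
    eigenvalues: np.ndarray        # all eigenvalues, descending
    proportion_explained: np.ndarray  # shares of the positive eigenvalue sum


def _branch_decomposition(tree: PhyloTree, taxon_ids) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and a branch x taxon descendant-tip indicator."""
    pos = {t: i for i, t in enumerate(taxon_ids)}
    tips = {t.name for t in tree.tips()}
    missing = [t for t in taxon_ids if t not in tips]
    if missing:
        raise ValueError(f"taxon missing from tree: {missing[0]!r}")
    lengths, rows = [], []
    for node in tree.postorder(include_self=False):
        if node.length is None:
            raise ValueError(f"missing branch length on node {node.name!r}")
        ind = np.zeros(len(taxon_ids), dtype=float)
        for tip in node.tips(include_self=True):
            if tip.name in pos:
                ind[pos[tip.name]] = 1.0
        lengths.append(node.length)
        rows.append(ind)
    return np.asarray(lengths), np.asarray(rows)


def gunifrac(table: OtuTable, tree: PhyloTree, alpha: float = 0.5) -> DistanceMatrix:
    """Generalized UniFrac distance matrix between samples."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    rel = to_relative_abundance(table)
    L, B = _branch_decomposition(tree, table.taxon_ids)
    P = B @ rel.values  # branch x sample descendant-abundance sums
    n = table.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = P[:, i], P[:, j]
            s = pa + pb
            mask = s > 0
            w = L[mask] * s[mask] ** alpha
            denom = w.sum()
            if denom == 0:
                d = 0.0
            else:
                d = float((w * np.abs(pa[mask] - pb[mask]) / s[mask]).sum() / denom)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(table.sample_ids, D)


def _permanova_stats(d2: np.ndarray, groups: np.ndarray):
    """(SS_total, group label list); d2 is the squared distance matrix."""
    n = len(d2)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    return ss_total


def _ss_within(d2: np.ndarray, groups: np.ndarray, labels) -> float:
    ss = 0.0
    for g in labels:
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss


def permanova(dist: DistanceMatrix, groups, n_perm: int | str = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``n_perm="exact"`` enumerates every distinct assignment of the group
    labels (identity included) and reports the exact permutation p-value;
    an integer draws that many seeded random label permutations and uses
    the +1-corrected estimate p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    groups = np.asarray(groups)
    n = len(dist.ids)
    if len(groups) != n:
        raise ValueError("group labels must match distance matrix samples")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or n < 4:
        raise ValueError("need >= 2 groups and >= 4 samples")
    if np.any(counts == 0):
        raise ValueError("empty group")
    k = len(labels)
    d2 = dist.values ** 2
    ss_total = _permanova_stats(d2, groups)
    ss_within = _ss_within(d2, groups, labels)
    ss_between = ss_total - ss_within

    def f_of(g):
        ssw = _ss_within(d2, g, labels)
        if ssw == 0:
            return np.inf
        return ((ss_total - ssw) / (k - 1)) / (ssw / (n - k))

    F = f_of(groups)
    R2 = ss_between / ss_total if ss_total > 0 else 0.0

    if n_perm == "exact":
        seen = set()
        hits = total = 0
        for perm in _perms(range(n)):
            key = tuple(groups[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            total += 1
            if f_of(np.asarray(key)) >= F - 1e-12:
                hits += 1
        p = hits / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(int(n_perm)):
            g = rng.permutation(groups)
            if f_of(g) >= F - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + int(n_perm))
        n_used = int(n_perm)
    return PermanovaResult(float(F), float(R2), float(p), n_used, seed)


def pcoa(dist: DistanceMatrix, k: int = 2) -> PcoaResult:
    """Classical (metric) multidimensional scaling.

    Coordinates are returned for the top-``k`` positive eigenvalues (fewer,
    with a warning, if the matrix has fewer positive eigenvalues);
    negative eigenvalues are reported in ``eigenvalues`` untouched.
    """
    D = dist.values
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(Bmat)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        log.warning("pcoa: only %d positive eigenvalues available (%d requested)",
                    n_pos, k)
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    pos_sum = eigvals[pos].sum()
    shares = np.where(pos[:k_eff], eigvals[:k_eff] / pos_sum, 0.0) if pos_sum > 0 \
        else np.zeros(k_eff)
    frame = pd.DataFrame(coords, index=list(dist.ids),
                         columns=[f"PC{i + 1}" for i in range(k_eff)])
    return PcoaResult(frame, eigvals, shares)
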